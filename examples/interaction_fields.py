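"""Instantaneous interactions and their elementary-mechanism decomposition.

Builds the toxin-nutrient model (one species A that consumes a nutrient n
and degrades a toxin q) and evaluates the instantaneous self-interaction
a'_AA(r) = grad g_A(r) . f_A(r) at several environment states, then scans
a coarse field to locate the sign-change contour.
"""

import numpy as np

import ecofeedback as ef

model = ef.make_toxin_nutrient()

print("a'_AA and its per-factor terms (depletion via n, detoxification via q):")
for n, q in [(1.0, 0.4), (1.0, 0.1), (1.0, 0.0), (0.2, 0.4)]:
    r = ef.EnvironmentState(("n", "q"), [n, q])
    iv = ef.instantaneous_interaction(model, "A", "A", r)
    terms = iv.as_dict()
    print(
        f"  (n={n:4.1f}, q={q:3.1f})  total={iv.total:+.4f}  "
        f"depletion={terms['n']:+.4f}  detox={terms['q']:+.4f}"
    )

# Positive totals mean the population is currently helping itself (detox
# outweighs nutrient competition); negative means self-inhibition.

field = ef.interaction_field(
    model, "A", "A", [np.linspace(0.05, 1.2, 24), np.linspace(0.0, 0.5, 26)]
)
frac_positive = float((field.values > 0).mean())
print(f"\nfield on [0.05,1.2]x[0,0.5]: {frac_positive:.0%} of states are facilitative")
for i in (0, 12, 23):
    row = field.values[i]
    crossing = np.nonzero(np.diff(np.sign(row)) > 0)[0]
    q_at = field.axes[1][crossing[0]] if crossing.size else None
    print(
        f"  n={field.axes[0][i]:.2f}: interaction turns positive at q ~ "
        f"{q_at if q_at is not None else 'never (depletion always wins)'}"
    )
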