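"""Interspecific interaction dynamics in a crossfeeding community.

A degrader D converts a polymer p into a metabolite m that feeds a
crossfeeder C; once p runs low, D switches from net production to net
consumption of m and the two species compete.  The cumulative
interspecific interactions capture both phases.
"""

import numpy as np

import ecofeedback as ef

model = ef.make_degrader_crossfeeder()
traj = ef.integrate(
    model,
    ef.EnvironmentState(("p", "m"), [1.0, 0.0]),
    ef.AbundanceVector(("D", "C"), [0.01, 0.01]),
    30.0,
)
cums = ef.cumulative_interactions(model, traj)

d_on_c = cums[("C", "D")]
c_on_d = cums[("D", "C")]
i_pk = d_on_c.values.argmax()
print(f"D helps C most at t={d_on_c.times[i_pk]:.1f} h "
      f"(cumulative {d_on_c.values[i_pk]:+.3f}), decaying to "
      f"{d_on_c.values[-1]:+.3f} by t=30 h")
t5 = np.searchsorted(traj.times, 5.0)
print(f"C's effect on D: {c_on_d.values[t5]:+.4f} at t=5 h (near neutral), "
      f"{c_on_d.values[-1]:+.4f} at t=30 h (competition)")

# when does D's metabolite flux flip from production to consumption?
flux = np.array([model.impact_at("D", traj.environment[i])[1] for i in range(traj.times.size)])
switch = traj.times[np.nonzero(flux < 0)[0][0]]
print(f"D switches to net metabolite consumption at t={switch:.1f} h "
      f"(polymer then at p={traj.environment[np.nonzero(flux < 0)[0][0], 0]:.3f})")
print(f"final abundances: D={traj.abundances[-1, 0]:.3f}, C={traj.abundances[-1, 1]:.3f}")
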