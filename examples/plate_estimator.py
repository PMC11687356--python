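"""Estimating interactions from two-density growth curves.

Generates a synthetic 96-well plate experiment (4x4 toxin x nutrient
grid, three replicates at each of two inoculation densities, 4:1 ratio,
OD read every 30 min for 120 h, realistic plate-reader noise), then runs
the measured-interaction estimator: background correction, density
normalisation and curve subtraction.  Positive values mean the extra
cells in the high-density wells helped their matched subpopulation.
"""

import ecofeedback as ef

plate, truth = ef.generate_plate_experiment(seed=1)
print(f"plate: {len(plate.series)} wells, {len(truth.conditions)} conditions, "
      f"R = {truth.ratio:.0f}:1")

corrected = ef.background_correct(plate)
print(f"estimated inoculum OD signal kappa = {corrected.metadata['kappa']:.4f}")

print("\ncondition           peak     @hour    final")
for ct in truth.conditions:
    if ct.nutrient0 != 1.0:
        continue  # show one nutrient level; the pattern repeats across levels
    s = ef.summarize(ef.measured_interaction(corrected, ct.condition))
    print(f"{ct.condition:16s} {s.peak:+8.4f}  {s.peak_time:6.1f}  {s.final:+8.4f}")

# Peaks grow with the initial toxin level (density-dependent detox lag),
# the toxin-free condition is neutral until stationary phase, and every
# condition ends negative once nutrient competition dominates.
from ecofeedback.plate import sign_switch_time  # noqa: E402

ct = truth.conditions[-1]
curve = ef.measured_interaction(corrected, ct.condition)
# arm the detector above the noise floor so read noise around zero
# does not register as an early switch
t_meas = sign_switch_time(curve, threshold=0.01)
t_true = ct.cumulative["high"].sign_switch_time()
print(f"\nhighest-toxin condition: measured sign switch at {t_meas:.1f} h, "
      f"true cumulative-interaction switch at {t_true:.1f} h")
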