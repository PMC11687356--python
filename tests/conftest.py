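"""Shared fixtures.

Session-scoped fixtures hold the expensive simulations (the noise-free
synthetic plate and the flowcell scenario runs) so the unit tests and the
acceptance tests share one computation each.
"""

import numpy as np
import pytest

import ecofeedback as ef
from ecofeedback.models import DegraderCrossfeederParams


@pytest.fixture
def tn_model():
    return ef.make_toxin_nutrient()


@pytest.fixture
def dc_model():
    return ef.make_degrader_crossfeeder()


@pytest.fixture(scope="session")
def noise_free_truth():
    """Noise-free synthetic two-density plate over the 4x4 condition grid."""
    plate, truth = ef.generate_plate_experiment(
        noise=ef.NoiseModel(background_mean=0.0, background_sd=0.0, od_sd=0.0),
        seed=7,
    )
    return plate, truth


@pytest.fixture(scope="session")
def noise_free_summaries(noise_free_truth):
    """Corrected plate, measured curves and summaries per condition."""
    plate, truth = noise_free_truth
    corrected = ef.background_correct(plate)
    curves = {}
    summaries = {}
    for ct in truth.conditions:
        curve = ef.measured_interaction(corrected, ct.condition)
        curves[ct.condition] = curve
        summaries[ct.condition] = ef.summarize(curve)
    return corrected, curves, summaries


FLOWCELL_INLET = ef.EnvironmentState(("p", "m"), [1.0, 0.0])


def _niche_run(vx, **overrides):
    cfg = ef.FlowcellConfig(
        inlet=FLOWCELL_INLET,
        vx=vx,
        N=60,
        steady_tol=1e-4,
        t_max=10000.0,
        **overrides,
    )
    model = ef.make_degrader_crossfeeder(DegraderCrossfeederParams())
    prof = ef.simulate_flowcell(model, cfg, np.array([0.01, 0.01]))
    return model, cfg, prof


@pytest.fixture(scope="session")
def niche_runs():
    """Steady flowcell profiles of the crossfeeding community at three flow rates."""
    return {vx: _niche_run(vx) for vx in (5.0, 10.0, 20.0)}


@pytest.fixture(scope="session")
def equivalence_run():
    """Vanishing-washout channel plus the matched batch trajectory."""
    cfg = ef.FlowcellConfig(
        inlet=FLOWCELL_INLET, vx=10.0, N=60, theta=1e-3, steady_tol=1e-4, t_max=10000.0
    )
    scenario = ef.generate_flowcell_scenario(cfg=cfg)
    return scenario
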