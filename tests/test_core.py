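"""Interaction calculus: sensitivities, impacts, gradients, decomposition."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ecofeedback as ef
from ecofeedback.core import finite_difference_gradient
from ecofeedback.functions import Constant, Linear, Monod, Sum, VectorFunction
from ecofeedback.models import ToxinNutrientParams

P = ToxinNutrientParams()


def two_factor_state(n, q):
    return ef.EnvironmentState(("n", "q"), [n, q])


def make_linear_model():
    """g = 2n - q, f = (-1, 0): hand-checkable throughout."""
    sp = ef.SpeciesSpec(
        name="X",
        sensitivity=Linear([2.0, -1.0]),
        impact=VectorFunction([Constant(-1.0, 2), Constant(0.0, 2)]),
    )
    return ef.EOModel(species=[sp], environment=("n", "q"))


class TestEnvironmentState:
    def test_rejects_negative_and_nonfinite(self):
        with pytest.raises(ef.ValidationError):
            ef.EnvironmentState(("n",), [-0.1])
        with pytest.raises(ef.ValidationError):
            ef.EnvironmentState(("n",), [np.nan])

    def test_length_mismatch(self):
        with pytest.raises(ef.ConfigurationError):
            ef.EnvironmentState(("n", "q"), [1.0])

    def test_dict_roundtrip(self):
        r = ef.EnvironmentState.from_dict({"n": 1.0, "q": 0.4})
        assert r.as_dict() == {"n": 1.0, "q": 0.4}
        assert r["q"] == 0.4


class TestSensitivities:
    def test_constant_growth_any_environment(self):
        sp = ef.SpeciesSpec(
            "K", sensitivity=Constant(0.5, 2), impact=VectorFunction([Constant(0.0, 2)] * 2)
        )
        model = ef.EOModel([sp], ("n", "q"))
        for n, q in [(0, 0), (1, 0.4), (10, 3)]:
            assert ef.evaluate_sensitivities(model, two_factor_state(n, q)) == [0.5]

    def test_zero_toxin_limit_is_pure_monod(self, tn_model):
        n = 0.7
        g = ef.evaluate_sensitivities(tn_model, two_factor_state(n, 0.0))[0]
        assert g == pytest.approx(P.mu_max * n / (P.K_n + n), rel=1e-14)

    def test_matches_hand_evaluation(self, tn_model):
        # independent arithmetic: two Monod terms evaluated longhand
        n, q = 1.0, 0.4
        expected = P.mu_max * n / (P.K_n + n) - P.delta_max * q / (P.K_q + q)
        g = ef.evaluate_sensitivities(tn_model, two_factor_state(n, q))[0]
        assert g == pytest.approx(expected, rel=1e-14)

    def test_dimension_mismatch_is_configuration_error(self, tn_model):
        with pytest.raises(ef.ConfigurationError):
            ef.evaluate_sensitivities(tn_model, ef.EnvironmentState(("n",), [1.0]))

    def test_nonfinite_output_names_species(self):
        sp = ef.SpeciesSpec(
            "bad", sensitivity=lambda r: np.inf, impact=VectorFunction([Constant(0.0, 1)])
        )
        model = ef.EOModel([sp], ("n",))
        with pytest.raises(ef.ModelEvaluationError, match="bad"):
            ef.evaluate_sensitivities(model, ef.EnvironmentState(("n",), [1.0]))


class TestImpacts:
    def test_no_organisms_no_autogenic_change(self, tn_model):
        s = ef.AbundanceVector(("A",), [0.0])
        out = ef.evaluate_impacts(tn_model, two_factor_state(1.0, 0.4), s)
        assert np.all(out == 0.0)

    def test_linear_in_abundance(self, tn_model):
        r = two_factor_state(1.0, 0.4)
        one = ef.evaluate_impacts(tn_model, r, ef.AbundanceVector(("A",), [0.5]))
        two = ef.evaluate_impacts(tn_model, r, ef.AbundanceVector(("A",), [1.0]))
        np.testing.assert_allclose(two, 2 * one, rtol=1e-14)

    def test_chemostat_inflow_balances_at_rin(self, tn_model):
        rin = np.array([1.0, 0.4])
        tn_model.allogenic = lambda r: 0.3 * (rin - r)
        r = two_factor_state(*rin)
        s = ef.AbundanceVector(("A",), [0.2])
        with_sigma = ef.evaluate_impacts(tn_model, r, s)
        tn_model.allogenic = None
        autogenic = ef.evaluate_impacts(tn_model, r, s)
        np.testing.assert_allclose(with_sigma, autogenic, rtol=1e-14)

    def test_negative_abundance_rejected(self):
        with pytest.raises(ef.ValidationError):
            ef.AbundanceVector(("A",), [-1.0])


class TestGradient:
    def test_linear_gradient_everywhere(self):
        model = make_linear_model()
        for n, q in [(0.0, 0.0), (1.0, 2.0), (5.0, 0.1)]:
            grad = ef.sensitivity_gradient(model, "X", two_factor_state(n, q))
            np.testing.assert_allclose(grad, [2.0, -1.0], rtol=1e-9)

    @pytest.mark.parametrize("model_name", ["toxin_nutrient", "degrader_crossfeeder"])
    def test_analytic_matches_finite_difference(self, model_name):
        model = ef.load_model(model_name)
        rng = np.random.default_rng(42)
        for _ in range(50):
            rv = rng.uniform(0.05, 2.0, size=2)
            r = ef.EnvironmentState(model.environment, rv)
            for sp in model.species:
                grad = ef.sensitivity_gradient(model, sp.name, r)
                fd = finite_difference_gradient(sp.sensitivity, rv)
                scale = max(np.linalg.norm(grad), 1e-12)
                assert np.abs(grad - fd).max() / scale < 1e-6

    def test_independent_factor_has_zero_component(self, dc_model):
        # crossfeeder C is insensitive to the polymer p
        grad = ef.sensitivity_gradient(
            dc_model, "C", ef.EnvironmentState(("p", "m"), [0.8, 0.3])
        )
        assert grad[0] == 0.0

    def test_one_sided_at_boundary_never_probes_negative(self):
        seen = []

        def g(r):
            seen.append(r.copy())
            return float(r[0] ** 2)

        sp = ef.SpeciesSpec("X", sensitivity=g, impact=VectorFunction([Constant(0.0, 1)]))
        model = ef.EOModel([sp], ("n",))
        ef.sensitivity_gradient(model, "X", ef.EnvironmentState(("n",), [0.0]))
        assert all(r[0] >= 0 for r in seen)


class TestInstantaneousInteraction:
    def test_inert_effector(self):
        sp = ef.SpeciesSpec(
            "X", sensitivity=Linear([1.0, 0.0]), impact=VectorFunction([Constant(0.0, 2)] * 2)
        )
        model = ef.EOModel([sp], ("n", "q"))
        iv = ef.instantaneous_interaction(model, "X", "X", two_factor_state(1.0, 1.0))
        assert iv.total == 0.0
        assert np.all(iv.per_factor == 0.0)

    def test_pure_depletion_hand_value(self):
        iv = ef.instantaneous_interaction(
            make_linear_model(), "X", "X", two_factor_state(1.0, 1.0)
        )
        assert iv.total == pytest.approx(-2.0)  # grad (2,-1) . f (-1,0)
        np.testing.assert_allclose(iv.per_factor, [-2.0, 0.0])

    def test_detox_dominates_at_high_toxin(self, tn_model):
        hi = ef.instantaneous_interaction(tn_model, "A", "A", two_factor_state(1.0, 0.4))
        assert hi.total > 0
        assert hi.per_factor[1] > 0 and hi.per_factor[1] > abs(hi.per_factor[0])
        lo = ef.instantaneous_interaction(tn_model, "A", "A", two_factor_state(1.0, 0.0))
        assert lo.total < 0

    def test_unknown_species_is_lookup_error(self, tn_model):
        with pytest.raises(KeyError):
            ef.instantaneous_interaction(tn_model, "A", "Z", two_factor_state(1, 0))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        n=st.floats(0.0, 5.0, allow_nan=False),
        q=st.floats(0.0, 2.0, allow_nan=False),
        pair=st.sampled_from([("D", "D"), ("D", "C"), ("C", "D"), ("C", "C")]),
    )
    def test_per_factor_sums_to_scalar_product(self, n, q, pair):
        """Closure: the elementary terms reassemble grad g . f exactly."""
        model = ef.make_degrader_crossfeeder()
        r = ef.EnvironmentState(("p", "m"), [n, q])
        iv = ef.instantaneous_interaction(model, pair[0], pair[1], r)
        assert iv.total == pytest.approx(iv.per_factor.sum(), rel=1e-12, abs=1e-300)
        grad = ef.sensitivity_gradient(model, pair[0], r)
        f = model.impact_at(pair[1], r.values)
        assert iv.total == pytest.approx(float(grad @ f), rel=1e-12, abs=1e-15)

    def test_factor_permutation_symmetry(self):
        p = ToxinNutrientParams()
        fwd = ef.make_toxin_nutrient(p)
        # same model with factors in (q, n) order
        sp = ef.SpeciesSpec(
            "A",
            sensitivity=Sum(Monod(p.mu_max, p.K_n, 1, 2), Monod(-p.delta_max, p.K_q, 0, 2)),
            impact=VectorFunction(
                [Monod(-p.d_max, p.K_d, 0, 2), Monod(-p.mu_max / p.Y, p.K_n, 1, 2)]
            ),
        )
        rev = ef.EOModel([sp], ("q", "n"))
        a = ef.instantaneous_interaction(fwd, "A", "A", two_factor_state(1.0, 0.4))
        b = ef.instantaneous_interaction(
            rev, "A", "A", ef.EnvironmentState(("q", "n"), [0.4, 1.0])
        )
        assert a.total == pytest.approx(b.total, rel=1e-14)
        np.testing.assert_allclose(a.per_factor, b.per_factor[::-1], rtol=1e-14)

    def test_impact_scaling_scales_interaction(self, tn_model):
        c = 3.5
        p = ToxinNutrientParams()
        scaled = ef.make_toxin_nutrient(
            ToxinNutrientParams(
                mu_max=p.mu_max,
                K_n=p.K_n,
                delta_max=p.delta_max,
                K_q=p.K_q,
                Y=p.Y / c,  # scales the nutrient impact by c
                d_max=p.d_max * c,  # scales the toxin impact by c
                K_d=p.K_d,
            )
        )
        r = two_factor_state(0.8, 0.3)
        base = ef.instantaneous_interaction(tn_model, "A", "A", r)
        big = ef.instantaneous_interaction(scaled, "A", "A", r)
        assert big.total == pytest.approx(c * base.total, rel=1e-12)


class TestInteractionField:
    def test_degenerate_grid_equals_pointwise(self, tn_model):
        fld = ef.interaction_field(tn_model, "A", "A", [np.array([1.0]), np.array([0.4])])
        iv = ef.instantaneous_interaction(tn_model, "A", "A", two_factor_state(1.0, 0.4))
        assert fld.values.shape == (1, 1)
        assert fld.values[0, 0] == pytest.approx(iv.total, rel=1e-14)

    def test_empty_axis_rejected(self, tn_model):
        with pytest.raises(ef.ValidationError):
            ef.interaction_field(tn_model, "A", "A", [np.array([]), np.array([0.1])])

    def test_toxin_nutrient_field_sign_structure(self, tn_model):
        """Self-interaction: negative at low toxin, one positive high-toxin band.

        Along increasing toxin at fixed nutrient the interaction starts
        negative (pure nutrient depletion) and can turn positive once
        detoxification dominates; because both the detox impact and the
        death-term gradient saturate, the positive band is a single
        contiguous stretch.
        """
        n_ax = np.linspace(0.0, 1.2, 50)
        q_ax = np.linspace(0.0, 0.5, 50)
        fld = ef.interaction_field(tn_model, "A", "A", [n_ax, q_ax])
        assert fld.values.shape == (50, 50)
        assert np.all(fld.values[1:, 0] < 0)  # toxin-free column: depletion only
        saw_positive = False
        for i, n in enumerate(n_ax):
            if n <= 0:
                continue
            row = fld.values[i, :]
            signs = np.sign(row)
            nonzero = signs[signs != 0]
            assert nonzero[0] < 0  # low toxin: depletion dominates
            pos = np.nonzero(row > 0)[0]
            if pos.size:
                saw_positive = True
                assert np.all(np.diff(pos) == 1)  # one contiguous positive band
        assert saw_positive  # the detox-dominated region exists on this window

    def test_crossfeeder_field_sign_regions(self, dc_model):
        p_ax = np.linspace(0.0, 1.2, 50)
        m_ax = np.linspace(0.0, 0.8, 50)
        fld = ef.interaction_field(dc_model, "C", "D", [p_ax, m_ax])
        assert fld.values[-1, 1] > 0  # plenty of polymer: enrichment of C
        assert fld.values[0, -1] < 0  # no polymer, metabolite present: depletion
        df = fld.to_dataframe()
        assert set(df.columns) == {"p", "m", "value"}
        assert len(df) == 2500
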