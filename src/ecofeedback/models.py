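"""Built-in EO models: toxin-nutrient detoxifier and degrader-crossfeeder.

Both are Monod-based consumer-resource models assembled from the parametric
function registry, so they carry analytic sensitivity gradients and export
to the YAML/JSON model config format.

Default parameter values are package choices, tuned so that each model
reproduces its qualitative signature from realistic starting conditions: for
the toxin-nutrient model, a self-interaction that is positive under high
toxin (detoxification dominates) and switches to negative as the toxin is
exhausted and nutrient competition takes over; for the degrader-crossfeeder
model, a production-to-consumption switch of the shared metabolite driven
purely by flux balance.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

from .core import EOModel, SpeciesSpec
from .errors import ValidationError
from .functions import Constant, Monod, Sum, VectorFunction

__all__ = [
    "ToxinNutrientParams",
    "DegraderCrossfeederParams",
    "make_toxin_nutrient",
    "make_degrader_crossfeeder",
    "MODEL_CONSTRUCTORS",
]


def _check_positive(params) -> None:
    for f in fields(params):
        v = getattr(params, f.name)
        if not v > 0:
            raise ValidationError(f"parameter {f.name} must be strictly positive, got {v}")


@dataclass(frozen=True)
class ToxinNutrientParams:
    """Kinetics of a single detoxifying consumer A on nutrient n and toxin q.

    mu_max    : maximal growth rate on the nutrient (1/h)
    K_n       : nutrient half-saturation
    delta_max : maximal toxin-induced death rate (1/h)
    K_q       : toxin half-saturation of the death term
    Y         : biomass yield per unit nutrient
    d_max     : maximal per-capita toxin degradation rate
    K_d       : toxin half-saturation of degradation

    Degradation is per-capita enzymatic removal independent of the growth
    state (secreted-enzyme kinetics), so detoxification continues even while
    net growth is negative.
    """

    mu_max: float = 0.8
    K_n: float = 0.5
    delta_max: float = 0.45
    K_q: float = 0.3
    Y: float = 1.0
    d_max: float = 0.8
    K_d: float = 0.1


def make_toxin_nutrient(params: ToxinNutrientParams | None = None) -> EOModel:
    """Single species A over (n, q): Monod growth minus Monod death.

        g_A(n,q) = mu_max n/(K_n+n) - delta_max q/(K_q+q)
        f_A(n,q) = ( -(mu_max/Y) n/(K_n+n),  -d_max q/(K_d+q) )

    Nutrient uptake is tied to the growth term through the yield Y (death
    does not recycle nutrient); toxin removal is growth-independent.
    """
    p = params or ToxinNutrientParams()
    _check_positive(p)
    nf = 2
    sens = Sum(Monod(p.mu_max, p.K_n, 0, nf), Monod(-p.delta_max, p.K_q, 1, nf))
    impact = VectorFunction(
        [Monod(-p.mu_max / p.Y, p.K_n, 0, nf), Monod(-p.d_max, p.K_d, 1, nf)]
    )
    species = SpeciesSpec(name="A", sensitivity=sens, impact=impact)
    return EOModel(
        species=[species],
        environment=("n", "q"),
        name="toxin_nutrient",
        metadata={"params": {f.name: getattr(p, f.name) for f in fields(p)}},
    )


@dataclass(frozen=True)
class DegraderCrossfeederParams:
    """Kinetics of degrader D (polymer p -> metabolite m) and crossfeeder C.

    u_p, K_p : polymer uptake kinetics of D
    phi      : metabolite yield per unit polymer degraded (<= 1, stoichiometric cap)
    u_m, K_m : metabolite uptake kinetics of D
    e_p, e_m : growth efficiencies of D on polymer and on free metabolite
    u_c, K_c : metabolite uptake kinetics of C
    e_c      : growth efficiency of C on the metabolite
    """

    u_p: float = 3.0
    K_p: float = 0.5
    phi: float = 1.0
    u_m: float = 0.5
    K_m: float = 0.5
    e_p: float = 0.3
    e_m: float = 0.3
    u_c: float = 1.0
    K_c: float = 0.5
    e_c: float = 0.45

    def __post_init__(self):
        if self.phi > 1.0:
            raise ValidationError(
                f"phi={self.phi} exceeds the stoichiometric cap of 1 metabolite per polymer"
            )


def make_degrader_crossfeeder(params: DegraderCrossfeederParams | None = None) -> EOModel:
    """Species D and C over (p, m).

        f_D(p,m) = ( -u_p p/(K_p+p),  phi u_p p/(K_p+p) - u_m m/(K_m+m) )
        g_D(p,m) = e_p u_p p/(K_p+p) + e_m u_m m/(K_m+m)
        f_C(p,m) = ( 0,  -u_c m/(K_c+m) )
        g_C(p,m) = e_c u_c m/(K_c+m)

    D's metabolite impact is a flux balance between production from polymer
    degradation and its own uptake: net production while polymer is abundant,
    net consumption once it runs out.  No explicit switch function is needed.
    """
    p = params or DegraderCrossfeederParams()
    _check_positive(p)
    nf = 2
    degrader = SpeciesSpec(
        name="D",
        sensitivity=Sum(Monod(p.e_p * p.u_p, p.K_p, 0, nf), Monod(p.e_m * p.u_m, p.K_m, 1, nf)),
        impact=VectorFunction(
            [
                Monod(-p.u_p, p.K_p, 0, nf),
                Sum(Monod(p.phi * p.u_p, p.K_p, 0, nf), Monod(-p.u_m, p.K_m, 1, nf)),
            ]
        ),
    )
    crossfeeder = SpeciesSpec(
        name="C",
        sensitivity=Monod(p.e_c * p.u_c, p.K_c, 1, nf),
        impact=VectorFunction([Constant(0.0, nf), Monod(-p.u_c, p.K_c, 1, nf)]),
    )
    return EOModel(
        species=[degrader, crossfeeder],
        environment=("p", "m"),
        name="degrader_crossfeeder",
        metadata={"params": {f.name: getattr(p, f.name) for f in fields(p)}},
    )


MODEL_CONSTRUCTORS = {
    "toxin_nutrient": (make_toxin_nutrient, ToxinNutrientParams),
    "degrader_crossfeeder": (make_degrader_crossfeeder, DegraderCrossfeederParams),
}
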