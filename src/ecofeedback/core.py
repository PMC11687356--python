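"""Environment-organism (EO) models and the instantaneous-interaction calculus.

An EO model couples a set of species to a shared chemical environment
r = (r_1, ..., r_F): each species beta carries an *impact function* f_beta(r)
(per-capita rate of change it causes in each environment factor; secretion
positive, consumption negative) and a *sensitivity function* g_alpha(r)
(per-capita growth rate in environment r).  The feedback between the two is
summarised by the instantaneous interaction

    a'_{alpha beta}(r) = grad g_alpha(r) . f_beta(r)

whose sign says whether beta is currently pushing the environment in a
direction that helps (positive) or harms (negative) alpha's growth.  Its
per-factor terms are the elementary mechanisms: enrichment, depletion,
pollution and detoxification.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .errors import ConfigurationError, ModelEvaluationError, ValidationError
from .functions import ScalarFunction

__all__ = [
    "EnvironmentState",
    "AbundanceVector",
    "SpeciesSpec",
    "EOModel",
    "InteractionValue",
    "InteractionField",
    "evaluate_sensitivities",
    "evaluate_impacts",
    "sensitivity_gradient",
    "instantaneous_interaction",
    "interaction_field",
]


def _check_nonneg_finite(values: np.ndarray, what: str) -> None:
    if not np.all(np.isfinite(values)):
        raise ValidationError(f"{what} contains non-finite values: {values}")
    if np.any(values < 0):
        raise ValidationError(f"{what} contains negative values: {values}")


@dataclass(frozen=True)
class EnvironmentState:
    """A position in environment space: named factors and their concentrations."""

    factors: tuple
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "factors", tuple(self.factors))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if len(self.factors) != self.values.shape[-1] or self.values.ndim != 1:
            raise ConfigurationError(
                f"{len(self.factors)} factor names but values shape {self.values.shape}"
            )
        _check_nonneg_finite(self.values, "environment state")

    @classmethod
    def from_dict(cls, d: dict) -> "EnvironmentState":
        return cls(tuple(d.keys()), np.array(list(d.values()), dtype=float))

    def as_dict(self) -> dict:
        return dict(zip(self.factors, self.values.tolist()))

    def __getitem__(self, factor: str) -> float:
        return float(self.values[self.factors.index(factor)])


@dataclass(frozen=True)
class AbundanceVector:
    """Species biomass abundances, in the model's biomass units."""

    species: tuple
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "species", tuple(self.species))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if len(self.species) != self.values.shape[-1] or self.values.ndim != 1:
            raise ConfigurationError(
                f"{len(self.species)} species names but values shape {self.values.shape}"
            )
        _check_nonneg_finite(self.values, "abundance vector")

    @classmethod
    def from_dict(cls, d: dict) -> "AbundanceVector":
        return cls(tuple(d.keys()), np.array(list(d.values()), dtype=float))


@dataclass
class SpeciesSpec:
    """A species: a name plus its sensitivity and impact functions.

    ``sensitivity`` maps the raw environment value vector to a per-capita
    growth rate (1/time); ``impact`` maps it to the per-capita rate of change
    the species causes in each factor (concentration/time per unit biomass).
    ``analytic_gradient`` optionally supplies grad g(r); when absent, and the
    sensitivity is not a registry :class:`ScalarFunction`, gradients fall back
    to central finite differences.
    """

    name: str
    sensitivity: Callable[[np.ndarray], float]
    impact: Callable[[np.ndarray], np.ndarray]
    analytic_gradient: Optional[Callable[[np.ndarray], np.ndarray]] = None

    def gradient_function(self) -> Optional[Callable[[np.ndarray], np.ndarray]]:
        if self.analytic_gradient is not None:
            return self.analytic_gradient
        if isinstance(self.sensitivity, ScalarFunction):
            return self.sensitivity.gradient
        return None


@dataclass
class EOModel:
    """Species with impact/sensitivity functions over a named environment.

    ``allogenic`` is the external (non-organismal) environment forcing
    sigma(r); ``None`` means a *closed* model, for which the cumulative
    interaction decomposition of growth is exact.
    """

    species: list
    environment: tuple
    allogenic: Optional[Callable[[np.ndarray], np.ndarray]] = None
    name: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.environment = tuple(self.environment)
        names = [sp.name for sp in self.species]
        if len(set(names)) != len(names):
            raise ConfigurationError(f"species names must be unique, got {names}")

    @property
    def species_names(self) -> tuple:
        return tuple(sp.name for sp in self.species)

    @property
    def n_factors(self) -> int:
        return len(self.environment)

    @property
    def closed(self) -> bool:
        return self.allogenic is None

    def species_spec(self, name: str) -> SpeciesSpec:
        for sp in self.species:
            if sp.name == name:
                return sp
        raise KeyError(f"unknown species {name!r}; model has {self.species_names}")

    def _check_environment(self, r: EnvironmentState) -> np.ndarray:
        if tuple(r.factors) != self.environment:
            raise ConfigurationError(
                f"environment factors {r.factors} do not match model factors {self.environment}"
            )
        return r.values

    def sensitivity_at(self, name: str, rv: np.ndarray) -> float:
        """Evaluate g_name at a raw value vector, checking finiteness."""
        g = float(self.species_spec(name).sensitivity(rv))
        if not np.isfinite(g):
            raise ModelEvaluationError(
                f"sensitivity of species {name!r} returned {g} at r={rv}"
            )
        return g

    def impact_at(self, name: str, rv: np.ndarray) -> np.ndarray:
        """Evaluate f_name at a raw value vector, checking shape and finiteness."""
        f = np.asarray(self.species_spec(name).impact(rv), dtype=float)
        if f.shape != (self.n_factors,):
            raise ModelEvaluationError(
                f"impact of species {name!r} has shape {f.shape}, expected ({self.n_factors},)"
            )
        if not np.all(np.isfinite(f)):
            raise ModelEvaluationError(f"impact of species {name!r} returned {f} at r={rv}")
        return f


def evaluate_sensitivities(model: EOModel, r: EnvironmentState) -> np.ndarray:
    """Per-capita growth rate g_alpha(r) for every species, in species order."""
    rv = model._check_environment(r)
    return np.array([model.sensitivity_at(sp.name, rv) for sp in model.species])


def evaluate_impacts(model: EOModel, r: EnvironmentState, s: AbundanceVector) -> np.ndarray:
    """Total environment rate of change: sum_beta s_beta f_beta(r) + sigma(r)."""
    rv = model._check_environment(r)
    if tuple(s.species) != model.species_names:
        raise ConfigurationError(
            f"abundance species {s.species} do not match model species {model.species_names}"
        )
    out = np.zeros(model.n_factors)
    for sp, sb in zip(model.species, s.values):
        out += sb * model.impact_at(sp.name, rv)
    if model.allogenic is not None:
        out += np.asarray(model.allogenic(rv), dtype=float)
    return out


def finite_difference_gradient(
    fn: Callable[[np.ndarray], float], rv: np.ndarray
) -> np.ndarray:
    """Central-difference gradient, one-sided at the nonnegative boundary.

    Step h = max(1e-6, 1e-6*|r_rho|) per component; the lower probe is clipped
    so model functions are never evaluated at negative concentrations.
    """
    rv = np.asarray(rv, dtype=float)
    grad = np.zeros_like(rv)
    for i in range(rv.size):
        h = max(1e-6, 1e-6 * abs(rv[i]))
        hi = rv.copy()
        lo = rv.copy()
        hi[i] += h
        if rv[i] - h >= 0:
            lo[i] -= h
            denom = 2 * h
        else:
            denom = h  # forward difference at the boundary
        grad[i] = (float(fn(hi)) - float(fn(lo))) / denom
    return grad


def sensitivity_gradient(model: EOModel, species: str, r: EnvironmentState) -> np.ndarray:
    """grad g_alpha(r): analytic when the species provides it, else central FD."""
    rv = model._check_environment(r)
    sp = model.species_spec(species)
    gfun = sp.gradient_function()
    if gfun is not None:
        grad = np.asarray(gfun(rv), dtype=float)
        if grad.shape != (model.n_factors,):
            raise ModelEvaluationError(
                f"gradient of species {species!r} has shape {grad.shape}"
            )
        return grad
    return finite_difference_gradient(sp.sensitivity, rv)


@dataclass(frozen=True)
class InteractionValue:
    """a'_{target,effector}(r) and its per-factor elementary decomposition.

    ``per_factor[rho] = dg_target/dr_rho * f_effector,rho(r)``; the terms sum
    to ``total``.  A positive total means the effector's environmental impact
    is currently increasing the target's growth rate.
    """

    target: str
    effector: str
    at: EnvironmentState
    total: float
    per_factor: np.ndarray

    def as_dict(self) -> dict:
        return dict(zip(self.at.factors, self.per_factor.tolist()))


def instantaneous_interaction(
    model: EOModel, target: str, effector: str, r: EnvironmentState
) -> InteractionValue:
    """a'_{alpha beta}(r) = grad g_alpha(r) . f_beta(r), with per-factor terms."""
    rv = model._check_environment(r)
    grad = sensitivity_gradient(model, target, r)
    f = model.impact_at(effector, rv)
    per_factor = grad * f
    return InteractionValue(
        target=target,
        effector=effector,
        at=r,
        total=float(per_factor.sum()),
        per_factor=per_factor,
    )


@dataclass
class InteractionField:
    """a'_{alpha beta} evaluated on a rectangular grid over environment space."""

    target: str
    effector: str
    factors: tuple
    axes: tuple  # one 1D coordinate array per factor
    values: np.ndarray  # shape = tuple(len(ax) for ax in axes)

    def to_dataframe(self):
        """Long format: one row per grid point, factor coordinates + value."""
        import pandas as pd

        mesh = np.meshgrid(*self.axes, indexing="ij")
        data = {f: m.ravel() for f, m in zip(self.factors, mesh)}
        data["value"] = self.values.ravel()
        return pd.DataFrame(data)


def interaction_field(
    model: EOModel, target: str, effector: str, axes: Sequence[np.ndarray]
) -> InteractionField:
    """Evaluate the instantaneous interaction over the outer product of axes.

    ``axes`` gives one nonnegative coordinate vector per environment factor,
    in factor order.
    """
    axes = tuple(np.asarray(ax, dtype=float) for ax in axes)
    if len(axes) != model.n_factors:
        raise ConfigurationError(
            f"{len(axes)} axes for a model with {model.n_factors} factors"
        )
    for ax in axes:
        if ax.size == 0:
            raise ValidationError("empty grid axis")
        _check_nonneg_finite(ax, "grid axis")
    shape = tuple(ax.size for ax in axes)
    values = np.empty(shape)
    for idx in itertools.product(*(range(n) for n in shape)):
        rv = np.array([ax[i] for ax, i in zip(axes, idx)])
        r = EnvironmentState(model.environment, rv)
        values[idx] = instantaneous_interaction(model, target, effector, r).total
    return InteractionField(target, effector, model.environment, axes, values)
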