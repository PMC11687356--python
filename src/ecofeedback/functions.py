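"""Parametric scalar functions over the environment space.

Impact and sensitivity functions are built from a small registry of named
forms (constant, linear, Monod, sums and products of these).  Every form
knows its own analytic gradient, so models assembled from the registry get
exact sensitivity gradients for free, and every form serialises to a plain
dict so models round-trip through YAML/JSON configs without executing
arbitrary code.

Forms broadcast over leading axes: called with an (..., F) array of
environment states they return (...) values and (..., F) gradients, which
the spatial simulator relies on for whole-grid evaluation.  Arbitrary
Python callables are still accepted wherever a ``ScalarFunction`` is, at
the cost of config export, analytic gradients and vectorisation.
"""

from __future__ import annotations

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "ScalarFunction",
    "Constant",
    "Linear",
    "Monod",
    "Sum",
    "Product",
    "VectorFunction",
    "function_from_config",
]


class ScalarFunction:
    """A differentiable scalar function of the environment vector r."""

    def __call__(self, r):  # pragma: no cover - abstract
        raise NotImplementedError

    def gradient(self, r):  # pragma: no cover - abstract
        raise NotImplementedError

    def to_config(self) -> dict:  # pragma: no cover - abstract
        raise NotImplementedError


class Constant(ScalarFunction):
    def __init__(self, value: float, n_factors: int):
        self.value = float(value)
        self.n_factors = int(n_factors)

    def __call__(self, r):
        r = np.asarray(r, dtype=float)
        return np.full(r.shape[:-1], self.value)

    def gradient(self, r):
        return np.zeros_like(np.asarray(r, dtype=float))

    def to_config(self):
        return {"form": "constant", "value": self.value}

    def __repr__(self):
        return f"Constant({self.value})"


class Linear(ScalarFunction):
    """c . r + b."""

    def __init__(self, coeffs, intercept: float = 0.0):
        self.coeffs = np.asarray(coeffs, dtype=float)
        self.intercept = float(intercept)

    def __call__(self, r):
        return np.asarray(r, dtype=float) @ self.coeffs + self.intercept

    def gradient(self, r):
        r = np.asarray(r, dtype=float)
        return np.broadcast_to(self.coeffs, r.shape).copy()

    def to_config(self):
        return {
            "form": "linear",
            "coeffs": self.coeffs.tolist(),
            "intercept": self.intercept,
        }

    def __repr__(self):
        return f"Linear(coeffs={self.coeffs.tolist()}, intercept={self.intercept})"


class Monod(ScalarFunction):
    """vmax * r_i / (K + r_i) acting on a single environment factor.

    ``vmax`` may be negative, giving saturating loss terms (toxin-induced
    death, consumption fluxes).
    """

    def __init__(self, vmax: float, K: float, factor_index: int, n_factors: int):
        if K <= 0:
            raise ConfigurationError(f"Monod half-saturation must be positive, got {K}")
        self.vmax = float(vmax)
        self.K = float(K)
        self.factor_index = int(factor_index)
        self.n_factors = int(n_factors)

    def __call__(self, r):
        x = np.asarray(r, dtype=float)[..., self.factor_index]
        return self.vmax * x / (self.K + x)

    def gradient(self, r):
        r = np.asarray(r, dtype=float)
        g = np.zeros_like(r)
        x = r[..., self.factor_index]
        g[..., self.factor_index] = self.vmax * self.K / (self.K + x) ** 2
        return g

    def to_config(self):
        return {
            "form": "monod",
            "vmax": self.vmax,
            "K": self.K,
            "factor_index": self.factor_index,
        }

    def __repr__(self):
        return f"Monod(vmax={self.vmax}, K={self.K}, factor={self.factor_index})"


class Sum(ScalarFunction):
    def __init__(self, *terms: ScalarFunction):
        self.terms = tuple(terms)

    def __call__(self, r):
        out = self.terms[0](r)
        for t in self.terms[1:]:
            out = out + t(r)
        return out

    def gradient(self, r):
        out = self.terms[0].gradient(r)
        for t in self.terms[1:]:
            out = out + t.gradient(r)
        return out

    def to_config(self):
        return {"form": "sum", "terms": [t.to_config() for t in self.terms]}

    def __repr__(self):
        return "Sum(" + ", ".join(map(repr, self.terms)) + ")"


class Product(ScalarFunction):
    def __init__(self, *terms: ScalarFunction):
        self.terms = tuple(terms)

    def __call__(self, r):
        out = self.terms[0](r)
        for t in self.terms[1:]:
            out = out * t(r)
        return out

    def gradient(self, r):
        vals = [np.asarray(t(r), dtype=float) for t in self.terms]
        grad = np.zeros_like(np.asarray(r, dtype=float))
        for i, t in enumerate(self.terms):
            rest = 1.0
            for j, v in enumerate(vals):
                if j != i:
                    rest = rest * v
            grad = grad + np.asarray(rest)[..., None] * t.gradient(r)
        return grad

    def to_config(self):
        return {"form": "product", "terms": [t.to_config() for t in self.terms]}

    def __repr__(self):
        return "Product(" + ", ".join(map(repr, self.terms)) + ")"


class VectorFunction:
    """One scalar form per environment factor; used for impact functions."""

    def __init__(self, components):
        self.components = tuple(components)

    def __call__(self, r):
        return np.stack([np.asarray(c(r), dtype=float) for c in self.components], axis=-1)

    def to_config(self):
        return [c.to_config() for c in self.components]

    def __repr__(self):
        return "VectorFunction(" + ", ".join(map(repr, self.components)) + ")"


_FORMS = {"constant", "linear", "monod", "sum", "product"}


def function_from_config(cfg: dict, n_factors: int) -> ScalarFunction:
    """Rebuild a registered scalar form from its config dict."""
    if not isinstance(cfg, dict) or "form" not in cfg:
        raise ConfigurationError(f"function config must be a dict with a 'form' key, got {cfg!r}")
    form = cfg["form"]
    if form == "constant":
        return Constant(cfg["value"], n_factors)
    if form == "linear":
        coeffs = np.asarray(cfg["coeffs"], dtype=float)
        if coeffs.shape != (n_factors,):
            raise ConfigurationError(
                f"linear coeffs length {coeffs.shape} does not match {n_factors} factors"
            )
        return Linear(coeffs, cfg.get("intercept", 0.0))
    if form == "monod":
        idx = int(cfg["factor_index"])
        if not 0 <= idx < n_factors:
            raise ConfigurationError(f"monod factor_index {idx} out of range")
        return Monod(cfg["vmax"], cfg["K"], idx, n_factors)
    if form == "sum":
        return Sum(*(function_from_config(t, n_factors) for t in cfg["terms"]))
    if form == "product":
        return Product(*(function_from_config(t, n_factors) for t in cfg["terms"]))
    raise ConfigurationError(f"unknown function form {form!r}; known forms: {sorted(_FORMS)}")
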