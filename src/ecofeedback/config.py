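"""Model (de)serialisation to YAML/JSON configs.

A model config names the environment factors, per-species sensitivity and
impact forms from the parametric registry, and an optional allogenic block
(chemostat dilution and inflow composition).  Only registry-built models can
be exported; loading never executes arbitrary code.

Example::

    environment: [n, q]
    species:
      - name: A
        sensitivity: {form: sum, terms: [...]}
        impact: [{form: monod, ...}, {form: monod, ...}]
    allogenic:
      dilution: 0.1
      inflow: {n: 1.0, q: 0.4}
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .core import EOModel, SpeciesSpec
from .errors import ConfigurationError
from .functions import ScalarFunction, VectorFunction, function_from_config
from .models import MODEL_CONSTRUCTORS

__all__ = ["model_to_config", "model_from_config", "load_model", "save_model"]


class _ChemostatInflow:
    """sigma(r) = d * (r_in - r): dilution-driven exchange with fresh media."""

    def __init__(self, dilution: float, inflow: np.ndarray):
        self.dilution = float(dilution)
        self.inflow = np.asarray(inflow, dtype=float)

    def __call__(self, r):
        return self.dilution * (self.inflow - np.asarray(r, dtype=float))


def model_to_config(model: EOModel) -> dict:
    """Serialise a registry-built model to a plain dict."""
    species = []
    for sp in model.species:
        if not isinstance(sp.sensitivity, ScalarFunction) or not isinstance(
            sp.impact, VectorFunction
        ):
            raise ConfigurationError(
                f"species {sp.name!r} uses plain callables; only registry-form "
                "models can be exported to config"
            )
        species.append(
            {
                "name": sp.name,
                "sensitivity": sp.sensitivity.to_config(),
                "impact": sp.impact.to_config(),
            }
        )
    cfg = {"environment": list(model.environment), "species": species}
    if model.name:
        cfg["name"] = model.name
    if isinstance(model.allogenic, _ChemostatInflow):
        cfg["allogenic"] = {
            "dilution": model.allogenic.dilution,
            "inflow": dict(zip(model.environment, model.allogenic.inflow.tolist())),
        }
    elif model.allogenic is not None:
        raise ConfigurationError("only chemostat-style allogenic terms can be exported")
    return cfg


def model_from_config(cfg: dict) -> EOModel:
    """Rebuild an EOModel from a config dict."""
    try:
        factors = tuple(cfg["environment"])
        species_cfg = cfg["species"]
    except (KeyError, TypeError) as exc:
        raise ConfigurationError(f"model config needs 'environment' and 'species': {exc}")
    nf = len(factors)
    species = []
    for sc in species_cfg:
        impact_cfg = sc["impact"]
        if len(impact_cfg) != nf:
            raise ConfigurationError(
                f"species {sc.get('name')!r}: impact has {len(impact_cfg)} components "
                f"for {nf} factors"
            )
        species.append(
            SpeciesSpec(
                name=sc["name"],
                sensitivity=function_from_config(sc["sensitivity"], nf),
                impact=VectorFunction(
                    [function_from_config(c, nf) for c in impact_cfg]
                ),
            )
        )
    allogenic = None
    if "allogenic" in cfg and cfg["allogenic"]:
        blk = cfg["allogenic"]
        inflow = np.array([blk["inflow"][f] for f in factors], dtype=float)
        allogenic = _ChemostatInflow(blk["dilution"], inflow)
    return EOModel(
        species=species, environment=factors, allogenic=allogenic, name=cfg.get("name", "")
    )


def load_model(path) -> EOModel:
    """Load a model from a YAML or JSON config file, or by built-in name."""
    if isinstance(path, str) and path in MODEL_CONSTRUCTORS:
        make, _ = MODEL_CONSTRUCTORS[path]
        return make()
    p = Path(path)
    text = p.read_text()
    cfg = json.loads(text) if p.suffix == ".json" else yaml.safe_load(text)
    return model_from_config(cfg)


def save_model(model: EOModel, path) -> None:
    """Write a registry-built model to a YAML or JSON config file."""
    cfg = model_to_config(model)
    p = Path(path)
    if p.suffix == ".json":
        p.write_text(json.dumps(cfg, indent=2))
    else:
        p.write_text(yaml.safe_dump(cfg, sort_keys=False))
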