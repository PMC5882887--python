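"""YAML serialization of models and gains.

Matrices are stored as nested row-major lists with an explicit ``shape``
field, so non-symmetric matrices cannot be silently transposed on the way
through.  Documents carry a ``schema_version`` and a ``kind`` tag and are
validated on load by reconstructing the domain object (which re-runs all
type invariants).
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import numpy as np
import yaml

from .model import (
    EstimatorGains,
    ExponentialKernel,
    GRNModel,
    UncertaintyStructure,
)

__all__ = ["model_to_dict", "model_from_dict", "save_model", "load_model",
           "save_gains", "load_gains"]

SCHEMA_VERSION = 1


def _mat(a: np.ndarray) -> dict:
    a = np.asarray(a, dtype=float)
    return {"shape": list(a.shape), "rows": a.tolist()}


def _unmat(d: dict, name: str) -> np.ndarray:
    a = np.asarray(d["rows"], dtype=float)
    if list(a.shape) != list(d["shape"]):
        raise ValueError(f"matrix {name}: shape field {d['shape']} != data {a.shape}")
    return a


def model_to_dict(model: GRNModel) -> dict:
    doc = {
        "schema_version": SCHEMA_VERSION,
        "kind": "grn_model",
        "n": model.n,
        "l": model.l,
        "matrices": {
            name: _mat(getattr(model, name))
            for name in ("A", "B", "C", "D", "E", "F", "H", "Lx", "Ly", "M", "N")
        },
        "delays": {
            "rho1": model.rho1, "rho2": model.rho2,
            "delta_m": model.delta_m, "delta_M": model.delta_M,
            "tau_m": model.tau_m, "tau_M": model.tau_M,
        },
        "kernels": {
            "mu": {"family": "exponential", "rate": model.mu_kernel.rate},
            "xi": {"family": "exponential", "rate": model.xi_kernel.rate},
        },
        "dropout": {"alpha0": model.alpha0, "beta0": model.beta0},
        "hill_coeff": model.hill_coeff,
        "extras": model.extras,
    }
    if model.uncertainty is not None:
        u = model.uncertainty
        doc["uncertainty"] = {"R": _mat(u.R)}
        doc["uncertainty"].update({f"W{i}": _mat(u.W[i - 1]) for i in range(1, 7)})
    return doc


def model_from_dict(doc: dict) -> GRNModel:
    if doc.get("kind") != "grn_model":
        raise ValueError("document is not a grn_model")
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(f"unsupported schema_version {doc.get('schema_version')}")
    mats = {k: _unmat(v, k) for k, v in doc["matrices"].items()}
    unc = None
    if "uncertainty" in doc:
        u = doc["uncertainty"]
        unc = UncertaintyStructure(
            R=_unmat(u["R"], "R"),
            **{f"W{i}": _unmat(u[f"W{i}"], f"W{i}") for i in range(1, 7)},
        )
    d = doc["delays"]
    k = doc["kernels"]
    for ch in ("mu", "xi"):
        if k[ch]["family"] != "exponential":
            raise ValueError(f"unknown kernel family {k[ch]['family']!r}")
    return GRNModel(
        **mats,
        rho1=d["rho1"], rho2=d["rho2"],
        delta_m=d["delta_m"], delta_M=d["delta_M"],
        tau_m=d["tau_m"], tau_M=d["tau_M"],
        mu_kernel=ExponentialKernel(k["mu"]["rate"]),
        xi_kernel=ExponentialKernel(k["xi"]["rate"]),
        alpha0=doc["dropout"]["alpha0"],
        beta0=doc["dropout"]["beta0"],
        hill_coeff=doc.get("hill_coeff", 2.0),
        uncertainty=unc,
        extras=doc.get("extras", {}),
    )


def save_model(model: GRNModel, path: Union[str, Path]) -> None:
    Path(path).write_text(
        yaml.safe_dump(model_to_dict(model), sort_keys=False), encoding="utf-8"
    )


def load_model(path: Union[str, Path]) -> GRNModel:
    return model_from_dict(yaml.safe_load(Path(path).read_text(encoding="utf-8")))


def save_gains(gains: EstimatorGains, path: Union[str, Path]) -> None:
    doc = {
        "schema_version": SCHEMA_VERSION,
        "kind": "estimator_gains",
        "matrices": {k: _mat(getattr(gains, k)) for k in ("Ax", "Ay", "Bx", "By")},
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")


def load_gains(path: Union[str, Path]) -> EstimatorGains:
    doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if doc.get("kind") != "estimator_gains":
        raise ValueError("document is not estimator gains")
    m = doc["matrices"]
    return EstimatorGains(**{k: _unmat(m[k], k) for k in ("Ax", "Ay", "Bx", "By")})
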