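"""The 16 data-driven normalization methods, grouped as sample-wise methods
(removing sample-to-sample variation: dilution, baseline differences) and
feature-wise methods (rescaling or transforming each metabolite to tame
heteroscedasticity).

Every method exposes two code paths: fitting on training samples (returning a
persistable reference model) and applying a frozen model to held-out samples,
so validation data never influence the normalization parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from ..datamodel import NormalizedTable, PeakTable

__all__ = [
    "ReferenceModel",
    "SAMPLE_METHODS",
    "FEATURE_METHODS",
    "ALL_METHODS",
    "DISPLAY_NAMES",
    "POSITIVE_REQUIRED",
    "normalize",
    "apply_model",
    "save_model",
    "load_model",
]


@dataclass
class ReferenceModel:
    """Frozen normalization parameters, re-applicable to new samples."""

    method: str
    payload: dict[str, Any] = field(default_factory=dict)
    fitted_on: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        def conv(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            if isinstance(v, (np.floating, np.integer)):
                return v.item()
            return v

        return {
            "method": self.method,
            "fitted_on": list(self.fitted_on),
            "payload": {k: conv(v) for k, v in self.payload.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ReferenceModel":
        payload = {
            k: (np.asarray(v, dtype=float) if isinstance(v, list) and v and isinstance(v[0], (int, float)) else v)
            for k, v in d["payload"].items()
        }
        return cls(method=d["method"], payload=payload, fitted_on=list(d.get("fitted_on", [])))


def save_model(model, path) -> None:
    with open(path, "w") as fh:
        json.dump(model.to_dict(), fh, indent=2)


def load_model(path):
    with open(path) as fh:
        d = json.load(fh)
    from .feature import ScalerParams, VsnParams

    if d.get("type") == "scaler":
        return ScalerParams.from_dict(d)
    if d.get("type") == "vsn":
        return VsnParams.from_dict(d)
    return ReferenceModel.from_dict(d)


from . import sample as _sample  # noqa: E402
from . import feature as _feature  # noqa: E402

SAMPLE_METHODS = (
    "linear_baseline",
    "pqn",
    "mstus",
    "quantile",
    "cyclic_loess",
    "contrast",
    "cubic_splines",
    "li_wong",
)
FEATURE_METHODS = ("auto", "level", "pareto", "range", "vast", "power", "log", "vsn")
ALL_METHODS = SAMPLE_METHODS + FEATURE_METHODS

DISPLAY_NAMES = {
    "linear_baseline": "Linear Baseline",
    "pqn": "PQN",
    "mstus": "MSTUS",
    "quantile": "Quantile",
    "cyclic_loess": "Cyclic Loess",
    "contrast": "Contrast",
    "cubic_splines": "Cubic Splines",
    "li_wong": "Li-Wong",
    "auto": "Auto Scaling",
    "level": "Level Scaling",
    "pareto": "Pareto Scaling",
    "range": "Range Scaling",
    "vast": "Vast Scaling",
    "power": "Power Scaling",
    "log": "Log Transformation",
    "vsn": "VSN",
}

# methods that take logs internally and need strictly positive input
POSITIVE_REQUIRED = frozenset({"cyclic_loess", "contrast", "cubic_splines", "li_wong", "log"})

_SCALER_MODES = ("auto", "level", "pareto", "range", "vast", "power")


def normalize(table: PeakTable, method: str, model=None, **params):
    """Dispatch to one of the 16 methods.

    Returns (NormalizedTable, model). With ``model`` given, the stored
    reference is applied to the table instead of refitting.
    """
    if method not in ALL_METHODS:
        raise ValueError(
            f"unknown method {method!r}; valid methods: {', '.join(ALL_METHODS)}"
        )
    if method in _SCALER_MODES:
        return _feature.scale_features(table, mode=method, model=model, **params)
    if method == "log":
        return _feature.log_transform(table, model=model, **params)
    if method == "vsn":
        return _feature.vsn_fit_transform(table, model=model, **params)
    fn = {
        "linear_baseline": _sample.linear_baseline,
        "pqn": _sample.pqn,
        "mstus": _sample.mstus,
        "quantile": _sample.quantile_normalize,
        "cyclic_loess": _sample.cyclic_loess,
        "contrast": _sample.contrast_normalize,
        "cubic_splines": _sample.cubic_splines,
        "li_wong": _sample.li_wong,
    }[method]
    return fn(table, model=model, **params)


def apply_model(table: PeakTable, model, **params) -> NormalizedTable:
    """Apply a frozen reference model to (held-out) samples."""
    out, _ = normalize(table, model.method, model=model, **params)
    return out
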