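"""Feature-wise normalization: per-metabolite scaling, log transformation and
the variance-stabilizing arsinh transform (VSN).

Scalers use the sample standard deviation (n-1 denominator). VSN fits one
affine pair (a_j, b_j) per sample so that h_j(x) = arsinh((x - a_j)/b_j)
matches a common per-feature reference profile; the fit is a trimmed least
squares (robust to a fraction of outlying features) alternated with reference
updates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import optimize

from ..datamodel import NormalizedTable, PeakTable, Scale
from . import ReferenceModel

__all__ = ["ScalerParams", "VsnParams", "scale_features", "log_transform", "vsn_fit_transform"]

SCALER_MODES = ("auto", "level", "pareto", "range", "vast", "power")


@dataclass
class ScalerParams:
    """Frozen per-feature statistics of one scaler fit."""

    mode: str
    mean: np.ndarray
    sd: np.ndarray
    min: np.ndarray
    max: np.ndarray
    mean_sqrt: np.ndarray | None = None  # used by power scaling
    fitted_on: list[str] = field(default_factory=list)

    @property
    def method(self) -> str:
        return self.mode

    def to_dict(self) -> dict:
        d = {
            "type": "scaler",
            "method": self.mode,
            "mode": self.mode,
            "fitted_on": list(self.fitted_on),
            "mean": self.mean.tolist(),
            "sd": self.sd.tolist(),
            "min": self.min.tolist(),
            "max": self.max.tolist(),
        }
        if self.mean_sqrt is not None:
            d["mean_sqrt"] = self.mean_sqrt.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScalerParams":
        return cls(
            mode=d["mode"],
            mean=np.asarray(d["mean"], dtype=float),
            sd=np.asarray(d["sd"], dtype=float),
            min=np.asarray(d["min"], dtype=float),
            max=np.asarray(d["max"], dtype=float),
            mean_sqrt=np.asarray(d["mean_sqrt"], dtype=float) if "mean_sqrt" in d else None,
            fitted_on=list(d.get("fitted_on", [])),
        )


def _matrix(table: PeakTable) -> np.ndarray:
    x = table.intensities
    if np.isnan(x).any():
        raise ValueError("normalization requires an imputed (complete) table")
    return np.array(x, dtype=float)


def scale_features(
    table: PeakTable,
    mode: str,
    degenerate: str = "error",
    model: ScalerParams | None = None,
) -> tuple[NormalizedTable, ScalerParams]:
    """Apply one of the six per-feature scalers.

    auto: (x-mu)/s; level: (x-mu)/mu; pareto: (x-mu)/sqrt(s);
    range: (x-mu)/(max-min); vast: ((x-mu)/s)*(mu/s); power: sqrt(x) - mean(sqrt(x)).

    Features with a degenerate denominator raise by default; with
    ``degenerate="drop"`` they are removed with a warning.
    """
    if mode not in SCALER_MODES:
        raise ValueError(f"unknown scaler mode {mode!r}; valid: {SCALER_MODES}")
    x = _matrix(table)
    feature_ids = list(table.feature_ids)
    if model is None:
        if mode == "power" and (x < 0).any():
            raise ValueError("power scaling requires nonnegative intensities")
        sqrt_x = np.sqrt(np.clip(x, 0, None))
        model = ScalerParams(
            mode=mode,
            mean=x.mean(axis=1),
            sd=x.std(axis=1, ddof=1),
            min=x.min(axis=1),
            max=x.max(axis=1),
            mean_sqrt=sqrt_x.mean(axis=1) if mode == "power" else None,
            fitted_on=list(table.sample_ids),
        )
    mu, s = model.mean, model.sd
    rng_ = model.max - model.min

    if mode in ("auto", "pareto", "vast"):
        bad = s == 0
    elif mode == "level":
        bad = mu == 0
    elif mode == "range":
        bad = rng_ == 0
    else:
        bad = np.zeros(len(feature_ids), dtype=bool)
    if bad.any():
        offenders = [feature_ids[i] for i in np.flatnonzero(bad)]
        if degenerate == "drop":
            warnings.warn(
                f"{mode} scaling: dropping {len(offenders)} degenerate features", stacklevel=2
            )
            keep = ~bad
            sub = table.select_features([f for f, k in zip(feature_ids, keep) if k])
            submodel = ScalerParams(
                mode=mode,
                mean=mu[keep],
                sd=s[keep],
                min=model.min[keep],
                max=model.max[keep],
                mean_sqrt=model.mean_sqrt[keep] if model.mean_sqrt is not None else None,
                fitted_on=model.fitted_on,
            )
            return scale_features(sub, mode, degenerate="error", model=submodel)
        raise ValueError(f"{mode} scaling: degenerate features {offenders[:10]}")

    if mode == "auto":
        out = (x - mu[:, None]) / s[:, None]
    elif mode == "level":
        out = (x - mu[:, None]) / mu[:, None]
    elif mode == "pareto":
        out = (x - mu[:, None]) / np.sqrt(s)[:, None]
    elif mode == "range":
        out = (x - mu[:, None]) / rng_[:, None]
    elif mode == "vast":
        out = (x - mu[:, None]) / s[:, None] * (mu / s)[:, None]
    else:  # power
        if (x < 0).any():
            raise ValueError("power scaling requires nonnegative intensities")
        out = np.sqrt(x) - model.mean_sqrt[:, None]
    result = NormalizedTable(feature_ids, list(table.sample_ids), out, mode, Scale.RAW)
    return result, model


_LOG_BASES = {"2": 2.0, "e": np.e, "10": 10.0, 2: 2.0, 10: 10.0}


def log_transform(
    table: PeakTable,
    base=2,
    offset_policy: str = "strict",
    model: ReferenceModel | None = None,
    nonpositive: str | None = None,
) -> tuple[NormalizedTable, ReferenceModel]:
    """Elementwise logarithm; turns multiplicative relations additive and
    symmetrizes right-skewed intensity distributions.

    ``offset_policy="half_min"`` replaces non-positive cells by half the
    smallest positive value (stored in the model so held-out samples reuse the
    same epsilon); "strict" raises on non-positive input.
    """
    if nonpositive is not None:  # alias shared with the sample-wise methods
        offset_policy = {"half_min": "half_min", "error": "strict"}[nonpositive]
    if base not in _LOG_BASES:
        raise ValueError("base must be one of 2, 'e', 10")
    b = _LOG_BASES[base]
    x = _matrix(table)
    if model is not None:
        b = float(model.payload["base"])
        eps = model.payload.get("epsilon")
        if eps is not None:
            x = np.where(x <= 0, float(eps), x)
    elif (x <= 0).any():
        if offset_policy == "half_min":
            pos = x[x > 0]
            if pos.size == 0:
                raise ValueError("log transform: no positive values")
            eps = 0.5 * float(pos.min())
            x = np.where(x <= 0, eps, x)
        else:
            rows, cols = np.where(x <= 0)
            cells = [
                (table.feature_ids[r], table.sample_ids[c]) for r, c in zip(rows[:5], cols[:5])
            ]
            raise ValueError(f"log transform requires positive values; offenders include {cells}")
    if model is None:
        eps_used = None
        if offset_policy == "half_min":
            # always recorded, so frozen application to held-out samples that
            # do contain zeros has a well-defined training-derived epsilon
            pos = table.intensities[table.intensities > 0]
            if pos.size:
                eps_used = 0.5 * float(pos.min())
        model = ReferenceModel("log", {"base": b, "epsilon": eps_used}, list(table.sample_ids))
    if (x <= 0).any():
        raise ValueError("log transform: non-positive values remain after epsilon policy")
    out = np.log(x) / np.log(b)
    return (
        NormalizedTable(list(table.feature_ids), list(table.sample_ids), out, "log", Scale.LOG_LIKE),
        model,
    )


# ---------------------------------------------------------------------------
# VSN
# ---------------------------------------------------------------------------


@dataclass
class VsnParams:
    """Per-sample affine parameters of the arsinh variance-stabilizing fit."""

    a: np.ndarray  # per-sample offset
    b: np.ndarray  # per-sample scale, > 0
    trim_q: float
    reference: np.ndarray | None = None
    n_iter: int = 0
    final_change: float = np.inf
    converged: bool = False
    fitted_on: list[str] = field(default_factory=list)

    @property
    def method(self) -> str:
        return "vsn"

    def to_dict(self) -> dict:
        return {
            "type": "vsn",
            "method": "vsn",
            "a": self.a.tolist(),
            "b": self.b.tolist(),
            "trim_q": self.trim_q,
            "reference": self.reference.tolist() if self.reference is not None else None,
            "n_iter": self.n_iter,
            "final_change": float(self.final_change),
            "converged": self.converged,
            "fitted_on": list(self.fitted_on),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VsnParams":
        return cls(
            a=np.asarray(d["a"], dtype=float),
            b=np.asarray(d["b"], dtype=float),
            trim_q=float(d["trim_q"]),
            reference=np.asarray(d["reference"], dtype=float) if d.get("reference") is not None else None,
            n_iter=int(d.get("n_iter", 0)),
            final_change=float(d.get("final_change", np.inf)),
            converged=bool(d.get("converged", False)),
            fitted_on=list(d.get("fitted_on", [])),
        )


def _trimmed_objective(params: np.ndarray, x: np.ndarray, ref: np.ndarray, n_keep: int) -> float:
    """Trimmed profile-likelihood objective for one sample against a FIXED
    reference profile (used for frozen application to held-out samples).

    A pure trimmed sum of squares is scale-degenerate (compressing the
    transform shrinks every residual), so the Gaussian profile likelihood is
    used: m/2 * log(RSS) minus the log-Jacobian sum log h'(x), with
    h'(x) = 1/sqrt(b^2 + (x-a)^2). Trimming keeps the fraction of features
    with the smallest squared residuals; the Jacobian sum runs over the same
    kept set.
    """
    a, log_b = params
    b = np.exp(log_b)
    h = np.arcsinh((x - a) / b)
    r2 = (h - ref) ** 2
    if n_keep < r2.size:
        keep = np.argpartition(r2, n_keep - 1)[:n_keep]
        r2 = r2[keep]
        xk = x[keep]
    else:
        xk = x
    rss = float(r2.sum())
    if rss <= 0:
        rss = np.finfo(float).tiny
    log_jac = -0.5 * float(np.log(b * b + (xk - a) ** 2).sum())
    return 0.5 * n_keep * np.log(rss) - log_jac


def _fit_sample(
    x: np.ndarray, ref: np.ndarray, a0: float, b0: float, trim_q: float
) -> tuple[float, float]:
    """Fit one sample's (a, b) against a fixed reference profile."""
    n_keep = max(int(np.floor(trim_q * x.size)), 2)
    res = optimize.minimize(
        _trimmed_objective,
        np.array([a0, np.log(b0)]),
        args=(x, ref, n_keep),
        method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 600},
    )
    a, log_b = res.x
    return float(a), float(np.exp(log_b))


def _joint_objective_grad(
    theta: np.ndarray, x: np.ndarray, kept: np.ndarray
) -> tuple[float, np.ndarray]:
    """Joint trimmed profile likelihood over all samples' (a_j, log b_j).

    F = sum_j [ m_j/2 * log RSS_j + 1/2 * sum_{i kept j} log(b_j^2 + (x_ij - a_j)^2) ]
    with residuals r_ij = h_ij - ref_i against the per-feature mean reference
    ref_i = mean_j h_ij, h = arsinh((x - a_j)/b_j). The log-Jacobian term makes
    the scale identifiable (it penalizes compressing the transform). Returns
    (value, gradient); ``kept`` flags the per-sample feature sets retained by
    trimming.
    """
    p, n = x.shape
    a = theta[:n]
    b = np.exp(theta[n:])
    xc = x - a[None, :]
    denom2 = b[None, :] ** 2 + xc**2
    g = 1.0 / np.sqrt(denom2)
    h = np.arcsinh(xc / b[None, :])
    ref = h.mean(axis=1)
    r = h - ref[:, None]
    rk = np.where(kept, r, 0.0)
    m = kept.sum(axis=0).astype(float)
    rss = (rk**2).sum(axis=0)
    rss = np.maximum(rss, np.finfo(float).tiny)
    jac = 0.5 * np.where(kept, np.log(denom2), 0.0).sum(axis=0)
    value = float((0.5 * m * np.log(rss)).sum() + jac.sum())

    # dh/da_j = -g ; dh/dlogb_j = -(x - a_j) * g
    w = m / rss  # per-sample weight m_j / RSS_j
    s = (rk * w[None, :]).sum(axis=1)  # per-feature sum_k w_k r_ik over kept
    dh_da = -g
    dh_dlb = -xc * g
    # term1: own-sample residual coupling; term2: through the shared reference
    t1_a = w * (rk * dh_da).sum(axis=0)
    t1_lb = w * (rk * dh_dlb).sum(axis=0)
    t2_a = (s[:, None] * dh_da).sum(axis=0) / n
    t2_lb = (s[:, None] * dh_dlb).sum(axis=0) / n
    g2k = np.where(kept, g**2, 0.0)
    jac_a = -(xc * g2k).sum(axis=0)
    jac_lb = (b[None, :] ** 2 * g2k).sum(axis=0)
    grad = np.concatenate([t1_a - t2_a + jac_a, t1_lb - t2_lb + jac_lb])
    return value, grad


def vsn_fit_transform(
    table: PeakTable,
    trim_q: float = 0.9,
    max_iter: int = 50,
    tol: float = 1e-6,
    model: VsnParams | None = None,
) -> tuple[NormalizedTable, VsnParams]:
    """Variance-stabilizing normalization via per-sample arsinh transforms.

    Alternates (i) reference update: per-feature mean of the transformed
    matrix, and (ii) per-sample trimmed-least-squares fit of (a_j, b_j)
    minimizing the deviation of arsinh((x_ij - a_j)/b_j) from the reference.
    Output is on a natural-log-like scale. With a fitted ``model``, held-out
    samples are fit against the stored (frozen) reference only.
    """
    x = _matrix(table)
    p, n = x.shape
    if n < 2:
        raise ValueError("VSN requires at least 2 samples")
    if not 0.0 < trim_q <= 1.0:
        raise ValueError("trim_q must lie in (0, 1]")

    if model is not None:
        ref = model.reference
        if ref is None:
            raise ValueError("frozen VSN model lacks a reference profile")
        trim_q = model.trim_q
        a = np.empty(n)
        b = np.empty(n)
        for j in range(n):
            a0, b0 = _init_sample(x[:, j])
            a[j], b[j] = _fit_sample(x[:, j], ref, a0, b0, trim_q)
        H = np.arcsinh((x - a[None, :]) / b[None, :])
        out = NormalizedTable(
            list(table.feature_ids), list(table.sample_ids), H, "vsn", Scale.LOG_LIKE
        )
        new_model = VsnParams(
            a=a, b=b, trim_q=trim_q, reference=ref, n_iter=1, final_change=0.0,
            converged=True, fitted_on=list(model.fitted_on),
        )
        return out, new_model

    theta = np.empty(2 * n)
    for j in range(n):
        a0, b0 = _init_sample(x[:, j])
        theta[j] = a0
        theta[n + j] = np.log(b0)
    n_keep = max(int(np.floor(trim_q * p)), 2)
    kept = np.ones((p, n), dtype=bool)
    change = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        res = optimize.minimize(
            _joint_objective_grad,
            theta,
            args=(x, kept),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-9},
        )
        change = max(
            float(np.max(np.abs(res.x[:n] - theta[:n]) / (1.0 + np.abs(theta[:n])))),
            float(np.max(np.abs(res.x[n:] - theta[n:]))),
        )
        theta = res.x
        if not np.all(np.isfinite(theta)):
            raise ValueError("degenerate VSN scale parameter")
        if n_keep >= p:
            break
        # refresh the per-sample trimmed feature sets and refit if they moved
        a, b = theta[:n], np.exp(theta[n:])
        H = np.arcsinh((x - a[None, :]) / b[None, :])
        r2 = (H - H.mean(axis=1)[:, None]) ** 2
        new_kept = np.zeros_like(kept)
        for j in range(n):
            new_kept[np.argpartition(r2[:, j], n_keep - 1)[:n_keep], j] = True
        if np.array_equal(new_kept, kept) or change < tol:
            kept = new_kept
            break
        kept = new_kept
    a, b = theta[:n], np.exp(theta[n:])
    H = np.arcsinh((x - a[None, :]) / b[None, :])
    converged = (n_keep >= p) or (it < max_iter)
    if not converged:
        warnings.warn(
            f"VSN did not converge after {max_iter} iterations (last change {change:.2e}); "
            "returning best iterate",
            stacklevel=2,
        )
    params = VsnParams(
        a=a, b=b, trim_q=trim_q, reference=H.mean(axis=1), n_iter=it,
        final_change=change, converged=converged, fitted_on=list(table.sample_ids),
    )
    out = NormalizedTable(
        list(table.feature_ids), list(table.sample_ids), H, "vsn", Scale.LOG_LIKE
    )
    return out, params


def _init_sample(xj: np.ndarray) -> tuple[float, float]:
    """Starting values: no offset, scale from the low-intensity spread."""
    med = float(np.median(xj))
    b0 = max(med / 10.0, 1e-6)
    return 0.0, b0
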