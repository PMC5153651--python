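"""Seeded generator of LC/MS-like two-class peak tables with known ground truth.

The generator emulates the salient structure of untargeted LC/MS peak tables:
right-skewed base intensities (log-normal feature means), per-sample dilution
(log-normal factors), a two-component additive + multiplicative noise model
(the model variance-stabilizing transforms are designed for), pooled QC
samples with exponential signal drift along the injection sequence, and a
mixture of intensity-dependent (MNAR) and completely-random (MCAR)
missingness in the band reported for real studies (10-40% of cells).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats

from .datamodel import PeakTable, SampleMetadata, ROLE_QC, ROLE_STUDY

__all__ = ["SyntheticSpec", "GroundTruth", "generate", "skewness_check"]


@dataclass
class SyntheticSpec:
    """Parameters of one simulated study.

    noise_a is the SD of additive (background) noise in intensity units;
    noise_b the SD of multiplicative noise on the natural-log scale.
    drift_slope is the per-injection log-scale drift applied to every sample.
    """

    n_features: int = 500
    n_per_class: tuple[int, int] = (60, 60)
    n_qc: int = 12
    n_spikein: int = 25
    effect_fold: float = 2.0
    dilution_sd: float = 0.3
    noise_a: float = 5.0
    noise_b: float = 0.15
    missing_total_frac: float = 0.2
    mnar_weight: float = 0.7
    affected_features_frac: float = 0.8
    drift_slope: float = -0.002
    batches: int = 1
    seed: int = 42
    mu_log_mean: float = 5.5
    mu_log_sd: float = 1.2

    def validate(self) -> None:
        if self.n_spikein > self.n_features:
            raise ValueError("n_spikein exceeds n_features")
        if not 0.0 <= self.missing_total_frac <= 1.0:
            raise ValueError("missing_total_frac must lie in [0, 1]")
        if not 0.0 <= self.mnar_weight <= 1.0:
            raise ValueError("mnar_weight must lie in [0, 1]")
        if not 0.0 < self.affected_features_frac <= 1.0:
            raise ValueError("affected_features_frac must lie in (0, 1]")
        if self.missing_total_frac > self.affected_features_frac:
            raise ValueError(
                "infeasible missingness: missing_total_frac exceeds the affected feature fraction"
            )
        if self.effect_fold < 1.0:
            raise ValueError("effect_fold must be >= 1")
        if self.dilution_sd < 0 or self.noise_a < 0 or self.noise_b < 0:
            raise ValueError("spread parameters must be nonnegative")
        if self.batches < 1:
            raise ValueError("batches must be >= 1")

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticSpec":
        d = dict(d)
        if "n_per_class" in d:
            d["n_per_class"] = tuple(d["n_per_class"])
        return cls(**d)


@dataclass
class GroundTruth:
    spikein_ids: list[str]
    dilution: dict[str, float]
    drift_curve: dict[str, float]
    true_labels: dict[str, str]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


CLASS_NAMES = ("control", "case")


def generate(spec: SyntheticSpec) -> tuple[PeakTable, SampleMetadata, GroundTruth]:
    """Simulate one study; bit-reproducible from ``spec.seed``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n1, n2 = spec.n_per_class
    n_study = n1 + n2
    n_total = n_study + spec.n_qc
    p = spec.n_features

    feature_ids = _feature_ids(rng, p)
    spike_idx = rng.choice(p, size=spec.n_spikein, replace=False)
    spike_mask = np.zeros(p, dtype=bool)
    spike_mask[spike_idx] = True

    sample_ids = [f"S{i + 1:04d}" for i in range(n_study)]
    qc_ids = [f"QC{i + 1:03d}" for i in range(spec.n_qc)]
    labels = [CLASS_NAMES[0]] * n1 + [CLASS_NAMES[1]] * n2

    # base means, right-skewed
    mu = np.exp(rng.normal(spec.mu_log_mean, spec.mu_log_sd, size=p))

    # per-sample dilution; QCs are the same pooled material (dilution 1)
    d_study = np.exp(rng.normal(0.0, spec.dilution_sd, size=n_study))
    dilution = np.concatenate([d_study, np.ones(spec.n_qc)])

    # class effect: spike-in features raised by effect_fold in class 2
    fold = np.ones((p, n_study))
    fold[np.ix_(spike_mask, np.array([lab == CLASS_NAMES[1] for lab in labels]))] = spec.effect_fold

    # injection sequence: QCs interleaved evenly, study order randomized so
    # drift is not confounded with class
    pos = _global_positions(n_study, spec.n_qc)
    pos[:n_study] = pos[:n_study][rng.permutation(n_study)]
    order_all, batch_all = _injection_design(pos, spec.batches)
    drift = np.exp(spec.drift_slope * pos)

    # QC signal: pooled mean of the study design
    pooled_fold = (n1 * 1.0 + n2 * np.where(spike_mask, spec.effect_fold, 1.0)) / n_study
    qc_mu = mu * pooled_fold

    signal = np.empty((p, n_total))
    signal[:, :n_study] = mu[:, None] * fold * dilution[None, :n_study]
    signal[:, n_study:] = qc_mu[:, None] * dilution[None, n_study:]
    signal = signal * drift[None, :]

    eta = rng.standard_normal((p, n_total))
    eps = rng.standard_normal((p, n_total))
    x = signal * np.exp(spec.noise_b * eta) + spec.noise_a * eps
    np.clip(x, 0.0, None, out=x)

    mask = _missingness(
        rng, x, spec.missing_total_frac, spec.mnar_weight, spec.affected_features_frac
    )

    all_ids = sample_ids + qc_ids
    table = PeakTable(feature_ids, all_ids, np.where(mask, np.nan, x), mask)
    meta = SampleMetadata.from_records(
        all_ids,
        labels + ["pool"] * spec.n_qc,
        roles=[ROLE_STUDY] * n_study + [ROLE_QC] * spec.n_qc,
        batches=list(batch_all),
        injection_orders=list(order_all),
    )
    truth = GroundTruth(
        spikein_ids=[feature_ids[i] for i in np.sort(spike_idx)],
        dilution={sid: float(v) for sid, v in zip(all_ids, dilution)},
        drift_curve={sid: float(v) for sid, v in zip(all_ids, drift)},
        true_labels={sid: lab for sid, lab in zip(sample_ids, labels)},
    )
    return table, meta, truth


def _feature_ids(rng: np.random.Generator, p: int) -> list[str]:
    """IDs in the conventional "mz_rt" form."""
    mz = np.round(rng.uniform(80, 1200, size=p), 4)
    rt = np.round(rng.uniform(10, 900, size=p), 1)
    ids = [f"{m:.4f}_{t:.1f}" for m, t in zip(mz, rt)]
    # de-duplicate in the (unlikely) event of a collision
    seen: dict[str, int] = {}
    out = []
    for s in ids:
        if s in seen:
            seen[s] += 1
            s = f"{s}_{seen[s]}"
        else:
            seen[s] = 0
        out.append(s)
    return out


def _global_positions(n_study: int, n_qc: int) -> np.ndarray:
    """Global injection positions (0-based) with QCs evenly interleaved."""
    n_total = n_study + n_qc
    if n_qc == 0:
        return np.arange(n_total, dtype=float)
    qc_pos = np.linspace(0, n_total - 1, n_qc).round().astype(int)
    qc_pos = np.unique(qc_pos)
    while len(qc_pos) < n_qc:  # resolve rounding collisions
        free = np.setdiff1d(np.arange(n_total), qc_pos)
        qc_pos = np.sort(np.append(qc_pos, free[0]))
    study_pos = np.setdiff1d(np.arange(n_total), qc_pos)
    out = np.empty(n_total)
    out[: n_study] = study_pos
    out[n_study:] = qc_pos
    return out.astype(float)


def _injection_design(positions: np.ndarray, batches: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample injection order (1-based, unique within batch) and batch."""
    pos = np.asarray(positions).astype(int)
    n_total = pos.size
    bounds = np.linspace(0, n_total, batches + 1).round().astype(int)
    batch_of = np.empty(n_total, dtype=int)
    order_of = np.empty(n_total, dtype=int)
    for b in range(batches):
        lo, hi = bounds[b], bounds[b + 1]
        sel = (pos >= lo) & (pos < hi)
        batch_of[sel] = b + 1
        order_of[sel] = pos[sel] - lo + 1
    return order_of, batch_of


def _missingness(
    rng: np.random.Generator,
    x: np.ndarray,
    total_frac: float,
    mnar_weight: float,
    affected_frac: float,
) -> np.ndarray:
    """Mixture of intensity-dependent and uniform missingness.

    Only ``affected_frac`` of the features (the lowest-intensity ones, as in
    real tables where dropout tracks abundance) can lose cells; the remaining
    features stay fully observed, which keeps a shared-by-all-samples feature
    set in existence.
    """
    mask = np.zeros(x.shape, dtype=bool)
    p, n = x.shape
    n_cells = x.size
    n_missing = int(round(total_frac * n_cells))
    if n_missing == 0:
        return mask
    n_affected = max(int(round(affected_frac * p)), 1)
    if n_missing > n_affected * n:
        raise ValueError("infeasible missingness fraction for the affected feature set")
    # affected features = those with the lowest mean intensity
    feat_order = np.argsort(x.mean(axis=1), kind="stable")
    affected = feat_order[:n_affected]
    sub = x[affected]  # n_affected x n
    sub_cells = sub.size
    flat = sub.ravel()
    n_mnar = int(round(mnar_weight * n_missing))
    sub_mask = np.zeros(sub_cells, dtype=bool)
    if n_mnar > 0:
        # lowest intensities most likely to drop out
        ranks = stats.rankdata(flat, method="ordinal")
        w = (sub_cells - ranks + 1.0) ** 2
        w /= w.sum()
        mnar_idx = rng.choice(sub_cells, size=n_mnar, replace=False, p=w)
        sub_mask[mnar_idx] = True
    n_mcar = n_missing - n_mnar
    if n_mcar > 0:
        remaining = np.flatnonzero(~sub_mask)
        mcar_idx = rng.choice(remaining, size=n_mcar, replace=False)
        sub_mask[mcar_idx] = True
    mask[affected] = sub_mask.reshape(sub.shape)
    # keep every feature observable at least once so imputation stays defined
    empty = mask.all(axis=1)
    if empty.any():
        for r in np.flatnonzero(empty):
            mask[r, rng.integers(n)] = False
    return mask


def skewness_check(table: PeakTable) -> float:
    """Sample skewness of all observed intensities (0 for a constant matrix)."""
    obs = table.intensities[~table.missing_mask]
    if obs.size < 10:
        raise ValueError("need at least 10 observed values")
    if np.ptp(obs) == 0:
        return 0.0
    return float(stats.skew(obs, bias=False))
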