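"""Core data containers for peak tables, sample metadata and normalized matrices.

The canonical orientation everywhere in this package is *features in rows,
samples in columns*: per-feature statistics are row statistics and per-sample
corrections are column operations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PeakTable",
    "SampleMetadata",
    "NormalizedTable",
    "Scale",
    "ROLE_STUDY",
    "ROLE_QC",
]

ROLE_STUDY = "study"
ROLE_QC = "qc"


class Scale(str, Enum):
    """Scale annotation of a normalized matrix."""

    RAW = "raw"
    LOG_LIKE = "log_like"


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: dict[str, int] = {}
    dups = []
    for i in ids:
        if i in seen:
            dups.append(i)
        seen[i] = 1
    if dups:
        raise ValueError(f"duplicate {what}: {sorted(set(dups))}")


@dataclass
class PeakTable:
    """Feature x sample intensity matrix with an explicit missing mask.

    ``intensities`` holds NaN at missing positions; ``missing_mask`` is True
    exactly where a feature was not detected in a sample.
    """

    feature_ids: list[str]
    sample_ids: list[str]
    intensities: np.ndarray
    missing_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.missing_mask is None:
            self.missing_mask = np.isnan(self.intensities)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        self.validate()

    def validate(self) -> None:
        n_feat, n_samp = self.intensities.shape
        if len(self.feature_ids) != n_feat or len(self.sample_ids) != n_samp:
            raise ValueError("ID lists do not match matrix shape")
        if n_feat < 2 or n_samp < 2:
            raise ValueError("peak table requires at least 2 features and 2 samples")
        _check_unique(self.feature_ids, "feature_ids")
        _check_unique(self.sample_ids, "sample_ids")
        if self.missing_mask.shape != self.intensities.shape:
            raise ValueError("missing_mask shape mismatch")
        obs = self.intensities[~self.missing_mask]
        if np.any(obs[np.isfinite(obs)] < 0):
            rows, cols = np.where((self.intensities < 0) & ~self.missing_mask)
            cells = [(self.feature_ids[r], self.sample_ids[c]) for r, c in zip(rows[:5], cols[:5])]
            raise ValueError(f"negative intensities at {cells}")
        if np.any(np.isnan(obs)):
            raise ValueError("NaN present at positions not flagged missing")
        # keep NaN sentinel in sync with the mask
        self.intensities = self.intensities.copy()
        self.intensities[self.missing_mask] = np.nan

    # -- convenience -------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.intensities.shape

    @property
    def n_features(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[1]

    @property
    def is_complete(self) -> bool:
        return not self.missing_mask.any()

    def sample_index(self, ids: Sequence[str]) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in ids if s not in pos]
        if missing:
            raise KeyError(f"unknown sample ids: {missing}")
        return np.array([pos[s] for s in ids], dtype=int)

    def select_samples(self, ids: Sequence[str]) -> "PeakTable":
        idx = self.sample_index(ids)
        return PeakTable(
            feature_ids=list(self.feature_ids),
            sample_ids=[self.sample_ids[i] for i in idx],
            intensities=self.intensities[:, idx],
            missing_mask=self.missing_mask[:, idx],
        )

    def select_features(self, ids: Sequence[str]) -> "PeakTable":
        pos = {f: i for i, f in enumerate(self.feature_ids)}
        idx = np.array([pos[f] for f in ids], dtype=int)
        return PeakTable(
            feature_ids=[self.feature_ids[i] for i in idx],
            sample_ids=list(self.sample_ids),
            intensities=self.intensities[idx],
            missing_mask=self.missing_mask[idx],
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.intensities, index=self.feature_ids, columns=self.sample_ids)

    def copy(self) -> "PeakTable":
        return PeakTable(
            list(self.feature_ids),
            list(self.sample_ids),
            self.intensities.copy(),
            self.missing_mask.copy(),
        )


class SampleMetadata:
    """Per-sample annotations: class label, role (study/QC), batch, injection order."""

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        required = {"sample_id", "class_label", "role", "batch", "injection_order"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"metadata missing columns: {sorted(missing)}")
        df["sample_id"] = df["sample_id"].astype(str)
        if df["sample_id"].duplicated().any():
            dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValueError(f"duplicate sample ids in metadata: {dups}")
        df["role"] = df["role"].astype(str).str.lower()
        bad = set(df["role"]) - {ROLE_STUDY, ROLE_QC}
        if bad:
            raise ValueError(f"unknown roles: {sorted(bad)}")
        df["batch"] = df["batch"].astype(int)
        if (df["batch"] < 1).any():
            raise ValueError("batch must be >= 1")
        df["injection_order"] = df["injection_order"].astype(int)
        if (df["injection_order"] < 1).any():
            raise ValueError("injection_order must be >= 1")
        for _, grp in df.groupby("batch"):
            if grp["injection_order"].duplicated().any():
                raise ValueError("injection_order must be unique within batch")
        self._df = df.set_index("sample_id", drop=False)

    @classmethod
    def from_records(
        cls,
        sample_ids: Sequence[str],
        class_labels: Sequence,
        roles: Sequence[str] | None = None,
        batches: Sequence[int] | None = None,
        injection_orders: Sequence[int] | None = None,
    ) -> "SampleMetadata":
        n = len(sample_ids)
        df = pd.DataFrame(
            {
                "sample_id": list(sample_ids),
                "class_label": list(class_labels),
                "role": list(roles) if roles is not None else [ROLE_STUDY] * n,
                "batch": list(batches) if batches is not None else [1] * n,
                "injection_order": (
                    list(injection_orders) if injection_orders is not None else list(range(1, n + 1))
                ),
            }
        )
        return cls(df)

    @property
    def df(self) -> pd.DataFrame:
        return self._df

    @property
    def sample_ids(self) -> list[str]:
        return list(self._df["sample_id"])

    def study_ids(self) -> list[str]:
        return list(self._df.loc[self._df["role"] == ROLE_STUDY, "sample_id"])

    def qc_ids(self) -> list[str]:
        return list(self._df.loc[self._df["role"] == ROLE_QC, "sample_id"])

    def study_classes(self) -> list:
        return sorted(self._df.loc[self._df["role"] == ROLE_STUDY, "class_label"].unique().tolist())

    def labels(self, sample_ids: Sequence[str]) -> np.ndarray:
        return self._df.loc[list(sample_ids), "class_label"].to_numpy()

    def injection_orders(self, sample_ids: Sequence[str]) -> np.ndarray:
        return self._df.loc[list(sample_ids), "injection_order"].to_numpy()

    def batches(self, sample_ids: Sequence[str]) -> np.ndarray:
        return self._df.loc[list(sample_ids), "batch"].to_numpy()

    def subset(self, sample_ids: Sequence[str]) -> "SampleMetadata":
        return SampleMetadata(self._df.loc[list(sample_ids)].reset_index(drop=True))

    def check_covers(self, table: PeakTable) -> None:
        known = set(self._df["sample_id"])
        missing = [s for s in table.sample_ids if s not in known]
        if missing:
            raise ValueError(f"samples present in table but absent from metadata: {missing}")

    def check_two_classes(self) -> None:
        classes = self.study_classes()
        if len(classes) != 2:
            raise ValueError(f"classification requires exactly 2 study classes, found {classes}")


@dataclass
class NormalizedTable:
    """Output of one normalization method: same IDs/shape, real-valued matrix."""

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    method: str
    scale: Scale = Scale.RAW

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError("values shape does not match IDs")
        if np.isnan(self.values).any():
            raise ValueError("normalized table contains NaN (input must be imputed)")
        self.scale = Scale(self.scale)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)
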