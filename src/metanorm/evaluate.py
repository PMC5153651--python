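"""Classification-based assessment of normalization performance.

Differential features are selected by the intersection of PLS-DA VIP > 1 and
two-sample t-test p < 0.05; an RBF-kernel SVM tuned by stratified 10-fold
cross-validation is then scored on a held-out validation set via the accuracy
ACC = (TP+TN)/(TP+FP+TN+FN) and the ROC curve / AUC of its decision values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.cross_decomposition import PLSRegression
from sklearn.metrics import roc_curve
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .datamodel import NormalizedTable

__all__ = [
    "PlsdaModel",
    "EvaluationResult",
    "ttest_pvalues",
    "plsda_vip",
    "select_features",
    "train_svm_cv",
    "evaluate_on_validation",
]


def _as_matrix(matrix) -> tuple[np.ndarray, list[str]]:
    """Accept a NormalizedTable or a bare features-x-samples array."""
    if isinstance(matrix, NormalizedTable):
        return matrix.values, list(matrix.feature_ids)
    x = np.asarray(matrix, dtype=float)
    return x, [f"f{i}" for i in range(x.shape[0])]


def _two_classes(labels) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError(f"exactly 2 classes required, found {classes.tolist()}")
    return labels, classes


def ttest_pvalues(matrix, labels, equal_var: bool = False) -> np.ndarray:
    """Per-feature two-sample t-test p-values (Welch by default).

    Features with zero variance in both classes get p = 1 with a warning.
    """
    x, _ = _as_matrix(matrix)
    labels, classes = _two_classes(labels)
    g1 = x[:, labels == classes[0]]
    g2 = x[:, labels == classes[1]]
    if g1.shape[1] < 2 or g2.shape[1] < 2:
        raise ValueError("each class needs at least 2 samples for a t-test")
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(g1, g2, axis=1, equal_var=equal_var)
    p = np.asarray(p, dtype=float)
    bad = ~np.isfinite(p)
    if bad.any():
        warnings.warn(
            f"{bad.sum()} features with zero variance in both classes: p set to 1", stacklevel=2
        )
        p[bad] = 1.0
    return np.clip(p, np.finfo(float).tiny, 1.0)


@dataclass
class PlsdaModel:
    """Fitted PLS-DA summary: weights, scores, explained-Y variance, VIP."""

    n_components: int
    weights: np.ndarray  # p x A, each column unit norm
    scores: np.ndarray  # n x A
    explained_ss: np.ndarray  # length A
    vip: np.ndarray  # length p
    feature_ids: list[str] = field(default_factory=list)


def plsda_vip(matrix, labels, n_components: int = 2) -> PlsdaModel:
    """Fit a two-class PLS-DA (NIPALS) and compute VIP scores.

    VIP_i = sqrt( p * sum_a[ SS_a * (w_ia/||w_a||)^2 ] / sum_a SS_a ) with
    SS_a the Y sum of squares explained by component a; the mean of squared
    VIPs is 1 by construction. Features are auto-scaled inside the fit only.
    """
    x, feature_ids = _as_matrix(matrix)
    labels, classes = _two_classes(labels)
    X = x.T  # samples x features
    y = (labels == classes[1]).astype(float)
    n, p = X.shape
    max_comp = min(n - 1, p)
    if n_components > max_comp:
        warnings.warn(
            f"n_components reduced from {n_components} to {max_comp} (rank limit)", stacklevel=2
        )
        n_components = max_comp
    if n_components < 1:
        raise ValueError("need at least 1 PLS component")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pls = PLSRegression(n_components=n_components, scale=True)
        pls.fit(X, y)
    W = pls.x_weights_  # p x A, unit columns
    T = pls.x_scores_  # n x A
    Q = pls.y_loadings_  # 1 x A
    ss = (T**2).sum(axis=0) * Q[0] ** 2
    if ss.sum() <= 0:
        raise ValueError("PLS explained no Y variance")
    wnorm2 = (W**2).sum(axis=0)
    wnorm2[wnorm2 == 0] = 1.0
    vip = np.sqrt(p * ((W**2 / wnorm2[None, :]) * ss[None, :]).sum(axis=1) / ss.sum())
    return PlsdaModel(
        n_components=n_components,
        weights=W,
        scores=T,
        explained_ss=ss,
        vip=vip,
        feature_ids=feature_ids,
    )


def select_features(
    matrix,
    labels,
    vip_threshold: float = 1.0,
    p_threshold: float = 0.05,
    n_components: int = 2,
    equal_var: bool = False,
    fallback: str | None = None,
    fallback_k: int = 10,
) -> list[str]:
    """Differential features: VIP > vip_threshold AND t-test p < p_threshold.

    An empty intersection raises by default; ``fallback="top_k"`` instead
    returns the ``fallback_k`` highest-VIP features (logged via warning) so
    long benchmark sweeps never die silently.
    """
    model = plsda_vip(matrix, labels, n_components=n_components)
    pvals = ttest_pvalues(matrix, labels, equal_var=equal_var)
    keep = (model.vip > vip_threshold) & (pvals < p_threshold)
    selected = [f for f, k in zip(model.feature_ids, keep) if k]
    if selected:
        return selected
    if fallback == "top_k":
        order = np.argsort(model.vip)[::-1][:fallback_k]
        warnings.warn(
            f"empty VIP/p selection: falling back to top-{fallback_k} VIP features", stacklevel=2
        )
        return [model.feature_ids[i] for i in sorted(order)]
    raise ValueError(
        "no feature passed VIP > {0} and p < {1}; consider fallback='top_k'".format(
            vip_threshold, p_threshold
        )
    )


DEFAULT_SVM_GRID = {"C": (0.1, 1.0, 10.0, 100.0), "gamma_scale": (1e-3, 1e-2, 1e-1, 1.0)}
REDUCED_SVM_GRID = {"C": (1.0, 10.0), "gamma_scale": (1e-2, 1e-1)}


def train_svm_cv(
    matrix,
    labels,
    grid: dict | None = None,
    n_folds: int = 10,
    seed: int = 0,
):
    """Tune an RBF SVM by stratified cross-validated accuracy and refit.

    ``grid["gamma_scale"]`` values are divided by the feature count p to give
    gamma. Features are standardized inside the classifier (training
    statistics frozen for later application to validation samples), matching
    the default behavior of the standard SVM implementations this procedure
    follows. Folds are reduced with a warning when the smaller class cannot
    populate 10 folds. Returns (classifier, best_params).
    """
    x, _ = _as_matrix(matrix)
    labels, classes = _two_classes(labels)
    X = x.T
    n, p = X.shape
    grid = grid or DEFAULT_SVM_GRID
    gammas = [g / p for g in grid["gamma_scale"]]
    counts = [int((labels == c).sum()) for c in classes]
    folds = min(n_folds, min(counts))
    if folds < n_folds:
        warnings.warn(f"folds reduced from {n_folds} to {folds} (small class)", stacklevel=2)
    if folds < 2:
        raise ValueError("need at least 2 samples per class for cross-validation")
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    pipe = Pipeline([("scale", StandardScaler()), ("svm", SVC(kernel="rbf"))])
    search = GridSearchCV(
        pipe,
        {"svm__C": list(grid["C"]), "svm__gamma": gammas},
        scoring="accuracy",
        cv=cv,
        n_jobs=None,
        refit=True,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        search.fit(X, labels)
    best = {k.replace("svm__", ""): v for k, v in search.best_params_.items()}
    return search.best_estimator_, best


@dataclass
class EvaluationResult:
    """Held-out performance of one (method, sub-dataset) cell."""

    selected_feature_ids: list[str]
    tp: int
    fp: int
    tn: int
    fn: int
    acc: float
    roc_points: np.ndarray  # rows of (fpr, tpr, threshold)
    auc: float
    method: str = ""
    subset_size: int = 0

    def __post_init__(self) -> None:
        total = self.tp + self.fp + self.tn + self.fn
        if total <= 0:
            raise ValueError("empty confusion table")
        expected = (self.tp + self.tn) / total
        if abs(self.acc - expected) > 1e-12:
            raise ValueError("ACC does not match confusion counts")
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError("AUC outside [0, 1]")
        pts = np.asarray(self.roc_points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError("roc_points must be (n, 3)")
        if not (pts[0, 0] == 0 and pts[0, 1] == 0 and pts[-1, 0] == 1 and pts[-1, 1] == 1):
            raise ValueError("ROC must start at (0,0) and end at (1,1)")
        self.roc_points = pts

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "subset_size": self.subset_size,
            "selected_feature_ids": list(self.selected_feature_ids),
            "confusion": {"tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn},
            "acc": self.acc,
            "auc": self.auc,
            "roc_points": self.roc_points.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EvaluationResult":
        c = d["confusion"]
        return cls(
            selected_feature_ids=list(d["selected_feature_ids"]),
            tp=c["tp"],
            fp=c["fp"],
            tn=c["tn"],
            fn=c["fn"],
            acc=d["acc"],
            roc_points=np.asarray(d["roc_points"], dtype=float),
            auc=d["auc"],
            method=d.get("method", ""),
            subset_size=d.get("subset_size", 0),
        )


def trapezoid_auc(fpr: np.ndarray, tpr: np.ndarray) -> float:
    return float(np.trapezoid(tpr, fpr))


def evaluate_on_validation(
    classifier,
    matrix,
    labels,
    selected_feature_ids: list[str] | None = None,
    method: str = "",
    subset_size: int = 0,
) -> EvaluationResult:
    """Score a trained classifier on held-out samples.

    Confusion counts use decision threshold 0; the ROC sweeps all decision
    values; AUC is the trapezoid area (equal to the Mann-Whitney statistic).
    """
    x, _ = _as_matrix(matrix)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("validation set must contain both classes for a ROC")
    X = x.T
    scores = classifier.decision_function(X)
    positive = classifier.classes_[1]
    y = labels == positive
    pred = scores > 0
    tp = int(np.sum(pred & y))
    fp = int(np.sum(pred & ~y))
    tn = int(np.sum(~pred & ~y))
    fn = int(np.sum(~pred & y))
    acc = (tp + tn) / (tp + fp + tn + fn)
    fpr, tpr, thr = roc_curve(y, scores, drop_intermediate=False)
    auc = trapezoid_auc(fpr, tpr)
    pts = np.column_stack([fpr, tpr, thr])
    return EvaluationResult(
        selected_feature_ids=list(selected_feature_ids or []),
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        acc=acc,
        roc_points=pts,
        auc=auc,
        method=method,
        subset_size=subset_size,
    )
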