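"""Outcome dichotomisation, hierarchical feature sets, and cross-validated
SVM classification with AUROC evaluation.

Models are organised in tiers of increasing information content — age only,
age plus comorbidities, plus total lesion volume, plus the voxel-level lesion
mask on the coarse analysis grid, plus the combined mask and zeta map — so
the incremental value of the imaging can be read off the AUROC sequence.
AUROC is the Mann-Whitney concordance (ties counted half); confidence
intervals come from stratified bootstrap resampling of the pooled
out-of-fold scores, and paired model comparison uses the DeLong test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
from scipy.stats import norm, rankdata
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

__all__ = [
    "ClinicalRecord",
    "FeatureSpec",
    "ModelEval",
    "dichotomize",
    "build_features",
    "cv_train_eval",
    "auroc",
    "bootstrap_ci",
    "compare_auroc",
    "DEFAULT_GRID",
    "TIERS",
]

TIERS = (
    "age",
    "age+comorbidities",
    "+lesion_volume",
    "+voxel_mask",
    "+voxel_mask_zeta",
    "tissue_maps",
)

#: rbf-SVM grid: cost 2^-5..2^15 and kernel width 2^-15..2^3, by powers of 4.
DEFAULT_GRID = {
    "C": [2.0**e for e in range(-5, 16, 2)],
    "gamma": [2.0**e for e in range(-15, 4, 2)],
}

COMORBIDITIES = ("diabetes", "hypertension", "atrial_fibrillation", "chf")


@dataclass
class ClinicalRecord:
    """One subject's demographics, comorbidities and stroke scores."""

    age: float
    sex: int
    diabetes: int = 0
    hypertension: int = 0
    atrial_fibrillation: int = 0
    chf: int = 0
    pre_mrs: int | None = None
    dis_mrs: int | None = None
    nihss_admit: int | None = None
    nihss_24h: int | None = None
    thrombolysed: int = 0

    def __post_init__(self) -> None:
        if self.pre_mrs is not None and not 0 <= self.pre_mrs <= 5:
            raise ValueError("pre_mrs must lie in 0-5")
        if self.dis_mrs is not None and not 0 <= self.dis_mrs <= 6:
            raise ValueError("dis_mrs must lie in 0-6")
        for f in ("nihss_admit", "nihss_24h"):
            v = getattr(self, f)
            if v is not None and v < 0:
                raise ValueError(f"{f} must be >= 0")


@dataclass(frozen=True)
class FeatureSpec:
    """Which tier of features to assemble; voxel features are flattened in C
    (row-major) order of the canonical axes so voxel j means the same
    anatomical location for every subject."""

    tier: str = "age"

    def __post_init__(self) -> None:
        if self.tier not in TIERS:
            raise ValueError(f"unknown tier {self.tier!r}; choose from {TIERS}")


@dataclass
class ModelEval:
    """Cross-validated evaluation at the selected grid point."""

    fold_aurocs: list[float]
    mean_auroc: float
    scores: np.ndarray  # pooled out-of-fold decision scores, original subject order
    labels: np.ndarray
    ci_low: float
    ci_high: float
    best_params: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return {
            "fold_aurocs": [float(a) for a in self.fold_aurocs],
            "mean_auroc": float(self.mean_auroc),
            "ci_low": float(self.ci_low),
            "ci_high": float(self.ci_high),
            "best_params": {k: float(v) for k, v in self.best_params.items()},
            "scores": [float(s) for s in self.scores],
            "labels": [int(y) for y in self.labels],
        }


# ---------------------------------------------------------------------------
# Outcomes


class MissingField(ValueError):
    """Raised when a record lacks a field the chosen outcome requires."""


def dichotomize(rec: ClinicalRecord, outcome: str) -> int:
    """Binary label for one outcome.

    ``pre_mrs``/``dis_mrs``: 0 for functional independence (mRS 0-2), 1 for
    dependence (3+). ``nihss_deterioration``: 1 when NIHSS rises by more than
    2 points at 24 h. ``sex``: passthrough.
    """
    if outcome in ("pre_mrs", "dis_mrs"):
        v = getattr(rec, outcome)
        if v is None:
            raise MissingField(f"record lacks {outcome}")
        return int(v >= 3)
    if outcome == "nihss_deterioration":
        if rec.nihss_admit is None or rec.nihss_24h is None:
            raise MissingField("record lacks an NIHSS score")
        return int(rec.nihss_24h - rec.nihss_admit > 2)
    if outcome == "sex":
        return int(rec.sex)
    raise ValueError(f"unknown outcome {outcome!r}")


def build_features(
    rec: ClinicalRecord,
    lesion=None,
    spec: FeatureSpec = FeatureSpec("age"),
    tissue_maps: Sequence[np.ndarray] | None = None,
) -> np.ndarray:
    """Deterministic feature vector for one subject at the requested tier.

    Clinical scalars come first (age, then the four comorbidities), followed
    by flattened analysis-grid voxel features where the tier includes them.
    ``lesion`` is a :class:`~ctseg.lesion_mask.LesionResult`.
    """
    tier = spec.tier
    if tier == "tissue_maps":
        if tissue_maps is None:
            raise ValueError("tier 'tissue_maps' requires tissue probability maps")
        return np.concatenate([np.asarray(m, dtype=np.float64).ravel() for m in tissue_maps])
    feats = [float(rec.age)]
    if tier == "age":
        return np.asarray(feats)
    feats += [float(getattr(rec, c)) for c in COMORBIDITIES]
    if tier == "age+comorbidities":
        return np.asarray(feats)
    if lesion is None:
        raise ValueError(f"tier {tier!r} requires a lesion segmentation result")
    if tier == "+lesion_volume":
        return np.asarray(feats + [float(lesion.volume_ml)])
    mask_vec = lesion.mask_mni4.data.astype(np.float64).ravel()
    if tier == "+voxel_mask":
        return np.concatenate([feats, mask_vec])
    zeta_vec = lesion.zeta_mni4.data.astype(np.float64).ravel()
    return np.concatenate([feats, mask_vec, zeta_vec])


# ---------------------------------------------------------------------------
# AUROC and uncertainty


def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUROC: P(score_pos > score_neg) with ties counted half."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC undefined: both classes must be present")
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def bootstrap_ci(
    scores: np.ndarray,
    labels: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Stratified bootstrap percentile CI for the AUROC.

    Pairs are resampled with replacement within each class, so every
    resample retains both classes.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    rng = np.random.default_rng(seed)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    stats = np.empty(n_boot)
    for b in range(n_boot):
        ps = rng.choice(pos, pos.size, replace=True)
        ns = rng.choice(neg, neg.size, replace=True)
        s = np.concatenate([ps, ns])
        y = np.concatenate([np.ones(ps.size, int), np.zeros(ns.size, int)])
        stats[b] = auroc(s, y)
    lo, hi = np.percentile(stats, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def _delong_components(scores: np.ndarray, labels: np.ndarray):
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    # structural components via mid-ranks
    allr = rankdata(np.concatenate([pos, neg]))
    rp = rankdata(pos)
    rn = rankdata(neg)
    v10 = (allr[:m] - rp) / n  # per-positive
    v01 = 1.0 - (allr[m:] - rn) / m  # per-negative
    a = float(v10.mean())
    return a, v10, v01


def compare_auroc(eval1: ModelEval, eval2: ModelEval) -> float:
    """Two-sided DeLong paired test on the pooled out-of-fold scores.

    Both evaluations must cover the same subjects with identical labels.
    Returns the p-value for equality of the two AUROCs; identical score
    vectors give p = 1.
    """
    y1 = np.asarray(eval1.labels).astype(int)
    y2 = np.asarray(eval2.labels).astype(int)
    if y1.shape != y2.shape or not np.array_equal(y1, y2):
        raise ValueError("paired comparison requires the same subjects and labels")
    s1 = np.asarray(eval1.scores, dtype=np.float64)
    s2 = np.asarray(eval2.scores, dtype=np.float64)
    a1, v10_1, v01_1 = _delong_components(s1, y1)
    a2, v10_2, v01_2 = _delong_components(s2, y1)
    m, n = v10_1.size, v01_1.size
    s10 = np.cov(np.vstack([v10_1, v10_2]), ddof=1)
    s01 = np.cov(np.vstack([v01_1, v01_2]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    diff = a1 - a2
    if var <= 0:
        return 1.0 if abs(diff) < 1e-12 else 0.0
    z = diff / np.sqrt(var)
    return float(2 * norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# Cross-validated training


def _scale_unit(train: np.ndarray, test: np.ndarray):
    lo = train.min(axis=0)
    hi = train.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    return (train - lo) / span, (test - lo) / span


def _grid_points(grid: dict[str, Sequence[float]]):
    for c in grid.get("C", [1.0]):
        for g in grid.get("gamma", ["scale"]):
            yield {"C": float(c), "gamma": g}


def cv_train_eval(
    X: np.ndarray,
    y: np.ndarray,
    kernel: str = "rbf",
    grid: dict[str, Sequence[float]] | None = None,
    k: int = 10,
    seed: int = 0,
    n_boot: int = 1000,
) -> ModelEval:
    """Stratified k-fold SVM with grid search on mean out-of-fold AUROC.

    For every grid point the same folds are used; the point with the highest
    fold-averaged AUROC is selected and reported together with its per-fold
    AUROCs, the pooled out-of-fold decision scores, and a stratified
    bootstrap CI on the pooled scores. Features are min-max scaled to [0, 1]
    on each training fold.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y).astype(int)
    if X.ndim == 1:
        X = X[:, None]
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2 or counts.min() < 2:
        raise ValueError("need two classes with at least 2 examples each")
    k = min(k, int(counts.min()))
    grid = grid or DEFAULT_GRID
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))

    best = None
    for params in _grid_points(grid):
        fold_aucs = []
        pooled = np.zeros(y.size)
        ok = True
        for tr, te in splits:
            Xtr, Xte = _scale_unit(X[tr], X[te])
            clf = SVC(kernel=kernel, C=params["C"], gamma=params["gamma"])
            clf.fit(Xtr, y[tr])
            s = clf.decision_function(Xte)
            pooled[te] = s
            if np.unique(y[te]).size == 2:
                fold_aucs.append(auroc(s, y[te]))
        if not fold_aucs:
            ok = False
        mean_auc = float(np.mean(fold_aucs)) if ok else -np.inf
        if best is None or mean_auc > best[0]:
            best = (mean_auc, params, fold_aucs, pooled)

    mean_auc, params, fold_aucs, pooled = best
    lo, hi = bootstrap_ci(pooled, y, n_boot=n_boot, seed=seed)
    return ModelEval(
        fold_aurocs=fold_aucs,
        mean_auroc=mean_auc,
        scores=pooled,
        labels=y,
        ci_low=lo,
        ci_high=hi,
        best_params=params,
    )
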