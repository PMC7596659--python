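"""Random-forest case/control classification with leave-one-out ROC.

Each sample is scored by a forest trained on the remaining n-1 samples
(leave-one-out cross-validation); the out-of-fold score is the fraction
of trees voting for the case class. Discrimination is summarized by the
area under the ROC curve computed by the rank (Mann-Whitney)
formulation with ties counted 1/2, with a 95% DeLong confidence
interval. Rank-level comparison re-runs the full procedure on
abundances aggregated to genus/family/order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_curve

from .containers import AbundanceMatrix
from .exceptions import InputError


@dataclass
class ClassifierReport:
    """LOOCV ROC summary for one taxonomic rank."""

    rank: str
    auc: float
    auc_ci_low: float
    auc_ci_high: float
    scores: pd.Series
    curve: pd.DataFrame
    importance: pd.Series | None = None


def _check_labels(groups: pd.Series, pos_label: str) -> np.ndarray:
    y = (groups == pos_label).to_numpy()
    if y.all() or not y.any():
        raise InputError("both classes must be present")
    return y


def loocv_scores(
    matrix: AbundanceMatrix,
    groups: pd.Series,
    n_trees: int = 500,
    seed: int = 0,
    pos_label: str = "ALL",
    max_features: str | float = "sqrt",
) -> pd.Series:
    """Out-of-fold predicted probability of the case class per sample."""
    groups = groups.loc[matrix.abundance.index]
    x = matrix.abundance.to_numpy(dtype=float)
    y = _check_labels(groups, pos_label)
    n = len(y)
    if n < 4:
        raise InputError("LOOCV needs at least 4 samples")
    if min(y.sum(), n - y.sum()) < 2:
        raise InputError("each class needs >= 2 samples so no training fold is single-class")
    scores = np.empty(n)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        forest = RandomForestClassifier(
            n_estimators=n_trees,
            max_features=max_features,
            random_state=seed,
            n_jobs=1,
        ).fit(x[mask], y[mask])
        pos_col = int(np.flatnonzero(forest.classes_)[0])
        scores[i] = forest.predict_proba(x[i : i + 1])[0, pos_col]
        mask[i] = True
    return pd.Series(scores, index=matrix.abundance.index, name="score")


def rank_auc(scores: np.ndarray, y: np.ndarray) -> float:
    """AUC via mid-ranks (Mann-Whitney), ties counted one half."""
    m = int(y.sum())
    n = len(y) - m
    ranks = rankdata(scores)
    return float((ranks[y.astype(bool)].sum() - m * (m + 1) / 2.0) / (m * n))


def _midrank(x: np.ndarray) -> np.ndarray:
    return rankdata(x, method="average")

def delong_ci(scores: np.ndarray, y: np.ndarray, level: float = 0.95) -> tuple[float, float, float]:
    """AUC with DeLong confidence interval for a single ROC curve.

    Uses the structural-component formulation: per-positive and
    per-negative placement values whose empirical variances estimate
    the sampling variance of the Mann-Whitney AUC.
    """
    pos = scores[y.astype(bool)]
    neg = scores[~y.astype(bool)]
    m, n = len(pos), len(neg)
    tz = _midrank(np.concatenate([pos, neg]))
    tx = _midrank(pos)
    ty = _midrank(neg)
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v01 = (tz[:m] - tx) / n            # placement of each positive among negatives
    v10 = 1.0 - (tz[m:] - ty) / m      # placement of each negative among positives
    var = (np.var(v01, ddof=1) / m if m > 1 else 0.0) + (
        np.var(v10, ddof=1) / n if n > 1 else 0.0
    )
    z = norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(max(var, 0.0))
    return float(auc), float(max(0.0, auc - half)), float(min(1.0, auc + half))


def roc_auc(
    scores: pd.Series,
    groups: pd.Series,
    pos_label: str = "ALL",
    rank: str = "species",
) -> ClassifierReport:
    """ROC curve, AUC and 95% DeLong CI from out-of-fold scores."""
    groups = groups.loc[scores.index]
    y = _check_labels(groups, pos_label)
    s = scores.to_numpy(dtype=float)
    auc, lo, hi = delong_ci(s, y)
    fpr, tpr, thresholds = roc_curve(y, s)
    curve = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds})
    return ClassifierReport(
        rank=rank, auc=auc, auc_ci_low=lo, auc_ci_high=hi, scores=scores, curve=curve
    )


def feature_importance(
    matrix: AbundanceMatrix,
    groups: pd.Series,
    n_trees: int = 500,
    seed: int = 0,
    pos_label: str = "ALL",
    top_k: int | None = 10,
) -> pd.Series:
    """Mean-decrease-in-impurity importances from a forest on all samples."""
    groups = groups.loc[matrix.abundance.index]
    y = _check_labels(groups, pos_label)
    forest = RandomForestClassifier(
        n_estimators=n_trees, max_features="sqrt", random_state=seed, n_jobs=1
    ).fit(matrix.abundance.to_numpy(dtype=float), y)
    imp = pd.Series(forest.feature_importances_, index=matrix.taxa, name="importance")
    imp = imp.sort_values(ascending=False)
    return imp.head(top_k) if top_k else imp


def classify_rank(
    matrix: AbundanceMatrix,
    groups: pd.Series,
    n_trees: int = 500,
    seed: int = 0,
    pos_label: str = "ALL",
    top_k: int | None = 10,
) -> ClassifierReport:
    """LOOCV + ROC + importances for one rank's abundance matrix."""
    scores = loocv_scores(matrix, groups, n_trees=n_trees, seed=seed, pos_label=pos_label)
    report = roc_auc(scores, groups, pos_label=pos_label, rank=matrix.rank)
    report.importance = feature_importance(
        matrix, groups, n_trees=n_trees, seed=seed, pos_label=pos_label, top_k=top_k
    )
    return report


def compare_ranks(
    matrices: dict[str, AbundanceMatrix],
    groups: pd.Series,
    n_trees: int = 500,
    seed: int = 0,
    pos_label: str = "ALL",
) -> dict[str, ClassifierReport]:
    """Independent LOOCV-AUC per taxonomic rank on aligned sample sets."""
    sample_sets = {tuple(m.samples) for m in matrices.values()}
    if len(sample_sets) > 1:
        raise InputError("rank matrices must share an identical sample set")
    return {
        rank: classify_rank(m, groups, n_trees=n_trees, seed=seed, pos_label=pos_label)
        for rank, m in matrices.items()
    }
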