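"""Alpha and beta diversity with group comparisons.

Alpha indices: Shannon (nats by default), Simpson (1 - dominance),
Chao1 and ACE. The richness estimators need integer counts with
singletons and doubletons, so relative abundances are rescaled to
pseudo-counts (default total 10,000, rounded) first. Beta diversity is
Bray-Curtis, ordinated by classical PCoA and by non-metric MDS
(Kruskal stress-1), with group structure tested by PERMANOVA on the
distance matrix.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import mannwhitneyu
from skbio import DistanceMatrix
from skbio.diversity.alpha import ace as _skbio_ace
from skbio.stats.distance import permanova as _skbio_permanova
from skbio.stats.ordination import pcoa as _skbio_pcoa
from sklearn.manifold import MDS

from .containers import AbundanceMatrix
from .exceptions import InputError, InsufficientDataError

logger = logging.getLogger(__name__)

ALPHA_INDICES = ("chao1", "ace", "shannon", "simpson")


@dataclass
class OrdinationResult:
    """Low-dimensional embedding of a sample distance matrix."""

    coordinates: pd.DataFrame
    method: str
    eigenvalues: np.ndarray | None = None
    proportion_explained: np.ndarray | None = None
    stress: float | None = None


@dataclass
class PermanovaResult:
    pseudo_F: float
    p_value: float
    n_permutations: int


def shannon_index(p: np.ndarray, base: float | None = None) -> float:
    """Shannon entropy H = -sum p ln p over p > 0 (natural log by default)."""
    p = p[p > 0]
    h = float(-(p * np.log(p)).sum())
    return h / np.log(base) if base else h


def simpson_index(p: np.ndarray) -> float:
    """Gini-Simpson diversity 1 - sum p^2."""
    return float(1.0 - (p * p).sum())


def chao1_index(counts: np.ndarray) -> float:
    """Chao1 richness: S_obs + F1^2/(2 F2), or the bias-corrected
    S_obs + F1(F1-1)/2 when no doubletons exist."""
    counts = counts[counts > 0]
    s_obs = len(counts)
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    if f2 > 0:
        return s_obs + f1 * f1 / (2.0 * f2)
    return s_obs + f1 * (f1 - 1) / 2.0


def ace_index(counts: np.ndarray, rare_threshold: int = 10) -> float:
    """Abundance-based coverage estimator with the standard rare cutoff."""
    counts = counts[counts > 0].astype(int)
    if len(counts) == 0:
        return 0.0
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            value = float(_skbio_ace(counts, rare_threshold=rare_threshold))
    except (ValueError, ZeroDivisionError):
        value = float(len(counts))
    if not np.isfinite(value):
        value = float(len(counts))
    return value


def alpha_diversity(matrix: AbundanceMatrix, pseudo_count_total: int = 10_000) -> pd.DataFrame:
    """Per-sample alpha diversity table (chao1, ace, shannon, simpson).

    ``pseudo_count_total`` controls the count rescaling used by the
    richness estimators; evenness indices are computed directly on the
    relative abundances. All-zero rows (blank samples) get zeros.
    """
    if pseudo_count_total < 1:
        raise InputError("pseudo_count_total must be >= 1")
    records = {}
    for sample_id, row in matrix.abundance.iterrows():
        p = row.to_numpy(dtype=float)
        if p.sum() == 0:
            logger.warning("sample %s has no positive species; indices set to 0", sample_id)
            records[sample_id] = dict.fromkeys(ALPHA_INDICES, 0.0)
            continue
        counts = np.rint(p * pseudo_count_total)
        records[sample_id] = {
            "chao1": chao1_index(counts),
            "ace": ace_index(counts),
            "shannon": shannon_index(p),
            "simpson": simpson_index(p),
        }
    return pd.DataFrame.from_dict(records, orient="index")[list(ALPHA_INDICES)]


def compare_alpha(table: pd.DataFrame, groups: pd.Series) -> pd.Series:
    """Two-sided Wilcoxon rank-sum p-value per alpha index between two groups.

    Uses the exact null distribution for small untied samples and the
    tie-corrected normal approximation otherwise.
    """
    groups = groups.loc[table.index]
    labels = groups.unique()
    if len(labels) != 2:
        raise InputError(f"expected exactly 2 groups, got {list(labels)}")
    a = table[groups == labels[0]]
    b = table[groups == labels[1]]
    if len(a) < 2 or len(b) < 2:
        raise InputError("each group needs at least 2 samples")
    pvals = {}
    for index in table.columns:
        pvals[index] = float(
            mannwhitneyu(a[index], b[index], alternative="two-sided", method="auto").pvalue
        )
    return pd.Series(pvals)


def bray_curtis(matrix: AbundanceMatrix) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between all sample pairs.

    d(i, j) = sum|x_i - x_j| / sum(x_i + x_j), in [0, 1]. A pair of
    all-zero samples has an undefined quotient; it is defined as 0
    (identical blanks) and flagged in the log.
    """
    x = matrix.abundance.to_numpy(dtype=float)
    if (x < 0).any():
        raise InputError("Bray-Curtis requires non-negative abundances")
    with np.errstate(invalid="ignore"):
        condensed = pdist(x, metric="braycurtis")
    if np.isnan(condensed).any():
        logger.warning("all-zero sample pairs found; their distance is defined as 0")
        condensed = np.nan_to_num(condensed, nan=0.0)
    return DistanceMatrix(squareform(condensed), ids=[str(s) for s in matrix.samples])


def pcoa(dist: DistanceMatrix) -> OrdinationResult:
    """Classical (metric) multidimensional scaling of a distance matrix.

    Eigendecomposition of the double-centered squared distances; axes
    are ordered by descending eigenvalue. Negative eigenvalues are
    reported as-is but excluded from the explained-variance denominator.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = _skbio_pcoa(dist, method="eigh")
    eig = res.eigvals.to_numpy()
    pos = eig[eig > 0]
    prop = np.where(eig > 0, eig / pos.sum(), 0.0) if pos.size else np.zeros_like(eig)
    coords = res.samples
    coords.index = pd.Index(dist.ids, name="sample_id")
    return OrdinationResult(
        coordinates=coords,
        method="PCoA",
        eigenvalues=eig,
        proportion_explained=prop,
    )


def nmds(
    dist: DistanceMatrix,
    k: int = 2,
    n_starts: int = 20,
    seed: int = 0,
    max_iter: int = 500,
) -> OrdinationResult:
    """Non-metric MDS minimizing Kruskal stress-1.

    SMACOF iterative majorization from ``n_starts`` random initial
    configurations; the lowest-stress solution is returned. Stress-1 of
    ~0.2 is conventionally a poor fit, <0.1 fair, <0.05 good.
    """
    model = MDS(
        n_components=k,
        metric_mds=False,
        n_init=n_starts,
        max_iter=max_iter,
        random_state=seed,
        metric="precomputed",
        normalized_stress=True,
        eps=1e-9,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        coords = model.fit_transform(dist.data)
    coordinates = pd.DataFrame(
        coords,
        index=pd.Index(dist.ids, name="sample_id"),
        columns=[f"NMDS{i + 1}" for i in range(k)],
    )
    return OrdinationResult(coordinates=coordinates, method="NMDS", stress=float(model.stress_))


def permanova(
    dist: DistanceMatrix,
    groups: pd.Series,
    n_permutations: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """Permutational multivariate ANOVA on a distance matrix.

    pseudo-F from the between/within sum-of-squares partition;
    p = (1 + #{F_perm >= F_obs}) / (1 + n_permutations) under free
    label permutation.
    """
    grouping = groups.loc[[s for s in dist.ids]] if not isinstance(groups, list) else groups
    counts = pd.Series(grouping).value_counts()
    if (counts < 2).any():
        raise InsufficientDataError("PERMANOVA needs >= 2 samples per group")
    if np.allclose(dist.condensed_form(), dist.condensed_form()[0]):
        raise InputError("constant distance matrix: pseudo-F undefined")
    res = _skbio_permanova(dist, list(grouping), permutations=n_permutations, seed=seed)
    return PermanovaResult(
        pseudo_F=float(res["test statistic"]),
        p_value=float(res["p-value"]),
        n_permutations=n_permutations,
    )
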