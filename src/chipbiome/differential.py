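"""LEfSe-style differential abundance: Kruskal-Wallis screen + LDA effect size.

The cascade follows the published LEfSe procedure for a two-class
design: per-taxon Kruskal-Wallis screen at ``alpha`` (with two groups
this is the Wilcoxon rank-sum test; the subclass Wilcoxon step is an
identity pass-through absent subclass structure), then bootstrap rounds
of two-class linear discriminant analysis on the screened taxa, with
abundances rescaled so each sample totals one million. The effect size
of a taxon is log10(1 + e), where e averages, over bootstrap rounds,
the mean of (a) the absolute raw between-class difference and (b) the
taxon's share of the class separation along the unit LDA axis. Taxa
with |score| >= ``lda_threshold`` (conventionally 2.0) are reported,
signed toward the enriched group.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import kruskal
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from statsmodels.stats.multitest import multipletests

from .containers import RANKS, AbundanceMatrix, ArrayManifest
from .exceptions import InputError
from .array_quant import aggregate_to_rank

logger = logging.getLogger(__name__)

#: Per-sample total after LEfSe rescaling.
LEFSE_SCALE = 1.0e6


@dataclass
class LefseResult:
    taxon: str
    rank: str
    kw_p: float
    lda_score: float
    enriched_group: str


def kruskal_wallis_screen(matrix: AbundanceMatrix, groups: pd.Series) -> pd.DataFrame:
    """Per-taxon Kruskal-Wallis p-values (tie-corrected H, chi-square null).

    A taxon constant across all samples carries no rank information;
    its p is set to 1 and flagged.
    """
    groups = groups.loc[matrix.abundance.index]
    labels = list(pd.unique(groups))
    if len(labels) < 2:
        raise InputError("need >= 2 groups")
    if groups.value_counts().min() < 2:
        raise InputError("each group needs >= 2 samples")
    split = [matrix.abundance[groups == g] for g in labels]
    records = []
    for taxon in matrix.taxa:
        samples = [s[taxon].to_numpy() for s in split]
        pooled = np.concatenate(samples)
        if np.all(pooled == pooled[0]):
            records.append({"taxon": taxon, "kw_p": 1.0, "constant": True})
            continue
        _, p = kruskal(*samples)
        records.append({"taxon": taxon, "kw_p": float(p), "constant": False})
    return pd.DataFrame.from_records(records).set_index("taxon")


def _lda_axis(model: LinearDiscriminantAnalysis) -> np.ndarray:
    w = getattr(model, "scalings_", None)
    if w is None:
        w = model.coef_.T
    return np.asarray(w)[:, 0]


def lda_effect_size(
    matrix: AbundanceMatrix,
    groups: pd.Series,
    taxa: list[str],
    n_boot: int = 30,
    subsample_fraction: float = 2.0 / 3.0,
    seed: int = 0,
) -> list[LefseResult]:
    """Bootstrap LDA effect sizes for screened taxa (two classes).

    Each round subsamples ``subsample_fraction`` of every class without
    replacement (at least 2 per class), fits an LDA over all screened
    taxa jointly on the 10^6-rescaled abundances, and accumulates each
    taxon's effect. Singular within-class scatter falls back to a
    shrinkage LDA and is flagged in the log.
    """
    if not taxa:
        return []
    groups = groups.loc[matrix.abundance.index]
    labels = sorted(pd.unique(groups))
    if len(labels) != 2:
        raise InputError("LDA effect size is defined for exactly 2 groups")
    x = matrix.abundance[taxa].to_numpy(dtype=float) * LEFSE_SCALE
    y = (groups == labels[0]).to_numpy()
    rng = np.random.default_rng(seed)
    idx0 = np.flatnonzero(y)
    idx1 = np.flatnonzero(~y)
    effects = np.zeros((n_boot, len(taxa)))
    for b in range(n_boot):
        # one uniform draw per sample, lowest kept within each class: the
        # subsample depends on sample identity only, so relabelling the
        # groups leaves every bootstrap round's data unchanged
        u = rng.random(len(y))
        take0 = idx0[np.argsort(u[idx0])[: max(2, round(len(idx0) * subsample_fraction))]]
        take1 = idx1[np.argsort(u[idx1])[: max(2, round(len(idx1) * subsample_fraction))]]
        sel = np.concatenate([take0, take1])
        xb, yb = x[sel], y[sel]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                model = LinearDiscriminantAnalysis(solver="svd").fit(xb, yb)
                w = _lda_axis(model)
            except np.linalg.LinAlgError:
                logger.warning("singular scatter in bootstrap %d; shrinkage LDA applied", b)
                model = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto").fit(xb, yb)
                w = _lda_axis(model)
        norm = np.linalg.norm(w)
        w_unit = w / norm if norm > 0 else w
        proj = xb @ w_unit
        ld_gap = abs(proj[yb].mean() - proj[~yb].mean())
        coeff = np.abs(w_unit * ld_gap)
        raw_gap = np.abs(xb[yb].mean(axis=0) - xb[~yb].mean(axis=0))
        effects[b] = 0.5 * (raw_gap + coeff)
    mean_effect = effects.mean(axis=0)
    results = []
    mean0 = matrix.abundance.loc[groups == labels[0], taxa].mean()
    mean1 = matrix.abundance.loc[groups == labels[1], taxa].mean()
    for j, taxon in enumerate(taxa):
        enriched = labels[0] if mean0[taxon] >= mean1[taxon] else labels[1]
        sign = 1.0 if enriched == labels[0] else -1.0
        score = sign * math.log10(1.0 + mean_effect[j])
        results.append(
            LefseResult(
                taxon=taxon,
                rank=matrix.rank,
                kw_p=float("nan"),
                lda_score=score,
                enriched_group=enriched,
            )
        )
    return results


def run_lefse(
    matrix: AbundanceMatrix,
    groups: pd.Series,
    alpha: float = 0.05,
    lda_threshold: float = 2.0,
    n_boot: int = 30,
    seed: int = 0,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Full two-class LEfSe cascade on one abundance matrix.

    Returns a frame (taxon, rank, kw_p, lda_score, enriched_group) of
    taxa with screen p < alpha and |LDA score| >= lda_threshold, sorted
    by |score| descending. ``bh_correct`` optionally screens on
    Benjamini-Hochberg adjusted p-values instead of raw ones (off by
    default, matching LEfSe convention).
    """
    screen = kruskal_wallis_screen(matrix, groups)
    pvals = screen["kw_p"].copy()
    if bh_correct:
        pvals[:] = multipletests(pvals.to_numpy(), method="fdr_bh")[1]
    candidates = list(pvals.index[pvals < alpha])
    results = lda_effect_size(matrix, groups, candidates, n_boot=n_boot, seed=seed)
    records = [
        {
            "taxon": r.taxon,
            "rank": r.rank,
            "kw_p": float(screen.at[r.taxon, "kw_p"]),
            "lda_score": r.lda_score,
            "enriched_group": r.enriched_group,
        }
        for r in results
        if abs(r.lda_score) >= lda_threshold
    ]
    out = pd.DataFrame.from_records(
        records, columns=["taxon", "rank", "kw_p", "lda_score", "enriched_group"]
    )
    return out.sort_values("lda_score", key=np.abs, ascending=False).reset_index(drop=True)


def build_cladogram_table(
    matrix: AbundanceMatrix,
    groups: pd.Series,
    manifest: ArrayManifest,
    alpha: float = 0.05,
    lda_threshold: float = 2.0,
    n_boot: int = 30,
    seed: int = 0,
) -> pd.DataFrame:
    """Rank-nested enrichment table driving a cladogram rendering.

    Runs the LEfSe cascade at species level and again on abundances
    aggregated to genus, family and order, annotating each reported
    taxon with its full lineage so nested enrichment can be drawn.
    """
    frames = []
    lineage = manifest.data.drop_duplicates("species").set_index("species")
    for rank in RANKS:
        agg = aggregate_to_rank(matrix, manifest, rank)
        res = run_lefse(
            agg, groups, alpha=alpha, lda_threshold=lda_threshold, n_boot=n_boot, seed=seed
        )
        if res.empty:
            continue
        if rank == "species":
            for parent in RANKS[1:]:
                res[parent] = res["taxon"].map(lineage[parent])
                if res[parent].isna().any():
                    logger.warning("species without %s lineage reported at species level", parent)
        frames.append(res)
    if not frames:
        return pd.DataFrame(columns=["taxon", "rank", "kw_p", "lda_score", "enriched_group"])
    return pd.concat(frames, ignore_index=True)
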