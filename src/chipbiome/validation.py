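"""qPCR ΔCt quantification and species-cytokine correlation analysis.

The qPCR relative abundance of a target species in a sample is
``2^(Ct_universal - Ct_specific) x 10,000``: each threshold cycle
earlier than the universal 16S reaction doubles the inferred share of
the target in total bacterial DNA, and the x10^4 scaling expresses it
per ten thousand 16S copies. Platform concordance compares the array
and qPCR calls per target; immune coupling is assessed by Spearman rank
correlation between species abundances and the serum cytokine panel.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, spearmanr
from statsmodels.stats.multitest import multipletests

from .containers import UNIVERSAL, AbundanceMatrix, CtTable, SampleMetadata
from .exceptions import InputError, InsufficientDataError

logger = logging.getLogger(__name__)

QPCR_SCALE = 10_000.0


def qpcr_relative_abundance(ct_universal: float, ct_specific: float) -> float:
    """ΔCt relative abundance: 2^(Ct_universal - Ct_specific) x 10,000.

    Strictly increasing in the universal Ct and strictly decreasing in
    the specific Ct; equal cycles give exactly 10,000.
    """
    return float(2.0 ** (ct_universal - ct_specific) * QPCR_SCALE)


def qpcr_table_abundance(ct_table: CtTable) -> pd.DataFrame:
    """Apply the ΔCt formula to every (sample, target) pair of a Ct table.

    Returns samples x targets; censored specific reactions (no
    amplification) are reported as 0. A specific Ct without a matching
    universal Ct in the same sample is an error.
    """
    uni = ct_table.universal()
    specific = ct_table.data[ct_table.data["target"] != UNIVERSAL]
    values = {}
    for target, sub in specific.groupby("target"):
        col = {}
        for _, row in sub.iterrows():
            sid = row["sample_id"]
            if row["censored"]:
                col[sid] = 0.0
            else:
                col[sid] = qpcr_relative_abundance(float(uni.loc[sid]), float(row["ct"]))
        values[str(target)] = col
    return pd.DataFrame(values).sort_index()


def compare_platforms(
    matrix: AbundanceMatrix,
    ct_table: CtTable,
    groups: pd.Series,
    targets: list[str] | None = None,
) -> pd.DataFrame:
    """Array vs qPCR concordance per validated target species.

    For each target: two-sided Wilcoxon rank-sum group p on each
    platform, agreement of the group-median difference sign, and the
    Spearman correlation between platforms across samples (censored
    qPCR values are excluded from the correlation rather than imputed).
    """
    qpcr = qpcr_table_abundance(ct_table)
    if targets is None:
        targets = list(qpcr.columns)
    groups = groups.loc[matrix.abundance.index]
    labels = sorted(pd.unique(groups))
    records = []
    for target in targets:
        if target not in matrix.taxa or target not in qpcr.columns:
            logger.warning("target %s missing on a platform; skipped", target)
            continue
        array_vals = matrix.abundance[target]
        qpcr_vals = qpcr[target].reindex(array_vals.index)
        rec: dict[str, object] = {"target": target}
        for platform, vals in (("array", array_vals), ("qpcr", qpcr_vals)):
            a = vals[groups == labels[0]].dropna()
            b = vals[groups == labels[1]].dropna()
            rec[f"{platform}_p"] = float(
                mannwhitneyu(a, b, alternative="two-sided", method="auto").pvalue
            )
            rec[f"{platform}_median_diff"] = float(a.median() - b.median())
        rec["sign_agreement"] = bool(
            np.sign(rec["array_median_diff"]) == np.sign(rec["qpcr_median_diff"])
        )
        censored = ct_table.data[
            (ct_table.data["target"] == target) & ct_table.data["censored"]
        ]["sample_id"]
        keep = array_vals.index.difference(censored)
        a_k, q_k = array_vals.loc[keep], qpcr_vals.loc[keep].dropna()
        common = a_k.index.intersection(q_k.index)
        if a_k.loc[common].nunique() < 2 or q_k.loc[common].nunique() < 2:
            logger.warning("constant values for %s; platform rho undefined", target)
            rec["rho"], rec["rho_p"] = float("nan"), float("nan")
        else:
            rho, p = spearmanr(a_k.loc[common], q_k.loc[common])
            rec["rho"], rec["rho_p"] = float(rho), float(p)
        records.append(rec)
    return pd.DataFrame.from_records(records)


def _stars(p: float) -> str:
    if np.isnan(p):
        return ""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def spearman_matrix(
    matrix: AbundanceMatrix,
    metadata: SampleMetadata,
    cytokines: list[str] | None = None,
    group_filter: str | None = "ALL",
) -> pd.DataFrame:
    """Species x cytokine Spearman correlations within one group.

    Rank correlation with average-rank tie handling, two-sided p by the
    t approximation; raw p-values are starred at the 0.05/0.01 tiers
    and a Benjamini-Hochberg-adjusted column is emitted alongside.
    Constant variables have undefined rho and are flagged.
    """
    cyt = metadata.cytokines()
    if cytokines is not None:
        missing = set(cytokines) - set(cyt.columns)
        if missing:
            raise InputError(f"cytokines absent from metadata: {sorted(missing)}")
        cyt = cyt[cytokines]
    samples = matrix.abundance.index.intersection(cyt.index)
    if group_filter is not None:
        groups = metadata.groups.loc[samples]
        samples = samples[groups == group_filter]
    if len(samples) < 3:
        raise InsufficientDataError("need >= 3 samples after group filtering")
    ab = matrix.abundance.loc[samples]
    cyt = cyt.loc[samples]
    records = []
    for species in ab.columns:
        a = ab[species].to_numpy()
        for name in cyt.columns:
            c = cyt[name].to_numpy()
            if len(np.unique(a)) < 2 or len(np.unique(c)) < 2:
                records.append(
                    {
                        "species": species,
                        "cytokine": name,
                        "rho": float("nan"),
                        "p_value": float("nan"),
                        "constant": True,
                    }
                )
                continue
            rho, p = spearmanr(a, c)
            records.append(
                {
                    "species": species,
                    "cytokine": name,
                    "rho": float(rho),
                    "p_value": float(p),
                    "constant": False,
                }
            )
    out = pd.DataFrame.from_records(records)
    ok = ~out["p_value"].isna()
    adjusted = np.full(len(out), np.nan)
    if ok.any():
        adjusted[ok.to_numpy()] = multipletests(out.loc[ok, "p_value"], method="fdr_bh")[1]
    out["p_bh"] = adjusted
    out["stars"] = out["p_value"].map(_stars)
    return out
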