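"""Detection calling and relative abundance from two-channel spot intensities.

The quantification chain, per array (per sample):

1. Average the triplicate spots of each species in each channel and
   form the species' mean Cy5/Cy3 ratio from the channel means.
2. Estimate the array's background fluorescence as the mean Cy5 of the
   lowest 30% of species ranked by mean signal intensity.
3. Estimate the baseline Cy5/Cy3 ratio as the mean of the lower half of
   the species ratio ranking.
4. Call a species positive when its mean Cy5 exceeds ``fold`` times the
   background AND its ratio exceeds ``fold`` times the baseline ratio
   (both strict inequalities; ``fold`` defaults to 5).
5. Report the relative abundance of each positive species as its ratio
   divided by the sum of ratios over all positive species; negative
   species get exactly 0.

Background and baseline are per-array statistics: each hybridization has
its own reference mix, so arrays are never pooled for thresholding.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import RANKS, AbundanceMatrix, ArrayManifest, SpotTable
from .exceptions import InputError, InsufficientDataError

logger = logging.getLogger(__name__)

#: Columns of the per-sample species signal frame.
SIGNAL_COLUMNS = ("mean_cy5", "mean_cy3", "ratio", "n_spots")


@dataclass(frozen=True)
class DetectionCall:
    """Outcome of the two-pass positivity rule for one species."""

    species: str
    background: float
    baseline_ratio: float
    pass_intensity: bool
    pass_ratio: bool

    @property
    def positive(self) -> bool:
        return self.pass_intensity and self.pass_ratio


def aggregate_spots(spots: SpotTable, manifest: ArrayManifest) -> pd.DataFrame:
    """Collapse spot replicates to per-species channel means and ratio.

    Returns a frame indexed by species with columns ``mean_cy5``,
    ``mean_cy3``, ``ratio`` and ``n_spots``. A species whose reference
    channel averages to zero has an undefined ratio (NaN); it is flagged
    here and excluded from the ratio ranking downstream.
    """
    df = spots.data.copy()
    df["species"] = manifest.species_of(df["probe_id"])
    grouped = df.groupby("species", sort=True)
    out = pd.DataFrame(
        {
            "mean_cy5": grouped["cy5"].mean(),
            "mean_cy3": grouped["cy3"].mean(),
            "n_spots": grouped.size(),
        }
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = out["mean_cy5"] / out["mean_cy3"]
    out["ratio"] = ratio.where(out["mean_cy3"] > 0, np.nan)
    if out["ratio"].isna().any():
        bad = list(out.index[out["ratio"].isna()])
        logger.warning("species with zero reference signal, ratio undefined: %s", bad[:5])
    return out[list(SIGNAL_COLUMNS)]


def estimate_background(signals: pd.DataFrame) -> float:
    """Background fluorescence: mean Cy5 of the dimmest 30% of species.

    Species are ranked ascending by mean signal intensity (the Cy5 test
    channel); the lowest ``floor(0.3 * S)`` species (at least one) are
    averaged. Ties in intensity are broken by species label so the
    selected set is reproducible; ties cannot change the mean itself
    unless they straddle the cut.
    """
    n = len(signals)
    if n < 4:
        raise InsufficientDataError(f"background needs >= 4 species, got {n}")
    k = max(1, math.floor(0.3 * n))
    ranked = signals.reset_index().sort_values(["mean_cy5", "species"], kind="mergesort")
    return float(ranked["mean_cy5"].iloc[:k].mean())


def estimate_baseline_ratio(signals: pd.DataFrame) -> float:
    """Baseline Cy5/Cy3: mean of the lower half of the ratio ranking.

    Only species with a defined ratio participate; the lowest
    ``floor(S/2)`` ratios are averaged.
    """
    defined = signals.dropna(subset=["ratio"])
    n = len(defined)
    if n < 2:
        raise InsufficientDataError(f"baseline ratio needs >= 2 defined ratios, got {n}")
    k = max(1, math.floor(n / 2))
    ranked = defined.reset_index().sort_values(["ratio", "species"], kind="mergesort")
    return float(ranked["ratio"].iloc[:k].mean())


def call_detection(
    signals: pd.DataFrame,
    background: float,
    baseline_ratio: float,
    fold: float = 5.0,
) -> list[DetectionCall]:
    """Two-pass positivity: intensity filter then ratio filter.

    Both comparisons are strict: a species sitting exactly at
    ``fold x background`` (or ``fold x baseline``) is negative. Species
    with an undefined ratio fail the ratio pass.
    """
    cy5 = signals["mean_cy5"].to_numpy(dtype=float)
    ratio = signals["ratio"].to_numpy(dtype=float)
    pass_intensity = cy5 > fold * background
    pass_ratio = ~np.isnan(ratio) & (ratio > fold * baseline_ratio)
    return [
        DetectionCall(
            species=str(species),
            background=background,
            baseline_ratio=baseline_ratio,
            pass_intensity=bool(pi),
            pass_ratio=bool(pr),
        )
        for species, pi, pr in zip(signals.index, pass_intensity, pass_ratio)
    ]


def normalize_abundance(calls: list[DetectionCall], signals: pd.DataFrame) -> pd.Series:
    """Relative abundance: each positive species' ratio over the positive total.

    Negative species get exactly 0. If no species is positive the row is
    all zero and a warning is logged (the sample is effectively blank).
    """
    abundance = pd.Series(0.0, index=signals.index)
    positive = [c.species for c in calls if c.positive]
    if not positive:
        logger.warning("no positive species on this array; emitting an all-zero row")
        return abundance
    ratios = signals.loc[positive, "ratio"]
    abundance.loc[positive] = ratios / ratios.sum()
    return abundance


def quantify_sample(
    spots: SpotTable, manifest: ArrayManifest, fold: float = 5.0
) -> tuple[pd.Series, pd.DataFrame]:
    """Run the full chain for one array.

    Returns the abundance row and a per-species report frame
    (signal columns + background, baseline and the three flags).
    """
    signals = aggregate_spots(spots, manifest)
    background = estimate_background(signals)
    baseline = estimate_baseline_ratio(signals)
    calls = call_detection(signals, background, baseline, fold=fold)
    abundance = normalize_abundance(calls, signals)
    report = signals.copy()
    report["background"] = background
    report["baseline_ratio"] = baseline
    report["pass_intensity"] = [c.pass_intensity for c in calls]
    report["pass_ratio"] = [c.pass_ratio for c in calls]
    report["positive"] = [c.positive for c in calls]
    report["abundance"] = abundance
    return abundance, report


def quantify_cohort(
    spot_tables: list[SpotTable],
    manifest: ArrayManifest,
    fold: float = 5.0,
) -> AbundanceMatrix:
    """Quantify every sample against one shared manifest.

    Background and baseline are estimated independently per array. The
    matrix columns are the union of species over the manifest, so every
    sample row is comparable.
    """
    ids = [t.sample_id for t in spot_tables]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise InputError(f"duplicate sample ids: {dupes}")
    rows = {}
    flags = {}
    species = manifest.species
    for table in spot_tables:
        abundance, report = quantify_sample(table, manifest, fold=fold)
        rows[table.sample_id] = abundance.reindex(species, fill_value=0.0)
        flags[table.sample_id] = report["positive"].reindex(species, fill_value=False)
    abundance_df = pd.DataFrame(rows).T[species]
    detected_df = pd.DataFrame(flags).T[species].astype(bool)
    return AbundanceMatrix(abundance=abundance_df, detected=detected_df, rank="species")


def aggregate_to_rank(
    matrix: AbundanceMatrix, manifest: ArrayManifest, rank: str
) -> AbundanceMatrix:
    """Sum species abundances into taxa of the requested rank.

    Aggregation preserves row sums; a taxon counts as detected in a
    sample when any of its species does. Aggregating to ``species`` is
    the identity.
    """
    if rank not in RANKS:
        raise InputError(f"unknown rank {rank!r}; expected one of {RANKS}")
    if rank == "species":
        return matrix
    mapping = manifest.rank_of(rank)
    missing = set(matrix.taxa) - set(mapping.index)
    if missing:
        raise InputError(f"species missing from manifest: {sorted(missing)[:3]}")
    groups = mapping.loc[matrix.taxa]
    abundance = matrix.abundance.T.groupby(groups.to_numpy()).sum().T
    detected = matrix.detected.T.groupby(groups.to_numpy()).any().T
    return AbundanceMatrix(abundance=abundance, detected=detected, rank=rank)
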