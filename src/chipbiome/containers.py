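"""Core in-memory containers shared across the pipeline.

The pipeline's data model is deliberately thin: each container wraps a
:class:`pandas.DataFrame` in the orientation the downstream stages expect,
plus the invariants that make the stages composable (probes resolve to a
taxonomy, abundance rows are compositions over positive calls, ...).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InputError

#: Taxonomic ranks known to the manifest, most to least resolved.
RANKS = ("species", "genus", "family", "order")

#: Serum cytokine panel measured alongside the stool samples.
CYTOKINES = ("IL-1B", "IL-2R", "IL-6", "IL-8", "IL-10", "TNF-a")

#: Label used in Ct tables for the universal 16S primer pair.
UNIVERSAL = "UNIVERSAL"


@dataclass
class SpotTable:
    """Per-spot two-channel fluorescence for a single hybridized array.

    ``data`` has one row per printed spot with columns ``probe_id``,
    ``cy5`` (test-sample channel, 635 nm foreground) and ``cy3``
    (reference-pool channel, 532 nm foreground). Layout columns
    (``block``, ``row``, ``column``) are preserved when present but are
    not used analytically.
    """

    sample_id: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = {"probe_id", "cy5", "cy3"} - set(self.data.columns)
        if missing:
            raise InputError(f"spot table {self.sample_id!r} lacks columns {sorted(missing)}")
        if (self.data[["cy5", "cy3"]].to_numpy() < 0).any():
            raise InputError(f"spot table {self.sample_id!r} has negative intensities")


@dataclass
class ArrayManifest:
    """Probe-to-taxonomy map for one array design.

    ``data`` is indexed by ``probe_id`` with columns ``species``,
    ``genus``, ``family``, ``order``. The rank mapping must be
    functional: every species has exactly one genus, every genus one
    family, every family one order.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(RANKS) - set(self.data.columns)
        if missing:
            raise InputError(f"manifest lacks rank columns {sorted(missing)}")
        for child, parent in zip(RANKS[:-1], RANKS[1:]):
            n_parents = self.data.groupby(child, sort=False)[parent].nunique()
            bad = n_parents[n_parents > 1]
            if len(bad):
                raise InputError(
                    f"manifest maps {child} {bad.index[0]!r} to multiple {parent} taxa"
                )

    @property
    def species(self) -> list[str]:
        return sorted(self.data["species"].unique())

    def species_of(self, probe_ids: pd.Series) -> pd.Series:
        """Resolve probe ids to species labels; unknown probes are an error."""
        mapped = probe_ids.map(self.data["species"])
        if mapped.isna().any():
            orphan = probe_ids[mapped.isna()].iloc[0]
            raise InputError(f"probe {orphan!r} absent from manifest")
        return mapped

    def rank_of(self, rank: str) -> pd.Series:
        """Species -> taxon mapping at the requested rank."""
        if rank not in RANKS:
            raise InputError(f"unknown rank {rank!r}; expected one of {RANKS}")
        return self.data.drop_duplicates("species").set_index("species")[rank]


@dataclass
class AbundanceMatrix:
    """Samples x taxa relative abundances with per-cell detection flags.

    Each row is a composition over the taxa called positive in that
    sample: positive cells are fractions summing to 1, non-positive
    cells are exactly 0. A sample with no positive call has an all-zero
    row.
    """

    abundance: pd.DataFrame
    detected: pd.DataFrame
    rank: str = "species"

    def __post_init__(self) -> None:
        if not self.abundance.index.equals(self.detected.index) or not self.abundance.columns.equals(
            self.detected.columns
        ):
            raise InputError("abundance and detection grids are misaligned")
        sums = self.abundance.sum(axis=1).to_numpy()
        if not np.all((np.abs(sums - 1.0) < 1e-9) | (sums == 0.0)):
            raise InputError("abundance rows must sum to 1 (or 0 when nothing is positive)")

    @property
    def samples(self) -> list[str]:
        return list(self.abundance.index)

    @property
    def taxa(self) -> list[str]:
        return list(self.abundance.columns)


@dataclass
class SampleMetadata:
    """Group labels and the serum cytokine panel, indexed by sample id."""

    data: pd.DataFrame
    group_column: str = "group"

    def __post_init__(self) -> None:
        if self.group_column not in self.data.columns:
            raise InputError(f"metadata lacks group column {self.group_column!r}")

    @property
    def groups(self) -> pd.Series:
        return self.data[self.group_column]

    def cytokines(self) -> pd.DataFrame:
        present = [c for c in CYTOKINES if c in self.data.columns]
        return self.data[present]


@dataclass
class CtTable:
    """qPCR threshold cycles, long format.

    Columns: ``sample_id``, ``target`` (species label or ``UNIVERSAL``),
    ``ct`` (cycles, duplicate wells already averaged), ``censored``
    (no amplification within the run's cycle ceiling).
    """

    data: pd.DataFrame
    max_cycle: float = 45.0

    def __post_init__(self) -> None:
        missing = {"sample_id", "target", "ct", "censored"} - set(self.data.columns)
        if missing:
            raise InputError(f"Ct table lacks columns {sorted(missing)}")
        ct = self.data["ct"].to_numpy(dtype=float)
        if ((ct <= 0) | (ct > self.max_cycle)).any():
            raise InputError(f"Ct values must lie in (0, {self.max_cycle}]")

    def universal(self) -> pd.Series:
        """Per-sample universal-primer Ct; every sample must carry one."""
        uni = self.data[self.data["target"] == UNIVERSAL].set_index("sample_id")["ct"]
        specific = self.data.loc[self.data["target"] != UNIVERSAL, "sample_id"]
        missing = set(specific) - set(uni.index)
        if missing:
            raise InputError(f"samples without a universal Ct: {sorted(missing)[:3]}")
        return uni
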