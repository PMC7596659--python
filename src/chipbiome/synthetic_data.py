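"""Synthetic two-channel 16S microarray cohorts with known ground truth.

The generator emulates the structure of a case/control gut-microbiome
microarray study: an array whose probes cover more species than any one
gut community contains, a log-normal community abundance profile, a
group effect applied as fold-changes on selected species, triplicate
spot printing with multiplicative scanner noise on both channels, a
serum cytokine panel linearly coupled to selected species, and a qPCR
Ct table constructed so the universal-vs-specific ΔCt formula inverts
exactly to the planted relative abundance when noise is zero.

Every draw is derived from a single integer seed via independent,
stage-keyed :class:`numpy.random.Generator` streams, so identical
configurations reproduce byte-identical artifacts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .containers import CYTOKINES, UNIVERSAL, ArrayManifest, CtTable, SampleMetadata, SpotTable
from .exceptions import ConfigurationError

#: Typical serum baselines (pg/mL except IL-2R in U/mL) used as cytokine intercepts.
CYTOKINE_BASELINES = {
    "IL-1B": 5.0,
    "IL-2R": 500.0,
    "IL-6": 7.0,
    "IL-8": 15.0,
    "IL-10": 5.0,
    "TNF-a": 10.0,
}

_STREAMS = {"community": 1, "samples": 2, "spots": 3, "metadata": 4, "ct": 5}


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort.

    The cohort shape (58 leukemia cases vs 23 healthy controls) is the
    default study design; every distributional choice the real study
    leaves unobservable (abundance spread, effect sizes, scanner noise)
    is surfaced here rather than hard-coded.
    """

    n_all: int = 58
    n_nc: int = 23
    n_species: int = 150
    n_differential: int = 15
    present_fraction: float = 0.5
    triplicate_cv: float = 0.15
    background_mean: float = 100.0
    signal_scale: float = 1.0e6
    reference_channel_mean: float = 500.0
    abundance_sigma: float = 1.0
    sample_sigma: float = 0.4
    fold_min: float = 2.0
    fold_max: float = 8.0
    species_per_genus: int = 3
    genera_per_family: int = 3
    families_per_order: int = 3
    cytokine_coupling_strength: float = 1.0
    cytokine_noise: float = 0.3
    ct_universal_mean: float = 15.0
    ct_noise_sd: float = 0.25
    max_cycle: float = 45.0
    n_qpcr_targets: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_all": self.n_all,
            "n_nc": self.n_nc,
            "n_species": self.n_species,
        }
        for name, value in counts.items():
            if value < 1:
                raise ConfigurationError(f"{name} must be >= 1, got {value}")
        if self.n_differential < 0 or self.n_differential > self.n_present:
            raise ConfigurationError(
                f"n_differential must lie in [0, {self.n_present}], got {self.n_differential}"
            )
        if self.triplicate_cv < 0:
            raise ConfigurationError("triplicate_cv must be >= 0")
        if not 0 < self.present_fraction <= 1:
            raise ConfigurationError("present_fraction must be in (0, 1]")
        if self.fold_min <= 0 or self.fold_max < self.fold_min:
            raise ConfigurationError("fold range must satisfy 0 < fold_min <= fold_max")
        if self.background_mean <= 0 or self.reference_channel_mean <= 0 or self.signal_scale <= 0:
            raise ConfigurationError("intensity scales must be positive")

    @property
    def n_present(self) -> int:
        return max(1, round(self.present_fraction * self.n_species))

    @property
    def n_samples(self) -> int:
        return self.n_all + self.n_nc

    def rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STREAMS[stage]])


@dataclass
class CommunityTruth:
    """Ground truth of a simulated cohort.

    ``base_abundance`` is the community composition shared by both
    groups before the group effect; species absent from the community
    (but present on the array) carry exactly 0. ``differential`` maps
    species -> (fold_change, enriched_group): samples of the enriched
    group have that species' base abundance multiplied by the fold
    before per-sample renormalization. ``cytokine_coupling`` maps
    cytokine -> (species, slope, noise_sd); metadata rendering adds the
    cytokine's serum baseline as intercept.
    """

    species_names: list[str]
    base_abundance: np.ndarray
    differential: dict[str, tuple[float, str]]
    group_assignment: pd.Series
    cytokine_coupling: dict[str, tuple[str, float, float]]

    def __post_init__(self) -> None:
        if abs(float(self.base_abundance.sum()) - 1.0) > 1e-9:
            raise ConfigurationError("base_abundance must sum to 1")
        names = set(self.species_names)
        for sp, (fold, group) in self.differential.items():
            if sp not in names:
                raise ConfigurationError(f"differential species {sp!r} not in community")
            if fold <= 0:
                raise ConfigurationError(f"fold-change for {sp!r} must be > 0")
        for cyt, (sp, _, _) in self.cytokine_coupling.items():
            if cyt not in CYTOKINES:
                raise ConfigurationError(f"unknown cytokine {cyt!r}")
            if sp not in names:
                raise ConfigurationError(f"coupled species {sp!r} not in community")

    @property
    def differential_species(self) -> list[str]:
        return list(self.differential)


def _species_name(i: int) -> str:
    return f"Species_{i + 1:04d}"


def generate_community(
    config: SimulationConfig,
    differential: dict[str, tuple[float, str]] | None = None,
) -> CommunityTruth:
    """Draw a community profile and plant the group effect.

    Base abundances are log-normal over the present species and zero for
    array species absent from the community. Unless ``differential`` is
    given explicitly, the differential species are drawn from the
    better-represented half of the community (a fold-change on a species
    near the detection floor would be invisible to any platform), with
    fold-changes uniform on [fold_min, fold_max] and enriched groups
    alternating between cases and controls.
    """
    rng = config.rng("community")
    names = [_species_name(i) for i in range(config.n_species)]

    present_idx = np.sort(rng.choice(config.n_species, size=config.n_present, replace=False))
    base = np.zeros(config.n_species)
    base[present_idx] = rng.lognormal(mean=0.0, sigma=config.abundance_sigma, size=config.n_present)
    base /= base.sum()

    if differential is None:
        present_base = base[present_idx]
        eligible = present_idx[present_base >= np.median(present_base)]
        n_diff = min(config.n_differential, len(eligible))
        chosen = rng.choice(eligible, size=n_diff, replace=False)
        differential = {}
        for k, idx in enumerate(sorted(chosen)):
            fold = float(rng.uniform(config.fold_min, config.fold_max))
            differential[names[idx]] = (fold, "ALL" if k % 2 == 0 else "NC")

    sample_ids = [f"ALL_{i + 1:03d}" for i in range(config.n_all)] + [
        f"NC_{i + 1:03d}" for i in range(config.n_nc)
    ]
    groups = pd.Series(
        ["ALL"] * config.n_all + ["NC"] * config.n_nc, index=sample_ids, name="group"
    )

    coupling: dict[str, tuple[str, float, float]] = {}
    diff_names = list(differential) or [names[present_idx[int(np.argmax(base[present_idx]))]]]
    for k, cyt in enumerate(CYTOKINES):
        sp = diff_names[k % len(diff_names)]
        sp_base = base[names.index(sp)]
        baseline = CYTOKINE_BASELINES[cyt]
        # slope scaled so a doubling of the species moves the cytokine by
        # coupling_strength x its serum baseline
        slope = config.cytokine_coupling_strength * baseline / max(sp_base, 1e-12)
        coupling[cyt] = (sp, slope, config.cytokine_noise * baseline)

    return CommunityTruth(
        species_names=names,
        base_abundance=base,
        differential=differential,
        group_assignment=groups,
        cytokine_coupling=coupling,
    )


def sample_abundances(truth: CommunityTruth, config: SimulationConfig) -> pd.DataFrame:
    """Per-sample true relative abundances (samples x species).

    Each sample perturbs the base community with log-normal dispersion,
    applies the group fold-changes, and renormalizes — so the group
    effect is compositional, as it would be in any relative measurement.
    """
    rng = config.rng("samples")
    base = truth.base_abundance
    n_sp = len(base)
    name_to_idx = {n: i for i, n in enumerate(truth.species_names)}
    rows = []
    for sample_id, group in truth.group_assignment.items():
        x = base.copy()
        if config.sample_sigma > 0:
            noise = rng.lognormal(mean=0.0, sigma=config.sample_sigma, size=n_sp)
        else:
            noise = np.ones(n_sp)
        x = x * noise
        for sp, (fold, up_group) in truth.differential.items():
            if group == up_group:
                x[name_to_idx[sp]] *= fold
        total = x.sum()
        rows.append(x / total if total > 0 else x)
    return pd.DataFrame(rows, index=truth.group_assignment.index, columns=truth.species_names)


def build_manifest(config: SimulationConfig) -> ArrayManifest:
    """Deterministic probe -> taxonomy map: one probe per species, with a
    balanced synthetic taxonomy (consecutive species share genera)."""
    records = []
    for i in range(config.n_species):
        g = i // config.species_per_genus
        f = g // config.genera_per_family
        o = f // config.families_per_order
        records.append(
            {
                "probe_id": f"probe_{i + 1:04d}",
                "species": _species_name(i),
                "genus": f"Genus_{g + 1:03d}",
                "family": f"Family_{f + 1:03d}",
                "order": f"Order_{o + 1:03d}",
            }
        )
    return ArrayManifest(data=pd.DataFrame.from_records(records).set_index("probe_id"))


def _lognormal_factor(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Unit-mean multiplicative noise with the requested coefficient of variation."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def render_spot_tables(
    truth: CommunityTruth, config: SimulationConfig
) -> tuple[list[SpotTable], ArrayManifest]:
    """Render one GenePix-style spot table per sample.

    Each species' probe is printed in triplicate. The Cy5 (test) channel
    is additive background plus a signal proportional to the sample's
    true abundance, each term carrying independent multiplicative
    log-normal noise; the Cy3 (reference-pool) channel lights up every
    spot at a common level with the same noise model. Species absent
    from the community receive background-only Cy5.
    """
    manifest = build_manifest(config)
    abundances = sample_abundances(truth, config)
    rng = config.rng("spots")
    probe_ids = np.repeat(manifest.data.index.to_numpy(), 3)
    n_spots = len(probe_ids)
    tables = []
    for sample_id in abundances.index:
        a = np.repeat(abundances.loc[sample_id].to_numpy(), 3)
        cy5 = config.background_mean * _lognormal_factor(
            rng, config.triplicate_cv, n_spots
        ) + config.signal_scale * a * _lognormal_factor(rng, config.triplicate_cv, n_spots)
        cy3 = config.reference_channel_mean * _lognormal_factor(rng, config.triplicate_cv, n_spots)
        data = pd.DataFrame(
            {
                "block": 1,
                "row": np.arange(n_spots) // 3 + 1,
                "column": np.arange(n_spots) % 3 + 1,
                "probe_id": probe_ids,
                "cy5": cy5,
                "cy3": cy3,
            }
        )
        tables.append(SpotTable(sample_id=sample_id, data=data))
    return tables, manifest


def render_metadata(truth: CommunityTruth, config: SimulationConfig) -> SampleMetadata:
    """Group labels plus a cytokine panel linearly coupled to species.

    cytokine = baseline + slope x (coupled species' true relative
    abundance) + Gaussian noise.
    """
    abundances = sample_abundances(truth, config)
    rng = config.rng("metadata")
    df = pd.DataFrame({"group": truth.group_assignment})
    for cyt, (sp, slope, noise_sd) in truth.cytokine_coupling.items():
        values = CYTOKINE_BASELINES[cyt] + slope * abundances[sp].to_numpy()
        if noise_sd > 0:
            values = values + rng.normal(0.0, noise_sd, size=len(values))
        df[cyt] = values
    return SampleMetadata(data=df)


def render_ct_table(
    truth: CommunityTruth,
    config: SimulationConfig,
    targets: list[str] | None = None,
) -> CtTable:
    """qPCR Ct table for selected target species plus the universal primer.

    Each recorded Ct is the average of two replicate wells. The specific
    Ct is constructed as Ct_universal - log2(true abundance) (+ noise),
    so the downstream ΔCt quantification ``2^(Ct_uni - Ct_spec) x 10^4``
    recovers exactly ``10^4 x abundance`` in the noise-free limit.
    Species with zero abundance never amplify: their Ct is censored at
    the run's cycle ceiling.
    """
    if targets is None:
        targets = truth.differential_species[: config.n_qpcr_targets]
    unknown = set(targets) - set(truth.species_names)
    if unknown:
        raise ConfigurationError(f"qPCR targets not in community: {sorted(unknown)}")
    abundances = sample_abundances(truth, config)
    rng = config.rng("ct")
    rows = []
    for sample_id in abundances.index:
        true_uni = config.ct_universal_mean
        uni_ct = float(np.mean(true_uni + rng.normal(0.0, config.ct_noise_sd, size=2)))
        rows.append(
            {"sample_id": sample_id, "target": UNIVERSAL, "ct": uni_ct, "censored": False}
        )
        for sp in targets:
            a = float(abundances.at[sample_id, sp])
            if a <= 0:
                rows.append(
                    {
                        "sample_id": sample_id,
                        "target": sp,
                        "ct": config.max_cycle,
                        "censored": True,
                    }
                )
                continue
            ideal = true_uni - math.log2(a)
            ct = float(np.mean(ideal + rng.normal(0.0, config.ct_noise_sd, size=2)))
            if ct >= config.max_cycle:
                rows.append(
                    {
                        "sample_id": sample_id,
                        "target": sp,
                        "ct": config.max_cycle,
                        "censored": True,
                    }
                )
            else:
                rows.append(
                    {"sample_id": sample_id, "target": sp, "ct": ct, "censored": False}
                )
    return CtTable(data=pd.DataFrame.from_records(rows), max_cycle=config.max_cycle)


@dataclass
class SimulatedCohort:
    """Bundle of all artifacts of one simulated study."""

    config: SimulationConfig
    truth: CommunityTruth
    spot_tables: list[SpotTable]
    manifest: ArrayManifest
    metadata: SampleMetadata
    ct_table: CtTable
    true_abundance: pd.DataFrame


def simulate_cohort(
    config: SimulationConfig,
    differential: dict[str, tuple[float, str]] | None = None,
) -> SimulatedCohort:
    """Generate a complete cohort: spots, manifest, metadata, Ct table."""
    truth = generate_community(config, differential=differential)
    spot_tables, manifest = render_spot_tables(truth, config)
    metadata = render_metadata(truth, config)
    ct_table = render_ct_table(truth, config)
    return SimulatedCohort(
        config=config,
        truth=truth,
        spot_tables=spot_tables,
        manifest=manifest,
        metadata=metadata,
        ct_table=ct_table,
        true_abundance=sample_abundances(truth, config),
    )


def write_cohort(cohort: SimulatedCohort, outdir: str | Path) -> dict[str, Path]:
    """Write every artifact as TSV under ``outdir``; returns the paths."""
    outdir = Path(outdir)
    spots_dir = outdir / "spots"
    spots_dir.mkdir(parents=True, exist_ok=True)
    for table in cohort.spot_tables:
        io.write_spot_table(table, spots_dir / f"{table.sample_id}.tsv")
    paths = {
        "spots": spots_dir,
        "manifest": outdir / "manifest.tsv",
        "metadata": outdir / "metadata.tsv",
        "ct": outdir / "ct.tsv",
        "true_abundance": outdir / "true_abundance.tsv",
    }
    io.write_manifest(cohort.manifest, paths["manifest"])
    io.write_metadata(cohort.metadata, paths["metadata"])
    io.write_ct_table(cohort.ct_table, paths["ct"])
    cohort.true_abundance.rename_axis("sample_id").to_csv(paths["true_abundance"], sep="\t")
    return paths
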