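"""End-to-end orchestration: simulate -> quantify -> diversity -> LEfSe ->
classify -> validate, driven by one structured config.

Stages communicate only through their declared file artifacts, every
artifact is hashed into a run manifest, and all randomness is derived
from explicit seeds in the config, so a rerun of the same config is
bit-identical for the deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import array_quant, classify, differential, diversity, io, plots, synthetic_data, validation
from .containers import RANKS
from .exceptions import ConfigurationError

logger = logging.getLogger(__name__)

STAGES = ("simulate", "quantify", "diversity", "differential", "classify", "validate")


@dataclass
class RunConfig:
    """One reproducible run of the whole pipeline."""

    outdir: str = "chipbiome_run"
    simulation: synthetic_data.SimulationConfig = field(
        default_factory=synthetic_data.SimulationConfig
    )
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    fold: float = 5.0
    alpha: float = 0.05
    lda_threshold: float = 2.0
    n_trees: int = 500
    n_permutations: int = 999
    nmds_starts: int = 20
    analysis_seed: int = 0
    correlate_group: str | None = "ALL"

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ConfigurationError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = synthetic_data.SimulationConfig(**raw.pop("simulation", {}))
        return cls(simulation=sim, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order.

    Returns the run manifest (parameters, artifact paths and hashes).
    A stage failure halts the run; artifacts of completed stages are
    left in place for inspection.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    seed = config.analysis_seed

    def record(name: str, path: Path) -> None:
        artifacts[name] = str(path.relative_to(outdir))

    enabled = [s for s in STAGES if s in config.stages]
    data_dir = outdir / "data"
    if "simulate" in enabled:
        logger.info("stage simulate: %d samples, %d species",
                    config.simulation.n_samples, config.simulation.n_species)
        cohort = synthetic_data.simulate_cohort(config.simulation)
        paths = synthetic_data.write_cohort(cohort, data_dir)
        for name, p in paths.items():
            if p.is_dir():
                for f in sorted(p.iterdir()):
                    record(f"spots/{f.name}", f)
            else:
                record(name, p)

    matrix = None
    if "quantify" in enabled:
        logger.info("stage quantify: fold threshold %s", config.fold)
        manifest = io.read_manifest(data_dir / "manifest.tsv")
        tables = [io.read_spot_table(p) for p in sorted((data_dir / "spots").iterdir())]
        matrix = array_quant.quantify_cohort(tables, manifest, fold=config.fold)
        io.write_abundance(matrix, outdir / "abundance.tsv", outdir / "detected.tsv")
        record("abundance", outdir / "abundance.tsv")
        record("detected", outdir / "detected.tsv")

    needs_data = [s for s in enabled if s not in ("simulate", "quantify")]
    if needs_data:
        if matrix is None:
            matrix = io.read_abundance(outdir / "abundance.tsv", outdir / "detected.tsv")
        metadata = io.read_metadata(data_dir / "metadata.tsv")
        groups = metadata.groups
        manifest = io.read_manifest(data_dir / "manifest.tsv")

    if "diversity" in enabled:
        logger.info("stage diversity: PERMANOVA with %d permutations", config.n_permutations)
        alpha_tab = diversity.alpha_diversity(matrix)
        alpha_tab.rename_axis("sample_id").to_csv(outdir / "alpha_diversity.tsv", sep="\t")
        record("alpha_diversity", outdir / "alpha_diversity.tsv")
        alpha_p = diversity.compare_alpha(alpha_tab, groups)
        dist = diversity.bray_curtis(matrix)
        pd.DataFrame(dist.data, index=dist.ids, columns=dist.ids).rename_axis("sample_id").to_csv(
            outdir / "bray_curtis.tsv", sep="\t"
        )
        record("bray_curtis", outdir / "bray_curtis.tsv")
        pcoa_res = diversity.pcoa(dist)
        nmds_res = diversity.nmds(dist, n_starts=config.nmds_starts, seed=seed)
        pcoa_res.coordinates.to_csv(outdir / "pcoa_coordinates.tsv", sep="\t")
        nmds_res.coordinates.to_csv(outdir / "nmds_coordinates.tsv", sep="\t")
        record("pcoa_coordinates", outdir / "pcoa_coordinates.tsv")
        record("nmds_coordinates", outdir / "nmds_coordinates.tsv")
        perm = diversity.permanova(dist, groups, n_permutations=config.n_permutations, seed=seed)
        summary = {
            "alpha_wilcoxon_p": alpha_p.to_dict(),
            "permanova": dataclasses.asdict(perm),
            "nmds_stress": nmds_res.stress,
        }
        (outdir / "diversity_summary.json").write_text(json.dumps(summary, indent=2))
        record("diversity_summary", outdir / "diversity_summary.json")
        plots.ordination_plot(pcoa_res, groups, outdir / "fig1a_pcoa.png")
        plots.ordination_plot(nmds_res, groups, outdir / "fig1b_nmds.png")

    if "differential" in enabled:
        logger.info("stage differential: alpha=%s, LDA threshold=%s",
                    config.alpha, config.lda_threshold)
        lefse = differential.run_lefse(
            matrix, groups, alpha=config.alpha, lda_threshold=config.lda_threshold, seed=seed
        )
        lefse.to_csv(outdir / "lefse_species.tsv", sep="\t", index=False)
        record("lefse_species", outdir / "lefse_species.tsv")
        clado = differential.build_cladogram_table(
            matrix, groups, manifest, alpha=config.alpha,
            lda_threshold=config.lda_threshold, seed=seed,
        )
        clado.to_csv(outdir / "cladogram_table.tsv", sep="\t", index=False)
        record("cladogram_table", outdir / "cladogram_table.tsv")
        plots.lefse_barplot(lefse, outdir / "fig2_lefse.png")

    if "classify" in enabled:
        logger.info("stage classify: %d trees, LOOCV per rank", config.n_trees)
        matrices = {r: array_quant.aggregate_to_rank(matrix, manifest, r) for r in RANKS}
        reports = classify.compare_ranks(matrices, groups, n_trees=config.n_trees, seed=seed)
        species_rep = reports["species"]
        species_rep.scores.rename_axis("sample_id").to_frame().to_csv(
            outdir / "loocv_scores.tsv", sep="\t"
        )
        record("loocv_scores", outdir / "loocv_scores.tsv")
        species_rep.curve.to_csv(outdir / "roc_points.tsv", sep="\t", index=False)
        record("roc_points", outdir / "roc_points.tsv")
        species_rep.importance.rename_axis("taxon").to_frame().to_csv(
            outdir / "importance.tsv", sep="\t"
        )
        record("importance", outdir / "importance.tsv")
        report_json = {
            r: {"auc": rep.auc, "ci": [rep.auc_ci_low, rep.auc_ci_high]}
            for r, rep in reports.items()
        }
        (outdir / "classifier_report.json").write_text(json.dumps(report_json, indent=2))
        record("classifier_report", outdir / "classifier_report.json")
        plots.roc_plot(reports, outdir / "fig4a_roc.png")
        plots.importance_plot(species_rep.importance, outdir / "fig4b_importance.png")

    if "validate" in enabled:
        logger.info("stage validate: qPCR concordance and cytokine correlations")
        ct = io.read_ct_table(data_dir / "ct.tsv", max_cycle=config.simulation.max_cycle)
        concord = validation.compare_platforms(matrix, ct, groups)
        concord.to_csv(outdir / "qpcr_concordance.tsv", sep="\t", index=False)
        record("qpcr_concordance", outdir / "qpcr_concordance.tsv")
        corr = validation.spearman_matrix(matrix, metadata, group_filter=config.correlate_group)
        corr.to_csv(outdir / "cytokine_correlations.tsv", sep="\t", index=False)
        record("cytokine_correlations", outdir / "cytokine_correlations.tsv")
        plots.correlation_heatmap(corr, outdir / "fig5_correlations.png")

    manifest_doc = {
        "config": config.to_dict(),
        "stages_run": enabled,
        "artifacts": {name: _sha256(outdir / rel) for name, rel in sorted(artifacts.items())},
    }
    (outdir / "run_manifest.json").write_text(json.dumps(manifest_doc, indent=2, sort_keys=True))
    return manifest_doc


_REPORT_SECTIONS = (
    ("Beta diversity (ordination and PERMANOVA)", ["fig1a_pcoa.png", "fig1b_nmds.png"],
     "diversity_summary.json"),
    ("Differential taxa (LEfSe)", ["fig2_lefse.png"], "lefse_species.tsv"),
    ("qPCR validation", [], "qpcr_concordance.tsv"),
    ("Classification (random forest, LOOCV)", ["fig4a_roc.png", "fig4b_importance.png"],
     "classifier_report.json"),
    ("Species-cytokine correlations", ["fig5_correlations.png"], "cytokine_correlations.tsv"),
)


def make_report(outdir: str | Path) -> Path:
    """Assemble a markdown summary of a completed run (idempotent)."""
    outdir = Path(outdir)
    manifest_path = outdir / "run_manifest.json"
    manifest = json.loads(manifest_path.read_text()) if manifest_path.exists() else {}
    lines = ["# chipbiome run report", ""]
    for title, figures, key_artifact in _REPORT_SECTIONS:
        lines.append(f"## {title}")
        path = outdir / key_artifact
        if not path.exists():
            lines.append("_Section absent: stage not run._")
            lines.append("")
            continue
        if path.suffix == ".json":
            lines.append("```json")
            lines.append(path.read_text().strip())
            lines.append("```")
        else:
            df = pd.read_csv(path, sep="\t")
            if df.empty:
                lines.append("_No taxa passed._" if "lefse" in key_artifact else "_Empty table._")
            else:
                lines.append(df.head(15).to_markdown(index=False))
        for fig in figures:
            if (outdir / fig).exists():
                lines.append(f"![{fig}]({fig})")
        lines.append("")
    if manifest:
        lines.append("## Provenance")
        lines.append(f"Stages run: {', '.join(manifest.get('stages_run', []))}.")
        seeds = {
            "simulation seed": manifest["config"]["simulation"]["seed"],
            "analysis seed": manifest["config"]["analysis_seed"],
        }
        lines.append(f"Seeds: {seeds}.")
    report_path = outdir / "report.md"
    report_path.write_text("\n".join(lines) + "\n")
    return report_path
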