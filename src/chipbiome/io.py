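"""Readers and writers for the pipeline's plain-text exchange formats.

All artifacts are tab-separated text so that runs diff cleanly and stay
inspectable. Spot files follow the GenePix results layout used by
dual-channel scanners: one file per hybridized array with columns
``Block``, ``Row``, ``Column``, ``Probe_ID``, ``F635_Mean`` (Cy5) and
``F532_Mean`` (Cy3).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .containers import AbundanceMatrix, ArrayManifest, CtTable, SampleMetadata, SpotTable
from .exceptions import InputError

_GPR_COLUMNS = ["Block", "Row", "Column", "Probe_ID", "F635_Mean", "F532_Mean"]


def write_spot_table(table: SpotTable, path: str | Path) -> None:
    df = table.data.copy()
    for layout, default in (("block", 1), ("row", 0), ("column", 0)):
        if layout not in df.columns:
            df[layout] = default
    out = df.rename(
        columns={
            "block": "Block",
            "row": "Row",
            "column": "Column",
            "probe_id": "Probe_ID",
            "cy5": "F635_Mean",
            "cy3": "F532_Mean",
        }
    )[_GPR_COLUMNS]
    out.to_csv(path, sep="\t", index=False)


def read_spot_table(path: str | Path, sample_id: str | None = None) -> SpotTable:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    missing = set(_GPR_COLUMNS) - set(df.columns)
    if missing:
        raise InputError(f"{path.name}: not a spot file, missing {sorted(missing)}")
    data = df.rename(
        columns={
            "Block": "block",
            "Row": "row",
            "Column": "column",
            "Probe_ID": "probe_id",
            "F635_Mean": "cy5",
            "F532_Mean": "cy3",
        }
    )
    return SpotTable(sample_id=sample_id or path.stem, data=data)


def write_manifest(manifest: ArrayManifest, path: str | Path) -> None:
    manifest.data.rename_axis("probe_id").to_csv(path, sep="\t")


def read_manifest(path: str | Path) -> ArrayManifest:
    df = pd.read_csv(path, sep="\t").set_index("probe_id")
    return ArrayManifest(data=df)


def write_metadata(metadata: SampleMetadata, path: str | Path) -> None:
    metadata.data.rename_axis("sample_id").to_csv(path, sep="\t")


def read_metadata(path: str | Path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t").set_index("sample_id")
    return SampleMetadata(data=df)


def write_ct_table(table: CtTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index=False)


def read_ct_table(path: str | Path, max_cycle: float = 45.0) -> CtTable:
    df = pd.read_csv(path, sep="\t")
    df["censored"] = df["censored"].astype(bool)
    return CtTable(data=df, max_cycle=max_cycle)


def write_abundance(matrix: AbundanceMatrix, abundance_path: str | Path, detected_path: str | Path | None = None) -> None:
    matrix.abundance.rename_axis("sample_id").to_csv(abundance_path, sep="\t")
    if detected_path is not None:
        matrix.detected.astype(int).rename_axis("sample_id").to_csv(detected_path, sep="\t")


def read_abundance(
    abundance_path: str | Path,
    detected_path: str | Path | None = None,
    rank: str = "species",
) -> AbundanceMatrix:
    ab = pd.read_csv(abundance_path, sep="\t").set_index("sample_id")
    if detected_path is not None:
        det = pd.read_csv(detected_path, sep="\t").set_index("sample_id").astype(bool)
    else:
        det = ab > 0
    return AbundanceMatrix(abundance=ab, detected=det, rank=rank)
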