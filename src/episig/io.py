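"""Readers and writers for the text formats the pipeline touches.

TSV is the canonical dialect; CSV is accepted via ``dialect="csv"``.
Missing beta values are encoded as ``NA``.  Model objects serialize to a
single versioned JSON document.
"""

from __future__ import annotations

import json
import os
from typing import Any

import numpy as np
import pandas as pd

from .types import (
    BetaMatrix,
    FormatError,
    PhenotypeTable,
    ProbeManifest,
    SampleSheet,
    ValidationError,
)

__all__ = [
    "read_beta_matrix",
    "write_beta_matrix",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_manifest",
    "write_manifest",
    "read_phenotype_table",
    "write_phenotype_table",
    "write_results",
    "read_table",
]

_SEPS = {"tsv": "\t", "csv": ","}


def _sep(dialect: str) -> str:
    try:
        return _SEPS[dialect]
    except KeyError:
        raise FormatError(f"unknown dialect {dialect!r}; use 'tsv' or 'csv'") from None


def read_beta_matrix(path: str | os.PathLike, dialect: str = "tsv") -> BetaMatrix:
    """Read a probe-by-sample beta matrix.

    The first column holds probe ids, the header row sample ids.  Values
    outside [0, 1] raise :class:`ValidationError` (never clamped); ``NA``
    marks a missing measurement.
    """
    df = pd.read_csv(path, sep=_sep(dialect), index_col=0, na_values=["NA"],
                     keep_default_na=False)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric beta value in {path}: {exc}") from exc
    return BetaMatrix(df)


def write_beta_matrix(beta: BetaMatrix, path: str | os.PathLike,
                      dialect: str = "tsv") -> None:
    df = beta.data.round(6)
    df.index.name = "probe_id"
    df.to_csv(path, sep=_sep(dialect), na_rep="NA", float_format="%.6f")


def read_sample_sheet(path: str | os.PathLike) -> SampleSheet:
    """Read a sample sheet TSV with columns sample_id, role, cohort_label.

    Unknown extra columns are preserved as covariates.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=["NA"],
                     keep_default_na=False)
    if "sample_id" not in df.columns:
        raise FormatError(f"{path}: sample sheet missing 'sample_id' column")
    df = df.set_index("sample_id")
    df.index = df.index.astype(str)
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path: str | os.PathLike) -> None:
    df = sheet.data.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", na_rep="NA")


def read_manifest(directory: str | os.PathLike) -> ProbeManifest:
    """Read a manifest directory: probes.tsv, islands.bed, genes.tsv."""
    directory = os.fspath(directory)
    probes = pd.read_csv(os.path.join(directory, "probes.tsv"), sep="\t",
                         dtype={"probe_id": str, "chrom": str, "pos": int})
    probes = probes.set_index("probe_id")
    islands = pd.read_csv(
        os.path.join(directory, "islands.bed"), sep="\t",
        names=["chrom", "start", "end"], dtype={"chrom": str},
    )
    genes = pd.read_csv(os.path.join(directory, "genes.tsv"), sep="\t",
                        dtype={"gene_id": str, "chrom": str, "strand": str,
                               "tss": int, "cds_blocks": str},
                        na_values=[], keep_default_na=False)
    genes = genes.set_index("gene_id")
    genes["cds_blocks"] = [_parse_blocks(b) for b in genes["cds_blocks"]]
    return ProbeManifest(probes=probes, islands=islands, genes=genes)


def _parse_blocks(text: str) -> list[tuple[int, int]]:
    if not text or text == ".":
        return []
    blocks = []
    for part in text.split(";"):
        s, e = part.split("-")
        blocks.append((int(s), int(e)))
    return blocks


def _format_blocks(blocks: list[tuple[int, int]]) -> str:
    return ";".join(f"{s}-{e}" for s, e in blocks) or "."


def write_manifest(manifest: ProbeManifest, directory: str | os.PathLike) -> None:
    directory = os.fspath(directory)
    os.makedirs(directory, exist_ok=True)
    probes = manifest.probes.copy()
    probes.index.name = "probe_id"
    probes.to_csv(os.path.join(directory, "probes.tsv"), sep="\t")
    manifest.islands.to_csv(os.path.join(directory, "islands.bed"), sep="\t",
                            header=False, index=False)
    genes = manifest.genes.copy()
    genes["cds_blocks"] = [_format_blocks(b) for b in genes["cds_blocks"]]
    genes.index.name = "gene_id"
    genes.to_csv(os.path.join(directory, "genes.tsv"), sep="\t")


def read_phenotype_table(path: str | os.PathLike) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=[],
                     keep_default_na=False)
    if "individual_id" not in df.columns:
        raise FormatError(f"{path}: phenotype table missing 'individual_id' column")
    df = df.set_index("individual_id")
    return PhenotypeTable(df)


def write_phenotype_table(table: PhenotypeTable, path: str | os.PathLike) -> None:
    df = table.data.copy()
    df.index.name = "individual_id"
    df.to_csv(path, sep="\t")


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a generic results TSV (DMP table, MVP table, DMR table...)."""
    return pd.read_csv(path, sep="\t")


def write_results(obj: Any, path: str | os.PathLike, format: str | None = None) -> None:
    """Serialize a result object.

    DataFrames become TSV (header always written, so an empty table yields
    a header-only file); objects exposing ``to_dict`` become a single JSON
    document.
    """
    if isinstance(obj, pd.DataFrame):
        df = obj
        df.to_csv(path, sep="\t", index=False, na_rep="NA")
    elif hasattr(obj, "to_dict"):
        payload = obj.to_dict()
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True, default=_json_default)
            fh.write("\n")
    else:
        raise ValidationError(
            f"cannot serialize object of type {type(obj).__name__}"
        )


def _json_default(value: Any) -> Any:
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.floating,)):
        return float(value)
    if isinstance(value, np.ndarray):
        return value.tolist()
    raise TypeError(f"not JSON serializable: {type(value).__name__}")
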