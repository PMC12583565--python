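"""Annotation of probes and DMRs by CpG-island and gene context.

CpG axis: ``island`` (inside an island), ``shore`` (within 2 kb of an
island boundary), ``shelf`` (2-4 kb), ``inter_CGI`` (beyond 4 kb).
Gene axis: ``promoter`` (0-1 kb upstream of a TSS, strand-aware),
``promoter_plus`` (1-5 kb upstream), ``CDS`` (inside a coding block),
``intergenic``.  The axes are independent; each feature gets exactly one
category per axis, with gene precedence promoter > promoter_plus > CDS.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .dmr import DmrRecord
from .types import ProbeManifest, ValidationError

__all__ = [
    "CPG_CATEGORIES",
    "GENE_CATEGORIES",
    "annotate_cpg_context",
    "annotate_gene_context",
    "annotate_probes",
    "annotate_dmrs",
    "summarize_context",
]

CPG_CATEGORIES = ("island", "shore", "shelf", "inter_CGI")
GENE_CATEGORIES = ("promoter", "promoter_plus", "CDS", "intergenic")

SHORE_BP = 2_000
SHELF_BP = 4_000
PROMOTER_BP = 1_000
PROMOTER_PLUS_BP = 5_000


def annotate_cpg_context(pos: int, chrom: str, islands: pd.DataFrame) -> str:
    """CpG-island category of a single position.

    Distance to an island is ``start - pos`` on the left flank and
    ``pos - end`` on the right flank of the half-open interval.
    """
    sub = islands[islands["chrom"] == chrom]
    if sub.empty:
        return "inter_CGI"
    start = sub["start"].to_numpy()
    end = sub["end"].to_numpy()
    inside = (pos >= start) & (pos < end)
    if inside.any():
        return "island"
    dist = np.where(pos < start, start - pos, pos - end).min()
    if dist <= SHORE_BP:
        return "shore"
    if dist <= SHELF_BP:
        return "shelf"
    return "inter_CGI"


def annotate_gene_context(
    pos: int, chrom: str, genes: pd.DataFrame
) -> tuple[str, str | None]:
    """Gene category and nearest gene for a single position.

    Upstream distance is strand-aware: ``tss - pos`` for ``+`` genes,
    ``pos - tss`` for ``-`` genes.  Within the winning category the gene
    with the nearest TSS is reported; for ``intergenic`` the nearest gene
    on the chromosome (if any).
    """
    sub = genes[genes["chrom"] == chrom]
    if sub.empty:
        return "intergenic", None
    bad = sub[~sub["strand"].isin(["+", "-"])]
    if len(bad):
        raise ValidationError(f"gene {bad.index[0]!r} lacks a valid strand")
    tss = sub["tss"].to_numpy()
    upstream = np.where(sub["strand"].to_numpy() == "+", tss - pos, pos - tss)
    abs_tss_dist = np.abs(tss - pos)

    promoter = (upstream >= 0) & (upstream <= PROMOTER_BP)
    if promoter.any():
        i = np.argmin(np.where(promoter, upstream, np.inf))
        return "promoter", str(sub.index[i])
    promoter_plus = (upstream > PROMOTER_BP) & (upstream <= PROMOTER_PLUS_BP)
    if promoter_plus.any():
        i = np.argmin(np.where(promoter_plus, upstream, np.inf))
        return "promoter_plus", str(sub.index[i])
    in_cds = np.array([
        any(s <= pos < e for s, e in blocks) for blocks in sub["cds_blocks"]
    ])
    if in_cds.any():
        i = np.argmin(np.where(in_cds, abs_tss_dist, np.inf))
        return "CDS", str(sub.index[i])
    return "intergenic", str(sub.index[np.argmin(abs_tss_dist)])


def annotate_probes(
    probe_ids: Sequence[str], manifest: ProbeManifest
) -> pd.DataFrame:
    """Annotate probes on both axes.

    Returns a DataFrame with columns ``feature_id, chrom, pos,
    cpg_category, gene_category, nearest_gene_id``.
    """
    positions = manifest.positions(list(probe_ids))
    rows = []
    for pid, row in positions.iterrows():
        chrom, pos = str(row["chrom"]), int(row["pos"])
        cpg = annotate_cpg_context(pos, chrom, manifest.islands)
        gene_cat, gene_id = annotate_gene_context(pos, chrom, manifest.genes)
        rows.append((pid, chrom, pos, cpg, gene_cat, gene_id))
    return pd.DataFrame(rows, columns=["feature_id", "chrom", "pos",
                                       "cpg_category", "gene_category",
                                       "nearest_gene_id"])


def annotate_dmrs(dmrs: list[DmrRecord], manifest: ProbeManifest) -> pd.DataFrame:
    """Annotate regions by their midpoint position."""
    rows = []
    for i, d in enumerate(dmrs):
        mid = (d.start + d.end) // 2
        cpg = annotate_cpg_context(mid, d.chrom, manifest.islands)
        gene_cat, gene_id = annotate_gene_context(mid, d.chrom, manifest.genes)
        rows.append((f"dmr{i+1:03d}", d.chrom, mid, cpg, gene_cat, gene_id))
    return pd.DataFrame(rows, columns=["feature_id", "chrom", "pos",
                                       "cpg_category", "gene_category",
                                       "nearest_gene_id"])


def summarize_context(
    annotations: pd.DataFrame, axis: str = "cpg_category"
) -> pd.Series:
    """Integer-percent category distribution along one axis.

    Percentages are rounded half away from zero to the nearest integer
    and the rounding remainder is assigned to the largest category, so
    the output always sums to exactly 100.
    """
    if axis not in ("cpg_category", "gene_category"):
        raise ValidationError(f"unknown axis {axis!r}")
    categories = CPG_CATEGORIES if axis == "cpg_category" else GENE_CATEGORIES
    if len(annotations) == 0:
        raise ValidationError("cannot summarize an empty annotation table")
    counts = annotations[axis].value_counts()
    counts = pd.Series({c: int(counts.get(c, 0)) for c in categories})
    raw = 100.0 * counts / counts.sum()
    rounded = np.floor(raw + 0.5).astype(int)  # half away from zero (raw >= 0)
    remainder = 100 - int(rounded.sum())
    if remainder != 0:
        rounded[counts.idxmax()] += remainder
    return rounded
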