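"""Run-based calling of differentially methylated regions (DMRs).

A transparent caller over the per-probe DMP table: significant probes
(q below a seed threshold) are sorted genomically and grown into runs
while consecutive significant probes stay within ``maxgap`` base pairs
and keep a constant direction.  Runs with at least ``min_probes``
members are emitted as regions; the region statistic is a Stouffer
combination of the member probes' direction-aligned one-sided z-scores,
and region p-values are BH-adjusted across candidate regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dmp import bh_adjust
from .types import ProbeManifest, ValidationError

__all__ = ["DmrRecord", "call_dmrs", "dmrs_to_frame", "summarize_dmr_directions"]


@dataclass
class DmrRecord:
    chrom: str
    start: int  # 0-based, half-open
    end: int
    n_probes: int
    probe_ids: list[str]
    mean_delta_beta: float
    direction: str  # hyper | hypo
    combined_z: float
    region_p: float
    region_q: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError(
                f"region {self.chrom}:{self.start}-{self.end} not half-open"
            )
        if self.direction not in ("hyper", "hypo"):
            raise ValidationError(f"bad direction {self.direction!r}")


def _aligned_z(p_two_sided: np.ndarray) -> np.ndarray:
    """One-sided z in the probe's own direction from a two-sided p."""
    p = np.clip(np.asarray(p_two_sided, dtype=float), 1e-300, 1.0)
    return stats.norm.isf(p / 2.0)


def call_dmrs(
    dmp_table: pd.DataFrame,
    manifest: ProbeManifest,
    maxgap: int = 1000,
    min_probes: int = 3,
    probe_q_max: float = 0.05,
) -> list[DmrRecord]:
    """Call DMRs from a DMP table (see module docstring).

    Region bounds are ``[first probe pos, last probe pos + 1)``.  Raises
    if any probe in the table is missing from the manifest.
    """
    if maxgap <= 0 or min_probes <= 0 or probe_q_max <= 0:
        raise ValidationError("maxgap, min_probes and probe_q_max must be positive")
    pos = manifest.positions(list(dmp_table["probe_id"]))
    table = dmp_table.copy()
    table["chrom"] = pos["chrom"].to_numpy()
    table["pos"] = pos["pos"].to_numpy()
    table = table.sort_values(["chrom", "pos"], kind="mergesort")
    sig = table[table["q_value"] <= probe_q_max]

    candidates: list[list[pd.Series]] = []
    current: list[pd.Series] = []
    for _, row in sig.iterrows():
        if current:
            prev = current[-1]
            same = (row["chrom"] == prev["chrom"]
                    and row["pos"] - prev["pos"] <= maxgap
                    and row["direction"] == prev["direction"])
            if not same:
                candidates.append(current)
                current = []
        current.append(row)
    if current:
        candidates.append(current)
    candidates = [run for run in candidates if len(run) >= min_probes]

    if not candidates:
        return []
    records = []
    region_p = []
    for run in candidates:
        z = _aligned_z(np.array([r["p_value"] for r in run]))
        combined = float(z.sum() / np.sqrt(len(z)))
        region_p.append(float(stats.norm.sf(combined)))
        records.append(run)
    region_q = bh_adjust(np.array(region_p)).to_numpy()

    out = []
    for run, p, q in zip(records, region_p, region_q):
        z = _aligned_z(np.array([r["p_value"] for r in run]))
        out.append(DmrRecord(
            chrom=str(run[0]["chrom"]),
            start=int(run[0]["pos"]),
            end=int(run[-1]["pos"]) + 1,
            n_probes=len(run),
            probe_ids=[str(r["probe_id"]) for r in run],
            mean_delta_beta=float(np.mean([r["delta_beta"] for r in run])),
            direction=str(run[0]["direction"]),
            combined_z=float(z.sum() / np.sqrt(len(z))),
            region_p=p,
            region_q=float(q),
        ))
    return out


def dmrs_to_frame(dmrs: list[DmrRecord]) -> pd.DataFrame:
    """Tabular form (header-only when empty)."""
    columns = ["chrom", "start", "end", "n_probes", "mean_delta_beta",
               "direction", "combined_z", "region_p", "region_q", "probe_ids"]
    rows = [
        (d.chrom, d.start, d.end, d.n_probes, d.mean_delta_beta, d.direction,
         d.combined_z, d.region_p, d.region_q, ";".join(d.probe_ids))
        for d in dmrs
    ]
    return pd.DataFrame(rows, columns=columns)


def summarize_dmr_directions(dmrs: list[DmrRecord]) -> tuple[int, int, int]:
    """(n_total, n_hyper, n_hypo)."""
    n_hyper = sum(1 for d in dmrs if d.direction == "hyper")
    return len(dmrs), n_hyper, len(dmrs) - n_hyper
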