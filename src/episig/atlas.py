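"""Cross-cohort comparison of methylation signatures.

Each cohort is summarized by its DMP table: a global profile (mean
methylation difference and fraction hypermethylated over significant
probes), a top-DMP set of at most 500 probes, an asymmetric pairwise
overlap matrix of the top sets, and a Euclidean tree over per-cohort
median beta vectors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage

from .cluster import Dendrogram
from .types import BetaMatrix, ValidationError

__all__ = ["CohortProfile", "global_profile", "top_dmps", "overlap_matrix",
           "cohort_tree"]

TOP_N = 500
FDR_MAX = 0.05


def global_profile(dmp_table: pd.DataFrame) -> tuple[float, float | None]:
    """(mean methylation difference, hyper fraction) over significant DMPs.

    Restricts to ``q < 0.05``.  With no significant probes, returns
    ``(0.0, None)`` — the fraction is undefined.
    """
    if "q_value" not in dmp_table.columns:
        raise ValidationError("DMP table lacks q_value column")
    sig = dmp_table[dmp_table["q_value"] < FDR_MAX]
    if sig.empty:
        return 0.0, None
    delta = sig["delta_beta"].to_numpy()
    return float(delta.mean()), float((delta > 0).mean())


def top_dmps(dmp_table: pd.DataFrame, n: int = TOP_N) -> list[str]:
    """Top DMP ids: significant probes ranked by q then |moderated t|.

    Returns min(number significant, n) probe ids; ties broken by probe id.
    """
    sig = dmp_table[dmp_table["q_value"] < FDR_MAX].copy()
    sig["abs_t"] = sig["moderated_t"].abs()
    sig = sig.sort_values(["q_value", "abs_t", "probe_id"],
                          ascending=[True, False, True], kind="mergesort")
    return list(sig["probe_id"].head(n))


@dataclass
class CohortProfile:
    """A cohort's differential-methylation summary."""

    cohort_label: str
    dmp_table: pd.DataFrame
    top_dmp_ids: list[str] = field(default_factory=list)
    mean_methylation_difference: float = 0.0
    hyper_fraction: float | None = None

    @classmethod
    def from_dmp_table(cls, label: str, dmp_table: pd.DataFrame,
                       n: int = TOP_N) -> "CohortProfile":
        mean_diff, hyper = global_profile(dmp_table)
        return cls(
            cohort_label=label,
            dmp_table=dmp_table,
            top_dmp_ids=top_dmps(dmp_table, n),
            mean_methylation_difference=mean_diff,
            hyper_fraction=hyper,
        )


def overlap_matrix(profiles: Sequence[CohortProfile]) -> pd.DataFrame:
    """Asymmetric percent-overlap matrix of top DMP sets.

    Entry (y, x) is ``100 * |top(y) & top(x)| / |top(y)|`` — the share of
    the row cohort's probes also present in the column cohort's probes.
    Diagonal is 100.  A cohort with an empty top set yields a zero row
    (diagonal included) with a warning.
    """
    if len(profiles) < 2:
        raise ValidationError("overlap matrix needs >=2 cohort profiles")
    labels = [p.cohort_label for p in profiles]
    if len(set(labels)) != len(labels):
        raise ValidationError("duplicate cohort labels")
    sets = {p.cohort_label: set(p.top_dmp_ids) for p in profiles}
    out = pd.DataFrame(0.0, index=labels, columns=labels)
    for y in labels:
        if not sets[y]:
            warnings.warn(f"cohort {y!r} has an empty top DMP set; zero row",
                          stacklevel=2)
            continue
        for x in labels:
            out.loc[y, x] = 100.0 * len(sets[y] & sets[x]) / len(sets[y])
    return out


def cohort_tree(
    beta_by_cohort: Mapping[str, BetaMatrix],
    probe_ids: Sequence[str],
    profiles: Sequence[CohortProfile] = (),
    linkage_method: str = "ward",
) -> tuple[Dendrogram, pd.DataFrame]:
    """Euclidean tree over per-cohort median beta vectors.

    Every cohort's samples are aggregated probe-wise by the median; the
    median vectors (restricted to ``probe_ids``, typically the union of
    all cohorts' top DMP sets) are clustered agglomeratively.  The
    returned node table carries, per cohort, the number of selected DMPs
    (node size) and the global mean methylation difference (node color)
    when profiles are supplied.

    Raises if any probe is missing from any cohort's matrix.
    """
    if not beta_by_cohort:
        raise ValidationError("no cohorts given")
    probe_ids = list(probe_ids)
    labels = sorted(beta_by_cohort)
    medians = {}
    for label in labels:
        beta = beta_by_cohort[label]
        sub = beta.subset(probes=probe_ids)  # raises on missing probes
        medians[label] = np.median(sub.values, axis=1)
    x = np.vstack([medians[label] for label in labels])
    merges = linkage(x, method=linkage_method, metric="euclidean")
    dendro = Dendrogram(leaf_ids=labels, merges=merges,
                        linkage_method=linkage_method, metric="euclidean")
    by_label = {p.cohort_label: p for p in profiles}
    rows = []
    for label in labels:
        p = by_label.get(label)
        rows.append((
            label,
            len(p.top_dmp_ids) if p else np.nan,
            p.mean_methylation_difference if p else np.nan,
        ))
    nodes = pd.DataFrame(rows, columns=["cohort_label", "n_top_dmps",
                                        "mean_methylation_difference"])
    return dendro, nodes
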