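"""Clinical-feature prevalence with explicit denominators.

Clinical tables for rare disorders report, per feature, the number of
affected individuals over the number of *responders* — individuals with
available data; individuals with unknown status never enter the
denominator.  Percentages are rounded half away from zero to the
nearest integer, except exact half-integers, which keep one decimal
(e.g. 87.5).

The module ships a deterministic example cohort for the ARID2-related
disorder (Coffin-Siris spectrum) built from published aggregate counts:
27 newly reported individuals plus 26 from the literature.  Per-individual
states are synthetic assignments consistent with every aggregate count —
the counts, not the individual phenotypes, are the contract.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .types import PhenotypeTable, ValidationError

__all__ = [
    "PrevalenceRow",
    "prevalence",
    "merge_series",
    "table_one",
    "example_phenotype_table",
    "example_series_tables",
    "TABLE1_COUNTS",
]

#: feature -> ((affected, responders) this series, (affected, responders)
#: literature).  ``de_novo_confirmed`` is assessed in the new series only.
TABLE1_COUNTS: dict[str, tuple[tuple[int, int], tuple[int, int]]] = {
    "male": ((13, 27), (17, 26)),
    "hypotonia": ((18, 27), (14, 20)),
    "psychomotor_delay": ((24, 24), (24, 25)),
    "speech_disorder": ((22, 25), (13, 15)),
    "intellectual_disability": ((14, 20), (22, 23)),
    "epilepsy": ((2, 26), (2, 24)),
    "brain_mri_anomalies": ((11, 18), (8, 13)),
    "behavioral_problems": ((16, 25), (15, 23)),
    "autism_spectrum_disorder": ((0, 25), (2, 23)),
    "adhd": ((10, 25), (7, 23)),
    "low_frustration_tolerance": ((5, 25), (3, 23)),
    "aggressive_behavior": ((3, 25), (3, 23)),
    "anxiety_disorder": ((3, 25), (4, 23)),
    "feeding_difficulties": ((12, 19), (8, 26)),
    "facial_features": ((27, 27), (25, 26)),
    "coarse_face": ((12, 19), (15, 21)),
    "ptosis": ((2, 23), (3, 23)),
    "myopia": ((4, 23), (6, 18)),
    "hyperopia": ((6, 23), (3, 17)),
    "strabismus": ((5, 23), (7, 18)),
    "astigmatism": ((2, 23), (1, 17)),
    "deafness": ((2, 20), (3, 12)),
    "dental_anomalies": ((19, 26), (6, 25)),
    "hair_anomalies": ((12, 24), (10, 20)),
    "nail_anomalies": ((16, 26), (8, 21)),
    "bone_anomalies": ((3, 16), (6, 19)),
    "hand_or_feet_anomalies": ((11, 25), (15, 26)),
    "short_stature": ((4, 27), (15, 25)),
    "cardiologic_features": ((3, 15), (4, 15)),
    "de_novo_confirmed": ((21, 27), (0, 0)),
}

N_THIS_SERIES = 27
N_LITERATURE = 26


@dataclass(frozen=True)
class PrevalenceRow:
    feature_name: str
    series: str  # this_series | literature | total
    n_affected: int
    n_responders: int
    percent: float | None
    no_responders: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.n_affected <= self.n_responders):
            raise ValidationError(
                f"{self.feature_name}/{self.series}: affected "
                f"{self.n_affected} exceeds responders {self.n_responders}"
            )


def round_percent(n_affected: int, n_responders: int) -> float:
    """Percentage under the half-integer-aware rounding rule."""
    value = 100.0 * n_affected / n_responders
    doubled = round(value * 2)
    if abs(value * 2 - doubled) < 1e-9 and doubled % 2 == 1:
        return doubled / 2.0  # exact half-integer: keep one decimal
    return float(int(value + 0.5))  # half away from zero (value >= 0)


def prevalence(table: PhenotypeTable, feature: str, series: str) -> PrevalenceRow:
    """Prevalence of one feature in one series (or ``total``)."""
    if feature not in table.feature_names:
        raise ValidationError(f"feature {feature!r} absent from table")
    if series == "total":
        sub = table.data
    elif series in PhenotypeTable.SERIES:
        sub = table.data[table.data["series"] == series]
    else:
        raise ValidationError(
            f"unknown series {series!r}; allowed: this_series, literature, total"
        )
    states = sub[feature]
    n_responders = int((states != "unknown").sum())
    n_affected = int((states == "present").sum())
    if n_responders == 0:
        return PrevalenceRow(feature, series, 0, 0, None, no_responders=True)
    return PrevalenceRow(feature, series, n_affected, n_responders,
                         round_percent(n_affected, n_responders))


def merge_series(a: PhenotypeTable, b: PhenotypeTable) -> PhenotypeTable:
    """Concatenate two phenotype tables with disjoint individual ids.

    Features present in only one table are ``unknown`` in the other.
    """
    collision = set(a.individual_ids) & set(b.individual_ids)
    if collision:
        raise ValidationError(
            f"individual id collision on merge: {sorted(collision)[:5]}"
        )
    if len(a) == 0:
        return PhenotypeTable(b.data.copy())
    if len(b) == 0:
        return PhenotypeTable(a.data.copy())
    merged = pd.concat([a.data, b.data], axis=0)
    feature_cols = [c for c in merged.columns if c != "series"]
    merged[feature_cols] = merged[feature_cols].fillna("unknown")
    return PhenotypeTable(merged)


def table_one(table: PhenotypeTable, features: list[str]) -> list[PrevalenceRow]:
    """Prevalence rows (this_series, literature, total) per feature, in order."""
    rows = []
    for feature in features:
        for series in ("this_series", "literature", "total"):
            rows.append(prevalence(table, feature, series))
    return rows


def _build_series(prefix: str, n: int, series: str, column: int) -> PhenotypeTable:
    ids = [f"{prefix}-{i + 1:02d}" for i in range(n)]
    data = {"series": [series] * n}
    for feature, counts in TABLE1_COUNTS.items():
        affected, responders = counts[column]
        states = (["present"] * affected
                  + ["absent"] * (responders - affected)
                  + ["unknown"] * (n - responders))
        data[feature] = states
    return PhenotypeTable(pd.DataFrame(data, index=pd.Index(ids)))


def example_series_tables() -> tuple[PhenotypeTable, PhenotypeTable]:
    """The new-series (27) and literature (26) example cohorts."""
    return (
        _build_series("I", N_THIS_SERIES, "this_series", 0),
        _build_series("L", N_LITERATURE, "literature", 1),
    )


def example_phenotype_table() -> PhenotypeTable:
    """The merged 53-individual example cohort."""
    a, b = example_series_tables()
    return merge_series(a, b)
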