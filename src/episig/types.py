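"""Core data containers for methylation episignature analysis.

All genomic coordinates are 0-based with half-open intervals (BED
convention).  Methylation levels are beta values: fractions in [0, 1],
with ``NaN`` marking missing measurements.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "FormatError",
    "ROLES",
    "FEATURE_STATES",
    "BetaMatrix",
    "SampleSheet",
    "ProbeManifest",
    "PhenotypeTable",
]


class ValidationError(ValueError):
    """A record violated a container invariant (value range, label set...)."""


class FormatError(ValueError):
    """A file or table is structurally malformed (duplicates, bad columns)."""


#: Allowed sample roles.  ``case`` samples define the signature; ``control``
#: and ``other_disorder`` samples form the background; ``test`` samples are
#: scored but never used for discovery or training.
ROLES = ("case", "control", "other_disorder", "test")

#: Tri-state clinical feature encoding.  ``unknown`` individuals are excluded
#: from prevalence denominators.
FEATURE_STATES = ("present", "absent", "unknown")


def _check_unique(values: Iterable[str], what: str) -> None:
    seen: dict[str, int] = {}
    for v in values:
        seen[v] = seen.get(v, 0) + 1
    dups = sorted(k for k, n in seen.items() if n > 1)
    if dups:
        raise FormatError(f"duplicate {what}: {', '.join(dups[:5])}")


@dataclass
class BetaMatrix:
    """Probe-by-sample matrix of methylation beta fractions.

    Parameters
    ----------
    data
        DataFrame indexed by probe id with one column per sample id.
        Values must lie in [0, 1]; NaN encodes a missing measurement.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index.astype(str), "probe ids")
        _check_unique(self.data.columns.astype(str), "sample ids")
        values = self.data.to_numpy(dtype=float)
        bad = (values < 0.0) | (values > 1.0)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"beta value {values[i, j]!r} out of [0, 1] at probe "
                f"{self.data.index[i]!r}, sample {self.data.columns[j]!r}"
            )
        self.data = self.data.astype(float)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def subset(
        self,
        probes: Sequence[str] | None = None,
        samples: Sequence[str] | None = None,
    ) -> "BetaMatrix":
        """Return a view restricted to the given probes and/or samples.

        Raises
        ------
        ValidationError
            If any requested probe or sample is absent.
        """
        df = self.data
        if probes is not None:
            missing = [p for p in probes if p not in df.index]
            if missing:
                raise ValidationError(
                    f"probes absent from matrix: {', '.join(missing[:5])}"
                )
            df = df.loc[list(probes)]
        if samples is not None:
            missing = [s for s in samples if s not in df.columns]
            if missing:
                raise ValidationError(
                    f"samples absent from matrix: {', '.join(missing[:5])}"
                )
            df = df[list(samples)]
        return BetaMatrix(df)

    def drop_incomplete_probes(self) -> "BetaMatrix":
        """Drop probes with any missing beta (the default NA policy)."""
        return BetaMatrix(self.data.dropna(axis=0))


@dataclass
class SampleSheet:
    """Per-sample roles, cohort labels and covariates.

    ``data`` is indexed by sample id with at least columns ``role`` and
    ``cohort_label``.  Any additional columns are treated as covariates,
    except the optional ``truth_label`` column carrying simulation ground
    truth.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index.astype(str), "sample ids")
        for col in ("role", "cohort_label"):
            if col not in self.data.columns:
                raise FormatError(f"sample sheet missing required column {col!r}")
        bad = self.data.loc[~self.data["role"].isin(ROLES)]
        if len(bad):
            raise ValidationError(
                f"unknown role {bad['role'].iloc[0]!r} for sample "
                f"{bad.index[0]!r}; allowed roles: {', '.join(ROLES)}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def __len__(self) -> int:
        return len(self.data)

    def role_of(self, sample_id: str) -> str:
        return str(self.data.loc[sample_id, "role"])

    def ids_with_role(self, *roles: str) -> list[str]:
        for r in roles:
            if r not in ROLES:
                raise ValidationError(f"unknown role {r!r}; allowed: {', '.join(ROLES)}")
        mask = self.data["role"].isin(roles)
        return list(self.data.index[mask])

    def ids_with_cohort(self, cohort_label: str) -> list[str]:
        return list(self.data.index[self.data["cohort_label"] == cohort_label])

    def cohorts(self, role: str | None = None) -> list[str]:
        df = self.data if role is None else self.data[self.data["role"] == role]
        return sorted(df["cohort_label"].unique())

    @property
    def covariate_names(self) -> list[str]:
        reserved = {"role", "cohort_label", "truth_label"}
        return [c for c in self.data.columns if c not in reserved]

    def require_subset_of(self, beta: BetaMatrix) -> None:
        """Check every listed sample exists in a beta matrix."""
        missing = [s for s in self.data.index if s not in beta.data.columns]
        if missing:
            raise ValidationError(
                f"samples in sheet but not in beta matrix: {', '.join(missing[:5])}"
            )

    def subset(self, sample_ids: Sequence[str]) -> "SampleSheet":
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing:
            raise ValidationError(
                f"samples absent from sheet: {', '.join(missing[:5])}"
            )
        return SampleSheet(self.data.loc[list(sample_ids)])


def _check_intervals(df: pd.DataFrame, what: str) -> None:
    bad = df[df["start"] >= df["end"]]
    if len(bad):
        r = bad.iloc[0]
        raise ValidationError(
            f"{what} interval not half-open [start, end): "
            f"{r['chrom']}:{r['start']}-{r['end']}"
        )


@dataclass
class ProbeManifest:
    """Genomic context for probes: positions, CpG islands and genes.

    Attributes
    ----------
    probes
        DataFrame indexed by probe id, columns ``chrom`` and ``pos``
        (0-based position of the interrogated C).
    islands
        DataFrame with columns ``chrom``, ``start``, ``end`` (half-open).
    genes
        DataFrame indexed by gene id with columns ``chrom``, ``strand``
        (``+``/``-``), ``tss`` (0-based), and ``cds_blocks`` — a list of
        half-open (start, end) tuples.
    """

    probes: pd.DataFrame
    islands: pd.DataFrame
    genes: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.probes.index.astype(str), "manifest probe ids")
        _check_intervals(self.islands, "island")
        bad = self.genes.loc[~self.genes["strand"].isin(["+", "-"])]
        if len(bad):
            raise ValidationError(
                f"gene {bad.index[0]!r} has no valid strand "
                f"(got {bad['strand'].iloc[0]!r}, need '+' or '-')"
            )
        for gid, blocks in self.genes["cds_blocks"].items():
            for s, e in blocks:
                if s >= e:
                    raise ValidationError(
                        f"gene {gid!r} CDS block not half-open: {s}-{e}"
                    )

    @property
    def probe_ids(self) -> list[str]:
        return list(self.probes.index)

    def position_of(self, probe_id: str) -> tuple[str, int]:
        if probe_id not in self.probes.index:
            raise ValidationError(f"probe {probe_id!r} absent from manifest")
        row = self.probes.loc[probe_id]
        return str(row["chrom"]), int(row["pos"])

    def positions(self, probe_ids: Sequence[str]) -> pd.DataFrame:
        missing = [p for p in probe_ids if p not in self.probes.index]
        if missing:
            raise ValidationError(
                f"probes absent from manifest: {', '.join(missing[:5])}"
            )
        return self.probes.loc[list(probe_ids)]


@dataclass
class PhenotypeTable:
    """Per-individual tri-state clinical features with series provenance.

    ``data`` is indexed by individual id with a ``series`` column
    (``this_series`` or ``literature``) and one column per feature taking
    values in :data:`FEATURE_STATES`.
    """

    data: pd.DataFrame

    SERIES = ("this_series", "literature")

    def __post_init__(self) -> None:
        _check_unique(self.data.index.astype(str), "individual ids")
        if "series" not in self.data.columns:
            raise FormatError("phenotype table missing required column 'series'")
        bad = self.data.loc[~self.data["series"].isin(self.SERIES)]
        if len(bad):
            raise ValidationError(
                f"unknown series {bad['series'].iloc[0]!r} for individual "
                f"{bad.index[0]!r}; allowed: {', '.join(self.SERIES)}"
            )
        for col in self.feature_names:
            colbad = self.data.loc[~self.data[col].isin(FEATURE_STATES)]
            if len(colbad):
                raise ValidationError(
                    f"feature {col!r} has invalid state "
                    f"{colbad[col].iloc[0]!r} for individual {colbad.index[0]!r}; "
                    f"allowed: {', '.join(FEATURE_STATES)}"
                )

    @property
    def feature_names(self) -> list[str]:
        return [c for c in self.data.columns if c != "series"]

    @property
    def individual_ids(self) -> list[str]:
        return list(self.data.index)

    def __len__(self) -> int:
        return len(self.data)
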