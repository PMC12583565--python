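"""Synthetic methylation cohorts with planted episignatures.

The generator emulates the statistical structure of a rare-disorder
episignature study: a small case group against an excess of controls,
several other-disorder cohorts with their own signatures, mosaic
carriers whose signal is diluted toward controls, and a probe manifest
with CpG islands and genes so that every genomic-context category is
populated.

Noise model: per-probe background means are drawn from a bimodal
distribution over [0.1, 0.9] (methylation arrays are dominated by
near-unmethylated and near-methylated CpGs); individual sample betas
follow Beta(mean * precision, (1 - mean) * precision).  Case effects are
planted on the mean (beta) scale.  All draws derive from a single seed
through fixed-order substreams, so any subset of samples is reproducible.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import io as eio
from .types import BetaMatrix, ProbeManifest, SampleSheet, ValidationError

__all__ = [
    "SimulationConfig",
    "OtherCohortSpec",
    "SimulationTruth",
    "simulate_manifest",
    "simulate_cohort",
    "make_fixture_suite",
]

BETA_FLOOR, BETA_CEIL = 0.001, 0.999
MEAN_FLOOR, MEAN_CEIL = 0.02, 0.98


@dataclass(frozen=True)
class OtherCohortSpec:
    """A background disorder cohort with its own planted signature."""

    label: str
    n_samples: int
    n_signature_probes: int
    mean_delta: float
    hyper_fraction: float


@dataclass
class SimulationConfig:
    n_probes: int = 10_000
    n_cases: int = 14
    n_controls: int = 30
    other_cohorts: list[OtherCohortSpec] = field(default_factory=list)
    n_signature_probes: int = 200
    mean_delta: float = 0.15
    hyper_fraction: float = 0.9
    precision: float = 50.0
    mosaic_fractions: list[float] = field(default_factory=list)
    batch_effect_sd: float = 0.0
    #: When set, signature probes are planted as this many genomic runs of
    #: adjacent probes (inside probe-dense islands), so that region callers
    #: have recoverable ground truth; ``None`` scatters them at random.
    n_signature_clusters: int | None = None
    #: Fraction of each other cohort's signature drawn from the case
    #: signature (shared-biology overlap).
    other_cohort_overlap: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_probes <= 0 or self.n_cases <= 0 or self.n_controls <= 0:
            raise ValidationError("all counts must be positive")
        if not (0.0 <= self.mean_delta <= 0.5):
            raise ValidationError(
                f"mean_delta must be in [0, 0.5], got {self.mean_delta}"
            )
        if not (0.0 <= self.hyper_fraction <= 1.0):
            raise ValidationError("hyper_fraction must be in [0, 1]")
        if not (0.0 <= self.other_cohort_overlap <= 1.0):
            raise ValidationError("other_cohort_overlap must be in [0, 1]")
        if self.n_signature_probes > self.n_probes:
            raise ValidationError("n_signature_probes exceeds n_probes")
        for f in self.mosaic_fractions:
            if not (0.0 <= f <= 1.0):
                raise ValidationError(f"mosaic fraction {f} outside [0, 1]")
        if self.precision <= 0:
            raise ValidationError("precision must be positive")
        for c in self.other_cohorts:
            if c.n_samples <= 0 or c.n_signature_probes <= 0:
                raise ValidationError(f"cohort {c.label!r}: counts must be positive")


@dataclass
class SimulationTruth:
    """Planted ground truth for recovery tests."""

    #: columns: probe_id, direction (hyper/hypo), planted_delta (signed,
    #: after mean clipping)
    signature: pd.DataFrame
    #: columns: sample_id, true_class, mosaic_fraction
    samples: pd.DataFrame
    #: other-cohort signature probe ids by cohort label
    other_signatures: dict[str, list[str]] = field(default_factory=dict)

    @property
    def signature_probe_ids(self) -> list[str]:
        return list(self.signature["probe_id"])

    def to_dict(self) -> dict:
        return {
            "signature": self.signature.to_dict(orient="list"),
            "samples": self.samples.to_dict(orient="list"),
            "other_signatures": {k: list(v) for k, v in self.other_signatures.items()},
        }


# ---------------------------------------------------------------------------
# manifest


def simulate_manifest(config: SimulationConfig) -> ProbeManifest:
    """Generate a probe manifest with islands and genes on 4 chromosomes.

    Probes are laid out in island-anchored units: a dense run inside each
    CpG island (~120 bp spacing), plus shore, shelf and distal probes and
    a probe inside the unit gene's CDS.  Genes alternate strand every
    seventh unit so both orientations occur.  Deterministic under the
    config seed.
    """
    config.validate()
    if config.n_probes < 100:
        raise ValidationError(
            f"n_probes={config.n_probes} too small to populate all "
            "genomic-context categories (need >= 100)"
        )
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    chroms = ["chr1", "chr2", "chr3", "chr4"]
    per_chrom = np.full(len(chroms), config.n_probes // len(chroms))
    per_chrom[: config.n_probes % len(chroms)] += 1

    probe_rows = []
    island_rows = []
    gene_rows = []
    unit_counter = 0
    for chrom, n_target in zip(chroms, per_chrom):
        cursor = 100_000
        made = 0
        while made < n_target:
            isl_start = cursor + int(rng.integers(0, 2_000))
            isl_len = int(rng.integers(600, 1_400))
            isl_end = isl_start + isl_len
            island_rows.append((chrom, isl_start, isl_end))

            unit_positions: list[int] = []
            # dense run inside the island
            p = isl_start + int(rng.integers(20, 80))
            while p < isl_end - 20 and len(unit_positions) < 8:
                unit_positions.append(p)
                p += int(rng.integers(80, 180))
            # shore (0-2 kb), shelf (2-4 kb), and distal probes
            unit_positions.append(isl_end + int(rng.integers(1, 2_000)))
            unit_positions.append(isl_end + int(rng.integers(2_001, 4_000)))
            unit_positions.append(isl_start - int(rng.integers(1, 1_900)))
            unit_positions.append(isl_end + int(rng.integers(9_500, 20_000)))

            # unit gene: promoter window covers the 4-5 kb downstream flank
            if unit_counter % 7 == 3:
                tss = isl_start - 5_000
                strand = "-"
                cds = [(tss - 2_200, tss - 200)]
            else:
                tss = isl_end + 5_000
                strand = "+"
                cds = [(tss + 200, tss + 2_200)]
            gene_rows.append((f"gene{unit_counter:05d}", chrom, strand, tss, cds))
            unit_positions.append(isl_end + 4_000 + int(rng.integers(0, 900)))
            if strand == "+":
                unit_positions.append(tss + 300 + int(rng.integers(0, 1_800)))
            else:
                unit_positions.append(tss - 2_100 + int(rng.integers(0, 1_800)))

            for pos in unit_positions:
                if made < n_target:
                    probe_rows.append((chrom, int(pos)))
                    made += 1
            unit_counter += 1
            cursor = isl_end + 29_000

    probes = pd.DataFrame(probe_rows, columns=["chrom", "pos"])
    probes = probes.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    probes.index = pd.Index(
        [f"cg{i:07d}" for i in range(len(probes))], name="probe_id"
    )
    islands = pd.DataFrame(island_rows, columns=["chrom", "start", "end"])
    genes = pd.DataFrame(gene_rows,
                         columns=["gene_id", "chrom", "strand", "tss", "cds_blocks"])
    genes = genes.set_index("gene_id")
    return ProbeManifest(probes=probes, islands=islands, genes=genes)


# ---------------------------------------------------------------------------
# cohort


def _background_means(rng: np.random.Generator, n: int) -> np.ndarray:
    """Bimodal background probe means over [0.1, 0.9]."""
    low = rng.uniform(0.1, 0.4, size=n)
    high = rng.uniform(0.6, 0.9, size=n)
    take_high = rng.random(n) < 0.5
    return np.where(take_high, high, low)


def _pick_signature(
    rng: np.random.Generator,
    manifest: ProbeManifest,
    n_sig: int,
    n_clusters: int | None,
    exclude: set[str] | None = None,
) -> list[str]:
    probe_ids = np.array(manifest.probe_ids)
    if exclude:
        probe_ids = probe_ids[~np.isin(probe_ids, list(exclude))]
    if n_clusters is None:
        return list(rng.choice(probe_ids, size=n_sig, replace=False))
    # clustered mode: take runs of genomically adjacent probes (gap <= 500)
    size = int(np.ceil(n_sig / n_clusters))
    probes = manifest.probes.sort_values(["chrom", "pos"], kind="mergesort")
    runs: list[list[str]] = []
    current: list[str] = []
    last_chrom, last_pos = None, None
    for pid, row in probes.iterrows():
        if exclude and pid in exclude:
            continue
        if (row["chrom"] != last_chrom or last_pos is None
                or row["pos"] - last_pos > 500):
            if len(current) >= size:
                runs.append(current[:size])
            current = []
        current.append(pid)
        last_chrom, last_pos = row["chrom"], row["pos"]
    if len(current) >= size:
        runs.append(current[:size])
    if len(runs) < n_clusters:
        raise ValidationError(
            f"manifest supports only {len(runs)} probe runs of length {size}; "
            f"requested {n_clusters} signature clusters"
        )
    chosen_idx = rng.choice(len(runs), size=n_clusters, replace=False)
    chosen: list[str] = []
    for i in sorted(chosen_idx):
        chosen.extend(runs[i])
    return chosen[:n_sig]


def _planted_means(
    rng: np.random.Generator,
    control_means: np.ndarray,
    probe_index: pd.Index,
    signature_ids: Sequence[str],
    mean_delta: float,
    hyper_fraction: float,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Shift signature probes by +/- mean_delta; return means and truth."""
    case_means = control_means.copy()
    idx = probe_index.get_indexer(list(signature_ids))
    n_sig = len(idx)
    n_hyper = int(round(hyper_fraction * n_sig))
    signs = np.full(n_sig, -1.0)
    order = rng.permutation(n_sig)
    signs[order[:n_hyper]] = 1.0
    shifted = control_means[idx] + signs * mean_delta
    clipped = np.clip(shifted, MEAN_FLOOR, MEAN_CEIL)
    if (clipped != shifted).any():
        warnings.warn(
            f"{int((clipped != shifted).sum())} planted means clipped to "
            f"[{MEAN_FLOOR}, {MEAN_CEIL}]", stacklevel=2)
    case_means[idx] = clipped
    truth = pd.DataFrame({
        "probe_id": list(signature_ids),
        "direction": np.where(signs > 0, "hyper", "hypo"),
        "planted_delta": clipped - control_means[idx],
    })
    return case_means, truth


def _draw_sample(
    rng: np.random.Generator,
    means: np.ndarray,
    precision: float,
    batch_effect_sd: float,
) -> np.ndarray:
    m = means
    if batch_effect_sd > 0:
        shift = rng.normal(0.0, batch_effect_sd)
        logit = np.log(m / (1.0 - m)) + shift
        m = 1.0 / (1.0 + np.exp(-logit))
        m = np.clip(m, MEAN_FLOOR, MEAN_CEIL)
    draw = rng.beta(m * precision, (1.0 - m) * precision)
    return np.clip(draw, BETA_FLOOR, BETA_CEIL)


@dataclass(frozen=True)
class _SampleSpec:
    sample_id: str
    role: str
    cohort_label: str
    means_key: str  # which mean vector to draw from
    true_class: str
    mosaic_fraction: float = np.nan


def _generate(
    config: SimulationConfig,
    manifest: ProbeManifest,
    extra_groups: Sequence[tuple[str, str, str, int, str]] = (),
) -> tuple[BetaMatrix, SampleSheet, SimulationTruth]:
    """Shared generator core.

    ``extra_groups`` entries are (cohort_label, role, means_key, count,
    true_class) for fixture groups beyond the basic design (validation
    cases, unresolved cases, VUS carriers...).
    """
    config.validate()
    if len(manifest.probes) < config.n_probes:
        raise ValidationError(
            f"manifest has {len(manifest.probes)} probes; "
            f"config requests {config.n_probes}"
        )
    root = np.random.SeedSequence(config.seed)
    # fixed spawn order: manifest(0), probe means(1), signature choice(2),
    # planting(3), other-cohort planting(4), then one stream per sample
    streams = root.spawn(5)
    rng_means = np.random.default_rng(streams[1])
    rng_sig = np.random.default_rng(streams[2])
    rng_plant = np.random.default_rng(streams[3])
    rng_other = np.random.default_rng(streams[4])

    probe_ids = manifest.probe_ids[: config.n_probes]
    probe_index = pd.Index(probe_ids)
    sub_manifest_probes = manifest.probes.loc[probe_ids]
    control_means = _background_means(rng_means, config.n_probes)

    signature_ids = _pick_signature(
        rng_sig, ProbeManifest(sub_manifest_probes, manifest.islands, manifest.genes),
        config.n_signature_probes, config.n_signature_clusters)
    case_means, truth_sig = _planted_means(
        rng_plant, control_means, probe_index, signature_ids,
        config.mean_delta, config.hyper_fraction)

    means_by_key: dict[str, np.ndarray] = {
        "control": control_means,
        "case": case_means,
    }
    other_signatures: dict[str, list[str]] = {}
    for spec in config.other_cohorts:
        n_shared = int(round(config.other_cohort_overlap * spec.n_signature_probes))
        n_shared = min(n_shared, len(signature_ids))
        shared = list(rng_other.choice(np.array(signature_ids), size=n_shared,
                                       replace=False)) if n_shared else []
        own = _pick_signature(
            rng_other,
            ProbeManifest(sub_manifest_probes, manifest.islands, manifest.genes),
            spec.n_signature_probes - n_shared, None,
            exclude=set(signature_ids))
        cohort_sig = shared + list(own)
        other_signatures[spec.label] = cohort_sig
        cohort_means, _ = _planted_means(
            rng_other, control_means, probe_index, cohort_sig,
            spec.mean_delta, spec.hyper_fraction)
        means_by_key[f"other:{spec.label}"] = cohort_means

    for f in config.mosaic_fractions:
        means_by_key[f"mosaic:{f}"] = f * case_means + (1.0 - f) * control_means

    specs: list[_SampleSpec] = []
    for i in range(config.n_cases):
        specs.append(_SampleSpec(f"case_{i+1:02d}", "case", "signature_cohort",
                                 "case", "case"))
    for i in range(config.n_controls):
        specs.append(_SampleSpec(f"control_{i+1:02d}", "control", "controls",
                                 "control", "control"))
    for spec in config.other_cohorts:
        for i in range(spec.n_samples):
            specs.append(_SampleSpec(f"{spec.label}_{i+1:02d}", "other_disorder",
                                     spec.label, f"other:{spec.label}",
                                     f"other:{spec.label}"))
    for j, f in enumerate(config.mosaic_fractions):
        specs.append(_SampleSpec(f"mosaic_{j+1:02d}", "test", "mosaic_parent",
                                 f"mosaic:{f}", "mosaic", f))
    for cohort_label, role, means_key, count, true_class in extra_groups:
        for i in range(count):
            specs.append(_SampleSpec(f"{cohort_label}_{i+1:02d}", role,
                                     cohort_label, means_key, true_class))

    sample_streams = root.spawn(len(specs))
    columns = {}
    sheet_rows = []
    truth_rows = []
    for spec, stream in zip(specs, sample_streams):
        rng = np.random.default_rng(stream)
        columns[spec.sample_id] = _draw_sample(
            rng, means_by_key[spec.means_key], config.precision,
            config.batch_effect_sd)
        sheet_rows.append((spec.sample_id, spec.role, spec.cohort_label,
                           spec.true_class))
        truth_rows.append((spec.sample_id, spec.true_class, spec.mosaic_fraction))

    beta = BetaMatrix(pd.DataFrame(columns, index=probe_index))
    sheet_df = pd.DataFrame(sheet_rows,
                            columns=["sample_id", "role", "cohort_label",
                                     "truth_label"]).set_index("sample_id")
    sheet = SampleSheet(sheet_df)
    truth = SimulationTruth(
        signature=truth_sig,
        samples=pd.DataFrame(truth_rows,
                             columns=["sample_id", "true_class",
                                      "mosaic_fraction"]),
        other_signatures=other_signatures,
    )
    return beta, sheet, truth


def simulate_cohort(
    config: SimulationConfig, manifest: ProbeManifest
) -> tuple[BetaMatrix, SampleSheet, SimulationTruth]:
    """Generate a case/control (+ other cohorts, mosaics) beta matrix.

    See the module docstring for the noise model.  Deterministic under
    ``config.seed``; each sample has its own substream, so adding samples
    does not perturb earlier ones.
    """
    return _generate(config, manifest)


# ---------------------------------------------------------------------------
# fixture suite

#: Inventory of the bundled study-like fixture: 14 discovery cases,
#: 3 validation cases, 3 unresolved cases carrying the signature, 2 mosaic
#: carrier parents (dilution 0.3 and 0), 4 VUS carriers without the
#: signature, 40 controls, and three other-disorder cohorts.
FIXTURE_CONFIG = SimulationConfig(
    n_probes=10_000,
    n_cases=14,
    n_controls=40,
    other_cohorts=[
        OtherCohortSpec("disorderA", 8, 300, 0.12, 0.8),
        OtherCohortSpec("disorderB", 8, 200, 0.12, 0.2),
        OtherCohortSpec("disorderC", 8, 150, 0.10, 0.5),
    ],
    n_signature_probes=200,
    mean_delta=0.15,
    hyper_fraction=0.9,
    precision=50.0,
    mosaic_fractions=[0.3, 0.0],
    other_cohort_overlap=0.25,
)

FIXTURE_EXTRA_GROUPS = [
    ("validation", "test", "case", 3, "case"),
    ("unresolved", "test", "case", 3, "case"),
    ("vus", "test", "control", 4, "control"),
]


def fixture_objects(
    seed: int,
) -> tuple[ProbeManifest, BetaMatrix, SampleSheet, SimulationTruth]:
    """In-memory fixture suite (used by :func:`make_fixture_suite` and tests)."""
    import dataclasses

    config = dataclasses.replace(FIXTURE_CONFIG, seed=seed)
    manifest = simulate_manifest(config)
    beta, sheet, truth = _generate(config, manifest, FIXTURE_EXTRA_GROUPS)
    return manifest, beta, sheet, truth


def make_fixture_suite(seed: int, out_dir: str | os.PathLike) -> dict[str, str]:
    """Write a ready-made study-like fixture directory.

    Emits ``beta.tsv``, ``samples.tsv``, ``truth.json`` and a
    ``manifest/`` subdirectory; returns the path map.  Byte-identical
    across repeated calls with the same seed.
    """
    import json

    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    manifest, beta, sheet, truth = fixture_objects(seed)
    paths = {
        "beta": os.path.join(out_dir, "beta.tsv"),
        "samples": os.path.join(out_dir, "samples.tsv"),
        "manifest": os.path.join(out_dir, "manifest"),
        "truth": os.path.join(out_dir, "truth.json"),
    }
    eio.write_beta_matrix(beta, paths["beta"])
    eio.write_sample_sheet(sheet, paths["samples"])
    eio.write_manifest(manifest, paths["manifest"])
    with open(paths["truth"], "w") as fh:
        json.dump(truth.to_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths
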