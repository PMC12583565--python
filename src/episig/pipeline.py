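"""End-to-end orchestration: simulate -> discover -> validate -> score.

A run directory contains every stage's output plus ``run_manifest.json``
recording inputs, parameters, seed and package version — enough to
reproduce the run bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import yaml

from . import __version__
from . import io as eio
from .cluster import hierarchical_cluster, mds_embed
from .context import annotate_dmrs, annotate_probes, summarize_context
from .dmp import moderated_t_test, select_probes
from .dmr import call_dmrs, dmrs_to_frame
from .model import (EpisignatureModel, loo_cross_validate, mvp_score,
                    partition_training, screen_samples, train_classifier)
from .simulate import make_fixture_suite
from .types import ValidationError

log = logging.getLogger("episig")

__all__ = ["RunConfig", "run_discovery_pipeline", "run_screen"]


@dataclass
class RunConfig:
    """Parameters for every pipeline stage plus global seed and output dir."""

    out_dir: str = "episig_run"
    seed: int = 0
    log_level: str = "INFO"
    # inputs: either an existing fixture directory, or simulate
    input_dir: str | None = None
    simulate: bool = True
    # probe selection
    q_max: float = 0.01
    delta_min: float = 0.05
    max_probes: int = 1000
    # classifier
    train_fraction: float = 0.75
    svm_c: float = 1.0
    call_threshold: float = 0.5
    run_loocv: bool = True
    # DMR calling
    maxgap: int = 1000
    min_probes: int = 3
    probe_q_max: float = 0.05

    def validate(self) -> None:
        if not (0.0 < self.q_max <= 1.0):
            raise ValidationError(f"q_max must be in (0, 1], got {self.q_max}")
        if not (0.0 <= self.delta_min < 1.0):
            raise ValidationError(f"delta_min must be in [0, 1), got {self.delta_min}")
        if self.max_probes <= 0:
            raise ValidationError("max_probes must be positive")
        if not (0.0 < self.train_fraction < 1.0):
            raise ValidationError("train_fraction must be in (0, 1)")
        if not (0.0 <= self.call_threshold <= 1.0):
            raise ValidationError("call_threshold must be in [0, 1]")
        if self.maxgap <= 0 or self.min_probes <= 0:
            raise ValidationError("maxgap and min_probes must be positive")
        if not (0.0 < self.probe_q_max <= 1.0):
            raise ValidationError("probe_q_max must be in (0, 1]")
        if not self.simulate and not self.input_dir:
            raise ValidationError("need input_dir when simulation is disabled")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.from_dict(payload)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            log.info("stage %s: start", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"stage {name} failed: {exc}") from exc
        return inner
    return wrap


def run_discovery_pipeline(config: RunConfig) -> str:
    """Execute the full discovery workflow; returns the run directory."""
    config.validate()
    logging.basicConfig(level=config.log_level)
    out = config.out_dir
    os.makedirs(out, exist_ok=True)

    if config.simulate:
        log.info("stage simulate: generating fixture suite (seed=%d)", config.seed)
        input_dir = os.path.join(out, "inputs")
        make_fixture_suite(config.seed, input_dir)
    else:
        input_dir = config.input_dir
    beta = eio.read_beta_matrix(os.path.join(input_dir, "beta.tsv"))
    sheet = eio.read_sample_sheet(os.path.join(input_dir, "samples.tsv"))
    manifest = eio.read_manifest(os.path.join(input_dir, "manifest"))
    sheet.require_subset_of(beta)

    log.info("stage dmp: differential methylation")
    dmp_table = moderated_t_test(beta, sheet)
    eio.write_results(dmp_table, os.path.join(out, "dmp.tsv"))

    log.info("stage select: probe selection")
    probes = select_probes(dmp_table, config.q_max, config.delta_min,
                           config.max_probes)
    eio.write_results(probes.to_frame(), os.path.join(out, "probes.tsv"))
    if len(probes) == 0:
        raise RuntimeError("stage select produced an empty signature; "
                           "downstream stages need probes")

    log.info("stage cluster: dendrogram and MDS")
    core_ids = sheet.ids_with_role("case", "control")
    dendro = hierarchical_cluster(beta, probes, sample_ids=core_ids)
    with open(os.path.join(out, "dendrogram.json"), "w") as fh:
        json.dump(dendro.to_dict(), fh, indent=1)
        fh.write("\n")
    embedding = mds_embed(beta, probes, sample_ids=core_ids)
    coords = embedding.coordinates.copy()
    coords.index.name = "sample_id"
    coords.reset_index().to_csv(os.path.join(out, "embedding.tsv"),
                                sep="\t", index=False)

    log.info("stage train: SVM + calibration")
    train_ids, test_ids = partition_training(sheet, config.train_fraction,
                                             config.seed)
    model = train_classifier(beta, probes, train_ids, sheet, C=config.svm_c,
                             seed=config.seed, test_ids=test_ids)
    model.save(os.path.join(out, "model.json"))
    mvp = mvp_score(model, beta)
    eio.write_results(mvp, os.path.join(out, "mvp.tsv"))

    if config.run_loocv:
        log.info("stage loocv: leave-one-case-out")
        loocv = loo_cross_validate(beta, sheet, q_max=config.q_max,
                                   delta_min=config.delta_min,
                                   max_probes=config.max_probes,
                                   fraction=config.train_fraction,
                                   seed=config.seed, C=config.svm_c)
        eio.write_results(loocv, os.path.join(out, "loocv.tsv"))

    log.info("stage dmr: region calling")
    dmrs = call_dmrs(dmp_table, manifest, maxgap=config.maxgap,
                     min_probes=config.min_probes,
                     probe_q_max=config.probe_q_max)
    eio.write_results(dmrs_to_frame(dmrs), os.path.join(out, "dmrs.tsv"))

    log.info("stage annotate: genomic context")
    annot = annotate_probes(probes.probe_ids, manifest)
    eio.write_results(annot, os.path.join(out, "probe_annotation.tsv"))
    summary = summarize_context(annot, "cpg_category").to_frame("percent")
    summary.index.name = "cpg_category"
    summary.reset_index().to_csv(os.path.join(out, "cpg_summary.tsv"),
                                 sep="\t", index=False)
    if dmrs:
        dmr_annot = annotate_dmrs(dmrs, manifest)
        eio.write_results(dmr_annot, os.path.join(out, "dmr_annotation.tsv"))

    run_manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "parameters": config.to_dict(),
        "inputs": {
            "beta": os.path.join(input_dir, "beta.tsv"),
            "samples": os.path.join(input_dir, "samples.tsv"),
            "manifest": os.path.join(input_dir, "manifest"),
        },
        "n_probes_selected": len(probes),
        "n_dmrs": len(dmrs),
    }
    with open(os.path.join(out, "run_manifest.json"), "w") as fh:
        json.dump(run_manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    log.info("run complete: %s", out)
    return out


def run_screen(model_path: str, beta_path: str, out_path: str,
               call_threshold: float = 0.5) -> None:
    """Score a screening beta matrix against a saved model."""
    model = EpisignatureModel.load(model_path)
    beta = eio.read_beta_matrix(beta_path)
    table = screen_samples(model, beta, beta.sample_ids, call_threshold)
    with open(out_path, "w") as fh:
        fh.write(f"# episig {__version__} screen: model={model_path} "
                 f"beta={beta_path} threshold={call_threshold}\n")
        table.to_csv(fh, sep="\t", index=False)
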