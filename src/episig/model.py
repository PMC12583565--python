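"""Episignature SVM classifier and Methylation Variant Pathogenicity scores.

A binary linear-kernel SVM separates signature carriers from everything
else (controls plus other-disorder samples).  Decision values are mapped
to probabilities with Platt's sigmoid fitted on the training decision
values, giving the MVP score: the calibrated probability that a sample
carries the episignature.  Training uses all cases plus a stratified
fraction (default 75%) of controls and of each other-disorder cohort;
the held-out remainder measures specificity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.svm import SVC

from .cluster import hierarchical_cluster, cut_two
from .dmp import EpisignatureProbeSet, moderated_t_test, select_probes
from .types import BetaMatrix, SampleSheet, ValidationError

__all__ = [
    "EpisignatureModel",
    "partition_training",
    "train_classifier",
    "mvp_score",
    "loo_cross_validate",
    "screen_samples",
]

SCHEMA_VERSION = 1


def _platt_fit(decision: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Fit Platt's sigmoid P(y=1|d) = 1/(1+exp(A*d+B)) by regularized MLE.

    Uses Platt's smoothed targets t+ = (N+ + 1)/(N+ + 2), t- = 1/(N- + 2)
    so calibrated probabilities stay off the 0/1 boundary even for a
    perfectly separated training set.
    """
    d = np.asarray(decision, dtype=float)
    y = np.asarray(y)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    t = np.where(y == 1, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))

    def nll(params: np.ndarray) -> float:
        a, b = params
        z = a * d + b
        # log(1 + exp(z)) computed stably
        log1pez = np.logaddexp(0.0, z)
        return float(np.sum(t * log1pez + (1.0 - t) * (log1pez - z)))

    res = minimize(nll, x0=np.array([-1.0, 0.0]), method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000})
    a, b = res.x
    return float(a), float(b)


def _platt_apply(decision: np.ndarray, a: float, b: float) -> np.ndarray:
    z = a * np.asarray(decision, dtype=float) + b
    return 1.0 / (1.0 + np.exp(z))


@dataclass
class EpisignatureModel:
    """Trained linear SVM over an episignature probe set."""

    probe_set: EpisignatureProbeSet
    weights: np.ndarray
    intercept: float
    platt_a: float
    platt_b: float
    train_ids: list[str]
    test_ids: list[str]
    train_fraction: float = 0.75
    seed: int = 0
    C: float = 1.0

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.weights) != len(self.probe_set):
            raise ValidationError(
                f"weight vector length {len(self.weights)} != probe set "
                f"size {len(self.probe_set)}"
            )
        overlap = set(self.train_ids) & set(self.test_ids)
        if overlap:
            raise ValidationError(
                f"train/test partitions overlap: {sorted(overlap)[:3]}"
            )

    def decision_values(self, beta: BetaMatrix,
                        sample_ids: Sequence[str] | None = None) -> pd.Series:
        ids = list(sample_ids) if sample_ids is not None else beta.sample_ids
        missing = [p for p in self.probe_set.probe_ids if p not in beta.data.index]
        if missing:
            raise ValidationError(
                f"probes required by model missing from matrix: "
                f"{', '.join(missing[:5])}"
                + (f" (+{len(missing) - 5} more)" if len(missing) > 5 else "")
            )
        x = beta.subset(probes=self.probe_set.probe_ids, samples=ids).values.T
        d = x @ self.weights + self.intercept
        return pd.Series(d, index=ids)

    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "probe_set": self.probe_set.to_dict(),
            "weights": [float(w) for w in self.weights],
            "intercept": self.intercept,
            "platt_a": self.platt_a,
            "platt_b": self.platt_b,
            "train_ids": list(self.train_ids),
            "test_ids": list(self.test_ids),
            "train_fraction": self.train_fraction,
            "seed": self.seed,
            "C": self.C,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EpisignatureModel":
        version = d.get("schema_version")
        if version != SCHEMA_VERSION:
            raise ValidationError(
                f"unsupported model schema_version {version!r} "
                f"(expected {SCHEMA_VERSION})"
            )
        return cls(
            probe_set=EpisignatureProbeSet.from_dict(d["probe_set"]),
            weights=np.asarray(d["weights"], dtype=float),
            intercept=float(d["intercept"]),
            platt_a=float(d["platt_a"]),
            platt_b=float(d["platt_b"]),
            train_ids=list(d["train_ids"]),
            test_ids=list(d["test_ids"]),
            train_fraction=float(d.get("train_fraction", 0.75)),
            seed=int(d.get("seed", 0)),
            C=float(d.get("C", 1.0)),
        )

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def load(cls, path: str) -> "EpisignatureModel":
        with open(path) as fh:
            try:
                payload = json.load(fh)
            except json.JSONDecodeError as exc:
                raise ValidationError(f"corrupt model JSON {path}: {exc}") from exc
        return cls.from_dict(payload)


def partition_training(
    sheet: SampleSheet, fraction: float = 0.75, seed: int = 0
) -> tuple[list[str], list[str]]:
    """Split background samples into train/test, stratified by cohort.

    All ``case`` samples go to train.  Controls and each other-disorder
    cohort are split ``fraction``/``1-fraction`` independently (floor of
    ``fraction * n`` to train, at least 1 when the cohort has >= 2
    samples).  A cohort with < 2 samples goes wholly to train with a
    warning.  ``test``-role samples belong to neither partition.
    """
    import warnings

    if not (0.0 < fraction < 1.0):
        raise ValidationError(f"fraction must be in (0, 1), got {fraction}")
    rng = np.random.default_rng(seed)
    train: list[str] = list(sheet.ids_with_role("case"))
    test: list[str] = []

    strata: list[list[str]] = [sheet.ids_with_role("control")]
    other = sheet.data[sheet.data["role"] == "other_disorder"]
    for label in sorted(other["cohort_label"].unique()):
        strata.append(list(other.index[other["cohort_label"] == label]))

    for ids in strata:
        ids = sorted(ids)
        if len(ids) < 2:
            if ids:
                warnings.warn(
                    f"cohort with <2 samples assigned wholly to train: {ids}",
                    stacklevel=2)
                train.extend(ids)
            continue
        n_train = max(1, int(np.floor(fraction * len(ids))))
        n_train = min(n_train, len(ids) - 1)
        perm = rng.permutation(len(ids))
        train.extend(ids[i] for i in sorted(perm[:n_train]))
        test.extend(ids[i] for i in sorted(perm[n_train:]))
    return train, test


def train_classifier(
    beta: BetaMatrix,
    probe_set: EpisignatureProbeSet,
    train_ids: Sequence[str],
    sheet: SampleSheet,
    C: float = 1.0,
    seed: int = 0,
    test_ids: Sequence[str] = (),
) -> EpisignatureModel:
    """Train the linear SVM (case vs rest) with Platt calibration.

    The feature space is the beta values of the signature probes.  The
    positive class is role ``case``; every other training sample is
    negative.  Deterministic for fixed inputs.
    """
    if len(probe_set) == 0:
        raise ValidationError("cannot train on an empty probe set")
    train_ids = list(train_ids)
    y = np.array([1 if sheet.role_of(s) == "case" else 0 for s in train_ids])
    if len(np.unique(y)) < 2:
        raise ValidationError("training set must contain both classes")
    x = beta.subset(probes=probe_set.probe_ids, samples=train_ids).values.T
    svm = SVC(kernel="linear", C=C, random_state=seed)
    svm.fit(x, y)
    weights = svm.coef_.ravel()
    intercept = float(svm.intercept_[0])
    decision = x @ weights + intercept
    # decision > 0 favors class 1; Platt A is negative for a correct model
    a, b = _platt_fit(decision, y)
    return EpisignatureModel(
        probe_set=probe_set,
        weights=weights,
        intercept=intercept,
        platt_a=a,
        platt_b=b,
        train_ids=train_ids,
        test_ids=list(test_ids),
        seed=seed,
        C=C,
    )


def mvp_score(
    model: EpisignatureModel,
    beta: BetaMatrix,
    sample_ids: Sequence[str] | None = None,
    partition_labels: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Calibrated MVP score in [0, 1] per sample.

    Raises if any signature probe is absent from the matrix (no silent
    imputation).  Returns a table with columns ``sample_id, mvp_score,
    partition``.
    """
    ids = list(sample_ids) if sample_ids is not None else beta.sample_ids
    d = model.decision_values(beta, ids)
    scores = np.clip(_platt_apply(d.to_numpy(), model.platt_a, model.platt_b),
                     0.0, 1.0)
    if partition_labels is None:
        partition_labels = {}
        for s in model.train_ids:
            partition_labels[s] = "train"
        for s in model.test_ids:
            partition_labels[s] = "test"
    partition = [partition_labels.get(s, "screen") for s in ids]
    return pd.DataFrame({
        "sample_id": ids,
        "mvp_score": scores,
        "partition": partition,
    })


def loo_cross_validate(
    beta: BetaMatrix,
    sheet: SampleSheet,
    q_max: float = 0.01,
    delta_min: float = 0.05,
    max_probes: int = 1000,
    fraction: float = 0.75,
    seed: int = 0,
    C: float = 1.0,
) -> pd.DataFrame:
    """Leave-one-case-out cross-validation of the full discovery loop.

    For each case: exclude it, re-run probe selection (remaining cases vs
    controls) and SVM training, then score the held-out case and record
    whether it joins the case branch when the dendrogram over the
    re-selected probes is cut into two clusters.

    Returns one row per round: ``held_out, n_probes, mvp, clusters_with_cases``.
    """
    case_ids = sheet.ids_with_role("case")
    if len(case_ids) < 3:
        raise ValidationError(f"LOOCV needs >=3 cases, got {len(case_ids)}")
    rows = []
    for held_out in case_ids:
        kept_cases = [c for c in case_ids if c != held_out]
        dmp = moderated_t_test(beta, sheet, case_ids=kept_cases,
                               control_ids=sheet.ids_with_role("control"))
        probes = select_probes(dmp, q_max=q_max, delta_min=delta_min,
                               max_probes=max_probes)
        if len(probes) == 0:
            rows.append((held_out, 0, np.nan, False))
            continue
        reduced = sheet.subset([s for s in sheet.sample_ids if s != held_out])
        train_ids, test_ids = partition_training(reduced, fraction, seed)
        model = train_classifier(beta, probes, train_ids, reduced,
                                 C=C, seed=seed, test_ids=test_ids)
        score = float(mvp_score(model, beta, [held_out])["mvp_score"].iloc[0])

        cluster_ids = kept_cases + sheet.ids_with_role("control") + [held_out]
        dendro = hierarchical_cluster(beta, probes, sample_ids=cluster_ids)
        assign = cut_two(dendro)
        case_labels = [assign[c] for c in kept_cases]
        majority = max(set(case_labels), key=case_labels.count)
        rows.append((held_out, len(probes), score, assign[held_out] == majority))
    return pd.DataFrame(rows, columns=["held_out", "n_probes", "mvp",
                                       "clusters_with_cases"])


def screen_samples(
    model: EpisignatureModel,
    beta: BetaMatrix,
    screen_ids: Sequence[str],
    call_threshold: float = 0.5,
) -> pd.DataFrame:
    """Score screening samples, descending MVP, with a call flag.

    The flag marks samples at or above ``call_threshold`` as putative
    signature carriers.
    """
    screen_ids = list(screen_ids)
    if not screen_ids:
        return pd.DataFrame(columns=["sample_id", "mvp_score", "partition",
                                     "called"])
    table = mvp_score(model, beta, screen_ids,
                      partition_labels={s: "screen" for s in screen_ids})
    table["called"] = table["mvp_score"] >= call_threshold
    return table.sort_values("mvp_score", ascending=False,
                             kind="mergesort").reset_index(drop=True)
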