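"""Differential methylation statistics and episignature probe selection.

Per-probe testing follows the empirical-Bayes moderated t approach:
probe-wise linear models are fit on M values (logit2 of beta), residual
variances are shrunk toward a common prior estimated by moment-matching
of log-variances, and the moderated t is referred to a t distribution
with augmented degrees of freedom.  Effect sizes (``delta_beta``) are
reported on the beta scale, the convention for methylation differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .types import BetaMatrix, SampleSheet, ValidationError

__all__ = [
    "beta_to_m",
    "moderated_t_test",
    "bh_adjust",
    "select_probes",
    "EpisignatureProbeSet",
]

DMP_COLUMNS = [
    "probe_id",
    "mean_beta_case",
    "mean_beta_control",
    "delta_beta",
    "moderated_t",
    "p_value",
    "q_value",
    "direction",
]


def beta_to_m(beta: np.ndarray | pd.DataFrame, epsilon: float = 1e-6):
    """Logit2 transform: ``M = log2(b / (1 - b))`` with b clipped away from 0/1.

    Parameters
    ----------
    beta
        Beta values in [0, 1]; array or DataFrame (shape preserved).
    epsilon
        Clip bound in (0, 0.5); absorbs exact 0/1 values.
    """
    if not (0.0 < epsilon < 0.5):
        raise ValidationError(f"epsilon must be in (0, 0.5), got {epsilon}")
    if isinstance(beta, pd.DataFrame):
        b = beta.to_numpy(dtype=float)
        clipped = np.clip(b, epsilon, 1.0 - epsilon)
        return pd.DataFrame(np.log2(clipped / (1.0 - clipped)),
                            index=beta.index, columns=beta.columns)
    b = np.asarray(beta, dtype=float)
    clipped = np.clip(b, epsilon, 1.0 - epsilon)
    return np.log2(clipped / (1.0 - clipped))


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration.

    Monotone decreasing target; the iteration below converges for all
    positive y (large y -> small x and vice versa).
    """
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Estimate prior df ``d0`` and scale ``s0^2`` for variance shrinkage.

    Moment-matching on z = log(s2): under the scaled-F sampling model,
    E[z] and Var[z] involve digamma/trigamma terms, giving closed-form
    estimates with ``d0`` obtained via the inverse trigamma.  Returns
    ``(inf, pooled mean variance)`` when the observed log-variance spread
    is no larger than expected from sampling alone (no evidence of
    heterogeneous true variances: complete shrinkage).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0)
    if ok.sum() < 2:
        raise ValidationError("need at least 2 positive residual variances")
    z = np.log(s2[ok])
    if np.var(z) < 1e-24:
        # no variance heterogeneity at all: shrink to the common value,
        # which keeps the moderated t equal to the ordinary t
        return np.inf, float(np.mean(s2[ok]))
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1))
    excess = e_var - float(special.polygamma(1, df / 2.0))
    if excess <= 0:
        # log-variance spread no larger than sampling alone: complete
        # shrinkage to the pooled (arithmetic-mean) variance
        return np.inf, float(np.mean(s2[ok]))
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def squeeze_variances(s2: np.ndarray, df: float,
                      prior: tuple[float, float] | None = None) -> np.ndarray:
    """Posterior variances ``(d0*s0^2 + df*s2) / (d0 + df)``."""
    if prior is None:
        prior = fit_variance_prior(s2, df)
    d0, s0_sq = prior
    if np.isinf(d0):
        return np.full_like(np.asarray(s2, dtype=float), s0_sq)
    return (d0 * s0_sq + df * np.asarray(s2, dtype=float)) / (d0 + df)


def moderated_t_test(
    beta: BetaMatrix,
    sheet: SampleSheet,
    covariates: Sequence[str] = (),
    case_ids: Sequence[str] | None = None,
    control_ids: Sequence[str] | None = None,
    epsilon: float = 1e-6,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Per-probe moderated t-test of cases versus controls.

    A linear model ``M ~ intercept + group (+ covariates)`` is fit per
    probe on M values; the group coefficient is the case-minus-control
    difference on the M scale.  Residual variances are moderated by the
    empirical-Bayes prior before forming the t statistic.  ``delta_beta``
    and the group means are computed on the beta scale.  Probes with any
    missing beta among the analysis samples are dropped.

    Parameters
    ----------
    covariates
        Sample-sheet column names entering the design additively
        (coerced to float).
    case_ids, control_ids
        Explicit group memberships; default to roles ``case``/``control``.
    prior_df
        Force the prior degrees of freedom ``d0`` (``np.inf`` gives the
        fully-shrunk limit); estimated from the data when ``None``.

    Returns
    -------
    DataFrame with columns ``probe_id, mean_beta_case, mean_beta_control,
    delta_beta, moderated_t, p_value, q_value, direction`` (q by
    Benjamini-Hochberg across all tested probes).
    """
    if case_ids is None:
        case_ids = sheet.ids_with_role("case")
    if control_ids is None:
        control_ids = sheet.ids_with_role("control")
    case_ids, control_ids = list(case_ids), list(control_ids)
    if len(case_ids) < 2 or len(control_ids) < 2:
        raise ValidationError(
            f"need >=2 samples per group, got {len(case_ids)} cases "
            f"and {len(control_ids)} controls"
        )
    for name in covariates:
        if name not in sheet.data.columns:
            raise ValidationError(f"covariate {name!r} absent from sample sheet")

    samples = case_ids + control_ids
    sub = beta.subset(samples=samples).drop_incomplete_probes()
    b = sub.values
    m = beta_to_m(b, epsilon=epsilon)
    n = len(samples)
    group = np.array([1.0] * len(case_ids) + [0.0] * len(control_ids))
    cols = [np.ones(n), group]
    for name in covariates:
        cols.append(sheet.data.loc[samples, name].astype(float).to_numpy())
    design = np.column_stack(cols)
    k = design.shape[1]
    if n - k < 1:
        raise ValidationError(
            f"no residual degrees of freedom: n={n}, parameters={k}"
        )

    xtx_inv = np.linalg.inv(design.T @ design)
    coef = m @ design @ xtx_inv  # probes x k
    resid = m - coef @ design.T
    df_resid = n - k
    s2 = np.einsum("ij,ij->i", resid, resid) / df_resid
    v_group = xtx_inv[1, 1]

    if prior_df is None:
        prior = fit_variance_prior(s2, df_resid)
    elif np.isinf(prior_df):
        prior = (np.inf, fit_variance_prior(s2, df_resid)[1])
    else:
        _, s0_sq = fit_variance_prior(s2, df_resid)
        prior = (float(prior_df), s0_sq)
    d0, _ = prior
    s2_post = squeeze_variances(s2, df_resid, prior)

    t = coef[:, 1] / np.sqrt(s2_post * v_group)
    df_total = df_resid + d0
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)

    mean_case = b[:, : len(case_ids)].mean(axis=1)
    mean_control = b[:, len(case_ids):].mean(axis=1)
    delta = mean_case - mean_control

    q = bh_adjust(pd.Series(p, index=sub.probe_ids))
    out = pd.DataFrame({
        "probe_id": sub.probe_ids,
        "mean_beta_case": mean_case,
        "mean_beta_control": mean_control,
        "delta_beta": delta,
        "moderated_t": t,
        "p_value": p,
        "q_value": q.to_numpy(),
        "direction": np.where(delta > 0, "hyper", "hypo"),
    })
    return out


def bh_adjust(p_values: pd.Series | np.ndarray) -> pd.Series:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), capped at 1."""
    if isinstance(p_values, pd.Series):
        index = p_values.index
        p = p_values.to_numpy(dtype=float)
    else:
        p = np.asarray(p_values, dtype=float)
        index = pd.RangeIndex(len(p))
    if len(p) == 0:
        return pd.Series([], index=index, dtype=float)
    bad = ~np.isfinite(p)
    if bad.any():
        raise ValidationError(f"NaN/inf p-value at {index[bad][0]!r}")
    if (p < 0).any() or (p > 1).any():
        off = (p < 0) | (p > 1)
        raise ValidationError(f"p-value out of [0,1] at {index[off][0]!r}")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return pd.Series(q, index=index)


@dataclass
class EpisignatureProbeSet:
    """An ordered episignature probe set with its selection provenance."""

    probe_ids: list[str]
    delta_beta: dict[str, float] = field(default_factory=dict)
    q_value: dict[str, float] = field(default_factory=dict)
    q_max: float = 0.01
    delta_min: float = 0.05
    max_probes: int = 1000

    def __len__(self) -> int:
        return len(self.probe_ids)

    def to_dict(self) -> dict:
        return {
            "probe_ids": list(self.probe_ids),
            "delta_beta": {k: float(v) for k, v in self.delta_beta.items()},
            "q_value": {k: float(v) for k, v in self.q_value.items()},
            "q_max": self.q_max,
            "delta_min": self.delta_min,
            "max_probes": self.max_probes,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EpisignatureProbeSet":
        return cls(
            probe_ids=list(d["probe_ids"]),
            delta_beta=dict(d.get("delta_beta", {})),
            q_value=dict(d.get("q_value", {})),
            q_max=d.get("q_max", 0.01),
            delta_min=d.get("delta_min", 0.05),
            max_probes=d.get("max_probes", 1000),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "probe_id": self.probe_ids,
            "delta_beta": [self.delta_beta.get(p, np.nan) for p in self.probe_ids],
            "q_value": [self.q_value.get(p, np.nan) for p in self.probe_ids],
        })


def select_probes(
    dmp_table: pd.DataFrame,
    q_max: float = 0.01,
    delta_min: float = 0.05,
    max_probes: int = 1000,
) -> EpisignatureProbeSet:
    """Select episignature probes by significance and effect size.

    Keeps probes with ``q <= q_max`` and ``|delta_beta| >= delta_min``,
    ranked by descending ``|moderated_t|`` (ties broken by probe id),
    truncated at ``max_probes``.  Returns an empty set with a warning if
    nothing passes.
    """
    passing = dmp_table[
        (dmp_table["q_value"] <= q_max)
        & (dmp_table["delta_beta"].abs() >= delta_min)
    ].copy()
    if passing.empty:
        warnings.warn("no probes passed selection thresholds; empty signature",
                      stacklevel=2)
        return EpisignatureProbeSet([], q_max=q_max, delta_min=delta_min,
                                    max_probes=max_probes)
    passing["abs_t"] = passing["moderated_t"].abs()
    passing = passing.sort_values(["abs_t", "probe_id"],
                                  ascending=[False, True], kind="mergesort")
    passing = passing.head(max_probes)
    return EpisignatureProbeSet(
        probe_ids=list(passing["probe_id"]),
        delta_beta=dict(zip(passing["probe_id"], passing["delta_beta"])),
        q_value=dict(zip(passing["probe_id"], passing["q_value"])),
        q_max=q_max,
        delta_min=delta_min,
        max_probes=max_probes,
    )
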