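"""Moderated t statistics, BH adjustment and probe selection.

The moderated-t path is checked against (a) an independently coded
per-probe brute-force evaluation of the moderation formulas (inverse
trigamma via root bracketing, not Newton) and (b) the limma reference
implementation run through Rscript on the same M matrix.
"""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import special, stats
from scipy.optimize import brentq

from episig.dmp import (beta_to_m, bh_adjust, fit_variance_prior,
                        moderated_t_test, select_probes)
from episig.types import BetaMatrix, ValidationError
from conftest import make_sheet


# ---------------------------------------------------------------------------
# beta -> M


@pytest.mark.parametrize("b,expected", [
    (0.5, 0.0),
    (0.8, 2.0),
    (0.0, np.log2(1e-6 / (1 - 1e-6))),  # ~ -19.93 with the default clip
])
def test_beta_to_m_values(b, expected):
    assert beta_to_m(np.array([b]), epsilon=1e-6)[0] == pytest.approx(expected,
                                                                      abs=1e-9)


def test_beta_to_m_rejects_bad_epsilon():
    with pytest.raises(ValidationError):
        beta_to_m(np.array([0.5]), epsilon=0.7)


# ---------------------------------------------------------------------------
# moderated t vs brute-force oracle


def _oracle_moderated(m_case: np.ndarray, m_ctrl: np.ndarray):
    """Direct per-probe evaluation of the moderation formulas.

    Two-group design only; prior estimated by the log-variance moment
    equations with the inverse trigamma found by bracketed root search.
    """
    n1, n2 = m_case.shape[1], m_ctrl.shape[1]
    delta = m_case.mean(axis=1) - m_ctrl.mean(axis=1)
    rss = (((m_case.T - m_case.mean(axis=1)) ** 2).sum(axis=0)
           + ((m_ctrl.T - m_ctrl.mean(axis=1)) ** 2).sum(axis=0))
    df = n1 + n2 - 2
    s2 = rss / df
    v = 1.0 / n1 + 1.0 / n2

    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    evar = float(np.sum((e - e.mean()) ** 2) / (len(e) - 1))
    excess = evar - float(special.polygamma(1, df / 2.0))
    if excess > 0:
        half_d0 = brentq(lambda x: special.polygamma(1, x) - excess,
                         1e-8, 1e8, xtol=1e-14, rtol=1e-15)
        d0 = 2.0 * half_d0
        s0 = np.exp(e.mean() + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
        s2_post = (d0 * s0 + df * s2) / (d0 + df)
        df_total = df + d0
        t = delta / np.sqrt(s2_post * v)
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    else:
        s0 = float(np.mean(s2))  # complete shrinkage to the pooled variance
        t = delta / np.sqrt(s0 * v)
        p = 2.0 * stats.norm.sf(np.abs(t))
    return t, p


def test_moderated_t_matches_brute_force_oracle():
    rng = np.random.default_rng(42)
    n1 = n2 = 4
    betas = rng.uniform(0.2, 0.8, size=(3, n1 + n2))
    beta = BetaMatrix(pd.DataFrame(
        betas, index=[f"cg{i}" for i in range(3)],
        columns=[f"a{i}" for i in range(n1)] + [f"b{i}" for i in range(n2)]))
    sheet = make_sheet([f"a{i}" for i in range(n1)],
                       [f"b{i}" for i in range(n2)])
    table = moderated_t_test(beta, sheet)

    m = beta_to_m(betas)
    t_exp, p_exp = _oracle_moderated(m[:, :n1], m[:, n1:])
    np.testing.assert_allclose(table["moderated_t"].to_numpy(), t_exp,
                               atol=1e-10)
    np.testing.assert_allclose(table["p_value"].to_numpy(), p_exp, atol=1e-10)


def test_equal_variances_reduce_to_classic_t():
    """When every probe has the same sample variance there is nothing to
    shrink: the moderated t must equal the ordinary two-sample t."""
    rng = np.random.default_rng(3)
    base_m = rng.uniform(-1.0, 1.0, size=8)
    # identical M-scale spread for every probe, different means
    m_rows = np.vstack([base_m + shift for shift in (0.0, 0.3, 0.6, -0.3)])
    betas = 2.0 ** m_rows / (1.0 + 2.0 ** m_rows)  # inverse logit2
    beta = BetaMatrix(pd.DataFrame(
        betas, index=[f"cg{i}" for i in range(4)],
        columns=[f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)]))
    sheet = make_sheet([f"a{i}" for i in range(4)], [f"b{i}" for i in range(4)])
    table = moderated_t_test(beta, sheet)

    m = beta_to_m(betas)
    classic = stats.ttest_ind(m[:, :4], m[:, 4:], axis=1)
    np.testing.assert_allclose(table["moderated_t"].to_numpy(),
                               classic.statistic, atol=1e-8)


def test_forced_infinite_prior_uses_common_variance():
    rng = np.random.default_rng(9)
    betas = rng.uniform(0.2, 0.8, size=(20, 10))
    beta = BetaMatrix(pd.DataFrame(
        betas, index=[f"cg{i}" for i in range(20)],
        columns=[f"a{i}" for i in range(5)] + [f"b{i}" for i in range(5)]))
    sheet = make_sheet([f"a{i}" for i in range(5)], [f"b{i}" for i in range(5)])
    table = moderated_t_test(beta, sheet, prior_df=np.inf)

    m = beta_to_m(betas)
    delta = m[:, :5].mean(axis=1) - m[:, 5:].mean(axis=1)
    rss = (((m[:, :5].T - m[:, :5].mean(axis=1)) ** 2).sum(axis=0)
           + ((m[:, 5:].T - m[:, 5:].mean(axis=1)) ** 2).sum(axis=0))
    s2 = rss / 8.0
    _, s0 = fit_variance_prior(s2, 8.0)
    expected = delta / np.sqrt(s0 * (1 / 5 + 1 / 5))
    np.testing.assert_allclose(table["moderated_t"].to_numpy(), expected,
                               atol=1e-10)


def test_zero_variance_probe_yields_finite_statistic():
    betas = np.array([
        [0.2, 0.2, 0.2, 0.8, 0.8, 0.8],        # constant within groups
        [0.3, 0.4, 0.5, 0.3, 0.5, 0.6],
        [0.6, 0.7, 0.65, 0.2, 0.25, 0.3],
    ])
    beta = BetaMatrix(pd.DataFrame(
        betas, index=["cg0", "cg1", "cg2"],
        columns=["a0", "a1", "a2", "b0", "b1", "b2"]))
    sheet = make_sheet(["a0", "a1", "a2"], ["b0", "b1", "b2"])
    table = moderated_t_test(beta, sheet)
    assert np.isfinite(table["moderated_t"]).all()


def test_small_group_rejected(tiny_beta):
    sheet = make_sheet(["s1"], ["s2", "s3", "s4"])
    with pytest.raises(ValidationError, match=">=2"):
        moderated_t_test(tiny_beta, sheet)


@pytest.mark.skipif(shutil.which("Rscript") is None,
                    reason="Rscript not available")
def test_moderated_t_matches_limma(tmp_path):
    """Cross-check against the limma reference on one shared M matrix."""
    rng = np.random.default_rng(7)
    n1, n2 = 6, 6
    # heteroscedastic probes so the prior df estimate is finite
    sd = rng.uniform(0.2, 2.0, size=50)
    mu = rng.uniform(-2.0, 2.0, size=50)
    m = mu[:, None] + sd[:, None] * rng.standard_normal((50, n1 + n2))
    betas = 2.0 ** m / (1.0 + 2.0 ** m)
    mdf = pd.DataFrame(m, index=[f"cg{i}" for i in range(50)],
                       columns=[f"s{i}" for i in range(n1 + n2)])
    mpath = tmp_path / "m.tsv"
    mdf.to_csv(mpath, sep="\t")
    script = tmp_path / "limma.R"
    script.write_text(f"""
suppressMessages(library(limma))
m <- as.matrix(read.table("{mpath}", header=TRUE, row.names=1, sep="\\t"))
group <- factor(rep(c("case", "ctrl"), c({n1}, {n2})), levels=c("ctrl", "case"))
design <- model.matrix(~group)
fit <- eBayes(lmFit(m, design))
out <- data.frame(t=fit$t[, 2], p=fit$p.value[, 2])
write.table(out, "{tmp_path}/out.tsv", sep="\\t", quote=FALSE)
""")
    subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
    ref = pd.read_csv(tmp_path / "out.tsv", sep="\t")

    beta = BetaMatrix(pd.DataFrame(
        betas, index=mdf.index,
        columns=[f"s{i}" for i in range(n1 + n2)]))
    sheet = make_sheet([f"s{i}" for i in range(n1)],
                       [f"s{i}" for i in range(n1, n1 + n2)])
    table = moderated_t_test(beta, sheet)
    np.testing.assert_allclose(table["moderated_t"].to_numpy(),
                               ref["t"].to_numpy(), rtol=1e-6)
    np.testing.assert_allclose(table["p_value"].to_numpy(),
                               ref["p"].to_numpy(), rtol=1e-6)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg


def bh_oracle(p: np.ndarray) -> np.ndarray:
    """Brute-force step-up: q_i = min over j with p_(j) >= p_(i) of p_(j)*n/j."""
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(n)
    running = np.inf
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        q[i] = min(running, 1.0)
    return q


def test_bh_worked_example():
    q = bh_adjust(np.array([0.005, 0.009, 0.05, 0.5]))
    np.testing.assert_allclose(q.to_numpy(), [0.018, 0.018, 0.05 * 4 / 3, 0.5],
                               atol=1e-12)


def test_bh_single_and_tied_pvalues():
    assert bh_adjust(np.array([0.03]))[0] == pytest.approx(0.03)
    q = bh_adjust(np.array([0.2, 0.2, 0.2]))
    np.testing.assert_allclose(q.to_numpy(), [0.2, 0.2, 0.2])


def test_bh_rejects_nan_naming_probe():
    s = pd.Series([0.1, np.nan], index=["cgA", "cgB"])
    with pytest.raises(ValidationError, match="cgB"):
        bh_adjust(s)


@settings(max_examples=500, derandomize=True)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                max_size=8))
def test_bh_matches_brute_force_on_short_vectors(p_list):
    p = np.array(p_list)
    q = bh_adjust(p).to_numpy()
    np.testing.assert_allclose(q, bh_oracle(p), atol=1e-12)
    assert (q >= p - 1e-12).all() and (q <= 1.0 + 1e-12).all()


# ---------------------------------------------------------------------------
# probe selection


def _toy_dmp(n=50, seed=0):
    rng = np.random.default_rng(seed)
    t = rng.normal(0, 8, size=n)
    delta = np.sign(t) * rng.uniform(0.05, 0.3, size=n)
    return pd.DataFrame({
        "probe_id": [f"cg{i:03d}" for i in range(n)],
        "delta_beta": delta,
        "moderated_t": t,
        "p_value": 2 * stats.norm.sf(np.abs(t)),
        "q_value": np.minimum(2 * stats.norm.sf(np.abs(t)) * n, 1.0),
        "direction": np.where(delta > 0, "hyper", "hypo"),
    })


def test_selection_cap_and_ordering():
    table = _toy_dmp()
    table["q_value"] = 0.001  # everything passes the q filter
    sel = select_probes(table, q_max=0.01, delta_min=0.05, max_probes=10)
    assert len(sel) == 10
    abs_t = table.set_index("probe_id")["moderated_t"].abs()
    assert list(sel.probe_ids) == list(abs_t.sort_values(ascending=False)
                                       .head(10).index)


def test_selection_invariant_to_row_order():
    table = _toy_dmp()
    shuffled = table.sample(frac=1.0, random_state=4).reset_index(drop=True)
    a = select_probes(table)
    b = select_probes(shuffled)
    assert a.probe_ids == b.probe_ids


def test_selection_thresholds_enforced(fixture_dmp, fixture_probes):
    for pid in fixture_probes.probe_ids:
        assert fixture_probes.q_value[pid] <= fixture_probes.q_max
        assert abs(fixture_probes.delta_beta[pid]) >= fixture_probes.delta_min


def test_direction_matches_delta_sign(fixture_dmp):
    hyper = fixture_dmp["direction"] == "hyper"
    assert (hyper == (fixture_dmp["delta_beta"] > 0)).all()
    assert fixture_dmp["q_value"].between(0, 1).all()
    assert (fixture_dmp["q_value"] >= fixture_dmp["p_value"] - 1e-12).all()


def test_empty_selection_warns_not_raises():
    table = _toy_dmp()
    table["q_value"] = 1.0
    with pytest.warns(UserWarning, match="no probes passed"):
        sel = select_probes(table)
    assert len(sel) == 0
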