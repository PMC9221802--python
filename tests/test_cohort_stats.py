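"""mRECIST classification and the group-comparison statistics."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import gammaln

from rtae.cohort_stats import (
    CATEGORIES,
    ContingencyTable2x2,
    ResponseLabel,
    compare_groups,
    fisher_exact_2x2,
    mann_whitney_u,
    mrecist_classify,
    pearson_chi2,
    printed_table_pvalues,
    summarize_cohort,
)


# ---------------------------------------------------------------------------
# mRECIST
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "pre_e, post_e, pre_s, post_s, expected",
    [
        (100, 0, 20, 20, "CR"),      # enhancement gone
        (100, 70, 20, 20, "PR"),     # exactly 30% decrease (inclusive)
        (100, 90, 20, 24, "PD"),     # exactly 20% size increase
        (100, 80, 20, 21, "SD"),     # neither rule fires
        (100, 50, 20, 25, "PD"),     # progression beats enhancement drop
        (100, 0, 20, 30, "CR"),      # complete response beats progression
    ],
)
def test_mrecist_rules(pre_e, post_e, pre_s, post_s, expected):
    assert mrecist_classify(pre_e, post_e, pre_s, post_s).category == expected


def test_mrecist_exhaustive_and_exclusive():
    """Over a grid of inputs every lesion gets exactly one category."""
    for post_e in [0, 20, 65, 71, 100]:
        for post_s in [10, 20, 23.9, 24, 40]:
            lab = mrecist_classify(100, post_e, 20, post_s)
            assert lab.category in CATEGORIES
            assert lab.objective_response == (lab.category in ("CR", "PR"))


def test_mrecist_rejects_bad_input():
    with pytest.raises(ValueError):
        mrecist_classify(-1, 0, 20, 20)
    with pytest.raises(ValueError):
        mrecist_classify(0, 0, 20, 20)  # zero baseline enhancement


def test_summarize_cohort_published_mix():
    labels = (
        [ResponseLabel("CR")] * 14 + [ResponseLabel("PR")] * 15
        + [ResponseLabel("SD")] * 19 + [ResponseLabel("PD")] * 3
    )
    s = summarize_cohort(labels)
    assert s["endpoints"]["objective_response"] == {"count": 29, "pct": 56.9}
    assert s["endpoints"]["complete_response"] == {"count": 14, "pct": 27.5}
    assert s["categories"]["CR"]["count"] == 14
    total_pct = sum(v["pct"] for v in s["categories"].values())
    assert total_pct == pytest.approx(100.0, abs=0.2)


def test_summarize_single_patient():
    s = summarize_cohort([ResponseLabel("CR")])
    assert s["categories"]["CR"] == {"count": 1, "pct": 100.0}


# ---------------------------------------------------------------------------
# Fisher exact
# ---------------------------------------------------------------------------

def fisher_enumeration_oracle(a, b, c, d):
    """Full hypergeometric enumeration over tables with fixed margins."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def logp(x):
        # P(X = x) for X ~ Hypergeom(n, r1, c1)
        return (
            gammaln(r1 + 1) - gammaln(x + 1) - gammaln(r1 - x + 1)
            + gammaln(r2 + 1) - gammaln(c1 - x + 1) - gammaln(r2 - c1 + x + 1)
            - (gammaln(n + 1) - gammaln(c1 + 1) - gammaln(n - c1 + 1))
        )

    lo, hi = max(0, c1 - r2), min(r1, c1)
    p_obs = logp(a)
    total = 0.0
    for x in range(lo, hi + 1):
        lp = logp(x)
        if lp <= p_obs + np.log(1 + 1e-7):
            total += np.exp(lp)
    return min(total, 1.0)


def test_fisher_matches_enumeration_oracle(rng):
    for _ in range(60):
        a, b, c, d = rng.integers(0, 16, size=4)
        if a + b + c + d == 0:
            a = 1
        t = ContingencyTable2x2(int(a), int(b), int(c), int(d))
        assert fisher_exact_2x2(t) == pytest.approx(
            fisher_enumeration_oracle(int(a), int(b), int(c), int(d)), abs=1e-10
        )


def test_fisher_symmetry_and_degenerate():
    t = ContingencyTable2x2(3, 7, 11, 2)
    p = fisher_exact_2x2(t)
    assert fisher_exact_2x2(ContingencyTable2x2(7, 3, 2, 11)) == pytest.approx(p)
    assert fisher_exact_2x2(ContingencyTable2x2(11, 2, 3, 7)) == pytest.approx(p)
    assert fisher_exact_2x2(ContingencyTable2x2(1, 1, 1, 1)) == 1.0
    assert fisher_exact_2x2(ContingencyTable2x2(0, 0, 5, 7)) == 1.0  # zero margin


@pytest.mark.parametrize(
    "a, b, c, d, printed",
    [
        (0, 4, 14, 33, 0.565),    # threshold growth, CR contrast
        (13, 36, 1, 1, 0.478),    # nonrim APHE, CR contrast
        (1, 0, 13, 37, 0.275),    # blood products, CR contrast
        (4, 5, 10, 32, 0.236),    # US visibility, CR contrast
        (22, 21, 7, 1, 0.117),    # washout, OR contrast
    ],
)
def test_fisher_reproduces_published_pvalues(a, b, c, d, printed):
    assert round(fisher_exact_2x2(ContingencyTable2x2(a, b, c, d)), 3) == printed


# ---------------------------------------------------------------------------
# chi-squared
# ---------------------------------------------------------------------------

def test_chi2_hand_value_and_proportional():
    stat, p = pearson_chi2([[10, 20], [20, 10]])
    assert stat == pytest.approx(60 * (10 * 10 - 20 * 20) ** 2 / 30**4, abs=1e-9)
    assert stat == pytest.approx(6.667, abs=1e-3)
    stat0, p0 = pearson_chi2([[10, 20], [20, 40]])
    assert stat0 == pytest.approx(0.0, abs=1e-12)
    assert p0 == pytest.approx(1.0)


def test_chi2_agrees_with_permutation_null(rng):
    """The chi-squared p approximates a Monte-Carlo permutation p on a
    moderate-count table."""
    x = np.r_[np.ones(100, int), np.zeros(140, int)]
    g = np.r_[np.ones(57, int), np.zeros(43, int), np.ones(63, int), np.zeros(77, int)]
    a = int(np.sum(x & g))
    tab = [[a, int(np.sum(x & (1 - g)))], [int(np.sum((1 - x) & g)), int(np.sum((1 - x) & (1 - g)))]]
    stat, p = pearson_chi2(tab)
    count = 0
    n_perm = 4000
    for _ in range(n_perm):
        gp = rng.permutation(g)
        ap = int(np.sum(x & gp))
        tp = [[ap, int(np.sum(x & (1 - gp)))], [int(np.sum((1 - x) & gp)), int(np.sum((1 - x) & (1 - gp)))]]
        sp, _ = pearson_chi2(tp)
        count += sp >= stat - 1e-12
    assert p == pytest.approx(count / n_perm, abs=0.05)


def test_chi2_zero_expected_routes_to_fisher():
    with pytest.raises(ValueError):
        pearson_chi2([[0, 0], [5, 7]])


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------

def mwu_enumeration_oracle(x0, x1):
    """Exact two-sided p by enumerating all group assignments."""
    pooled = np.concatenate([x0, x1])
    n0 = len(x0)
    ranks = stats.rankdata(pooled)
    u_obs = ranks[:n0].sum() - n0 * (n0 + 1) / 2
    n = len(pooled)
    mean_u = n0 * (n - n0) / 2
    count = 0
    total = 0
    for idx in itertools.combinations(range(n), n0):
        u = ranks[list(idx)].sum() - n0 * (n0 + 1) / 2
        total += 1
        if abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-9:
            count += 1
    return count / total


def test_mwu_known_values():
    u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
    assert (u, p) == (0.0, pytest.approx(0.1))
    u_same, _ = mann_whitney_u([1, 2, 3, 4], [1, 2, 3, 4])
    assert u_same == 8.0  # n0*n1/2 for identical groups


def test_mwu_matches_enumeration_oracle(rng):
    for _ in range(10):
        n0, n1 = rng.integers(3, 6), rng.integers(3, 6)
        x = rng.permutation(np.arange(n0 + n1, dtype=float) * 1.7)  # distinct values
        _, p = mann_whitney_u(x[:n0], x[n0:])
        assert p == pytest.approx(mwu_enumeration_oracle(x[:n0], x[n0:]), abs=1e-10)


# ---------------------------------------------------------------------------
# compare_groups and the printed tables
# ---------------------------------------------------------------------------

def test_printed_table_rows_reproduce():
    """Routed Fisher/chi-squared tests reproduce the published p-values on
    every router-consistent row of the baseline tables."""
    df = printed_table_pvalues(verified_only=True)
    assert len(df) == 40
    assert np.allclose(df.recomputed_p.round(3), df.printed_p, atol=1.5e-4)


def test_compare_groups_report(rng):
    n = 51
    group = np.r_[np.ones(14, int), np.zeros(37, int)]
    table = pd.DataFrame(
        {
            "platelets": rng.lognormal(np.log(100), 0.4, n),
            "ascites": rng.integers(0, 2, n),
            "never_seen": np.zeros(n),  # constant: untestable
        }
    )
    rep = compare_groups(table, group)
    assert len(rep) == 3
    assert rep.set_index("variable").loc["never_seen", "test"] == "NA"
    assert rep.set_index("variable").loc["platelets", "test"] == "mannwhitney"
    assert set(rep.columns) >= {"variable", "summary_pos", "summary_neg", "test", "p"}
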