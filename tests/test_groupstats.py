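"""Mean-level statistics layer against exact enumeration and closed forms."""

import numpy as np
import pytest
from scipy import stats

from rfnet.errors import DomainError
from rfnet.groupstats import (
    bh_fdr,
    chisq_yates_2x2,
    cochran_armitage_trend,
    moderation_fit,
    welch_t,
    wilcoxon_ranksum_cc,
    wilcoxon_signedrank_cc,
)


# --- rank-sum -------------------------------------------------------------

def test_ranksum_exact_enumeration_example():
    x, y = [1.1, 2.3, 3.5], [4.2, 5.1, 6.3]
    res = wilcoxon_ranksum_cc(x, y, exact=True)
    assert res.statistic == 0.0  # U of the first sample
    assert res.p == pytest.approx(0.1)  # 2/20 orderings
    cc = wilcoxon_ranksum_cc(x, y)
    assert cc.p == pytest.approx(0.0809, abs=2e-4)


def test_ranksum_identical_samples():
    x = [1.0, 2.0, 3.0, 4.0]
    res = wilcoxon_ranksum_cc(x, list(x))
    assert res.p > 0.9


def test_ranksum_shift_invariance():
    rng = np.random.default_rng(0)
    x, y = rng.standard_normal(20), rng.standard_normal(25) + 0.5
    a = wilcoxon_ranksum_cc(x, y)
    b = wilcoxon_ranksum_cc(x + 10, y + 10)
    assert a.statistic == b.statistic and a.p == b.p


def test_ranksum_asymptotic_close_to_exact_small_n():
    rng = np.random.default_rng(1)
    for _ in range(10):
        x = rng.standard_normal(7)
        y = rng.standard_normal(8) + rng.uniform(-1, 1)
        pe = wilcoxon_ranksum_cc(x, y, exact=True).p
        pa = wilcoxon_ranksum_cc(x, y).p
        assert abs(pe - pa) < 0.05


# --- signed-rank ----------------------------------------------------------

def test_signedrank_exact_enumeration_example():
    # differences (1, -2, 3, -4, 5)
    res = wilcoxon_signedrank_cc([1, 0, 3, 0, 5], [0, 2, 0, 4, 0], exact=True)
    assert res.statistic == 9.0
    assert res.p == pytest.approx(26 / 32)


def test_signedrank_all_positive_differences():
    res = wilcoxon_signedrank_cc(np.arange(1, 11) + 5.0, np.arange(1, 11) * 1.0)
    assert res.statistic == 55.0


def test_signedrank_antisymmetry():
    rng = np.random.default_rng(2)
    d = rng.standard_normal(12)
    base = np.zeros(12)
    v_pos = wilcoxon_signedrank_cc(d, base).statistic
    v_neg = wilcoxon_signedrank_cc(base, d).statistic
    assert v_pos + v_neg == pytest.approx(12 * 13 / 2)


def test_signedrank_all_zero_differences_errors():
    with pytest.raises(DomainError):
        wilcoxon_signedrank_cc([1.0, 2.0], [1.0, 2.0])


def test_signedrank_matches_r_normal_approximation():
    # regression against the standard continuity-corrected normal formula
    d = np.array([0.5, -1.2, 2.0, 1.1, -0.3, 0.8, 1.9, -2.5, 0.4, 1.0])
    res = wilcoxon_signedrank_cc(d, np.zeros_like(d))
    ranks = stats.rankdata(np.abs(d))
    v = ranks[d > 0].sum()
    mu, var = 10 * 11 / 4, 10 * 11 * 21 / 24
    z = (v - mu - 0.5 * np.sign(v - mu)) / np.sqrt(var)
    assert res.p == pytest.approx(2 * stats.norm.sf(abs(z)))


# --- contingency ----------------------------------------------------------

@pytest.mark.parametrize(
    "table,expected",
    [
        ([[498, 133], [440, 59]], 16.27),
        ([[201, 437], [74, 427]], 42.00),
    ],
)
def test_yates_chi_square_known_tables(table, expected):
    assert chisq_yates_2x2(table).statistic == pytest.approx(expected, abs=0.005)


def test_yates_proportional_table_is_zero():
    res = chisq_yates_2x2([[50, 50], [50, 50]])
    assert res.statistic == 0.0 and res.p == 1.0


def test_yates_zero_margin_errors():
    with pytest.raises(DomainError):
        chisq_yates_2x2([[0, 0], [10, 20]])


def test_trend_identical_distributions_zero():
    assert cochran_armitage_trend([[10, 20, 30], [10, 20, 30]]).statistic == pytest.approx(0.0)


def test_trend_hypergeometric_variance_example():
    res = cochran_armitage_trend([[20, 10, 0], [0, 10, 20]])
    expected = -20 / np.sqrt(2400 * 900 / (3600 * 59))
    assert res.statistic == pytest.approx(expected, abs=1e-10)
    assert res.statistic == pytest.approx(-6.27, abs=0.005)


def test_trend_sign_flips_with_group_swap():
    a = cochran_armitage_trend([[20, 10, 5], [5, 10, 20]])
    b = cochran_armitage_trend([[5, 10, 20], [20, 10, 5]])
    assert a.statistic == pytest.approx(-b.statistic)


def test_trend_matches_permutation_null(rng):
    """Cross-check the hypergeometric variance by full permutation at small n."""
    table = np.array([[6, 3, 1], [2, 4, 4]])
    res = cochran_armitage_trend(table)
    group = np.repeat([0, 1], [10, 10])
    cats = np.repeat([0, 1, 2, 0, 1, 2], [6, 3, 1, 2, 4, 4])
    scores = cats + 1.0
    t_obs = scores[group == 0].sum()
    sims = np.array([scores[rng.permutation(20)[:10]].sum() for _ in range(20000)])
    z_mc = (t_obs - sims.mean()) / sims.std(ddof=0)
    assert res.statistic == pytest.approx(z_mc, abs=0.1)


# --- Welch ----------------------------------------------------------------

def test_welch_equal_n_equal_variance_closed_form():
    res = welch_t([1, 2, 3, 4, 5], [2, 3, 4, 5, 6])
    assert res.statistic == pytest.approx(-1.0)
    assert res.df == pytest.approx(8.0)


def test_welch_identical_samples_zero():
    assert welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]).statistic == 0.0


def test_welch_affine_equivariance():
    rng = np.random.default_rng(3)
    x, y = rng.standard_normal(15), rng.standard_normal(18) + 1
    a = welch_t(x, y)
    b = welch_t(3 * x + 7, 3 * y + 7)
    assert a.statistic == pytest.approx(b.statistic)
    assert a.p == pytest.approx(b.p)


# --- FDR ------------------------------------------------------------------

def test_bh_step_up_example():
    np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])


def test_bh_single_and_bounds():
    np.testing.assert_allclose(bh_fdr([0.2]), [0.2])
    out = bh_fdr(np.linspace(0.001, 1.0, 20))
    assert (np.diff(out[np.argsort(np.linspace(0.001, 1.0, 20))]) >= -1e-15).all()
    assert (out <= 1.0).all()


def test_bh_order_invariance(rng):
    p = rng.random(12)
    perm = rng.permutation(12)
    np.testing.assert_allclose(bh_fdr(p)[perm], bh_fdr(p[perm]))


def test_bh_rejects_out_of_range():
    with pytest.raises(DomainError):
        bh_fdr([0.1, 1.2])


# --- moderation -----------------------------------------------------------

def _long_panel(rng, n, interaction=0.0):
    sid = np.repeat(np.arange(n), 2)
    age = np.tile([0.0, 1.0], n)
    grp = np.repeat((rng.random(n) < 0.5).astype(float), 2)
    subj = np.repeat(rng.standard_normal(n) * 0.5, 2)
    y = 0.2 * age + interaction * age * grp + subj + rng.standard_normal(2 * n) * 0.8
    return y, age, grp, sid


def test_moderation_null_interaction_rarely_significant(rng):
    flagged = 0
    reps = 40
    for _ in range(reps):
        y, age, grp, sid = _long_panel(rng, 400, interaction=0.0)
        res = moderation_fit(y, age, grp, sid)
        if res.p < 0.05:
            flagged += 1
    assert flagged <= 8  # ~5% nominal; generous Monte-Carlo allowance


def test_moderation_recovers_planted_slope(rng):
    y, age, grp, sid = _long_panel(rng, 1000, interaction=0.3)
    res = moderation_fit(y, age, grp, sid)
    assert res.statistic == pytest.approx(0.3, abs=0.1)
    assert res.p < 0.05


def test_moderation_binary_null_odds_ratio_near_one(rng):
    n = 1500
    sid = np.repeat(np.arange(n), 2)
    age = np.tile([0.0, 1.0], n)
    grp = np.repeat((rng.random(n) < 0.5).astype(float), 2)
    y = (rng.random(2 * n) < 0.6).astype(float)
    res = moderation_fit(y, age, grp, sid)
    assert res.method == "moderation-logit"
    assert 0.6 < res.statistic < 1.6
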