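"""Brute-force oracles and null calibration for the test battery."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

import usvkit as uk


# ---------------------------------------------------------------------------
# independent enumeration oracles

def mw_exact_p_oracle(x, y):
    """Exact two-sided Mann-Whitney p by enumerating all C(n1+n2, n1) labelings."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1 = x.size
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)

    def u_of(idx):
        return ranks[list(idx)].sum() - n1 * (n1 + 1) / 2

    u_obs = u_of(range(n1))
    mu = n1 * y.size / 2
    count = total = 0
    for idx in itertools.combinations(range(pooled.size), n1):
        total += 1
        if abs(u_of(idx) - mu) >= abs(u_obs - mu) - 1e-9:
            count += 1
    return count / total


def wilcoxon_exact_p_oracle(d):
    """Exact two-sided signed-rank p over all 2^n sign assignments."""
    d = np.asarray(d, float)
    d = d[d != 0]
    n = d.size
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    mu = n * (n + 1) / 4
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = ranks[np.array(signs, bool)].sum()
        if abs(w - mu) >= abs(w_obs - mu) - 1e-9:
            count += 1
    return count / 2**n


def test_mann_whitney_trivial_cases():
    assert uk.mann_whitney_u([1, 2, 3], [4, 5, 6]).statistic == 0.0
    r = uk.mann_whitney_u([1, 2, 3], [1, 2, 3])
    assert r.statistic == 4.5  # n1*n2/2 under symmetry
    r2 = uk.mann_whitney_u([5, 5, 5], [5, 5])
    assert r2.p == 1.0 and r2.warning is not None


def test_u_plus_u_prime_identity(rng):
    for _ in range(20):
        x = rng.normal(size=rng.integers(2, 12))
        y = rng.normal(size=rng.integers(2, 12))
        r = uk.mann_whitney_u(x, y)
        assert r.extras["U1"] + r.extras["U2"] == x.size * y.size


def test_mann_whitney_matches_enumeration_oracle(rng):
    """Exact path agrees with full enumeration on n = 8 vs 7 instances."""
    for _ in range(5):
        x = rng.normal(size=8)
        y = rng.normal(size=7)
        r = uk.mann_whitney_u(x, y)
        assert r.exact
        assert r.p == pytest.approx(mw_exact_p_oracle(x, y), abs=1e-12)


def test_wilcoxon_trivial_cases():
    r = uk.wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])
    assert r.p == 1.0 and r.warning is not None
    # antisymmetric differences
    r2 = uk.wilcoxon_signed_rank(np.array([2.0, -2.0, 3.0, -3.0]))
    assert r2.z == 0.0


def test_wilcoxon_matches_enumeration_oracle(rng):
    """Exact path agrees with the 2^12 sign-pattern oracle."""
    for _ in range(4):
        d = rng.normal(size=12)
        r = uk.wilcoxon_signed_rank(d)
        assert r.exact
        assert r.p == pytest.approx(wilcoxon_exact_p_oracle(d), abs=1e-12)


def test_wilcoxon_sign_convention_and_flip():
    """Z < 0 when x dominates; swapping samples flips the sign only."""
    x = np.array([36.8, 53.8, 79.9, 48.5, 171.7, 102.4, 77.1, 60.0, 55.0, 90.0])
    y = np.array([27.7, 5.3, 48.6, 8.7, 80.9, 63.9, 14.8, 30.0, 61.0, 40.0])
    r = uk.wilcoxon_signed_rank(x, y)
    assert r.z < 0
    r2 = uk.wilcoxon_signed_rank(y, x)
    assert r2.z == pytest.approx(-r.z)
    assert r2.p == pytest.approx(r.p)


def test_wilcoxon_tie_corrected_z_hand_computed():
    """Frozen hand computation of the tie-corrected Z (no continuity corr.).

    d = (+1, +1, +1, -1, +2): |d| midranks are (2.5, 2.5, 2.5, 2.5, 5), so
    W+ = 12.5, mu = 7.5, sigma^2 = 5*6*11/24 - (4^3-4)/48 = 12.5 and
    Z = (7.5 - 12.5)/sqrt(12.5) = -sqrt(2).
    """
    r = uk.wilcoxon_signed_rank(np.array([1.0, 1.0, 1.0, -1.0, 2.0]))
    assert r.statistic == 12.5
    assert r.z == pytest.approx(-np.sqrt(2.0))
    assert r.tie_corrected


def test_kruskal_trivial_and_oracle(rng):
    assert uk.kruskal_wallis([1, 2, 3], [1, 2, 3]).statistic == 0.0
    # tie-corrected H equals the direct ranking formula on small samples
    for _ in range(5):
        gs = [rng.normal(size=3) for _ in range(3)]
        r = uk.kruskal_wallis(*gs)
        h_scipy, p_scipy = sps.kruskal(*gs)
        assert r.statistic == pytest.approx(h_scipy)
        assert r.p == pytest.approx(p_scipy)
        # permutation reference: H's null exceedance probability
        pooled = np.concatenate(gs)
        count = 0
        n_perm = 400
        prng = np.random.default_rng(0)
        for _ in range(n_perm):
            perm = prng.permutation(pooled)
            h_p, _ = sps.kruskal(perm[:3], perm[3:6], perm[6:])
            count += h_p >= r.statistic - 1e-9
        assert abs(count / n_perm - r.p) < 0.15  # chi2 approx vs permutation


def test_chi_square_and_warning():
    r = uk.chi_square([[10, 20], [20, 10]])
    # all expected cells are 15: chi2 = 4 * 25 / 15
    assert r.statistic == pytest.approx(20.0 / 3.0, abs=1e-9)
    assert r.warning is None
    r2 = uk.chi_square([[1, 0], [0, 1]])
    assert r2.warning is not None


def test_binomial_trivial():
    assert uk.binomial_test(5, 10).p == 1.0
    assert uk.binomial_test(10, 10).p == pytest.approx(2 * 0.5**10)


def test_spearman_and_levene_sanity(rng):
    x = np.arange(20.0)
    r = uk.spearman(x, x**3)
    assert r.statistic == pytest.approx(1.0)
    g1 = rng.normal(scale=1.0, size=50)
    g2 = rng.normal(scale=5.0, size=50)
    assert uk.levene(g1, g2).p < 0.01


def test_fdr_bh_ladder():
    """Hand-computed BH ladder: {.01,.02,.03,.04} -> all .04."""
    np.testing.assert_allclose(
        uk.fdr_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
    )
    np.testing.assert_allclose(uk.fdr_adjust([0.3]), [0.3])
    np.testing.assert_allclose(uk.fdr_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=12))
def test_fdr_never_decreases_and_preserves_ranking(ps):
    adj = uk.fdr_adjust(ps)
    assert np.all(adj >= np.asarray(ps) - 1e-12)
    assert np.all(adj <= 1.0 + 1e-12)
    order = np.argsort(ps)
    assert np.all(np.diff(adj[order]) >= -1e-12)


def test_lmm_noiseless_slope_recovery():
    """beta = 2 with zero noise and zero random variance recovers exactly."""
    x = np.tile(np.arange(6.0), 4)
    g = np.repeat(np.arange(4), 6)
    y = 2.0 * x + 1.0
    r = uk.lmm_step_effect(y, x, g)
    assert r.extras["slope"] == pytest.approx(2.0, abs=1e-8)


def test_lmm_single_trial_falls_back_to_ols(rng):
    x = rng.normal(size=12)
    y = 1.5 * x + rng.normal(scale=0.1, size=12)
    r = uk.lmm_step_effect(y, x, np.zeros(12))
    assert r.warning and "OLS" in r.warning
    assert r.extras["slope"] == pytest.approx(1.5, abs=0.2)


def test_lmm_detects_true_slope(rng):
    """With real random intercepts, the REML fit finds a strong fixed effect."""
    n_tr, per = 8, 6
    g = np.repeat(np.arange(n_tr), per)
    x = rng.normal(size=n_tr * per)
    y = 2.0 * x + np.repeat(rng.normal(scale=1.0, size=n_tr), per) + rng.normal(
        scale=0.5, size=n_tr * per
    )
    r = uk.lmm_step_effect(y, x, g)
    assert r.p < 1e-6
    assert r.extras["slope"] == pytest.approx(2.0, abs=0.3)
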