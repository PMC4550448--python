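"""Oracles and behavioral tests for outlier screening, block-PCA, SVM/DFA."""

import numpy as np
import pandas as pd
import pytest

import usvkit as uk
from usvkit.multivariate import (
    DEFAULT_BLOCKS,
    aggregate_by_individual_type,
    classify_dfa,
    classify_svm,
    fit_block_pca,
    manova_test,
    remove_outliers,
    wilks_lambda,
)
from usvkit.simulate import FEATURE_COLUMNS


def _toy_table(rng, n=40, p=3):
    cols = [f"v{i}" for i in range(p)]
    return pd.DataFrame(rng.normal(size=(n, p)), columns=cols), cols


# ---------------------------------------------------------------------------
# outlier screening

def test_remove_outliers_k0_is_identity(rng):
    t, cols = _toy_table(rng)
    out, removed = remove_outliers(t, cols, k=0)
    assert out.equals(t) and len(removed) == 0


def test_remove_outliers_catches_displaced_record(rng):
    t, cols = _toy_table(rng)
    t.loc[17, "v1"] += 10 * t["v1"].std()
    out, removed = remove_outliers(t, cols, k=1)
    assert list(removed) == [17]
    assert 17 not in out.index


def test_mahalanobis_matches_direct_matrix_oracle(rng):
    """Distances equal brute-force (x-mu)' S^-1 (x-mu) on standardized data."""
    t, cols = _toy_table(rng, n=10, p=3)
    x = t[cols].to_numpy()
    z = (x - x.mean(0)) / x.std(0, ddof=1)
    s_inv = np.linalg.inv(np.cov(z, rowvar=False, ddof=1))
    d2 = np.array([v @ s_inv @ v for v in z])
    # the k most distant by the oracle are exactly the records removed
    k = 3
    expect = set(t.index[np.argsort(-d2, kind="stable")[:k]])
    _, removed = remove_outliers(t, cols, k=k)
    assert set(removed) == expect


def test_remove_outliers_needs_enough_records(rng):
    t, cols = _toy_table(rng, n=10, p=3)
    with pytest.raises(ValueError, match="records"):
        remove_outliers(t, cols, k=9)


# ---------------------------------------------------------------------------
# block PCA

def _feature_frame(rng, n=80):
    data = {c: rng.normal(size=n) for c in FEATURE_COLUMNS}
    return pd.DataFrame(data)


def test_rank_one_frequency_block(rng):
    """12 perfectly correlated frequency variables: PC1 100%, PC2 0%."""
    t = _feature_frame(rng)
    base = rng.normal(size=len(t))
    for c in DEFAULT_BLOCKS["Freq"][0]:
        t[c] = base * rng.uniform(0.5, 2.0) + rng.uniform(-3, 3)
    model, _ = fit_block_pca(t)
    assert model.variance_fractions["Freq"][0] == pytest.approx(1.0, abs=1e-9)
    assert model.variance_fractions["Freq"][1] == pytest.approx(0.0, abs=1e-9)


def test_variance_fraction_matches_eigen_oracle(rng):
    """Block variance explained equals an independent SVD of standardized data."""
    t = _feature_frame(rng, n=120)
    model, _ = fit_block_pca(t)
    for name, (vars_, ncomp) in DEFAULT_BLOCKS.items():
        x = t[list(vars_)].to_numpy()
        z = (x - x.mean(0)) / x.std(0, ddof=1)
        sv = np.linalg.svd(z / np.sqrt(len(z) - 1), compute_uv=False)
        frac = sv**2 / np.sum(sv**2)
        np.testing.assert_allclose(
            model.variance_fractions[name], frac[:ncomp], atol=1e-9
        )


def test_scores_invariant_to_affine_rescaling(rng):
    """Correlation-matrix PCA ignores units of any input variable."""
    t = _feature_frame(rng)
    t2 = t.copy()
    t2["pAMPmax"] = t2["pAMPmax"] * 13.7 - 4.0
    t2["entstart"] = t2["entstart"] * 0.01 + 5.0
    _, red1 = fit_block_pca(t)
    _, red2 = fit_block_pca(t2)
    num = [c for c in red1.columns if c.startswith("PC")]
    np.testing.assert_allclose(red1[num].to_numpy(), red2[num].to_numpy(), atol=1e-9)


def test_constant_variable_is_named_in_error(rng):
    t = _feature_frame(rng)
    t["bandend"] = 3.0
    with pytest.raises(ValueError, match="bandend"):
        fit_block_pca(t)


def test_loading_orientation_positive(study_records):
    model, _ = fit_block_pca(study_records)
    for name, load in model.loadings.items():
        for col in load.columns:
            assert load[col].iloc[np.argmax(np.abs(load[col]))] > 0


# ---------------------------------------------------------------------------
# classifiers

def _two_group_frame(rng, sep, n=100, p=6):
    cols = ["PC1_Freq", "PC2_Freq", "PC_AMP", "PC_Band", "PC_ENT", "duration"]
    a = rng.normal(size=(n, p))
    b = rng.normal(size=(n, p)) + sep
    df = pd.DataFrame(np.vstack([a, b]), columns=cols)
    df["species"] = ["A"] * n + ["B"] * n
    return df


def test_svm_separable_limit(rng):
    """Two groups 10 SD apart: perfect test accuracy."""
    df = _two_group_frame(rng, sep=10.0, n=60)
    rep = classify_svm(df, "species", seed=0, grid=[0.1, 1.0])
    assert rep.overall_rate == 1.0


def test_svm_null_accuracy_near_half(rng):
    """Identical distributions: accuracy hovers at chance."""
    accs = [
        classify_svm(_two_group_frame(np.random.default_rng(s), 0.0, n=100),
                     "species", seed=s, grid=[2.0**-4, 1.0]).overall_rate
        for s in range(5)
    ]
    assert 0.3 < np.mean(accs) < 0.7


def test_dfa_identical_means_lambda_near_one(rng):
    df = _two_group_frame(rng, 0.0, n=80)
    rep = classify_dfa(df, "species")
    assert rep.wilks > 0.9
    assert rep.wilks_p > 0.01
    assert 0.3 < rep.overall_rate < 0.7


def test_dfa_separable_four_groups(rng):
    cols = ["PC1_Freq", "PC2_Freq", "PC_AMP", "PC_Band", "PC_ENT", "duration"]
    frames = []
    for i in range(4):
        x = rng.normal(size=(40, 6))
        x[:, i] += 8.0
        f = pd.DataFrame(x, columns=cols)
        f["population"] = f"G{i}"
        frames.append(f)
    df = pd.concat(frames, ignore_index=True)
    rep = classify_dfa(df, "population")
    assert rep.overall_rate > 0.9
    assert rep.wilks < 0.05


def test_wilks_matches_generalized_eigen_oracle(rng):
    """Lambda = prod 1/(1+theta) over eigenvalues of W^-1 B, three groups."""
    x = rng.normal(size=(60, 4))
    y = np.repeat(["a", "b", "c"], 20)
    x[y == "b"] += 0.8
    x[y == "c", 0] -= 1.0
    lam, f, dfs, p = wilks_lambda(x, y)
    # independent oracle via scipy generalized eigenproblem
    import scipy.linalg

    grand = x.mean(0)
    w = np.zeros((4, 4))
    b = np.zeros((4, 4))
    for c in np.unique(y):
        xc = x[y == c]
        d = xc - xc.mean(0)
        w += d.T @ d
        m = (xc.mean(0) - grand)[:, None]
        b += len(xc) * m @ m.T
    theta = scipy.linalg.eigh(b, w, eigvals_only=True)
    lam_oracle = np.prod(1.0 / (1.0 + np.maximum(theta, 0)))
    assert lam == pytest.approx(lam_oracle, rel=1e-9)


def test_wilks_matches_statsmodels_manova(rng):
    """Cross-check Wilks lambda and its F against statsmodels MANOVA."""
    from statsmodels.multivariate.manova import MANOVA

    x = rng.normal(size=(45, 3))
    y = np.repeat(["a", "b", "c"], 15)
    x[y == "c"] += 0.7
    lam, f, (df1, df2), p = wilks_lambda(x, y)
    df = pd.DataFrame(x, columns=["v1", "v2", "v3"])
    df["g"] = y
    res = MANOVA.from_formula("v1 + v2 + v3 ~ g", data=df).mv_test()
    row = res.results["g"]["stat"].loc["Wilks' lambda"]
    assert lam == pytest.approx(float(row["Value"]), rel=1e-6)
    assert f == pytest.approx(float(row["F Value"]), rel=1e-6)
    assert p == pytest.approx(float(row["Pr > F"]), rel=1e-6, abs=1e-12)


def test_manova_single_variable_reduces_to_anova_f(rng):
    from scipy import stats as sps

    cols = ["PC1_Freq", "PC2_Freq", "PC_AMP", "PC_Band", "PC_ENT", "duration"]
    df = _two_group_frame(rng, 0.5, n=30)
    df = pd.concat([df, _two_group_frame(rng, 1.0, n=30).assign(species="C")])
    lam, f, dfs, p = manova_test(df, "species", features=["PC_AMP"])
    groups = [g["PC_AMP"].to_numpy() for _, g in df.groupby("species")]
    f_anova, p_anova = sps.f_oneway(*groups)
    assert f == pytest.approx(f_anova, rel=1e-9)
    assert p == pytest.approx(p_anova, rel=1e-9)


def test_manova_single_group_rejected(rng):
    df = _two_group_frame(rng, 0.0, n=20)
    df["species"] = "A"
    with pytest.raises(ValueError, match="2 groups"):
        manova_test(df, "species")


def test_svm_dfa_expose_identical_marginals(study_records):
    rec, _ = remove_outliers(study_records, list(FEATURE_COLUMNS), k=12)
    _, red = fit_block_pca(rec)
    svm = classify_svm(red, "species", seed=3, grid=[2.0**-4, 1.0])
    dfa = classify_dfa(red, "species")
    assert svm.n_per_class == dfa.n_per_class
    # DFA confusion rows sum to the class counts
    for cls, n in dfa.n_per_class.items():
        assert dfa.confusion.loc[cls].sum() == n


def test_dfa_loo_is_deterministic(study_records):
    rec, _ = remove_outliers(study_records, list(FEATURE_COLUMNS), k=12)
    _, red = fit_block_pca(rec)
    a = classify_dfa(red, "species").overall_rate
    b = classify_dfa(red, "species").overall_rate
    assert a == b


def test_separation_monotonicity(rng):
    """Mean DFA LOO accuracy never decreases with group separation."""
    seps = [0.0, 1.0, 3.0]
    means = []
    for sep in seps:
        accs = [
            classify_dfa(
                _two_group_frame(np.random.default_rng(100 + r), sep, n=40),
                "species",
            ).overall_rate
            for r in range(10)
        ]
        means.append(np.mean(accs))
    assert means[0] <= means[1] + 0.02 <= means[2] + 0.04


def test_aggregation_uses_first_hundred_window(study_records):
    # records carry per-window syllable counts; none may exceed the cap
    assert study_records["n_syllables"].max() <= 100
    assert (study_records["n_syllables"] >= 1).all()
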