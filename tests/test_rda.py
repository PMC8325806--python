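"""RDA: oracle equivalence, permutation ANOVA, outliers, regional reruns."""

import numpy as np
import pandas as pd
import pytest

from adaptscan import rda
from adaptscan.rda import (
    RdaModel,
    anova_axes,
    anova_global,
    assign_predictor,
    detect_outliers,
    fit_rda,
    prescreen_predictors,
    regional_rda,
)


def naive_rda_oracle(Y, X):
    """Explicit hat-matrix fit + full PCA of fitted values."""
    Y = np.asarray(Y, float)
    X = np.asarray(X, float)
    n = Y.shape[0]
    Yc = Y - Y.mean(0)
    Xc = X - X.mean(0)
    H = Xc @ np.linalg.pinv(Xc.T @ Xc) @ Xc.T
    Yhat = H @ Yc
    C = Yhat.T @ Yhat / (n - 1)
    w, V = np.linalg.eigh((C + C.T) / 2)
    w, V = w[::-1], V[:, ::-1]
    q = np.linalg.matrix_rank(Xc)
    total = np.sum(Yc * Yc) / (n - 1)
    constrained = np.sum(Yhat * Yhat) / (n - 1)
    r2 = constrained / total
    adj = 1 - (1 - r2) * (n - 1) / (n - q - 1)
    loadings = V * np.sqrt(np.maximum(w, 0) * (n - 1))
    return w, r2, adj, loadings, q


def test_fit_rda_matches_naive_oracle():
    rng = np.random.default_rng(0)
    for _ in range(5):
        Y = rng.normal(size=(30, 50))
        X = rng.normal(size=(30, 4))
        m = fit_rda(Y, X)
        w, r2, adj, loadings, q = naive_rda_oracle(Y, X)
        np.testing.assert_allclose(m.eigenvalues, w[: len(m.eigenvalues)], atol=1e-8)
        assert m.r2 == pytest.approx(r2, abs=1e-10)
        assert m.adj_r2 == pytest.approx(adj, abs=1e-10)
        assert m.q == q
        for a in range(len(m.eigenvalues)):
            got, ref = m.loadings[:, a], loadings[:, a]
            assert min(np.abs(got - ref).max(), np.abs(got + ref).max()) < 1e-8


def test_fit_rda_fraction_identities():
    rng = np.random.default_rng(1)
    Y = rng.normal(size=(25, 40))
    X = rng.normal(size=(25, 3))
    m = fit_rda(Y, X)
    assert m.axis_fractions.sum() == pytest.approx(1.0, abs=1e-10)
    assert m.constrained_inertia + m.residual_inertia == pytest.approx(
        m.total_inertia, abs=1e-10)
    assert np.all(np.diff(m.eigenvalues) <= 1e-12)


def test_fit_rda_errors_and_warnings():
    rng = np.random.default_rng(2)
    Y = rng.normal(size=(10, 5))
    Y[0, 0] = np.nan
    with pytest.raises(ValueError, match="missing"):
        fit_rda(Y, rng.normal(size=(10, 2)))
    Y2 = rng.normal(size=(10, 5))
    X = rng.normal(size=(10, 2))
    Xdup = np.column_stack([X, X[:, 0]])
    with pytest.warns(UserWarning, match="rank-deficient"):
        m = fit_rda(Y2, Xdup)
    assert m.q == 2


def test_anova_global_signal_vs_null():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(40, 2))
    Y = X @ rng.normal(size=(2, 30)) + 0.3 * rng.normal(size=(40, 30))
    m = fit_rda(Y, X)
    f, p = anova_global(m, Y, X, n_perm=199, seed=1)
    assert p <= 0.01
    Ynull = rng.normal(size=(40, 30))
    m0 = fit_rda(Ynull, X)
    _, p0 = anova_global(m0, Ynull, X, n_perm=199, seed=1)
    assert p0 > 0.05


def test_axis1_p_equals_global_p_single_predictor():
    rng = np.random.default_rng(4)
    X = rng.normal(size=(30, 1))
    Y = X @ rng.normal(size=(1, 20)) + rng.normal(size=(30, 20))
    m = fit_rda(Y, X)
    _, p_global = anova_global(m, Y, X, n_perm=99, seed=7)
    p_axes = anova_axes(m, Y, X, n_perm=99, seed=7)
    assert p_axes[0] == pytest.approx(p_global, abs=1e-12)


def test_anova_axes_sequential_stop():
    rng = np.random.default_rng(5)
    X = rng.normal(size=(40, 3))
    # signal only along one combination of predictors -> later axes null
    Y = np.outer(X[:, 0], rng.normal(size=25)) + 0.5 * rng.normal(size=(40, 25))
    m = fit_rda(Y, X)
    p = anova_axes(m, Y, X, n_perm=99, seed=0)
    assert p[0] <= 0.05
    done = np.flatnonzero(~np.isnan(p))
    # after the first p > alpha, testing stopped (trailing NaNs)
    if len(done) < len(p):
        assert p[done[-1]] > 0.05


def test_detect_outliers_exact_constructed():
    L = 500
    rng = np.random.default_rng(6)
    load = rng.normal(size=L) * 0.1
    load[[7, 99]] = 5.0  # way past 3 SD
    model = RdaModel(
        predictors=["x"], coefficients=np.zeros((1, L)), fitted=np.zeros((4, L)),
        eigenvalues=np.array([1.0]), axis_fractions=np.array([1.0]),
        total_fractions=np.array([0.5]), loadings=load[:, None],
        site_scores=np.zeros((4, 1)), r2=0.5, adj_r2=0.4, n=4, q=1,
        total_inertia=2.0, constrained_inertia=1.0, residual_inertia=1.0,
    )
    out = detect_outliers(model, n_axes=1, sd_mult=3.0,
                          locus_ids=[f"l{j}" for j in range(L)])
    assert out.locus_ids() == {"l7", "l99"}
    assert (out.table["axis"] == 1).all()


def test_assign_predictor_best_correlate():
    rng = np.random.default_rng(7)
    n = 50
    x1 = rng.normal(size=n)
    x2 = rng.normal(size=n)
    d = np.clip(np.round(1.0 + x2), 0, 2)
    dosage = np.column_stack([d, rng.binomial(2, 0.5, size=n).astype(float)])
    X = pd.DataFrame({"x1": x1, "x2": x2})
    table = pd.DataFrame([{"locus_id": "a", "axis": 1, "loading": 9.0,
                           "predictor": None, "r": np.nan, "scope": "global"}])
    out = assign_predictor(rda.OutlierSet(table), dosage, X, ["a", "b"])
    assert out.table.iloc[0]["predictor"] == "x2"
    assert out.table.iloc[0]["r"] > 0.5


def test_prescreen_drops_lower_priority():
    rng = np.random.default_rng(8)
    a = rng.normal(size=40)
    X = pd.DataFrame({"keep": a, "drop": a + 0.01 * rng.normal(size=40),
                      "other": rng.normal(size=40)})
    kept, log = prescreen_predictors(X, r_max=0.7, priority=["keep"])
    assert "keep" in kept.columns and "drop" not in kept.columns
    assert log[0][0] == "drop" and log[0][1] == "keep"
    with pytest.raises(ValueError):
        prescreen_predictors(X[["keep"]])


def test_regional_rda_detects_within_cluster_cline():
    rng = np.random.default_rng(9)
    n_per = 30
    labels = np.array([0] * n_per + [1] * n_per)
    v = rng.normal(size=2 * n_per)
    from scipy.special import expit

    L = 200
    dosage = rng.binomial(2, 0.5, size=(2 * n_per, L)).astype(float)
    # loci 0-4: opposite-sign clines in the two clusters (cancel globally)
    sign = np.where(labels == 0, 1.0, -1.0)
    for j in range(5):
        dosage[:, j] = rng.binomial(2, expit(3.0 * sign * v)).astype(float)
    loci = pd.DataFrame({"contig": "c", "pos": np.arange(L) * 1000 + 1,
                         "ref": "A", "alt": "G",
                         "locus_id": [f"l{j}" for j in range(L)]})
    samples = pd.DataFrame({"sample": [str(i) for i in range(2 * n_per)],
                            "provenance": "P"})
    from adaptscan.geno import GenotypeMatrix

    G = GenotypeMatrix(dosage, loci, samples)
    X = pd.DataFrame({"v": v, "w": rng.normal(size=2 * n_per)})
    model, out = regional_rda(G, labels, 0, X, n_perm=199, seed=1, n_axes=1)
    assert not isinstance(out, str), out
    planted = {f"l{j}" for j in range(5)}
    assert out.locus_ids() & planted
    # globally the clines cancel: no planted locus among global outliers
    gm = fit_rda(dosage, X.to_numpy())
    gout = detect_outliers(gm, n_axes=1, locus_ids=loci["locus_id"])
    assert not (gout.locus_ids() & planted)


def test_regional_rda_small_cluster_reason():
    rng = np.random.default_rng(10)
    from adaptscan.geno import GenotypeMatrix

    dosage = rng.binomial(2, 0.5, size=(10, 20)).astype(float)
    loci = pd.DataFrame({"contig": "c", "pos": np.arange(20) + 1, "ref": "A",
                         "alt": "G", "locus_id": [f"l{j}" for j in range(20)]})
    samples = pd.DataFrame({"sample": [str(i) for i in range(10)], "provenance": "P"})
    G = GenotypeMatrix(dosage, loci, samples)
    labels = np.array([0] * 2 + [1] * 8)
    X = pd.DataFrame({"a": rng.normal(size=10), "b": rng.normal(size=10)})
    model, reason = regional_rda(G, labels, 0, X, n_perm=49, seed=0)
    assert model is None and "too small" in reason
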