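"""Redundancy analysis from first principles: multivariate OLS of the
(centered) dosage matrix on predictors, PCA of the fitted values,
permutation ANOVA, +/-3 SD loading outliers, Pearson predictor assignment,
and within-cluster regional reruns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class RdaModel:
    predictors: list[str]
    coefficients: np.ndarray        # q x L
    fitted: np.ndarray              # n x L
    eigenvalues: np.ndarray         # constrained, descending
    axis_fractions: np.ndarray      # of constrained inertia
    total_fractions: np.ndarray     # of total Y inertia
    loadings: np.ndarray            # L x n_axes (V * S)
    site_scores: np.ndarray         # n x n_axes (U)
    r2: float
    adj_r2: float
    n: int
    q: int
    total_inertia: float
    constrained_inertia: float
    residual_inertia: float
    global_f: float | None = None
    global_p: float | None = None
    axis_p: np.ndarray | None = None


@dataclass
class OutlierSet:
    table: pd.DataFrame  # locus_id, axis, loading, predictor, r, scope

    def locus_ids(self) -> set:
        return set(self.table["locus_id"])


def _center(M):
    M = np.asarray(M, dtype=float)
    return M - M.mean(axis=0)


def prescreen_predictors(
    X: pd.DataFrame, r_max: float = 0.7, priority: list[str] | None = None
) -> tuple[pd.DataFrame, list[tuple[str, str, float]]]:
    """Greedy collinearity prescreen.

    While any predictor pair has |r| > ``r_max``, the worst pair is found
    and its lower-priority member dropped.  ``priority`` lists names in
    keep-first order; unnamed predictors rank after named ones in column
    order.  Returns the retained table and a log of (dropped, kept, r).
    """
    if X.shape[1] < 2:
        raise ValueError("need at least 2 candidate predictors")
    priority = priority or []

    def rank(name):
        if name in priority:
            return priority.index(name)
        return len(priority) + list(X.columns).index(name)

    keep = list(X.columns)
    log: list[tuple[str, str, float]] = []
    while len(keep) > 1:
        corr = X[keep].corr().abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.argmax(corr), corr.shape)
        if corr[i, j] <= r_max:
            break
        a, b = keep[i], keep[j]
        drop = a if rank(a) > rank(b) else b
        kept = b if drop == a else a
        log.append((drop, kept, float(X[a].corr(X[b]))))
        keep.remove(drop)
    if len(keep) == 0:
        raise ValueError("all predictors mutually collinear")
    return X[keep], log


def fit_rda(Y, X, predictor_names: list[str] | None = None, center: bool = True) -> RdaModel:
    """Two-step RDA: OLS fit of Y on X, then SVD/PCA of the fitted values.

    Y must be complete (impute first).  Eigenvalue_a = s_a^2 / (n-1);
    R^2 = constrained / total inertia; adjusted R^2 uses Ezekiel's formula
    with q = rank of X.  Locus loadings are right singular vectors scaled by
    singular values; site scores are the left singular vectors.
    """
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    if np.isnan(Y).any():
        raise ValueError("Y contains missing values; impute first")
    n = Y.shape[0]
    Yc = _center(Y) if center else Y
    Xc = _center(X) if center else X
    rank = np.linalg.matrix_rank(Xc)
    if rank < Xc.shape[1]:
        warnings.warn("rank-deficient predictor matrix; using pseudo-inverse")
    q = int(rank)
    if n <= q + 1:
        raise ValueError("need n > q + 1 rows")
    B, *_ = np.linalg.lstsq(Xc, Yc, rcond=None)
    Yhat = Xc @ B
    U, S, Vt = np.linalg.svd(Yhat, full_matrices=False)
    n_axes = min(q, *Yhat.shape)
    U, S, Vt = U[:, :n_axes], S[:n_axes], Vt[:n_axes]
    eig = S**2 / (n - 1)
    total = float(np.sum(Yc * Yc)) / (n - 1)
    constrained = float(np.sum(eig))
    residual = total - constrained
    r2 = constrained / total if total > 0 else 0.0
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - q - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        axis_fr = eig / constrained if constrained > 0 else np.zeros_like(eig)
    names = predictor_names or [f"x{j + 1}" for j in range(X.shape[1])]
    return RdaModel(
        predictors=list(names),
        coefficients=B,
        fitted=Yhat,
        eigenvalues=eig,
        axis_fractions=axis_fr,
        total_fractions=eig / total if total > 0 else np.zeros_like(eig),
        loadings=(Vt.T * S),
        site_scores=U,
        r2=float(r2),
        adj_r2=float(adj_r2),
        n=n,
        q=q,
        total_inertia=total,
        constrained_inertia=constrained,
        residual_inertia=residual,
    )


def _constrained_inertia(Yc, Xc):
    """Constrained inertia via an orthonormal basis of X (fast, no SVD of
    the fitted matrix)."""
    Qx, _ = np.linalg.qr(Xc)
    proj = Qx.T @ Yc
    return float(np.sum(proj * proj)) / (Yc.shape[0] - 1)


def _pseudo_f(constrained, residual, q, n):
    if residual <= 0:
        return np.inf
    return (constrained / q) / (residual / (n - q - 1))


def anova_global(model: RdaModel, Y, X, n_perm: int = 1000, seed: int = 0) -> tuple[float, float]:
    """Global permutation test: pseudo-F with rows of X permuted.

    p = (#{F_perm >= F_obs} + 1) / (n_perm + 1).
    """
    rng = np.random.default_rng(seed)
    Yc = _center(Y)
    Xc = _center(X)
    n, q = model.n, model.q
    f_obs = _pseudo_f(model.constrained_inertia, model.residual_inertia, q, n)
    total = model.total_inertia
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        c = _constrained_inertia(Yc, Xc[perm])
        f = _pseudo_f(c, total - c, q, n)
        if f >= f_obs:
            count += 1
    p = (count + 1) / (n_perm + 1)
    model.global_f = float(f_obs)
    model.global_p = float(p)
    return float(f_obs), float(p)


def _residualize(M, Z):
    if Z is None or Z.shape[1] == 0:
        return M
    B, *_ = np.linalg.lstsq(Z, M, rcond=None)
    return M - Z @ B


def anova_axes(
    model: RdaModel,
    Y,
    X,
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    max_axes: int | None = None,
) -> np.ndarray:
    """Sequential (forward) per-axis permutation test.

    Axis a is tested by the first eigenvalue's pseudo-F after partialling
    the prior axes' site scores out of both Y and X (residualized
    permutation).  Testing stops at the first non-significant axis.
    """
    Yc = _center(Y)
    Xc = _center(X)
    n, q = model.n, model.q

    def _axis_stat(Yr, Xm, total_r):
        # first eigenvalue of the fitted-value PCA via the q x q Gram matrix
        Qx, _ = np.linalg.qr(Xm)
        A = Qx.T @ Yr
        ev = np.linalg.eigvalsh(A @ A.T) / (n - 1)
        lam1 = float(ev[-1])
        constrained = float(ev.sum())
        denom = (total_r - constrained) / (n - q - 1)
        return lam1 / denom if denom > 0 else np.inf

    n_axes = len(model.eigenvalues) if max_axes is None else min(max_axes, len(model.eigenvalues))
    pvals = np.full(n_axes, np.nan)
    # one sequential stream: with a single predictor the axis-1 permutations
    # (and hence p) coincide exactly with the global test at the same seed
    rng = np.random.default_rng(seed)
    for a in range(n_axes):
        Z = model.site_scores[:, :a] if a > 0 else None
        Yr = _residualize(Yc, Z)
        Xr = _residualize(Xc, Z)
        total_r = float(np.sum(Yr * Yr)) / (n - 1)
        f_obs = _axis_stat(Yr, Xr, total_r)
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            if _axis_stat(Yr, Xr[perm], total_r) >= f_obs:
                count += 1
        pvals[a] = (count + 1) / (n_perm + 1)
        if pvals[a] > alpha:
            break
    model.axis_p = pvals
    return pvals


def detect_outliers(
    model: RdaModel, n_axes: int = 2, sd_mult: float = 3.0, locus_ids=None,
    scope: str = "global",
) -> OutlierSet:
    """Loci whose loading on any of the first ``n_axes`` constrained axes
    lies more than ``sd_mult`` SD from that axis's mean loading."""
    n_axes = min(n_axes, model.loadings.shape[1])
    L = model.loadings.shape[0]
    ids = pd.Index(locus_ids) if locus_ids is not None else pd.RangeIndex(L)
    rows = []
    seen = set()
    for a in range(n_axes):
        load = model.loadings[:, a]
        mu, sd = load.mean(), load.std()
        if sd == 0:
            continue
        flagged = np.flatnonzero(np.abs(load - mu) > sd_mult * sd)
        for j in flagged:
            if ids[j] in seen:
                continue
            seen.add(ids[j])
            rows.append(
                {
                    "locus_id": ids[j],
                    "axis": a + 1,
                    "loading": float(load[j]),
                    "predictor": None,
                    "r": np.nan,
                    "scope": scope,
                }
            )
    cols = ["locus_id", "axis", "loading", "predictor", "r", "scope"]
    return OutlierSet(pd.DataFrame(rows, columns=cols))


def assign_predictor(
    outliers: OutlierSet, dosage: np.ndarray, X: pd.DataFrame, locus_ids
) -> OutlierSet:
    """Attach to each outlier the constraining variable with the strongest
    |Pearson r| against its dosage (ties break by predictor order)."""
    ids = pd.Index(locus_ids)
    Xm = np.asarray(X, dtype=float)
    Xc = Xm - Xm.mean(axis=0)
    Xs = Xc / Xc.std(axis=0)
    table = outliers.table.copy()
    for i, row in table.iterrows():
        j = ids.get_loc(row["locus_id"])
        d = dosage[:, j]
        ok = ~np.isnan(d)
        dd = d[ok] - d[ok].mean()
        sd = dd.std()
        if sd == 0:
            continue
        rs = (dd / sd) @ Xs[ok] / ok.sum()
        best = int(np.argmax(np.abs(rs)))
        table.at[i, "predictor"] = X.columns[best]
        table.at[i, "r"] = float(rs[best])
    return OutlierSet(table)


def regional_rda(
    G,
    cluster_labels: np.ndarray,
    target_cluster: int,
    X: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
    sd_mult: float = 3.0,
    n_axes: int = 2,
    r_max: float = 0.7,
    priority: list[str] | None = None,
):
    """Re-run prescreen -> RDA -> ANOVA -> outlier detection within one
    genetic cluster.

    Returns (model, outliers) or (None, reason) when the cluster is too
    small or its global test is not significant.
    """
    from .geno import impute_major, allele_frequency

    members = np.flatnonzero(np.asarray(cluster_labels) == target_cluster)
    Xsub = X.iloc[members]
    try:
        X_kept, _ = prescreen_predictors(Xsub, r_max=r_max, priority=priority)
    except ValueError as exc:
        return None, f"prescreen failed: {exc}"
    if len(members) < X_kept.shape[1] + 2:
        return None, f"cluster {target_cluster} too small ({len(members)} members)"
    Gsub = G.subset_individuals(members)
    p = allele_frequency(Gsub)
    poly = np.isfinite(p) & (p > 0) & (p < 1)
    Gsub = Gsub.subset_loci(poly)
    Gc = impute_major(Gsub)
    model = fit_rda(Gc.dosage, X_kept.to_numpy(), predictor_names=list(X_kept.columns))
    anova_global(model, Gc.dosage, X_kept.to_numpy(), n_perm=n_perm, seed=seed)
    if model.global_p > 0.05:
        return model, f"regional RDA not significant (p={model.global_p:.3f})"
    outliers = detect_outliers(
        model, n_axes=n_axes, sd_mult=sd_mult,
        locus_ids=Gc.locus_ids(), scope=f"cluster{target_cluster}",
    )
    outliers = assign_predictor(outliers, Gc.dosage, X_kept, Gc.locus_ids())
    return model, outliers
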