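"""Environmental PCA, Pearson and canonical correlations, and derived
phenotype variables for provenance-level tables.

The 19 bioclimatic predictors mix units (degrees C, mm), so the PCA is run on
the correlation matrix (standardized columns) and loadings are reported as
correlations between variables and component scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


class DegenerateVariableError(ValueError):
    """A column has zero variance where variation is required."""


@dataclass
class EnvPhenoTables:
    """Aligned provenance-level environment, geography and phenotype tables.

    ``pheno`` carries spring phenology score S, autumn phenology score A,
    height and survival; the growing-season proxy L = S - A is appended on
    construction.
    """

    env: pd.DataFrame
    geo: pd.DataFrame
    pheno: pd.DataFrame

    def __post_init__(self) -> None:
        idx = self.env.index
        if not (idx.equals(self.geo.index) and idx.equals(self.pheno.index)):
            raise ValueError("env/geo/pheno tables must share the same provenances")
        for name, tab in (("env", self.env), ("geo", self.geo), ("pheno", self.pheno)):
            if tab.isna().any().any():
                raise ValueError(f"{name} table contains missing values")
        if "L" not in self.pheno.columns:
            self.pheno = self.pheno.copy()
            self.pheno["L"] = derive_growing_season(self.pheno)

    @property
    def provenances(self) -> pd.Index:
        return self.env.index


@dataclass
class PcaResult:
    loadings: pd.DataFrame        # variable x component, as correlations
    explained: np.ndarray         # fraction of variance per component
    scores: pd.DataFrame          # site x component
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray      # orthonormal columns


@dataclass
class CanCorResult:
    correlations: np.ndarray      # descending, in [0, 1]
    x_weights: np.ndarray
    y_weights: np.ndarray
    wilks_lambda: float
    p_value: float                # Rao's F approximation, first pair


def env_pca(env: pd.DataFrame) -> PcaResult:
    """PCA of standardized environmental variables.

    Eigendecomposition of the correlation matrix via SVD of the standardized
    data.  Scores are standardized data times eigenvectors; loadings are
    correlations between variables and scores (eigenvector * sqrt(eigenvalue)).
    Each component is sign-flipped so its largest-magnitude loading is
    positive.
    """
    X = np.asarray(env, dtype=float)
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least 2 rows for PCA")
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = env.columns[np.flatnonzero(sd == 0)].tolist()
        raise DegenerateVariableError(f"constant column(s): {bad}")
    Z = (X - X.mean(axis=0)) / sd
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    eig = S**2 / (n - 1)
    V = Vt.T
    # sign convention: largest |loading| positive per component
    for a in range(V.shape[1]):
        j = np.argmax(np.abs(V[:, a]))
        if V[j, a] < 0:
            V[:, a] = -V[:, a]
    scores = Z @ V
    loadings = V * np.sqrt(eig)
    comp_names = [f"PC{a + 1}" for a in range(V.shape[1])]
    return PcaResult(
        loadings=pd.DataFrame(loadings, index=env.columns, columns=comp_names),
        explained=eig / eig.sum(),
        scores=pd.DataFrame(scores, index=env.index, columns=comp_names),
        eigenvalues=eig,
        eigenvectors=V,
    )


def pearson(a, b) -> tuple[float, float]:
    """Pearson r with a two-sided p from the t distribution on n-2 df."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need equal-length vectors, n >= 3")
    if a.std() == 0 or b.std() == 0:
        raise DegenerateVariableError("zero-variance input to correlation")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)


def canonical_correlation(X, Y) -> CanCorResult:
    """Canonical correlations between two variable groups.

    Computed via orthonormal (QR) bases of the centered sides and the SVD of
    their cross-product; rank-deficient sides are reduced with a warning.
    Significance of the first pair uses Wilks' lambda with Rao's F
    approximation.
    """
    import warnings as _warnings

    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y need the same number of rows")
    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)

    def _basis(M):
        Q, R, piv = _pivoted_qr(M)
        tol = max(M.shape) * np.finfo(float).eps * (abs(R[0, 0]) if R.size else 0)
        rank = int(np.sum(np.abs(np.diag(R)) > tol)) if R.size else 0
        return Q[:, :rank], rank

    Qx, px = _basis(Xc)
    Qy, py = _basis(Yc)
    if px < Xc.shape[1] or py < Yc.shape[1]:
        _warnings.warn("rank-deficient side reduced in canonical correlation")
    if px == 0 or py == 0:
        raise DegenerateVariableError("a side has no variance")
    U, S, Vt = np.linalg.svd(Qx.T @ Qy)
    m = min(px, py)
    corrs = np.clip(S[:m], 0.0, 1.0)
    lam = float(np.prod(1.0 - corrs**2))
    p_value = _wilks_rao_p(lam, n, px, py)
    return CanCorResult(
        correlations=corrs,
        x_weights=U[:, :m],
        y_weights=Vt.T[:, :m],
        wilks_lambda=lam,
        p_value=p_value,
    )


def _pivoted_qr(M):
    from scipy.linalg import qr

    if M.shape[1] == 0:
        return np.empty((M.shape[0], 0)), np.empty((0, 0)), np.array([], dtype=int)
    Q, R, piv = qr(M, mode="economic", pivoting=True)
    return Q, R, piv


def _wilks_rao_p(lam: float, n: int, p: int, q: int) -> float:
    """Rao's F approximation for Wilks' lambda (all canonical pairs)."""
    if lam <= 0:
        return 0.0
    if lam >= 1:
        return 1.0
    pq = p * q
    t = np.sqrt((p**2 * q**2 - 4) / (p**2 + q**2 - 5)) if (p**2 + q**2 - 5) > 0 else 1.0
    w = n - (p + q + 3) / 2.0
    df1 = pq
    df2 = w * t - pq / 2.0 + 1.0
    if df2 <= 0:
        return float("nan")
    lam_t = lam ** (1.0 / t)
    F = (1.0 - lam_t) / lam_t * df2 / df1
    return float(stats.f.sf(F, df1, df2))


def derive_growing_season(pheno: pd.DataFrame) -> pd.Series:
    """Growing-season proxy L = S - A (spring minus autumn phenology score)."""
    for col in ("spring", "autumn"):
        if col not in pheno.columns:
            raise ValueError(f"phenotype table lacks {col!r} column")
    return pheno["spring"] - pheno["autumn"]


def expand_to_individuals(values: pd.Series, provenance_of: pd.Series) -> np.ndarray:
    """Broadcast a provenance-level variable to individuals by lookup."""
    missing = set(provenance_of) - set(values.index)
    if missing:
        raise KeyError(f"provenances without values: {sorted(missing)[:5]}")
    return values.loc[provenance_of].to_numpy(dtype=float)


def predictor_table(tables: EnvPhenoTables, pca: PcaResult, n_pcs: int = 3) -> pd.DataFrame:
    """Provenance-level predictor table: geography, climate PCs, phenotypes."""
    parts = [
        tables.geo,
        pca.scores.iloc[:, :n_pcs],
        tables.pheno[["spring", "autumn", "height", "survival"]],
    ]
    return pd.concat(parts, axis=1)
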