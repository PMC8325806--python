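"""Latent-factor association scan with genomic-inflation calibration and
Benjamini-Hochberg FDR control.

Population structure is absorbed by K latent factors (leading left singular
vectors of the column-centered dosage matrix).  Each locus is then regressed
on [1, variable, factors] by ordinary least squares; the variable's z-score
is calibrated by the genomic inflation factor lambda = median(z^2) /
median(chi^2_1) and converted to a p-value, which is BH-adjusted across
loci.  This is the deterministic least-squares formulation of the
latent-factor mixed model: same estimands (per-locus z, lambda calibration,
FDR lists), no sampler.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ScanResult:
    """Per-locus association results for one explanatory variable."""

    variable: str
    locus_id: pd.Index
    beta: np.ndarray
    z: np.ndarray
    p_raw: np.ndarray
    p_calibrated: np.ndarray
    q: np.ndarray
    inflation: float
    candidate: np.ndarray = field(default=None)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "locus_id": self.locus_id,
                "variable": self.variable,
                "beta": self.beta,
                "z": self.z,
                "p_raw": self.p_raw,
                "p_calibrated": self.p_calibrated,
                "q": self.q,
                "candidate": self.candidate,
            }
        )


def fit_latent_factors(G_complete: np.ndarray, K: int) -> np.ndarray:
    """First K left singular vectors (scaled by singular values) of the
    column-centered dosage matrix; K = 0 gives an empty factor set."""
    G = np.asarray(G_complete, dtype=float)
    if np.isnan(G).any():
        raise ValueError("latent factors require a complete matrix; impute first")
    if K == 0:
        return np.empty((G.shape[0], 0))
    if K >= min(G.shape):
        raise ValueError("K must be smaller than both matrix dimensions")
    Gc = G - G.mean(axis=0)
    U, S, _ = np.linalg.svd(Gc, full_matrices=False)
    return U[:, :K] * S[:K]


def association_scan(
    G_complete: np.ndarray, v: np.ndarray, U: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """OLS of each locus dosage on [1, v, U]; returns (beta_v, z_v).

    z = beta / SE with residual df = n - K - 2.  A variable collinear with
    the factors yields a warning and missing z for all loci.
    """
    import warnings

    G = np.asarray(G_complete, dtype=float)
    v = np.asarray(v, dtype=float)
    n, L = G.shape
    X = np.column_stack([np.ones(n), v, U])
    k = X.shape[1]
    XtX = X.T @ X
    try:
        XtX_inv = np.linalg.inv(XtX)
    except np.linalg.LinAlgError:
        warnings.warn("variable collinear with latent factors; z set missing")
        return np.full(L, np.nan), np.full(L, np.nan)
    # guard near-singular designs
    if np.linalg.cond(XtX) > 1e12:
        warnings.warn("variable nearly collinear with latent factors; z set missing")
        return np.full(L, np.nan), np.full(L, np.nan)
    B = XtX_inv @ (X.T @ G)                      # k x L
    resid = G - X @ B
    df = n - k
    if df <= 0:
        raise ValueError("not enough residual degrees of freedom")
    sigma2 = np.sum(resid**2, axis=0) / df
    se = np.sqrt(np.maximum(XtX_inv[1, 1] * sigma2, 0.0))
    beta = B[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, 0.0)
    return beta, z


def genomic_inflation(z: np.ndarray) -> tuple[float, np.ndarray]:
    """Inflation factor lambda = median(z^2) / median(chi^2_1), and
    calibrated p-values from the upper chi^2_1 tail of z^2 / lambda."""
    z = np.asarray(z, dtype=float)
    z2 = z[np.isfinite(z)] ** 2
    if z2.size == 0:
        raise ValueError("no finite z-scores")
    chi2_median = stats.chi2.ppf(0.5, df=1)
    lam = float(np.median(z2) / chi2_median)
    if not (0.5 <= lam <= 2.0):
        import warnings

        warnings.warn(f"genomic inflation lambda = {lam:.3f} outside [0.5, 2]")
    p = stats.chi2.sf(np.asarray(z) ** 2 / lam, df=1)
    return lam, p


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone)."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def scan_variable(
    G_complete: np.ndarray,
    v: np.ndarray,
    U: np.ndarray,
    variable: str,
    locus_ids,
    fdr: float = 0.01,
    p_cut: float = 0.001,
) -> ScanResult:
    """Full scan for one variable: OLS z-scores, lambda calibration, BH
    adjustment and the conjunctive candidate rule (q <= fdr and q < p_cut)."""
    beta, z = association_scan(G_complete, v, U)
    lam, p_cal = genomic_inflation(z)
    p_raw = 2.0 * stats.norm.sf(np.abs(z))
    q = bh_adjust(np.nan_to_num(p_cal, nan=1.0))
    candidate = (q <= fdr) & (p_cal < p_cut)
    return ScanResult(
        variable=variable,
        locus_id=pd.Index(locus_ids),
        beta=beta,
        z=z,
        p_raw=p_raw,
        p_calibrated=p_cal,
        q=q,
        inflation=lam,
        candidate=candidate,
    )


def candidate_list(results: list[ScanResult]) -> pd.DataFrame:
    """Per-variable candidate records plus the deduplicated union.

    Returns a long DataFrame (one row per locus x variable membership);
    the union is its unique ``locus_id`` set.
    """
    frames = []
    for res in results:
        f = res.to_frame()
        frames.append(f[f["candidate"].astype(bool)])
    if not frames:
        return pd.DataFrame(
            columns=["locus_id", "variable", "beta", "z", "p_raw",
                     "p_calibrated", "q", "candidate"]
        )
    return pd.concat(frames, ignore_index=True)
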