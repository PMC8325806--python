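"""Additive polygenic scores over candidate loci, linear/quadratic trend
fits compared by AIC, and heterozygosity-variable regression.

For each focal variable, the "favored" allele at every candidate locus is
the one whose dosage correlates positively with the variable; an
individual's score is the count of favored alleles over the candidate set
(0..2L).  Scores are then regressed on each variable with a linear and a
quadratic model and compared by least-squares AIC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class TrendFit:
    form: str                 # "linear" | "quadratic"
    coef: np.ndarray
    stat: float               # r for linear, R^2 for quadratic
    p: float
    aic: float
    best: bool = False


def polarize_alleles(dosage: np.ndarray, v: np.ndarray, locus_ids) -> pd.Series:
    """Favored allele per locus for variable v: ALT if r(dosage, v) > 0,
    otherwise REF (ties to REF, logged).  Monomorphic loci are excluded."""
    ids = pd.Index(locus_ids)
    v = np.asarray(v, dtype=float)
    out = {}
    for j, lid in enumerate(ids):
        d = dosage[:, j]
        ok = ~np.isnan(d)
        if ok.sum() < 3 or np.nanstd(d[ok]) == 0:
            warnings.warn(f"monomorphic/undersampled candidate locus {lid} excluded")
            continue
        r = np.corrcoef(d[ok], v[ok])[0, 1]
        if r == 0:
            warnings.warn(f"zero correlation at {lid}; favored allele set to REF")
        out[lid] = "ALT" if r > 0 else "REF"
    return pd.Series(out, name="favored")


def polygenic_scores(
    dosage: np.ndarray, favored: pd.Series, locus_ids
) -> np.ndarray:
    """Per-individual favored-allele count over the polarized loci.

    Missing genotypes contribute the locus mean favored dosage, keeping the
    score comparable across individuals with different call rates.
    """
    ids = pd.Index(locus_ids)
    scores = np.zeros(dosage.shape[0])
    for lid, allele in favored.items():
        j = ids.get_loc(lid)
        d = dosage[:, j].copy()
        fav = d if allele == "ALT" else 2.0 - d
        mean_fav = np.nanmean(fav)
        fav = np.where(np.isnan(fav), mean_fav, fav)
        scores += fav
    return scores


def _ls_aic(rss: float, n: int, k: int) -> float:
    # least-squares AIC without additive constants (they cancel in
    # within-variable comparisons)
    return n * np.log(rss / n) + 2 * k


def score_models(scores: np.ndarray, v: np.ndarray) -> tuple[TrendFit, TrendFit]:
    """Linear and quadratic fits of score on a variable, compared by AIC.

    Linear reports Pearson r and its two-sided p; quadratic reports R^2 and
    the model F-test p.  The lower-AIC fit is flagged best.
    """
    scores = np.asarray(scores, dtype=float)
    v = np.asarray(v, dtype=float)
    n = scores.size
    if n < 4:
        raise ValueError("need at least 4 observations")
    if v.std() == 0:
        raise ValueError("zero-variance explanatory variable")

    def _ols(X):
        beta, *_ = np.linalg.lstsq(X, scores, rcond=None)
        resid = scores - X @ beta
        return beta, float(np.sum(resid**2))

    tss = float(np.sum((scores - scores.mean()) ** 2))

    X1 = np.column_stack([np.ones(n), v])
    b1, rss1 = _ols(X1)
    r, p_lin = stats.pearsonr(v, scores) if scores.std() > 0 else (0.0, 1.0)
    lin = TrendFit("linear", b1, float(r), float(p_lin), _ls_aic(rss1, n, 2))

    X2 = np.column_stack([np.ones(n), v, v**2])
    b2, rss2 = _ols(X2)
    r2 = 1.0 - rss2 / tss if tss > 0 else 0.0
    df1, df2 = 2, n - 3
    if rss2 > 0 and df2 > 0:
        F = (tss - rss2) / df1 / (rss2 / df2)
        p_quad = float(stats.f.sf(F, df1, df2))
    else:
        p_quad = 0.0
    quad = TrendFit("quadratic", b2, float(r2), p_quad, _ls_aic(rss2, n, 3))

    if lin.aic <= quad.aic:
        lin.best = True
    else:
        quad.best = True
    return lin, quad


def trend_table(
    scores_by_var: dict[str, np.ndarray], variables: pd.DataFrame
) -> pd.DataFrame:
    """Per-variable linear/quadratic summary (one row per variable)."""
    rows = []
    for name in variables.columns:
        lin, quad = score_models(scores_by_var[name], variables[name].to_numpy())
        rows.append(
            {
                "variable": name,
                "linear_r": lin.stat,
                "linear_p": lin.p,
                "linear_aic": lin.aic,
                "quadratic_r2": quad.stat,
                "quadratic_p": quad.p,
                "quadratic_aic": quad.aic,
                "best": "linear" if lin.best else "quadratic",
            }
        )
    return pd.DataFrame(rows)


def het_env_regression(
    het: np.ndarray, variables: pd.DataFrame, alpha: float = 0.05
):
    """Backward-eliminated linear model of individual heterozygosity.

    Starting from the full model, the largest-p coefficient is dropped until
    every remaining coefficient has p < alpha.  Returns the fitted
    statsmodels result (intercept-only when nothing survives, flagged by a
    warning).
    """
    import statsmodels.api as sm

    if variables.shape[1] < 2:
        raise ValueError("need at least 2 candidate variables")
    y = np.asarray(het, dtype=float)
    cols = list(variables.columns)
    while cols:
        X = sm.add_constant(variables[cols].to_numpy())
        fit = sm.OLS(y, X).fit()
        pvals = fit.pvalues[1:]
        worst = int(np.argmax(pvals))
        if pvals[worst] < alpha:
            return fit, cols
        cols.pop(worst)
    warnings.warn("no variable survived elimination; intercept-only model")
    fit = sm.OLS(y, np.ones((y.size, 1))).fit()
    return fit, []
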