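"""Individual ancestry estimation by masked nonnegative matrix factorization.

The dosage matrix G (entries 0/1/2, missing allowed) is modelled as
G ~ 2 Q F with Q the individuals x K ancestry fractions (rows on the
simplex) and F the K x loci cluster allele frequencies (entries in [0, 1]) —
the same estimands as sparse-NMF ancestry methods.  Fitting minimizes the
squared reconstruction error over observed (non-held-out) entries by
alternating projected-gradient steps with backtracking, which makes the
training loss monotonically non-increasing.  A randomly held-out 5% of the
observed entries yields a binomial cross-entropy used for replicate
selection and for choosing the number of clusters K.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class AncestryModel:
    K: int
    Q: np.ndarray                 # n_ind x K, rows sum to 1
    F: np.ndarray                 # K x n_loci, entries in [0, 1]
    cross_entropy: float          # held-out masked prediction loss
    train_loss: np.ndarray        # per outer iteration
    converged: bool
    seed: int


def _simplex_project(rows: np.ndarray) -> np.ndarray:
    """Euclidean projection of each row onto the probability simplex."""
    n, k = rows.shape
    u = np.sort(rows, axis=1)[:, ::-1]
    css = np.cumsum(u, axis=1) - 1.0
    ind = np.arange(1, k + 1)
    cond = u - css / ind > 0
    rho = k - np.argmax(cond[:, ::-1], axis=1) - 1  # last True index
    theta = css[np.arange(n), rho] / (rho + 1)
    return np.maximum(rows - theta[:, None], 0.0)


def _masked_loss(G, W, Q, F):
    R = np.where(W, G - 2.0 * (Q @ F), 0.0)
    return float(np.sum(R * R))


def _cross_entropy(G, mask, Q, F, eps=1e-6):
    if not mask.any():
        return float("nan")
    p = np.clip(Q @ F, eps, 1.0 - eps)
    g = G[mask] / 2.0
    ph = p[mask]
    return float(-np.mean(g * np.log(ph) + (1.0 - g) * np.log(1.0 - ph)))


def _dosage_of(G):
    return G.dosage if hasattr(G, "dosage") else np.asarray(G, dtype=float)


def _fit_once(G, W, K, rng, max_iter, tol):
    n, L = G.shape
    Q = rng.dirichlet(np.ones(K), size=n)
    F = rng.uniform(0.1, 0.9, size=(K, L))
    loss = [_masked_loss(G, W, Q, F)]
    tQ = tF = 1e-3
    converged = False
    for _ in range(max_iter):
        # F block: projected gradient with backtracking
        R = np.where(W, G - 2.0 * (Q @ F), 0.0)
        gradF = -4.0 * (Q.T @ R)
        cur = loss[-1]
        for _bt in range(40):
            F_new = np.clip(F - tF * gradF, 0.0, 1.0)
            l_new = _masked_loss(G, W, Q, F_new)
            if l_new <= cur:
                F = F_new
                cur = l_new
                tF *= 1.5
                break
            tF *= 0.5
        # Q block
        R = np.where(W, G - 2.0 * (Q @ F), 0.0)
        gradQ = -4.0 * (R @ F.T)
        for _bt in range(40):
            Q_new = _simplex_project(Q - tQ * gradQ)
            l_new = _masked_loss(G, W, Q_new, F)
            if l_new <= cur:
                Q = Q_new
                cur = l_new
                tQ *= 1.5
                break
            tQ *= 0.5
        loss.append(cur)
        if loss[-2] - loss[-1] <= tol * max(loss[-2], 1.0):
            converged = True
            break
    return Q, F, np.array(loss), converged


def fit_ancestry(
    G,
    K: int,
    seed: int = 0,
    n_reps: int = 10,
    holdout_frac: float = 0.05,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> AncestryModel:
    """Fit Q and F at a given K; best of ``n_reps`` restarts by held-out
    cross-entropy (training loss when ``holdout_frac`` is 0).

    K=1 has the closed form Q = 1, F = locus mean dosage / 2.
    """
    Gm = _dosage_of(G)
    n, L = Gm.shape
    if K < 1:
        raise ValueError("K must be >= 1")
    if K >= min(n, L):
        raise ValueError("K too large for matrix dimensions")
    observed = ~np.isnan(Gm)
    G0 = np.where(observed, Gm, 0.0)
    best = None
    for rep in range(n_reps):
        rng = np.random.default_rng((seed, rep))
        hold = observed & (rng.random(Gm.shape) < holdout_frac)
        W = observed & ~hold
        if K == 1:
            denom = np.maximum(W.sum(axis=0), 1)
            F = (np.where(W, G0, 0.0).sum(axis=0) / denom / 2.0)[None, :]
            Q = np.ones((n, 1))
            loss = np.array([_masked_loss(G0, W, Q, F)])
            converged = True
        else:
            Q, F, loss, converged = _fit_once(G0, W, K, rng, max_iter, tol)
        ce = _cross_entropy(G0, hold, Q, F)
        score = ce if np.isfinite(ce) else loss[-1]
        if best is None or score < best[0]:
            best = (score, AncestryModel(K, Q, F, ce, loss, converged, seed))
    return best[1]


def select_k(
    G,
    k_range=range(1, 11),
    seed: int = 0,
    n_reps: int = 3,
    one_se: bool = True,
    **fit_kwargs,
) -> tuple[int, pd.DataFrame]:
    """Choose K by replicated held-out cross-entropy.

    Returns the selected K and the profile (one row per K with mean/sd CE).
    With ``one_se`` the smallest K whose mean CE is within one standard
    error of the minimum is preferred, so flat profiles resolve to K = 1.
    """
    ks = list(k_range)
    if not ks:
        raise ValueError("empty K range")
    rows = []
    for k in ks:
        ces = [
            fit_ancestry(G, k, seed=(seed * 9973 + k * 101 + r) % (2**31), n_reps=1, **fit_kwargs).cross_entropy
            for r in range(n_reps)
        ]
        rows.append({"K": k, "mean_ce": float(np.mean(ces)), "sd_ce": float(np.std(ces, ddof=1)) if n_reps > 1 else 0.0, "n_reps": n_reps})
    profile = pd.DataFrame(rows)
    i_min = int(profile["mean_ce"].idxmin())
    if one_se:
        thr = profile.loc[i_min, "mean_ce"] + profile.loc[i_min, "sd_ce"] / np.sqrt(n_reps)
        k_star = int(profile.loc[profile["mean_ce"] <= thr, "K"].min())
    else:
        k_star = int(profile.loc[i_min, "K"])
    return k_star, profile


def delta_k(replicate_scores: pd.DataFrame) -> pd.Series:
    """Second-difference criterion on replicate log-scores per K.

    ``replicate_scores``: rows indexed by K (consecutive), columns are
    replicates.  Delta-K(k) = |mean L(k+1) - 2 mean L(k) + mean L(k-1)| /
    sd(L(k)); undefined (NaN) at range endpoints; zero sd gives +inf.
    """
    scores = replicate_scores.sort_index()
    ks = scores.index.to_numpy()
    if len(ks) < 3 or scores.shape[1] < 2:
        raise ValueError("need >= 3 consecutive K values and >= 2 replicates")
    if not np.all(np.diff(ks) == 1):
        raise ValueError("K values must be consecutive")
    m = scores.mean(axis=1).to_numpy()
    s = scores.std(axis=1, ddof=1).to_numpy()
    out = np.full(len(ks), np.nan)
    for i in range(1, len(ks) - 1):
        num = abs(m[i + 1] - 2 * m[i] + m[i - 1])
        out[i] = np.inf if s[i] == 0 else num / s[i]
    return pd.Series(out, index=scores.index, name="delta_k")


def assign_clusters(Q: np.ndarray, threshold: float = 0.70) -> np.ndarray:
    """Hard cluster labels: argmax cluster when max q >= threshold, else -1
    ("admixed")."""
    Q = np.asarray(Q, dtype=float)
    labels = np.argmax(Q, axis=1)
    labels = np.where(Q.max(axis=1) >= threshold, labels, -1)
    return labels


def impute_ancestry(G, model: AncestryModel):
    """Fill missing dosages with round(2 * q_i . f_l), clipped to {0,1,2}."""
    import copy

    pred = np.clip(np.rint(2.0 * (model.Q @ model.F)), 0, 2)
    if hasattr(G, "dosage"):
        out = G.copy()
        miss = np.isnan(out.dosage)
        out.dosage[miss] = pred[miss]
        return out
    Gm = np.array(G, dtype=float)
    miss = np.isnan(Gm)
    Gm[miss] = pred[miss]
    return Gm


def align_clusters(Q_est: np.ndarray, Q_ref: np.ndarray) -> np.ndarray:
    """Permute columns of Q_est to best match Q_ref (Hungarian assignment
    on column-wise L1 distance); resolves label switching in comparisons."""
    from scipy.optimize import linear_sum_assignment

    K = Q_ref.shape[1]
    cost = np.zeros((K, K))
    for a in range(K):
        for b in range(K):
            cost[a, b] = np.abs(Q_est[:, a] - Q_ref[:, b]).mean()
    row, col = linear_sum_assignment(cost)
    perm = np.empty(K, dtype=int)
    perm[col] = row
    return Q_est[:, perm]
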