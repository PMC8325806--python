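"""Variance partitioning of candidate-locus genotypes by partial RDA.

Four models decompose the constrained variance of the candidate dosage
matrix: Model 1 is the simple RDA on all three predictor blocks (geography,
climate, phenotype); Models 2-4 condition each block on the other two,
isolating its unique contribution.  The joint fraction is Model 1's inertia
minus the sum of unique inertias; percentages are reported relative to
Model 1, so the four fractions account for exactly 100% of the explainable
variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .rda import RdaModel, fit_rda, _center, _constrained_inertia, _pseudo_f


@dataclass
class PartitionResult:
    table: pd.DataFrame           # model, inertia, percentage, p
    total_y_inertia: float

    def joint_fraction(self) -> float:
        return float(
            self.table.loc[self.table["model"].str.startswith("joint"), "percentage"].iloc[0]
        )


def partial_rda(
    Y, X, Z, n_perm: int = 999, seed: int = 0, predictor_names=None
) -> RdaModel:
    """RDA of Y on X after residualizing both on the conditioning matrix Z.

    The permutation test permutes rows of the residualized X.  An empty Z
    reduces to plain RDA.
    """
    Y = _center(Y)
    X = _center(X)
    if Z is None:
        Z = np.empty((Y.shape[0], 0))
    Z = _center(np.asarray(Z, dtype=float))
    if Z.shape[1]:
        Bz, *_ = np.linalg.lstsq(Z, Y, rcond=None)
        Yr = Y - Z @ Bz
        Bx, *_ = np.linalg.lstsq(Z, X, rcond=None)
        Xr = X - Z @ Bx
        # columns absorbed by Z leave only rounding residue; zero them so the
        # pseudo-inverse cannot blow the residue back up into a projection
        negligible = (
            np.linalg.norm(Xr, axis=0)
            <= 1e-10 * np.maximum(np.linalg.norm(X, axis=0), 1.0)
        )
        Xr = Xr.copy()
        Xr[:, negligible] = 0.0
        if negligible.all():
            import warnings

            warnings.warn(
                "conditioning set spans the predictors; zero unique inertia"
            )
    else:
        Yr, Xr = Y, X
    model = fit_rda(Yr, Xr, predictor_names=predictor_names, center=False)
    # permutation p on the residualized problem
    n, q = model.n, max(model.q, 1)
    total = model.total_inertia
    f_obs = _pseudo_f(model.constrained_inertia, model.residual_inertia, q, n)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        c = _constrained_inertia(Yr, Xr[perm])
        if _pseudo_f(c, total - c, q, n) >= f_obs:
            count += 1
    model.global_f = float(f_obs)
    model.global_p = float((count + 1) / (n_perm + 1))
    return model


def variance_partition(
    Y_candidates,
    geo: pd.DataFrame,
    climate: pd.DataFrame,
    pheno: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
) -> PartitionResult:
    """Four-model decomposition of candidate-locus genetic variance.

    Model 1: Y ~ geo + climate + pheno (simple RDA); Models 2-4: each block
    conditioned on the other two.  Percentages are relative to Model 1's
    constrained inertia; the joint fraction is the remainder, so the
    accounting identity (sum = 100%) holds by construction and is audited.
    """
    Y = np.asarray(Y_candidates, dtype=float)
    if Y.shape[1] == 0:
        raise ValueError("empty candidate set; run outlier detection first")
    blocks = {"spatial": geo, "climate": climate, "phenotype": pheno}
    full_X = pd.concat(blocks.values(), axis=1)
    m1 = fit_rda(Y, full_X.to_numpy(), predictor_names=list(full_X.columns))
    from .rda import anova_global

    anova_global(m1, Y, full_X.to_numpy(), n_perm=n_perm, seed=seed)
    rows = [
        {
            "model": "full (spatial + climate + phenotype)",
            "inertia": m1.constrained_inertia,
            "percentage": 100.0,
            "p": m1.global_p,
        }
    ]
    unique_sum = 0.0
    for i, (name, block) in enumerate(blocks.items()):
        others = pd.concat([b for k, b in blocks.items() if k != name], axis=1)
        pm = partial_rda(
            Y, block.to_numpy(), others.to_numpy(),
            n_perm=n_perm, seed=seed + 1 + i,
            predictor_names=list(block.columns),
        )
        unique_sum += pm.constrained_inertia
        rows.append(
            {
                "model": f"{name} | others",
                "inertia": pm.constrained_inertia,
                "percentage": 100.0 * pm.constrained_inertia / m1.constrained_inertia,
                "p": pm.global_p,
            }
        )
    joint = m1.constrained_inertia - unique_sum
    rows.append(
        {
            "model": "joint (spatial & climate & phenotype)",
            "inertia": joint,
            "percentage": 100.0 * joint / m1.constrained_inertia,
            "p": np.nan,
        }
    )
    table = pd.DataFrame(rows)
    parts = table["percentage"].iloc[1:].sum()
    if not np.isclose(parts, 100.0, atol=1e-8):
        raise AssertionError(f"partition accounting violated: {parts}")
    if joint < -1e-8:
        import warnings

        warnings.warn(f"negative joint fraction ({joint:.3g}); reported as-is")
    return PartitionResult(table=table, total_y_inertia=m1.total_inertia)
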