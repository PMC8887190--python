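"""Per-CpG differential methylation testing with and without CTH adjustment.

Three modes, all ordinary least squares on beta values with two-sided
t-tests, vectorised over CpGs:

* ``test_unadjusted`` — beta ~ exposure;
* ``test_adjusted`` — beta ~ exposure + cell fractions (one cell type
  dropped to break the sum-to-one collinearity);
* ``test_celltype_specific`` — the interaction model
  beta ~ sum_k w_k + sum_k (w_k * exposure) without a global intercept,
  whose interaction coefficient for cell type k estimates the case/control
  methylation difference occurring inside that cell type.

Multiple testing is controlled per result table with Benjamini–Hochberg
q-values.  CpGs with zero variance are retained (p = 1, flagged) so the
CpG universe is stable across modes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .deconvolve import CellFractionEstimate

__all__ = [
    "DMCSetPartition",
    "test_unadjusted",
    "test_adjusted",
    "test_celltype_specific",
    "bh_adjust",
    "classify_dmc_sets",
    "significant_cpgs",
]

DEFAULT_ALPHA = 0.05

RESULT_COLUMNS = ["effect", "se", "t", "p", "q", "significant",
                  "degenerate", "mode"]


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values with enforced monotonicity.

    NaN p-values propagate to NaN q-values and are excluded from the
    ranking (the effective number of tests is the number of finite p's).
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvals must be one-dimensional")
    finite = ~np.isnan(p)
    if ((p[finite] < 0) | (p[finite] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    m = int(finite.sum())
    if m == 0:
        return q
    ps = p[finite]
    order = np.argsort(ps, kind="mergesort")
    ranked = ps[order] * m / np.arange(1, m + 1)
    qs = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(qs, 1.0)
    q[finite] = out
    return q


def _ols_table(Y: np.ndarray, X: np.ndarray, coef_idx: int,
               index: pd.Index, mode: str, alpha: float) -> pd.DataFrame:
    """Vectorised OLS of every row of Y on the shared design X."""
    n, k = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < k:
        raise ValueError("design matrix is rank deficient")
    dof = n - k
    if dof < 1:
        raise ValueError("not enough samples for the design")
    pinv = np.linalg.pinv(X)
    xtx_inv_jj = float((pinv @ pinv.T)[coef_idx, coef_idx])
    coef = Y @ pinv.T                       # G x k
    resid = Y - coef @ X.T
    s2 = np.einsum("ij,ij->i", resid, resid) / dof
    effect = coef[:, coef_idx]
    se = np.sqrt(np.maximum(s2, 0.0) * xtx_inv_jj)

    degenerate = Y.var(axis=1) <= 1e-24
    with np.errstate(divide="ignore", invalid="ignore"):
        t = effect / se
    p = 2.0 * scipy.stats.t.sf(np.abs(t), dof)
    # perfect fits: se == 0 but a real effect -> p = 0; flat CpGs -> p = 1
    perfect = (se == 0) & (np.abs(effect) > 1e-12)
    p[perfect] = 0.0
    t[perfect] = np.inf * np.sign(effect[perfect])
    flat = degenerate | ((se == 0) & ~perfect)
    p[flat] = 1.0
    t[flat] = 0.0
    effect = np.where(degenerate, 0.0, effect)

    q = bh_adjust(p)
    table = pd.DataFrame({
        "effect": effect, "se": se, "t": t, "p": p, "q": q,
        "significant": q <= alpha, "degenerate": degenerate,
        "mode": mode,
    }, index=index)
    table.index.name = "cpg_id"
    return table


def _check_groups(pheno: pd.DataFrame) -> np.ndarray:
    e = pheno["exposure"].to_numpy()
    if set(np.unique(e)) - {0, 1}:
        raise ValueError("exposure must be binary 0/1")
    if (e == 1).sum() < 2 or (e == 0).sum() < 2:
        raise ValueError("need at least two samples per exposure group")
    return e.astype(float)


def test_unadjusted(bulk: pd.DataFrame, pheno: pd.DataFrame,
                    alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Per-CpG two-group comparison: beta ~ intercept + exposure.

    Equivalent to a pooled-variance two-sample t-test per CpG.
    """
    pheno = pheno.loc[bulk.columns]
    e = _check_groups(pheno)
    X = np.column_stack([np.ones_like(e), e])
    return _ols_table(bulk.to_numpy(), X, 1, bulk.index, "unadjusted", alpha)


def _fraction_frame(fractions) -> pd.DataFrame:
    if isinstance(fractions, CellFractionEstimate):
        return fractions.fractions
    return fractions


def test_adjusted(bulk: pd.DataFrame, pheno: pd.DataFrame, fractions,
                  alpha: float = DEFAULT_ALPHA,
                  drop_cell_type: Optional[str] = None) -> pd.DataFrame:
    """Per-CpG exposure test adjusted for cell-type composition.

    Fits beta ~ intercept + exposure + fractions of K-1 cell types; the
    dropped cell type (by default the one with the largest mean fraction)
    breaks the collinearity induced by fractions summing to ~1.  The
    exposure p-value is invariant to which cell type is dropped.
    """
    W = _fraction_frame(fractions).loc[bulk.columns]
    pheno = pheno.loc[bulk.columns]
    e = _check_groups(pheno)
    if drop_cell_type is None:
        drop_cell_type = W.mean().idxmax()
    if drop_cell_type not in W.columns:
        raise ValueError(f"unknown cell type {drop_cell_type!r}")
    Wd = W.drop(columns=drop_cell_type)
    # constant fraction columns are absorbed by the intercept; dropping
    # them keeps the design full rank without changing the fit
    Wd = Wd.loc[:, Wd.var() > 1e-24]
    X = np.column_stack([np.ones_like(e), e, Wd.to_numpy()])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            "rank-deficient design: collinear columns among "
            f"['intercept', 'exposure'] + {list(Wd.columns)}"
        )
    return _ols_table(bulk.to_numpy(), X, 1, bulk.index, "adjusted", alpha)


def test_celltype_specific(bulk: pd.DataFrame, pheno: pd.DataFrame, fractions,
                           alpha: float = DEFAULT_ALPHA
                           ) -> Dict[str, pd.DataFrame]:
    """Interaction-model cell-type-specific differential methylation.

    Fits, per CpG, beta ~ sum_k w_k + sum_k (w_k * exposure) without a
    global intercept.  The coefficient of ``w_k * exposure`` estimates the
    within-cell-type case/control beta difference for cell type k; BH
    correction is applied separately per cell type.  Returns one result
    table per cell type.
    """
    W = _fraction_frame(fractions).loc[bulk.columns]
    pheno = pheno.loc[bulk.columns]
    e = _check_groups(pheno)
    k = W.shape[1]
    for ct in W.columns:
        if W[ct].var() < 1e-8:
            import warnings
            warnings.warn(
                f"fraction variance for {ct!r} is near zero; its "
                "interaction term is weakly identified", stacklevel=2,
            )
    X = np.column_stack([W.to_numpy(), W.to_numpy() * e[:, None]])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient interaction design")
    Y = bulk.to_numpy()
    results = {}
    for j, ct in enumerate(W.columns):
        results[ct] = _ols_table(Y, X, k + j, bulk.index,
                                 f"celltype:{ct}", alpha)
    return results


def significant_cpgs(table: pd.DataFrame,
                     alpha: Optional[float] = None) -> FrozenSet[str]:
    q = table["q"]
    if alpha is None:
        return frozenset(table.index[table["significant"]])
    return frozenset(table.index[q.notna() & (q <= alpha)])


@dataclass(frozen=True)
class DMCSetPartition:
    """The three-class partition of DMC calls across the two analyses.

    ``unadjusted_only`` holds CpGs driven entirely by composition shifts,
    ``adjusted_only`` those revealed only after CTH adjustment, and
    ``both`` CpGs significant in either analysis mode.
    """

    unadjusted_only: FrozenSet[str]
    adjusted_only: FrozenSet[str]
    both: FrozenSet[str]

    def __post_init__(self):
        if (self.unadjusted_only & self.adjusted_only
                or self.unadjusted_only & self.both
                or self.adjusted_only & self.both):
            raise ValueError("partition sets must be disjoint")

    @property
    def union(self) -> FrozenSet[str]:
        return self.unadjusted_only | self.adjusted_only | self.both


def classify_dmc_sets(unadj: pd.DataFrame, adj: pd.DataFrame,
                      alpha: float = DEFAULT_ALPHA) -> DMCSetPartition:
    """Partition significant CpGs into unadjusted-only / adjusted-only / both."""
    if not unadj.index.sort_values().equals(adj.index.sort_values()):
        raise ValueError("result tables cover different CpG universes")
    s_un = significant_cpgs(unadj, alpha)
    s_ad = significant_cpgs(adj, alpha)
    return DMCSetPartition(
        unadjusted_only=s_un - s_ad,
        adjusted_only=s_ad - s_un,
        both=s_un & s_ad,
    )
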