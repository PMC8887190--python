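"""Variance decomposition and unsupervised clustering of methylomes.

Reproduces the standard diagnostic views of a bulk methylation study:
principal-component variance fractions (fVAR) with per-PC factor
annotation, selection of the PCs most correlated with a binary exposure,
hierarchical clustering over those PCs, and residualisation of the beta
matrix on cell fractions ("CTH adjustment") for the adjusted arm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy
import scipy.stats
from sklearn.metrics import adjusted_rand_score

from .deconvolve import CellFractionEstimate
from .dmc import _fraction_frame

__all__ = [
    "PCSummary",
    "SelectedPCs",
    "ClusteringResult",
    "run_pca",
    "associate_pcs_factors",
    "select_exposure_pcs",
    "cluster_over_pcs",
    "adjust_betas_for_cth",
]


@dataclass
class PCSummary:
    """Top principal components of a beta matrix.

    ``scores`` is samples x PCs (columns PC1, PC2, ... ordered by
    decreasing variance); ``fvar`` is each PC's variance as a fraction of
    the total variance of the retained PCs, summing to 1.
    """

    scores: pd.DataFrame
    fvar: pd.Series

    def __post_init__(self):
        if not np.all(np.diff(self.fvar.to_numpy()) <= 1e-12):
            raise ValueError("PCs must be ordered by decreasing variance")

    @property
    def n_pcs(self) -> int:
        return self.scores.shape[1]


@dataclass
class SelectedPCs:
    """PCs ranked by absolute correlation with the exposure."""

    pc_names: List[str]
    correlations: pd.Series
    pvalues: pd.Series
    #: True when even the best-correlated PC is only marginally associated
    #: with the exposure (min p > 0.05) — clustering over these PCs is not
    #: expected to segregate samples by exposure.
    marginal: bool = False


@dataclass
class ClusteringResult:
    """Hierarchical clustering over selected PC scores."""

    labels: pd.Series
    linkage_method: str
    k: int
    ari: Optional[float] = None
    fisher_p: Optional[float] = None


def run_pca(bulk: pd.DataFrame, n_pcs: int = 15) -> PCSummary:
    """Centered PCA of samples; fVAR over the top ``n_pcs`` components.

    CpGs are mean-centered but not variance-scaled, preserving the
    beta-scale effect-size structure.  If fewer than ``n_pcs + 1`` samples
    are available the retained PCs are truncated with a warning.
    """
    n_samples = bulk.shape[1]
    max_pcs = n_samples - 1
    if n_pcs > max_pcs:
        warnings.warn(
            f"only {n_samples} samples: retaining {max_pcs} PCs instead of "
            f"{n_pcs}", stacklevel=2,
        )
        n_pcs = max_pcs
    X = bulk.to_numpy().T                      # samples x CpGs
    X = X - X.mean(axis=0, keepdims=True)
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    scores = U[:, :n_pcs] * s[:n_pcs]
    var = s[:n_pcs] ** 2
    total = var.sum()
    fvar = var / total if total > 0 else np.zeros_like(var)
    names = [f"PC{i}" for i in range(1, n_pcs + 1)]
    return PCSummary(
        scores=pd.DataFrame(scores, index=bulk.columns, columns=names),
        fvar=pd.Series(fvar, index=names, name="fVAR"),
    )


def _factor_pvalue(scores: np.ndarray, values: pd.Series) -> float:
    """Association p-value between one PC and one factor.

    Numeric factors use the linear-model F-test (equivalent to the Pearson
    correlation test); categorical factors use one-way ANOVA of the PC
    scores across factor levels.
    """
    if pd.api.types.is_numeric_dtype(values):
        x = values.to_numpy(dtype=float)
        if np.var(x) == 0:
            warnings.warn("constant factor: association p set to 1",
                          stacklevel=3)
            return 1.0
        _, p = scipy.stats.pearsonr(x, scores)
        return float(p)
    groups = [scores[values.to_numpy() == lev] for lev in values.unique()]
    groups = [g for g in groups if len(g) > 0]
    if len(groups) < 2:
        warnings.warn("constant factor: association p set to 1", stacklevel=3)
        return 1.0
    _, p = scipy.stats.f_oneway(*groups)
    return float(p)


def associate_pcs_factors(pcs: PCSummary,
                          factors: pd.DataFrame) -> pd.DataFrame:
    """Associate every retained PC with every factor column.

    Returns a PCs x factors table of p-values plus a ``top_factor`` column
    naming the minimum-p factor for each PC (the factor "driving" that PC).
    """
    factors = factors.loc[pcs.scores.index]
    out = pd.DataFrame(index=pcs.scores.columns, columns=factors.columns,
                       dtype=float)
    for pc in pcs.scores.columns:
        s = pcs.scores[pc].to_numpy()
        for f in factors.columns:
            out.loc[pc, f] = _factor_pvalue(s, factors[f])
    out["top_factor"] = out.idxmin(axis=1)
    return out


def select_exposure_pcs(pcs: PCSummary, exposure: pd.Series,
                        n_select: int = 2) -> SelectedPCs:
    """Rank PCs by absolute point-biserial correlation with the exposure."""
    if n_select > pcs.n_pcs:
        raise ValueError(
            f"n_select={n_select} exceeds the {pcs.n_pcs} retained PCs"
        )
    e = exposure.loc[pcs.scores.index].to_numpy(dtype=float)
    rs, ps = {}, {}
    for pc in pcs.scores.columns:
        r, p = scipy.stats.pointbiserialr(e, pcs.scores[pc].to_numpy())
        rs[pc], ps[pc] = float(r), float(p)
    corr = pd.Series(rs, name="r")
    pval = pd.Series(ps, name="p")
    order = corr.abs().sort_values(ascending=False, kind="mergesort").index
    chosen = list(order[:n_select])
    marginal = bool(pval.loc[chosen].min() > 0.05)
    if marginal:
        warnings.warn(
            "selected PCs show only marginal association with the exposure "
            f"(min p = {pval.loc[chosen].min():.3g})", stacklevel=2,
        )
    return SelectedPCs(chosen, corr.loc[chosen], pval.loc[chosen], marginal)


def cluster_over_pcs(pcs: PCSummary, selected, k: int = 2,
                     exposure: Optional[pd.Series] = None,
                     linkage_method: str = "average") -> ClusteringResult:
    """Agglomerative clustering of samples over selected PC scores.

    Euclidean distance with the given linkage, tree cut at ``k`` clusters.
    When an exposure is supplied the adjusted Rand index and (for k = 2
    and binary exposure) a 2x2 Fisher exact p-value are reported.
    """
    if isinstance(selected, SelectedPCs):
        selected = selected.pc_names
    if not selected:
        raise ValueError("no PCs selected for clustering")
    X = pcs.scores[list(selected)].to_numpy()
    n = X.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} samples")
    if k == n:
        labels = np.arange(1, n + 1)
    else:
        Z = scipy.cluster.hierarchy.linkage(X, method=linkage_method,
                                            metric="euclidean")
        labels = scipy.cluster.hierarchy.fcluster(Z, t=k, criterion="maxclust")
    labels = pd.Series(labels, index=pcs.scores.index, name="cluster")

    ari = fisher_p = None
    if exposure is not None:
        e = exposure.loc[labels.index].to_numpy()
        ari = float(adjusted_rand_score(e, labels.to_numpy()))
        if k == 2 and len(np.unique(e)) == 2:
            tab = pd.crosstab(labels, e).reindex(
                index=[1, 2], fill_value=0
            ).to_numpy()
            _, fisher_p = scipy.stats.fisher_exact(tab)
            fisher_p = float(fisher_p)
    return ClusteringResult(labels, linkage_method, k, ari, fisher_p)


def adjust_betas_for_cth(bulk: pd.DataFrame, fractions) -> pd.DataFrame:
    """Residualise each CpG on the cell fractions (CTH adjustment).

    Per CpG, the betas are regressed on K-1 fraction columns plus an
    intercept; the residuals, re-centered at the CpG's original mean, form
    the adjusted matrix.  Idempotent: adjusting twice equals adjusting once.
    """
    W = _fraction_frame(fractions).loc[bulk.columns].to_numpy()
    n = W.shape[0]
    # constant fraction columns carry no compositional signal beyond the
    # intercept; dropping them keeps the design full rank
    Wv = W[:, :-1]
    Wv = Wv[:, Wv.var(axis=0) > 1e-24]
    X = np.column_stack([np.ones(n), Wv])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient fraction design")
    H = X @ np.linalg.pinv(X)                  # n x n hat matrix
    Y = bulk.to_numpy()
    resid = Y - Y @ H.T
    out = resid + Y.mean(axis=1, keepdims=True)
    return pd.DataFrame(out, index=bulk.index, columns=bulk.columns)
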