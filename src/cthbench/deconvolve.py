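"""Reference-based cell-type deconvolution of bulk methylomes.

A reference matrix of cell-type-specific marker CpGs is built from purified
profiles, and per-sample cell-type fractions are estimated by regressing a
bulk sample's marker betas on the reference columns.  Three estimators are
provided:

* constrained least squares (``w >= 0``, ``sum(w) <= 1``), the default;
* robust (Huber) regression with truncation and renormalisation, which
  tolerates corrupted reference entries;
* a two-level hierarchical mode that first estimates a parent-lineage
  fraction (e.g. total immune) and then distributes it over its subtypes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
import pandas as pd
import scipy.optimize
import statsmodels.api as sm

from .simulate import PurifiedProfileSet

__all__ = [
    "ReferenceMatrix",
    "CellFractionEstimate",
    "build_reference",
    "estimate_fractions_constrained",
    "estimate_fractions_robust",
    "estimate_fractions_hierarchical",
]

MIN_MARKER_OVERLAP = 0.8
CONDITION_LIMIT = 1e8
# weight of the sum-to-one row in the augmented NNLS system; large enough
# that the slack variable enforces sum(w) <= 1 to well below solver noise
SUM_ROW_WEIGHT = 1e3


@dataclass
class ReferenceMatrix:
    """Marker-CpG x cell-type matrix of reference beta values.

    ``values`` holds the expected beta of each marker in each cell type;
    ``marker_for`` / ``direction`` record which cell type each marker tags
    and whether it is hyper- or hypomethylated in that type.
    """

    values: pd.DataFrame
    marker_for: pd.Series
    direction: pd.Series

    def __post_init__(self):
        if self.values.index.has_duplicates:
            raise ValueError("marker CpGs must be unique")
        if ((self.values.values < 0) | (self.values.values > 1)).any():
            raise ValueError("reference betas must lie in [0, 1]")
        counts = self.marker_for.value_counts()
        for ct in self.values.columns:
            if counts.get(ct, 0) < 1:
                raise ValueError(f"cell type {ct!r} has no marker CpG")

    @property
    def cell_types(self):
        return list(self.values.columns)


@dataclass
class CellFractionEstimate:
    """Estimated sample x cell-type fractions plus per-sample diagnostics.

    ``diagnostics`` has one row per sample with the residual norm of the
    fit and the number of coefficients clipped at the zero boundary.
    """

    fractions: pd.DataFrame
    diagnostics: pd.DataFrame
    method: str


def build_reference(profiles: PurifiedProfileSet, markers_per_type: int,
                    delta_min: float) -> ReferenceMatrix:
    """Select marker CpGs and assemble the deconvolution reference.

    For each cell type the CpGs with the largest one-vs-rest mean-beta gap
    (gap >= ``delta_min``) are chosen, balanced between markers hyper- and
    hypomethylated in the target type when both are available.  CpGs flagged
    ``reserved`` in the profile annotation (the spike-target pool) are never
    candidates, so spiked DMCs cannot bias the fraction estimates.
    """
    cell_types = profiles.cell_types
    if len(cell_types) < 2:
        raise ValueError("need at least two cell types to build a reference")
    if delta_min > 1.0:
        raise ValueError("delta_min cannot exceed 1: beta gaps are bounded by 1")

    means = profiles.mean_profiles()
    candidates = means.loc[~profiles.annotation["reserved"]]

    chosen: Dict[str, pd.DataFrame] = {}
    taken: set = set()
    rows = []
    for ct in cell_types:
        others = candidates.drop(columns=ct)
        gap_hyper = candidates[ct] - others.max(axis=1)
        gap_hypo = others.min(axis=1) - candidates[ct]
        per_dir = {"hyper": gap_hyper, "hypo": gap_hypo}
        qualifying = {
            d: g[(g >= delta_min) & ~g.index.isin(taken)].sort_values(
                ascending=False)
            for d, g in per_dir.items()
        }
        total = sum(len(g) for g in qualifying.values())
        if total == 0:
            raise ValueError(
                f"no marker CpG with one-vs-rest gap >= {delta_min} "
                f"for cell type {ct!r}"
            )
        half = markers_per_type // 2
        n_hyper = min(len(qualifying["hyper"]),
                      max(half + markers_per_type % 2,
                          markers_per_type - len(qualifying["hypo"])))
        n_hypo = min(len(qualifying["hypo"]), markers_per_type - n_hyper)
        for d, n_d in (("hyper", n_hyper), ("hypo", n_hypo)):
            for cpg in qualifying[d].index[:n_d]:
                rows.append((cpg, ct, d))
                taken.add(cpg)

    index = pd.Index([r[0] for r in rows], name="cpg_id")
    return ReferenceMatrix(
        values=means.loc[index],
        marker_for=pd.Series([r[1] for r in rows], index=index,
                             name="marker_for"),
        direction=pd.Series([r[2] for r in rows], index=index,
                            name="direction"),
    )


def _align(bulk: pd.DataFrame, ref: ReferenceMatrix):
    common = ref.values.index.intersection(bulk.index)
    overlap = len(common) / len(ref.values.index)
    if overlap < MIN_MARKER_OVERLAP:
        raise ValueError(
            f"bulk covers only {overlap:.0%} of reference markers "
            f"(need >= {MIN_MARKER_OVERLAP:.0%})"
        )
    if overlap < 1.0:
        n_missing = len(ref.values.index) - len(common)
        warnings.warn(
            f"{n_missing} reference marker CpGs missing from bulk; dropped",
            stacklevel=3,
        )
    R = ref.values.loc[common].to_numpy()
    if np.linalg.cond(R) > CONDITION_LIMIT:
        raise ValueError("reference columns are collinear beyond tolerance")
    return R, bulk.loc[common]


def _solve_constrained(R: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Least squares with w >= 0 and sum(w) <= 1 via slack-augmented NNLS."""
    m, k = R.shape
    A = np.zeros((m + 1, k + 1))
    A[:m, :k] = R
    A[m, :] = SUM_ROW_WEIGHT
    y = np.concatenate([b, [SUM_ROW_WEIGHT]])
    x, _ = scipy.optimize.nnls(A, y)
    return x[:k]


def estimate_fractions_constrained(bulk: pd.DataFrame,
                                   ref: ReferenceMatrix) -> CellFractionEstimate:
    """Constrained least-squares fraction estimates for every bulk sample.

    Solves, per sample, ``min ||R w - b||`` subject to ``w >= 0`` and
    ``sum(w) <= 1``; deterministic given its inputs.
    """
    R, marker_bulk = _align(bulk, ref)
    k = R.shape[1]
    W = np.empty((bulk.shape[1], k))
    resid = np.empty(bulk.shape[1])
    clipped = np.empty(bulk.shape[1], dtype=int)
    B = marker_bulk.to_numpy()
    for j in range(bulk.shape[1]):
        w = _solve_constrained(R, B[:, j])
        W[j] = w
        resid[j] = float(np.linalg.norm(R @ w - B[:, j]))
        clipped[j] = int(np.sum(w <= 1e-12))
    fractions = pd.DataFrame(W, index=bulk.columns, columns=ref.cell_types)
    fractions.attrs["true_or_estimated"] = "estimated"
    diagnostics = pd.DataFrame(
        {"residual_norm": resid, "n_clipped": clipped}, index=bulk.columns
    )
    return CellFractionEstimate(fractions, diagnostics, method="constrained")


def estimate_fractions_robust(bulk: pd.DataFrame,
                              ref: ReferenceMatrix,
                              max_iter: int = 50,
                              tol: float = 1e-6) -> CellFractionEstimate:
    """Huber-weighted robust fraction estimates, renormalised to sum to 1.

    Iteratively reweighted least squares downweights marker CpGs whose bulk
    value departs strongly from the reference fit (e.g. corrupted reference
    rows); negative coefficients are truncated to zero and the remainder is
    rescaled so every row sums to exactly 1.
    """
    R, marker_bulk = _align(bulk, ref)
    B = marker_bulk.to_numpy()
    W = np.empty((bulk.shape[1], R.shape[1]))
    resid = np.empty(bulk.shape[1])
    clipped = np.empty(bulk.shape[1], dtype=int)
    for j in range(bulk.shape[1]):
        model = sm.RLM(B[:, j], R, M=sm.robust.norms.HuberT())
        fit = model.fit(maxiter=max_iter, tol=tol)
        w = np.asarray(fit.params, dtype=float)
        clipped[j] = int(np.sum(w < 0))
        w = np.clip(w, 0.0, None)
        total = w.sum()
        if total <= 0:
            raise ValueError(
                f"all robust coefficients truncated to zero for sample "
                f"{bulk.columns[j]!r}"
            )
        w = w / total
        W[j] = w
        resid[j] = float(np.linalg.norm(R @ w - B[:, j]))
    fractions = pd.DataFrame(W, index=bulk.columns, columns=ref.cell_types)
    fractions.attrs["true_or_estimated"] = "estimated"
    diagnostics = pd.DataFrame(
        {"residual_norm": resid, "n_clipped": clipped}, index=bulk.columns
    )
    return CellFractionEstimate(fractions, diagnostics, method="robust")


def estimate_fractions_hierarchical(bulk: pd.DataFrame,
                                    ref_level1: ReferenceMatrix,
                                    ref_level2: ReferenceMatrix,
                                    parent: str) -> CellFractionEstimate:
    """Two-step hierarchical estimation for nested cell-type panels.

    Level 1 estimates fractions for the broad lineages (including
    ``parent``, e.g. total immune); level 2 estimates the within-parent
    composition over the subtypes; the final subtype fraction is the
    product of the parent fraction and the within-parent proportion.
    Non-parent level-1 columns are passed through unchanged.
    """
    if parent not in ref_level1.cell_types:
        raise ValueError(f"parent {parent!r} missing from level-1 reference")
    level1 = estimate_fractions_constrained(bulk, ref_level1)
    level2 = estimate_fractions_constrained(bulk, ref_level2)

    f_parent = level1.fractions[parent]
    sub = level2.fractions.copy()
    totals = sub.sum(axis=1)
    # within-parent proportions; a zero level-2 fit leaves all subtypes 0
    props = sub.div(totals.where(totals > 0, 1.0), axis=0)
    props[totals <= 0] = 0.0
    final = props.mul(f_parent, axis=0)

    passthrough = level1.fractions.drop(columns=parent)
    fractions = pd.concat([passthrough, final], axis=1)
    fractions.attrs["true_or_estimated"] = "estimated"
    diagnostics = pd.DataFrame({
        "residual_norm_level1": level1.diagnostics["residual_norm"],
        "residual_norm_level2": level2.diagnostics["residual_norm"],
        "n_clipped": level1.diagnostics["n_clipped"]
        + level2.diagnostics["n_clipped"],
    })
    return CellFractionEstimate(fractions, diagnostics, method="hierarchical")
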