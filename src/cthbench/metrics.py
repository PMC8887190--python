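"""Scoring of DMC calls against spike-in ground truth."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .dmc import DEFAULT_ALPHA, significant_cpgs

__all__ = ["DetectionMetrics", "compute_detection_metrics", "pooled_r2"]


@dataclass(frozen=True)
class DetectionMetrics:
    """Confusion counts and rates of one analysis arm vs the truth.

    ``precision`` is NaN (with ``precision_defined`` False) when the arm
    makes no calls at all — never reported as 0 or 1 in that case.
    """

    arm: str
    alpha: float
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def universe_size(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else math.nan

    @property
    def fpr(self) -> float:
        return self.fp / (self.fp + self.tn) if self.fp + self.tn else math.nan

    @property
    def precision_defined(self) -> bool:
        return self.tp + self.fp > 0

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.precision_defined else math.nan

    def as_dict(self) -> dict:
        return {
            "arm": self.arm, "alpha": self.alpha,
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "sensitivity": self.sensitivity, "fpr": self.fpr,
            "precision": self.precision,
            "precision_defined": self.precision_defined,
        }


def compute_detection_metrics(results: pd.DataFrame, truth: pd.DataFrame,
                              alpha: float = DEFAULT_ALPHA,
                              arm: str = "") -> DetectionMetrics:
    """Score one DMC result table against the spike-in truth at q <= alpha."""
    truth_cpgs = set(truth["cpg_id"])
    universe = set(results.index)
    missing = truth_cpgs - universe
    if missing:
        raise ValueError(
            f"{len(missing)} truth CpGs absent from the result table, "
            f"e.g. {sorted(missing)[:3]}"
        )
    called = set(significant_cpgs(results, alpha))
    tp = len(called & truth_cpgs)
    fp = len(called - truth_cpgs)
    fn = len(truth_cpgs - called)
    tn = len(universe) - tp - fp - fn
    arm = arm or str(results["mode"].iloc[0]) if "mode" in results else arm
    return DetectionMetrics(arm=arm, alpha=alpha, tp=tp, fp=fp, tn=tn, fn=fn)


def pooled_r2(estimated: pd.DataFrame, true: pd.DataFrame) -> float:
    """Squared Pearson correlation between estimated and true fractions,
    pooled over every (sample, cell type) pair."""
    common = [c for c in true.columns if c in estimated.columns]
    est = estimated.loc[true.index, common].to_numpy().ravel()
    tru = true[common].to_numpy().ravel()
    r = pd.Series(est).corr(pd.Series(tru))
    return float(r ** 2)
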