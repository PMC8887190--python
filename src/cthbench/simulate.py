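"""Synthetic purified methylomes, spike-in DMCs and bulk mixtures.

The generator emulates a matched-design purified-cell experiment: for every
individual it produces one methylome per cell type over a shared CpG index,
plants cell-type-specific marker CpGs with large (>= ``marker_delta``)
between-cell-type differences, spikes ground-truth differentially methylated
cytosines (DMCs) into the target cell type of the exposed cases, and mixes
the per-individual profiles into bulk beta values with Dirichlet-distributed
cell fractions.

Beta values are simulated with a latent-Gaussian model: a per-CpG
per-cell-type mean ``m`` is perturbed per individual on the logit scale,
``beta = expit(logit(m) + N(0, bio_sd^2))``, which keeps values in (0, 1)
and reproduces the variance squashing near 0 and 1 that beta values show.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .config import SimConfig

__all__ = [
    "PurifiedProfileSet",
    "generate_purified_profiles",
    "make_phenotype",
    "spike_dmcs",
    "apply_spikes",
    "sample_fractions",
    "mix_profiles",
    "generate_composition_shift_scenario",
]

BETA_FLOOR = 0.001
BETA_CEIL = 0.999
# margin added on top of marker_delta when planting marker means, so the
# one-vs-rest gap survives the shrinkage of noisy means toward 0.5
MARKER_MARGIN = 0.1

TRUTH_COLUMNS = ["cpg_id", "cell_type", "effect_size", "realized_effect"]


@dataclass
class PurifiedProfileSet:
    """Matched per-cell-type beta matrices over a common CpG/sample index.

    ``profiles[k]`` is a CpG x sample DataFrame for cell type ``k``; all
    matrices share both indices (matched design).  ``annotation`` is indexed
    by CpG with columns ``marker_for`` ("" for shared CpGs), ``direction``
    ("hyper"/"hypo" in the marked type, "" for shared) and ``reserved``
    (True for spike-target pool CpGs excluded from reference building).
    """

    profiles: Dict[str, pd.DataFrame]
    annotation: pd.DataFrame

    def __post_init__(self):
        cell_types = list(self.profiles)
        first = self.profiles[cell_types[0]]
        for k in cell_types[1:]:
            if not first.index.equals(self.profiles[k].index):
                raise ValueError("profile matrices must share the CpG index")
            if not first.columns.equals(self.profiles[k].columns):
                raise ValueError("profile matrices must share the sample index")
        if not first.index.equals(self.annotation.index):
            raise ValueError("annotation must be indexed by the CpG index")

    @property
    def cell_types(self):
        return list(self.profiles)

    @property
    def cpg_ids(self) -> pd.Index:
        return next(iter(self.profiles.values())).index

    @property
    def sample_ids(self) -> pd.Index:
        return next(iter(self.profiles.values())).columns

    def copy(self) -> "PurifiedProfileSet":
        return PurifiedProfileSet(
            {k: v.copy() for k, v in self.profiles.items()},
            self.annotation.copy(),
        )

    def mean_profiles(self) -> pd.DataFrame:
        """CpG x cell-type matrix of per-cell-type mean betas."""
        return pd.DataFrame(
            {k: v.mean(axis=1) for k, v in self.profiles.items()}
        )


def _cpg_ids(n: int) -> pd.Index:
    width = max(5, len(str(n)))
    return pd.Index([f"cpg{i:0{width}d}" for i in range(1, n + 1)], name="cpg_id")


def _sample_ids(n: int) -> pd.Index:
    return pd.Index([f"S{i:03d}" for i in range(1, n + 1)], name="sample_id")


def _noisy_betas(means: np.ndarray, bio_sd: float, n_samples: int,
                 rng: np.random.Generator) -> np.ndarray:
    lat = logit(np.clip(means, BETA_FLOOR, BETA_CEIL))[:, None]
    if bio_sd > 0:
        lat = lat + rng.normal(0.0, bio_sd, size=(means.size, n_samples))
    else:
        lat = np.broadcast_to(lat, (means.size, n_samples)).copy()
    return np.clip(expit(lat), BETA_FLOOR, BETA_CEIL)


def generate_purified_profiles(config: SimConfig) -> PurifiedProfileSet:
    """Generate matched purified methylomes for every cell type.

    Layout of the CpG index: for each cell type in order, ``markers_per_type``
    planted marker CpGs (alternating hyper/hypo in the marked type); then an
    ``n_dmcs``-sized pool of extra markers of the spike target, flagged
    ``reserved`` and never used for reference construction; the remaining
    CpGs share a common bimodal baseline mean across all cell types.
    """
    k = len(config.cell_types)
    n_marker = config.n_marker_cpgs
    if config.n_cpgs < n_marker + 1:
        raise ValueError("n_cpgs too small to host the marker CpGs")

    high = 0.5 + min(config.marker_delta + MARKER_MARGIN, 2 * BETA_CEIL - 1) / 2
    low = 1.0 - high

    cpgs = _cpg_ids(config.n_cpgs)
    samples = _sample_ids(config.n_samples)
    rng = config.rng("generate_purified_profiles")

    means = np.empty((config.n_cpgs, k))
    marker_for = np.full(config.n_cpgs, "", dtype=object)
    direction = np.full(config.n_cpgs, "", dtype=object)
    reserved = np.zeros(config.n_cpgs, dtype=bool)

    pos = 0

    def plant(ct_index: int, count: int, is_reserved: bool) -> None:
        nonlocal pos
        for i in range(count):
            # hyper/hypo refers to the marked cell type relative to the rest
            hyper = i % 2 == 0
            means[pos] = low if hyper else high
            means[pos, ct_index] = high if hyper else low
            marker_for[pos] = config.cell_types[ct_index]
            direction[pos] = "hyper" if hyper else "hypo"
            reserved[pos] = is_reserved
            pos += 1

    for ci in range(k):
        plant(ci, config.markers_per_type, is_reserved=False)
    plant(config.cell_types.index(config.spike_target), config.n_dmcs,
          is_reserved=True)

    # shared CpGs: bimodal baseline, identical mean across cell types
    n_shared = config.n_cpgs - pos
    u = rng.random(n_shared)
    lo_mode = rng.beta(0.3, 3.0, n_shared)
    hi_mode = rng.beta(3.0, 0.3, n_shared)
    mid = rng.uniform(0.2, 0.8, n_shared)
    base = np.where(u < 0.4, lo_mode, np.where(u < 0.8, hi_mode, mid))
    base = np.clip(base, BETA_FLOOR, BETA_CEIL)
    means[pos:] = base[:, None]

    profiles = {}
    for ci, ct in enumerate(config.cell_types):
        values = _noisy_betas(means[:, ci], config.bio_sd,
                              config.n_samples, rng)
        profiles[ct] = pd.DataFrame(values, index=cpgs, columns=samples)

    annotation = pd.DataFrame(
        {"marker_for": marker_for, "direction": direction, "reserved": reserved},
        index=cpgs,
    )
    return PurifiedProfileSet(profiles, annotation)


def make_phenotype(config: SimConfig, extra_factors: bool = False) -> pd.DataFrame:
    """Binary exposure table: exactly ``n_cases`` cases among the samples.

    Case status is assigned by a seeded permutation.  With ``extra_factors``
    two nuisance covariates ("sex" binary, "age" in years) are added for
    variance-structure analyses.
    """
    rng = config.rng("phenotype")
    samples = _sample_ids(config.n_samples)
    exposure = np.zeros(config.n_samples, dtype=int)
    exposure[rng.permutation(config.n_samples)[: config.n_cases]] = 1
    pheno = pd.DataFrame({"exposure": exposure}, index=samples)
    if extra_factors:
        pheno["sex"] = rng.integers(0, 2, config.n_samples)
        pheno["age"] = np.round(rng.normal(50.0, 10.0, config.n_samples), 1)
    return pheno


def apply_spikes(profiles: PurifiedProfileSet, records: pd.DataFrame,
                 case_ids) -> Tuple[PurifiedProfileSet, pd.DataFrame]:
    """Shift case-sample betas of the target cell type by given effects.

    ``records`` needs columns ``cpg_id``, ``cell_type``, ``effect_size``.
    Values are re-clipped to the valid beta range after shifting; the
    returned truth table adds ``realized_effect``, the mean post-clip shift
    actually applied to the case samples.
    """
    out = profiles.copy()
    realized = np.empty(len(records))
    case_ids = pd.Index(case_ids)
    for i, rec in enumerate(records.itertuples(index=False)):
        if rec.cell_type not in out.profiles:
            raise ValueError(f"unknown target cell type {rec.cell_type!r}")
        mat = out.profiles[rec.cell_type]
        before = mat.loc[rec.cpg_id, case_ids]
        after = np.clip(before + rec.effect_size, BETA_FLOOR, BETA_CEIL)
        mat.loc[rec.cpg_id, case_ids] = after
        realized[i] = float(np.mean(after - before))
    truth = records.copy().reset_index(drop=True)
    truth["realized_effect"] = realized
    return out, truth[TRUTH_COLUMNS]


def spike_dmcs(profiles: PurifiedProfileSet, pheno: pd.DataFrame,
               config: SimConfig) -> Tuple[PurifiedProfileSet, pd.DataFrame]:
    """Spike ``n_dmcs`` ground-truth DMCs into the target cell type of cases.

    Spiked CpGs are drawn from the reserved pool of spike-target marker CpGs
    (kept disjoint from the deconvolution reference).  Absolute effect sizes
    are uniform on [effect_low, effect_high]; the sign hypermethylates CpGs
    whose baseline mean is below 0.5 and hypomethylates the rest, avoiding
    systematic clipping.
    """
    if config.spike_target not in profiles.profiles:
        raise ValueError(
            f"spike target {config.spike_target!r} absent from profiles"
        )
    if config.n_dmcs == 0:
        return profiles.copy(), pd.DataFrame(columns=TRUTH_COLUMNS)

    ann = profiles.annotation
    pool = ann.index[ann["reserved"] & (ann["marker_for"] == config.spike_target)]
    if len(pool) < config.n_dmcs:
        raise ValueError(
            f"only {len(pool)} reserved spike-target marker CpGs available, "
            f"need {config.n_dmcs}"
        )
    rng = config.rng("spike_dmcs")
    chosen = pd.Index(rng.choice(pool.to_numpy(), config.n_dmcs, replace=False))
    magnitudes = rng.uniform(config.effect_low, config.effect_high,
                             config.n_dmcs)
    baseline = profiles.profiles[config.spike_target].loc[chosen].mean(axis=1)
    sign = np.where(baseline.to_numpy() < 0.5, 1.0, -1.0)
    records = pd.DataFrame({
        "cpg_id": chosen,
        "cell_type": config.spike_target,
        "effect_size": sign * magnitudes,
    })
    cases = pheno.index[pheno["exposure"] == 1]
    return apply_spikes(profiles, records, cases)


def sample_fractions(n: int, config: SimConfig,
                     means: Optional[tuple] = None,
                     rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Draw ``n`` cell-fraction rows from Dirichlet(concentration * means)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if config.fraction_concentration <= 0:
        raise ValueError("fraction concentration must be positive")
    if means is None:
        means = config.fraction_means
    if rng is None:
        rng = config.rng("sample_fractions")
    alpha = config.fraction_concentration * np.asarray(means, dtype=float)
    w = rng.dirichlet(alpha, size=n)
    frac = pd.DataFrame(w, index=_sample_ids(n), columns=list(config.cell_types))
    frac.attrs["true_or_estimated"] = "true"
    return frac


def mix_profiles(profiles: PurifiedProfileSet, fractions: pd.DataFrame,
                 meas_sd: float = 0.0,
                 rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Mix matched purified profiles into bulk betas.

    Sample ``i``'s bulk value at CpG ``g`` is the fraction-weighted convex
    combination of that same individual's purified profiles, plus optional
    Gaussian measurement noise on the beta scale, clipped to [0, 1].
    """
    if len(fractions) != len(profiles.sample_ids):
        raise ValueError("fractions rows must align with profile samples")
    missing = [c for c in fractions.columns if c not in profiles.profiles]
    if missing:
        raise ValueError(f"fraction columns without matching profile: {missing}")
    bulk = np.zeros((len(profiles.cpg_ids), len(profiles.sample_ids)))
    for ct in fractions.columns:
        bulk += profiles.profiles[ct].to_numpy() * fractions[ct].to_numpy()[None, :]
    if meas_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        bulk = bulk + rng.normal(0.0, meas_sd, size=bulk.shape)
    bulk = np.clip(bulk, 0.0, 1.0)
    return pd.DataFrame(bulk, index=profiles.cpg_ids,
                        columns=profiles.sample_ids)


def generate_composition_shift_scenario(
    config: SimConfig,
) -> Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Mixtures whose only case/control difference is cell composition.

    No DMCs are spiked; cases and controls draw their cell fractions from
    Dirichlet distributions with different means (``case_fraction_means`` /
    ``control_fraction_means``), emulating a disease that shifts blood
    composition without any within-cell-type methylation change.

    Returns (bulk beta matrix, phenotype table, true fraction matrix).
    """
    case_means = config.case_fraction_means
    ctrl_means = config.control_fraction_means
    if case_means is None or ctrl_means is None:
        raise ValueError(
            "composition-shift scenario needs case_fraction_means and "
            "control_fraction_means in the config"
        )
    if np.allclose(case_means, ctrl_means):
        warnings.warn(
            "case and control fraction means are identical: the scenario "
            "degenerates to a pure null", stacklevel=2,
        )
    profiles = generate_purified_profiles(config)
    pheno = make_phenotype(config)
    rng = config.rng("composition_shift_fractions")
    case_rows = pheno["exposure"].to_numpy() == 1
    alpha_case = config.fraction_concentration * np.asarray(case_means)
    alpha_ctrl = config.fraction_concentration * np.asarray(ctrl_means)
    w = np.empty((config.n_samples, len(config.cell_types)))
    w[case_rows] = rng.dirichlet(alpha_case, size=int(case_rows.sum()))
    w[~case_rows] = rng.dirichlet(alpha_ctrl, size=int((~case_rows).sum()))
    fractions = pd.DataFrame(w, index=pheno.index,
                             columns=list(config.cell_types))
    fractions.attrs["true_or_estimated"] = "true"
    bulk = mix_profiles(profiles, fractions, config.meas_sd,
                        config.rng("mix_profiles"))
    return bulk, pheno, fractions
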