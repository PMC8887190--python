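"""Simulation configuration for the cell-type-heterogeneity benchmark.

A single :class:`SimConfig` drives every stochastic stage of the pipeline.
Each stage draws from its own child random stream keyed by the stage name,
so a pipeline is reproducible stage-by-stage: regenerating the purified
profiles does not perturb the stream used to draw cell fractions.
"""

from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import yaml

__all__ = ["SimConfig", "DEFAULT_CELL_TYPES"]

DEFAULT_CELL_TYPES = ("neutrophil", "cd4t", "monocyte")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic bulk-methylation benchmark.

    The defaults emulate a whole-blood-like three-cell-type experiment:
    139 samples split into 69 exposed cases and 70 controls, 1000
    differentially methylated cytosines (DMCs) spiked into the monocyte
    compartment of the cases with beta-scale effect sizes drawn uniformly
    from [0.01, 0.2], and per-sample cell fractions drawn from a Dirichlet
    distribution centred on neutrophil/CD4T/monocyte = 0.70/0.20/0.10.

    Parameters
    ----------
    n_cpgs
        Number of CpGs on the synthetic array.
    cell_types
        Ordered cell-type names; the order fixes column order everywhere.
    n_samples, n_cases
        Total samples and number of exposed cases (controls = rest).
    n_dmcs
        Number of ground-truth DMCs spiked into ``spike_target``.
    effect_low, effect_high
        Bounds of the uniform distribution of absolute spike effect sizes,
        on the beta-value scale.
    marker_delta
        Minimum one-vs-rest mean beta difference a marker CpG must show.
    markers_per_type
        Marker CpGs planted per cell type for reference construction.
    bio_sd
        Inter-individual biological noise sd on the latent (logit) scale.
    meas_sd
        Measurement noise sd on the beta scale, added when mixing.
    fraction_means, fraction_concentration
        Mean vector and concentration of the Dirichlet cell-fraction model.
    spike_target
        Cell type receiving the spiked DMCs.
    case_fraction_means, control_fraction_means
        Optional per-group fraction means for the composition-shift-only
        scenario; both must be set to activate it.
    seed
        Global seed; every stage derives a child stream from it.
    """

    n_cpgs: int = 50_000
    cell_types: tuple = DEFAULT_CELL_TYPES
    n_samples: int = 139
    n_cases: int = 69
    n_dmcs: int = 1000
    effect_low: float = 0.01
    effect_high: float = 0.2
    marker_delta: float = 0.8
    markers_per_type: int = 50
    bio_sd: float = 0.3
    meas_sd: float = 0.01
    fraction_means: tuple = (0.70, 0.20, 0.10)
    fraction_concentration: float = 30.0
    spike_target: str = "monocyte"
    case_fraction_means: Optional[tuple] = None
    control_fraction_means: Optional[tuple] = None
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "cell_types", tuple(self.cell_types))
        object.__setattr__(self, "fraction_means", tuple(self.fraction_means))
        for name in ("case_fraction_means", "control_fraction_means"):
            v = getattr(self, name)
            if v is not None:
                object.__setattr__(self, name, tuple(v))
        self._validate()

    # -- validation ------------------------------------------------------

    def _validate(self) -> None:
        k = len(self.cell_types)
        if k < 2:
            raise ValueError("need at least two cell types")
        if len(set(self.cell_types)) != k:
            raise ValueError("cell type names must be unique")
        for name in ("n_cpgs", "n_samples", "n_cases", "markers_per_type"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_dmcs < 0:
            raise ValueError("n_dmcs must be non-negative")
        if not self.n_cases < self.n_samples:
            raise ValueError("n_cases must be smaller than n_samples")
        if not 0 < self.effect_low < self.effect_high <= 1:
            raise ValueError("require 0 < effect_low < effect_high <= 1")
        if not 0 < self.marker_delta < 1:
            raise ValueError("marker_delta must lie in (0, 1)")
        if self.bio_sd < 0 or self.meas_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.fraction_concentration <= 0:
            raise ValueError("fraction_concentration must be positive")
        if self.spike_target not in self.cell_types:
            raise ValueError(
                f"spike_target {self.spike_target!r} not among cell_types"
            )
        for name in ("fraction_means", "case_fraction_means", "control_fraction_means"):
            v = getattr(self, name)
            if v is None:
                continue
            if len(v) != k:
                raise ValueError(f"{name} must have one entry per cell type")
            if any(m <= 0 for m in v):
                raise ValueError(f"{name} entries must be positive")
            if abs(sum(v) - 1.0) > 1e-8:
                raise ValueError(f"{name} must sum to 1")
        # every cell type hosts markers_per_type markers; the spike target
        # additionally hosts an n_dmcs-sized reserved pool
        if self.n_cpgs < self.n_marker_cpgs + 1:
            raise ValueError(
                f"n_cpgs={self.n_cpgs} too small to host "
                f"{self.n_marker_cpgs} marker/reserved CpGs"
            )

    # -- derived sizes ---------------------------------------------------

    @property
    def n_controls(self) -> int:
        return self.n_samples - self.n_cases

    @property
    def n_marker_cpgs(self) -> int:
        """Marker CpGs planted in total, including the reserved spike pool."""
        return self.markers_per_type * len(self.cell_types) + self.n_dmcs

    # -- random streams --------------------------------------------------

    def rng(self, stage: str) -> np.random.Generator:
        """Child random generator for a named pipeline stage."""
        return np.random.default_rng([self.seed, zlib.crc32(stage.encode())])

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=int(seed))

    # -- (de)serialisation ----------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cell_types"] = list(self.cell_types)
        d["fraction_means"] = list(self.fraction_means)
        for name in ("case_fraction_means", "control_fraction_means"):
            if d[name] is not None:
                d[name] = list(d[name])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
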