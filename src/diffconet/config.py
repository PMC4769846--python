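"""Analysis configuration and the seeding discipline.

All randomness in a run flows from ``random_seed`` through
:meth:`AnalysisConfig.stage_rng`, which derives one independent child
stream per named stage. Re-running with the same config therefore
reproduces every permutation and simulation byte for byte.
"""
from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass

import numpy as np
import yaml

from .errors import InputError

CONNECTIVITY_BASES = ("adjacency", "similarity")


@dataclass
class AnalysisConfig:
    #: PVAC quality threshold; probe sets below it in every group are dropped.
    pvac_threshold: float = 0.4
    #: |t| boundary of the differential-expression axis of the sector plot.
    t_threshold: float = 1.96
    #: |diffK| boundary of the differential-connectivity axis.
    k_threshold: float = 0.3
    #: Number of case/control label permutations for the sector null.
    n_permutations: int = 1000
    #: BH false-discovery-rate level for calling genes up/down.
    fdr_alpha: float = 0.05
    #: Soft-thresholding power applied to the signed similarity.
    soft_power: float = 12.0
    #: Clusters smaller than this are relabelled "grey".
    module_min_size: int = 30
    #: Static dendrogram cut height on the 1−TOM scale, in (0, 1].
    tree_cut_height: float = 0.98
    #: Connectivity sums soft-thresholded adjacency ("adjacency") or raw
    #: signed similarity ("similarity"). Adjacency is the default: with raw
    #: similarity sums the constant baseline (n−1)/2 dominates and scaled
    #: connectivity is insensitive to network structure, so the ±0.3
    #: differential-connectivity boundary would never be reached.
    connectivity_basis: str = "adjacency"
    #: Use Welch's t (unequal variances) for unpaired comparisons.
    welch: bool = False
    #: Group labels naming the diffnet contrast; free strings.
    case_group: str | None = None
    control_group: str | None = None
    random_seed: int = 0

    def __post_init__(self) -> None:
        positive = {
            "pvac_threshold": self.pvac_threshold,
            "t_threshold": self.t_threshold,
            "k_threshold": self.k_threshold,
            "fdr_alpha": self.fdr_alpha,
            "soft_power": self.soft_power,
            "module_min_size": self.module_min_size,
        }
        for name, value in positive.items():
            if not value > 0:
                raise InputError(f"{name} must be positive, got {value}")
        if self.n_permutations < 1:
            raise InputError("n_permutations must be >= 1")
        if not 0 < self.tree_cut_height <= 1:
            raise InputError("tree_cut_height must lie in (0, 1]")
        if self.connectivity_basis not in CONNECTIVITY_BASES:
            raise InputError(
                f"connectivity_basis must be one of {CONNECTIVITY_BASES}"
            )

    def stage_rng(self, stage: str) -> np.random.Generator:
        """Deterministic child generator for a named pipeline stage."""
        return np.random.default_rng(
            [int(self.random_seed) % (2**31), zlib.crc32(stage.encode())]
        )

    def replace(self, **kwargs) -> "AnalysisConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
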