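"""Differential expression × differential connectivity sector analysis.

Each gene is placed in the plane spanned by (i) the unpaired t statistic
comparing case vs control per-subject responses and (ii) the difference
in max-scaled network connectivity between the case and control
networks (diffK = K1/max(K1) − K2/max(K2)). The plane is divided into
eight significance sectors by the boundaries |t| = 1.96 and
|diffK| = 0.3 (strict inequalities; boundary values are
non-significant):

    R1: t >  thr, diffK < −kthr     R5: t < −thr, diffK >  kthr
    R2: t >  thr, |diffK| <= kthr   R6: t < −thr, |diffK| <= kthr
    R3: t >  thr, diffK >  kthr     R7: t < −thr, diffK < −kthr
    R4: |t| <= thr, diffK >  kthr   R8: |t| <= thr, diffK < −kthr

so R2/R6 are differentially expressed only, R4/R8 differentially
connected only, and R1/R3/R5/R7 both; R3 collects genes upregulated in
both expression and connectivity in cases. Swapping case and control
negates t and diffK, mapping R1↔R5, R2↔R6, R3↔R7, R4↔R8.

Sector counts are tested against a null built from random permutations
of the subject-level case/control labels (group sizes preserved),
with the add-one tail estimator p = (1 + #{count_b >= observed})/(B+1).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .coexpression import signed_similarity, soft_adjacency
from .errors import InputError

log = logging.getLogger(__name__)

SECTORS = ("R1", "R2", "R3", "R4", "R5", "R6", "R7", "R8")
NO_SECTOR = "NS"


def _scaled_connectivity(X: np.ndarray, config: AnalysisConfig) -> np.ndarray:
    S = signed_similarity(X)
    if config.connectivity_basis == "adjacency":
        K = soft_adjacency(S, config.soft_power).sum(axis=1)
    else:
        K = S.sum(axis=1) - np.diagonal(S)
    kmax = K.max()
    return K / kmax if kmax > 0 else np.zeros_like(K)


def _pooled_t(pooled: np.ndarray, case_idx: np.ndarray, ctrl_idx: np.ndarray) -> np.ndarray:
    a, b = pooled[:, case_idx], pooled[:, ctrl_idx]
    n1, n2 = a.shape[1], b.shape[1]
    v1, v2 = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (a.mean(axis=1) - b.mean(axis=1)) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    return np.where(np.isnan(t), 0.0, t)


def differential_connectivity(
    ratios_case: pd.DataFrame,
    ratios_control: pd.DataFrame,
    config: AnalysisConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Scaled connectivity per group and their difference (case − control)."""
    if list(ratios_case.index) != list(ratios_control.index):
        raise InputError("case and control tables must share gene set and order")
    if ratios_case.shape[1] < 3 or ratios_control.shape[1] < 3:
        raise InputError("each group needs at least 3 subjects")
    k1 = _scaled_connectivity(ratios_case.to_numpy(), config)
    k2 = _scaled_connectivity(ratios_control.to_numpy(), config)
    return k1, k2, k1 - k2


def assign_sectors(
    t: np.ndarray, diff_k: np.ndarray, config: AnalysisConfig
) -> np.ndarray:
    """Sector label per gene; non-finite inputs are labelled NS."""
    t = np.asarray(t, dtype=float)
    diff_k = np.asarray(diff_k, dtype=float)
    if t.shape != diff_k.shape:
        raise InputError("t and diffK must have equal length")
    bad = ~(np.isfinite(t) & np.isfinite(diff_k))
    if bad.any():
        log.warning("%d gene(s) with non-finite t or diffK labelled NS", bad.sum())
    return np.asarray(
        [SECTORS[c - 1] if c >= 1 else NO_SECTOR for c in _sector_codes(t, diff_k, config)],
        dtype=object,
    )


def _sector_codes(
    t: np.ndarray, diff_k: np.ndarray, config: AnalysisConfig
) -> np.ndarray:
    """Integer sector codes: 1..8 for R1..R8, 0 for NS."""
    tt, kk = config.t_threshold, config.k_threshold
    with np.errstate(invalid="ignore"):
        up, down = t > tt, t < -tt
        kup, kdown = diff_k > kk, diff_k < -kk
        kmid = ~kup & ~kdown
        tmid = ~up & ~down
    codes = np.zeros(t.shape, dtype=np.intp)
    codes[up & kdown] = 1
    codes[up & kmid] = 2
    codes[up & kup] = 3
    codes[tmid & kup] = 4
    codes[down & kup] = 5
    codes[down & kmid] = 6
    codes[down & kdown] = 7
    codes[tmid & kdown] = 8
    bad = ~(np.isfinite(t) & np.isfinite(diff_k))
    codes[bad] = 0
    return codes


def _sector_counts(codes: np.ndarray) -> np.ndarray:
    """Counts indexed 0..8 (0 = NS)."""
    return np.bincount(codes, minlength=9)


@dataclass
class DiffNetResult:
    """Per-gene sector table, observed sector counts, permutation p-values."""

    table: pd.DataFrame  # index gene: t, k_case, k_control, diff_k, sector
    sector_counts: pd.Series  # R1..R8 + NS
    permutation_p: pd.Series  # R1..R8
    n_permutations: int
    case_group: str | None = None
    control_group: str | None = None

    def to_jsonable(self) -> dict:
        return {
            "case_group": self.case_group,
            "control_group": self.control_group,
            "n_permutations": self.n_permutations,
            "sector_counts": {k: int(v) for k, v in self.sector_counts.items()},
            "permutation_p": {k: float(v) for k, v in self.permutation_p.items()},
        }


def permutation_test(
    ratios_case: pd.DataFrame,
    ratios_control: pd.DataFrame,
    config: AnalysisConfig,
    rng: np.random.Generator | None = None,
) -> DiffNetResult:
    """Observed sectoring plus a subject-label permutation null.

    Subjects (not samples) are the exchangeable units: each of the B
    permutations reassigns subjects to pseudo-case/pseudo-control of the
    original sizes, recomputes t, both scaled connectivities and the
    sector counts, and each sector's p is the add-one upper-tail
    fraction of permutations reaching the observed count.
    """
    if config.n_permutations < 1:
        raise InputError("n_permutations must be >= 1")
    if list(ratios_case.index) != list(ratios_control.index):
        raise InputError("case and control tables must share gene set and order")
    n1, n2 = ratios_case.shape[1], ratios_control.shape[1]
    if n1 + n2 < 6:
        raise InputError("permutation test needs at least 6 subjects in total")
    rng = rng if rng is not None else config.stage_rng("diffnet")

    pooled = np.hstack([ratios_case.to_numpy(), ratios_control.to_numpy()])
    case_idx = np.arange(n1)
    ctrl_idx = np.arange(n1, n1 + n2)

    def stats_for(ci: np.ndarray, xi: np.ndarray):
        t = _pooled_t(pooled, ci, xi)
        k1 = _scaled_connectivity(pooled[:, ci], config)
        k2 = _scaled_connectivity(pooled[:, xi], config)
        return t, k1, k2

    t_obs, k1_obs, k2_obs = stats_for(case_idx, ctrl_idx)
    codes_obs = _sector_codes(t_obs, k1_obs - k2_obs, config)
    counts_obs = _sector_counts(codes_obs)

    B = config.n_permutations
    exceed = np.zeros(9, dtype=np.int64)
    for _ in range(B):
        perm = rng.permutation(n1 + n2)
        t_b, k1_b, k2_b = stats_for(perm[:n1], perm[n1:])
        counts_b = _sector_counts(_sector_codes(t_b, k1_b - k2_b, config))
        exceed += counts_b >= counts_obs
    pvals = (1.0 + exceed) / (B + 1.0)

    sectors = assign_sectors(t_obs, k1_obs - k2_obs, config)
    table = pd.DataFrame(
        {
            "t": t_obs,
            "k_case": k1_obs,
            "k_control": k2_obs,
            "diff_k": k1_obs - k2_obs,
            "sector": sectors,
        },
        index=ratios_case.index,
    )
    counts = pd.Series(
        {**{s: int(counts_obs[i + 1]) for i, s in enumerate(SECTORS)},
         NO_SECTOR: int(counts_obs[0])}
    )
    perm_p = pd.Series({s: pvals[i + 1] for i, s in enumerate(SECTORS)})
    log.info(
        "diffnet: sector counts %s",
        ", ".join(f"{s}={counts[s]}" for s in (*SECTORS, NO_SECTOR)),
    )
    return DiffNetResult(
        table, counts, perm_p, B, config.case_group, config.control_group
    )
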