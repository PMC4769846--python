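"""Synthetic allergen-stimulation study generator.

Emulates the statistical structure of a paired stimulated/unstimulated
CD4 T-cell study across three clinical groups: latent-factor
coexpression modules with group-specific loadings (differential
connectivity), group-specific stimulation responses (differential
expression), probe-level structure with a controllable fraction of
noisy probe sets, and optional additive batch shifts. Ground truth for
every planted effect is returned alongside the data.

Gene-level model for gene i, sample s (subject j, group g, condition c):

    x_is = mu_i + lambda[m(i), g] * z[m(i), s]
           + delta_i * 1[c = stim]
           + Delta_i * 1[c = stim and g = response_group]
           + eps_is,    eps ~ N(0, sigma^2)

z is a per-sample latent module activity, shared by all genes of a
module within a sample, drawn N(0, 1) and then standardised within each
(group, condition) stratum so that a loading lambda plants the same
coexpression strength in every realisation (conditional simulation).
Because z is drawn per sample (not per subject), module coexpression
survives in the per-subject log-ratios that downstream network stages
analyse.

Probe level: each gene expands to ``probes_per_set`` probes that add a
fixed per-probe offset and independent probe noise on top of the shared
gene signal. "Noisy" probe sets instead give every probe an independent
signal of matched variance, destroying within-set coherence so the set
falls below the PVAC quality threshold.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError
from .model import ExpressionMatrix, ProbeMatrix, SampleSheet

DEFAULT_GROUPS = ("case", "sensitized_control", "nonsensitized_control")
DEFAULT_GROUP_SIZES = (22, 26, 24)


@dataclass
class SimulationParams:
    group_labels: tuple[str, ...] = DEFAULT_GROUPS
    group_sizes: tuple[int, ...] = DEFAULT_GROUP_SIZES
    n_genes: int = 1442
    #: Genes 0..sum(module_sizes)-1 belong to modules M1, M2, ... in order.
    module_sizes: tuple[int, ...] = ()
    #: Loading per (module, group), each in [0, 1].
    module_loadings: tuple[tuple[float, ...], ...] = ()
    baseline_mean: float = 8.0
    baseline_sd: float = 1.0
    noise_sd: float = 0.5
    #: Stimulation effect per gene (log2), shared by all groups; None = zeros.
    stim_effects: np.ndarray | None = None
    #: Extra stimulation effect per gene in ``response_group`` only.
    response_effects: np.ndarray | None = None
    response_group: str = "case"
    probes_per_set: int = 4
    fraction_noisy_probesets: float = 0.0
    probe_offset_sd: float = 0.3
    probe_noise_sd: float = 0.2
    #: Additive log2 shift applied to samples of every second subject.
    batch_shift: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.group_labels) != len(self.group_sizes):
            raise InputError("group_labels and group_sizes lengths differ")
        if any(n < 1 for n in self.group_sizes):
            raise InputError("group sizes must be positive")
        if len(self.module_loadings) != len(self.module_sizes):
            raise InputError("one loading row per module is required")
        for row in self.module_loadings:
            if len(row) != len(self.group_labels):
                raise InputError("each loading row needs one value per group")
            if any(not 0 <= l <= 1 for l in row):
                raise InputError("module loadings must lie in [0, 1]")
        if sum(self.module_sizes) > self.n_genes:
            raise InputError("module sizes exceed n_genes")
        for name in ("noise_sd", "baseline_sd", "probe_offset_sd", "probe_noise_sd"):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be >= 0")
        if not 0 <= self.fraction_noisy_probesets <= 1:
            raise InputError("fraction_noisy_probesets must lie in [0, 1]")
        if self.probes_per_set < 1:
            raise InputError("probes_per_set must be >= 1")
        for arr_name in ("stim_effects", "response_effects"):
            arr = getattr(self, arr_name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if arr.shape != (self.n_genes,):
                    raise InputError(f"{arr_name} must have length n_genes")
                object.__setattr__(self, arr_name, arr)

    @property
    def n_modules(self) -> int:
        return len(self.module_sizes)


@dataclass
class SyntheticTruth:
    """Ground-truth labels for all planted effects."""

    de_genes: dict[str, list[str]]
    differentially_connected_genes: dict[str, list[str]]
    module_membership: dict[str, str]
    noisy_probesets: list[str]
    params: SimulationParams

    def to_jsonable(self) -> dict:
        p = self.params
        return {
            "de_genes": self.de_genes,
            "differentially_connected_genes": self.differentially_connected_genes,
            "module_membership": self.module_membership,
            "noisy_probesets": self.noisy_probesets,
            "params": {
                "group_labels": list(p.group_labels),
                "group_sizes": list(p.group_sizes),
                "n_genes": p.n_genes,
                "module_sizes": list(p.module_sizes),
                "module_loadings": [list(r) for r in p.module_loadings],
                "baseline_mean": p.baseline_mean,
                "baseline_sd": p.baseline_sd,
                "noise_sd": p.noise_sd,
                "response_group": p.response_group,
                "probes_per_set": p.probes_per_set,
                "fraction_noisy_probesets": p.fraction_noisy_probesets,
                "batch_shift": p.batch_shift,
                "seed": p.seed,
            },
        }


def default_study_design() -> SimulationParams:
    """Parameters emulating the source study design.

    Three clinical groups of 22 (case), 26 (sensitized control) and 24
    (nonsensitized control) subjects, each with one stimulated and one
    unstimulated sample. Two coexpression modules: M1 (120 genes) is the
    disease-associated module — strongly wired in cases (loading 0.8),
    weakly elsewhere (0.3), and its genes carry a +1.0 log2 case-specific
    stimulation response; M2 (80 genes) is a shared response module with
    equal loading 0.6 in every group, giving every network comparable
    dominant structure (as real transcriptomes have). 30% of genes
    respond to stimulation in all groups with alternating-sign log2
    effects of magnitude 1.0, and 20% of probe sets are noisy.
    """
    n_genes = 1442
    m1, m2 = 120, 80
    stim = np.zeros(n_genes)
    n_stim = int(round(0.3 * n_genes))
    start = m1 + m2  # responsive genes outside the modules
    signs = np.where(np.arange(n_stim) % 2 == 0, 1.0, -1.0)
    stim[start : start + n_stim] = signs
    response = np.zeros(n_genes)
    response[:m1] = 1.0
    return SimulationParams(
        module_sizes=(m1, m2),
        module_loadings=((0.8, 0.3, 0.3), (0.6, 0.6, 0.6)),
        n_genes=n_genes,
        stim_effects=stim,
        response_effects=response,
        response_group="case",
        fraction_noisy_probesets=0.2,
    )


def _module_index(params: SimulationParams) -> np.ndarray:
    """Per-gene module index; -1 for unassigned genes."""
    idx = np.full(params.n_genes, -1)
    start = 0
    for m, size in enumerate(params.module_sizes):
        idx[start : start + size] = m
        start += size
    return idx


def generate_dataset(
    params: SimulationParams,
) -> tuple[ProbeMatrix, ExpressionMatrix, SampleSheet, SyntheticTruth]:
    rng = np.random.default_rng(params.seed)
    n_groups = len(params.group_labels)

    # sample layout: per group, subjects in order, (stim, unstim) per subject
    rows = []
    for g, (label, size) in enumerate(zip(params.group_labels, params.group_sizes)):
        for j in range(size):
            subject = f"{label}_s{j + 1:02d}"
            batch = f"b{j % 2 + 1}" if params.batch_shift is not None else None
            for cond, tag in (("stimulated", "stim"), ("unstimulated", "unstim")):
                rows.append(
                    {
                        "sample_id": f"{subject}_{tag}",
                        "subject_id": subject,
                        "group": label,
                        "condition": cond,
                        "batch": batch,
                    }
                )
    sheet_frame = pd.DataFrame(rows)
    n_samples = len(sheet_frame)
    group_of_sample = sheet_frame["group"].to_numpy()
    is_stim = (sheet_frame["condition"] == "stimulated").to_numpy()

    gene_ids = [f"G{i + 1:04d}" for i in range(params.n_genes)]
    mu = rng.normal(params.baseline_mean, params.baseline_sd, params.n_genes)
    delta = (
        params.stim_effects
        if params.stim_effects is not None
        else np.zeros(params.n_genes)
    )
    big_delta = (
        params.response_effects
        if params.response_effects is not None
        else np.zeros(params.n_genes)
    )
    module_idx = _module_index(params)

    x = mu[:, None] + rng.normal(0.0, params.noise_sd, (params.n_genes, n_samples))
    x += np.outer(delta, is_stim)
    in_response_group = group_of_sample == params.response_group
    x += np.outer(big_delta, is_stim & in_response_group)

    if params.n_modules:
        z = rng.normal(0.0, 1.0, (params.n_modules, n_samples))
        # conditional simulation: standardise the latent activity within
        # each (group, condition) stratum so a loading lambda plants the
        # same coexpression strength in every realisation, instead of a
        # chi-square-distributed one that soft-thresholding would amplify
        for label in params.group_labels:
            for cond_stim in (True, False):
                stratum = (group_of_sample == label) & (is_stim == cond_stim)
                if stratum.sum() >= 2:
                    block = z[:, stratum]
                    z[:, stratum] = (
                        block - block.mean(axis=1, keepdims=True)
                    ) / block.std(axis=1, ddof=0, keepdims=True)
        loadings = np.asarray(params.module_loadings)  # modules x groups
        group_idx = np.array(
            [params.group_labels.index(g) for g in group_of_sample]
        )
        lam_sample = loadings[:, group_idx]  # modules x samples
        in_module = module_idx >= 0
        x[in_module] += (lam_sample * z)[module_idx[in_module]]

    if params.batch_shift is not None:
        in_b2 = (sheet_frame["batch"] == "b2").to_numpy()
        x[:, in_b2] += params.batch_shift

    # probe level
    P = params.probes_per_set
    n_noisy = int(round(params.fraction_noisy_probesets * params.n_genes))
    noisy_genes = np.sort(
        rng.choice(params.n_genes, size=n_noisy, replace=False)
    )
    noisy_mask = np.zeros(params.n_genes, dtype=bool)
    noisy_mask[noisy_genes] = True

    offsets = rng.normal(0.0, params.probe_offset_sd, (params.n_genes, P))
    probe_vals = np.repeat(x, P, axis=0)  # (n_genes*P) x samples
    # a noisy set's probes track independent signals, not the shared gene one
    signal_sd = np.sqrt(params.noise_sd**2 + params.probe_noise_sd**2)
    for gi in noisy_genes:
        block = slice(gi * P, (gi + 1) * P)
        probe_vals[block] = mu[gi] + rng.normal(0.0, signal_sd, (P, n_samples))
    clean = ~np.repeat(noisy_mask, P)
    probe_vals[clean] += rng.normal(
        0.0, params.probe_noise_sd, (int(clean.sum()), n_samples)
    )
    probe_vals += offsets.reshape(-1)[:, None]

    probe_ids = [f"{g}_p{k + 1}" for g in gene_ids for k in range(P)]
    probeset_of = pd.Series(np.repeat(gene_ids, P), index=probe_ids)

    sample_ids = list(sheet_frame["sample_id"])
    expr = ExpressionMatrix(pd.DataFrame(x, index=gene_ids, columns=sample_ids))
    probes = ProbeMatrix(
        pd.DataFrame(probe_vals, index=probe_ids, columns=sample_ids), probeset_of
    )
    sheet = SampleSheet(sheet_frame)

    # ground truth
    responsive = np.flatnonzero(delta != 0)
    de_genes = {}
    for label in params.group_labels:
        planted = set(responsive)
        if label == params.response_group:
            planted |= set(np.flatnonzero(big_delta != 0))
        de_genes[label] = [gene_ids[i] for i in sorted(planted)]
    loadings_arr = (
        np.asarray(params.module_loadings)
        if params.n_modules
        else np.zeros((0, n_groups))
    )
    dc_genes = {}
    for a in range(n_groups):
        for b in range(a + 1, n_groups):
            diff_modules = np.flatnonzero(loadings_arr[:, a] != loadings_arr[:, b])
            genes = [
                gene_ids[i]
                for i in np.flatnonzero(np.isin(module_idx, diff_modules))
            ]
            key = f"{params.group_labels[a]}_vs_{params.group_labels[b]}"
            dc_genes[key] = genes
    membership = {
        gene_ids[i]: (f"M{module_idx[i] + 1}" if module_idx[i] >= 0 else "none")
        for i in range(params.n_genes)
    }
    truth = SyntheticTruth(
        de_genes=de_genes,
        differentially_connected_genes=dc_genes,
        module_membership=membership,
        noisy_probesets=[gene_ids[i] for i in noisy_genes],
        params=params,
    )
    return probes, expr, sheet, truth
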