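"""Signed coexpression network construction and module detection.

The signed similarity s_ij = (1 + cor(x_i, x_j)) / 2 maps correlation
[−1, 1] onto [0, 1], so strongly negative correlations approach 0
rather than being folded onto positive ones. Soft-thresholding raises
the similarity to a power β, suppressing weak background similarity;
the topological overlap measure (TOM) then quantifies shared
neighbourhoods, and modules are branches of an average-linkage
dendrogram on 1 − TOM, cut at a fixed height, with undersized clusters
relabelled "grey" and the rest named by the conventional colour order
in decreasing size.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .config import AnalysisConfig
from .diffexpr import DEResult, bh_fdr
from .errors import InputError

log = logging.getLogger(__name__)

#: Conventional module colour order; clusters beyond it get numbered names.
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black",
    "pink", "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white",
)
UNASSIGNED = "grey"


def signed_similarity(expr_subset: np.ndarray) -> np.ndarray:
    """s_ij = (1 + Pearson cor)/2; zero-variance genes get cor 0 (s 0.5)."""
    X = np.asarray(expr_subset, dtype=float)
    if X.ndim != 2 or X.shape[1] < 3:
        raise InputError("similarity needs a genes x samples table with >=3 samples")
    sd = X.std(axis=1)
    flat = sd == 0
    if flat.any():
        log.warning(
            "%d zero-variance gene(s): correlations set to 0", int(flat.sum())
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X)
    corr[np.isnan(corr)] = 0.0
    corr = np.clip(corr, -1.0, 1.0)
    S = (1.0 + corr) / 2.0
    np.fill_diagonal(S, 1.0)
    return S


def soft_adjacency(S: np.ndarray, beta: float) -> np.ndarray:
    """a_ij = s_ij^β off-diagonal, zero diagonal."""
    if beta <= 0:
        raise InputError("soft power beta must be positive")
    A = np.power(S, beta)
    np.fill_diagonal(A, 0.0)
    return A


def tom(A: np.ndarray) -> np.ndarray:
    """Topological overlap: shared-neighbour-weighted closeness in [0, 1]."""
    A = np.asarray(A, dtype=float)
    if not np.allclose(A, A.T):
        raise InputError("adjacency must be symmetric")
    if np.abs(np.diagonal(A)).max(initial=0.0) > 1e-12:
        raise InputError("adjacency must have zero diagonal")
    k = A.sum(axis=1)
    L = A @ A
    denom = np.minimum.outer(k, k) + 1.0 - A
    with np.errstate(invalid="ignore", divide="ignore"):
        T = (L + A) / denom
    T[~np.isfinite(T)] = 0.0
    np.fill_diagonal(T, 1.0)
    return np.clip(T, 0.0, 1.0)


def detect_modules(
    tom_matrix: np.ndarray, config: AnalysisConfig, gene_ids: list[str]
) -> pd.Series:
    """Static-cut module detection on the 1−TOM dendrogram.

    Average linkage; flat clusters at ``tree_cut_height``; clusters below
    ``module_min_size`` become "grey"; the rest are colour-named in
    decreasing size, ties broken by the smallest member gene id.
    """
    n = tom_matrix.shape[0]
    if n < 2:
        raise InputError("module detection needs at least 2 genes")
    if len(gene_ids) != n:
        raise InputError("gene_ids length does not match TOM dimension")
    diss = 1.0 - tom_matrix
    np.fill_diagonal(diss, 0.0)
    Z = linkage(squareform(diss, checks=False), method="average")
    flat = fcluster(Z, t=config.tree_cut_height, criterion="distance")
    labels = pd.Series(UNASSIGNED, index=gene_ids, dtype=object)
    clusters = []
    for cid in np.unique(flat):
        members = [gene_ids[i] for i in np.flatnonzero(flat == cid)]
        if len(members) >= config.module_min_size:
            clusters.append(members)
    clusters.sort(key=lambda m: (-len(m), min(m)))
    for rank, members in enumerate(clusters):
        name = (
            MODULE_COLORS[rank]
            if rank < len(MODULE_COLORS)
            else f"module{rank + 1}"
        )
        labels[members] = name
    log.info("detected %d module(s) among %d genes", len(clusters), n)
    return labels


def connectivity(
    S: np.ndarray, config: AnalysisConfig, basis: str | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene connectivity K and max-scaled connectivity.

    ``basis="similarity"`` sums the raw signed similarity to all other
    genes; ``basis="adjacency"`` (config default) sums the
    soft-thresholded adjacency, which suppresses the constant background
    term and makes scaled connectivity sensitive to structure.
    """
    if S.shape[0] < 2:
        raise InputError("connectivity needs at least 2 genes")
    basis = basis or config.connectivity_basis
    if basis == "similarity":
        K = S.sum(axis=1) - np.diagonal(S)
    elif basis == "adjacency":
        K = soft_adjacency(S, config.soft_power).sum(axis=1)
    else:
        raise InputError(f"unknown connectivity basis {basis!r}")
    kmax = K.max()
    if kmax <= 0:
        log.warning("max connectivity is 0: scaled connectivity degenerate")
        return K, np.zeros_like(K)
    return K, K / kmax


@dataclass
class CoexpressionNetwork:
    """One group's signed network with modules and connectivity."""

    gene_ids: list[str]
    similarity: np.ndarray
    adjacency: np.ndarray
    tom: np.ndarray
    module_labels: pd.Series
    connectivity: np.ndarray
    scaled_connectivity: np.ndarray
    basis: str


def build_network(
    expr_subset: pd.DataFrame, config: AnalysisConfig
) -> CoexpressionNetwork:
    """Full network construction for one group (genes × samples frame)."""
    gene_ids = list(expr_subset.index)
    S = signed_similarity(expr_subset.to_numpy())
    A = soft_adjacency(S, config.soft_power)
    T = tom(A)
    labels = detect_modules(T, config, gene_ids)
    K, Ks = connectivity(S, config)
    return CoexpressionNetwork(gene_ids, S, A, T, labels, K, Ks, config.connectivity_basis)


def module_de_enrichment(labels: pd.Series, de: DEResult) -> pd.DataFrame:
    """Module-by-module enrichment of differential expression.

    For each module, exports n, the median −log10 p of its genes, a
    one-sided rank-sum p against all other genes (are the module's
    p-values smaller than the rest?), and a BH q across modules.
    """
    if set(labels.index) != set(de.table.index):
        raise InputError("module labels and DE results cover different genes")
    neglog = -np.log10(np.clip(de.table["p"].reindex(labels.index), 1e-300, None))
    rows = []
    for module in sorted(labels.unique()):
        mask = (labels == module).to_numpy()
        inside, outside = neglog[mask], neglog[~mask]
        if mask.sum() < 2 or (~mask).sum() < 1:
            log.warning("module %r too small for enrichment test; skipped", module)
            continue
        stat, p = stats.mannwhitneyu(inside, outside, alternative="greater")
        rows.append(
            {
                "module": module,
                "n": int(mask.sum()),
                "median_neglog10_p": float(np.median(inside)),
                "enrichment_p": float(p),
            }
        )
    out = pd.DataFrame(rows).set_index("module")
    if not out.empty:
        out["q"] = bh_fdr(list(out["enrichment_p"]))
    return out
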