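"""Differential expression on the paired stimulation design.

Within-group comparisons use the paired t-test, computed as a
one-sample t on per-subject log2 ratios (stimulated − unstimulated).
Between-group comparisons of the response use an unpaired two-sample t
on the log-ratios (pooled variance by default, Welch optional).
Multiple testing is controlled by Benjamini–Hochberg FDR.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .config import AnalysisConfig
from .errors import InputError
from .model import ExpressionMatrix, SampleSheet

log = logging.getLogger(__name__)


@dataclass
class LogRatioMatrix:
    """Per-subject response: log2(stimulated) − log2(unstimulated)."""

    data: pd.DataFrame  # genes x subjects
    groups: pd.Series  # subject -> group label

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def subject_ids(self) -> list[str]:
        return list(self.data.columns)

    def subjects_of_group(self, group: str) -> list[str]:
        subjects = list(self.groups.index[self.groups == group])
        if not subjects:
            raise InputError(f"no paired subjects in group {group!r}")
        return subjects


@dataclass
class DEResult:
    """Per-gene effect/t/p/q table plus up/down counts at the FDR level."""

    table: pd.DataFrame  # index gene: effect, t, df, p, q, degenerate
    alpha: float

    @property
    def n_up(self) -> int:
        t = self.table
        return int(((t["q"] < self.alpha) & (t["effect"] > 0)).sum())

    @property
    def n_down(self) -> int:
        t = self.table
        return int(((t["q"] < self.alpha) & (t["effect"] < 0)).sum())


def compute_log_ratios(expr: ExpressionMatrix, sheet: SampleSheet) -> LogRatioMatrix:
    pairs = sheet.pairs()
    if pairs.empty:
        raise InputError("no paired subjects: log ratios undefined")
    unpaired = sheet.unpaired_subjects()
    if unpaired:
        log.warning("skipping unpaired subjects: %s", ", ".join(map(str, unpaired)))
    missing = [
        s
        for s in pd.concat([pairs["stimulated"], pairs["unstimulated"]])
        if s not in expr.data.columns
    ]
    if missing:
        raise InputError(f"paired samples absent from expression matrix: {missing[:5]}")
    stim = expr.data[list(pairs["stimulated"])].to_numpy()
    unstim = expr.data[list(pairs["unstimulated"])].to_numpy()
    data = pd.DataFrame(
        stim - unstim, index=expr.data.index, columns=list(pairs["subject_id"])
    )
    groups = pd.Series(list(pairs["group"]), index=list(pairs["subject_id"]))
    return LogRatioMatrix(data, groups)


def _one_sample_t(diffs: np.ndarray) -> pd.DataFrame:
    """Vectorised one-sample t across gene rows of a differences table."""
    n = diffs.shape[1]
    df = n - 1
    effect = diffs.mean(axis=1)
    sd = diffs.std(axis=1, ddof=1)
    degenerate = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = effect / (sd / np.sqrt(n))
    p = 2 * stats.t.sf(np.abs(t), df)
    t = np.where(degenerate, np.nan, t)
    p = np.where(degenerate, 1.0, p)
    return pd.DataFrame(
        {"effect": effect, "t": t, "df": float(df), "p": p, "degenerate": degenerate}
    )


def paired_de(
    expr: ExpressionMatrix,
    sheet: SampleSheet,
    group: str,
    config: AnalysisConfig,
) -> DEResult:
    """Paired stimulated-vs-unstimulated comparison within one group."""
    ratios = compute_log_ratios(expr, sheet)
    subjects = ratios.subjects_of_group(group)
    if len(subjects) < 3:
        raise InputError(f"group {group!r} has fewer than 3 paired subjects")
    table = _one_sample_t(ratios.data[subjects].to_numpy())
    table.index = ratios.data.index
    table["q"] = bh_fdr(list(table["p"]))
    return DEResult(table, config.fdr_alpha)


def _two_sample_t(
    a: np.ndarray, b: np.ndarray, welch: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n1, n2 = a.shape[1], b.shape[1]
    m1, m2 = a.mean(axis=1), b.mean(axis=1)
    v1, v2 = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    if welch:
        se2 = v1 / n1 + v2 / n2
        with np.errstate(divide="ignore", invalid="ignore"):
            df = se2**2 / (
                (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
            )
    else:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se2 = sp2 * (1 / n1 + 1 / n2)
        df = np.full(a.shape[0], float(n1 + n2 - 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(se2)
    return t, df, m1 - m2


def unpaired_de(
    ratios: LogRatioMatrix,
    group_a: str,
    group_b: str,
    config: AnalysisConfig,
) -> DEResult:
    """Two-sample comparison of log-ratio responses between groups."""
    sa = ratios.subjects_of_group(group_a)
    sb = ratios.subjects_of_group(group_b)
    if len(sa) < 2 or len(sb) < 2:
        raise InputError("both groups need at least 2 paired subjects")
    a = ratios.data[sa].to_numpy()
    b = ratios.data[sb].to_numpy()
    t, df, effect = _two_sample_t(a, b, config.welch)
    # zero pooled variance with zero effect leaves t as 0/0: call it 0, p = 1
    degenerate = np.isnan(t)
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate, 1.0, 2 * stats.t.sf(np.abs(t), df))
    table = pd.DataFrame(
        {"effect": effect, "t": t, "df": df, "p": p, "degenerate": degenerate},
        index=ratios.data.index,
    )
    table["q"] = bh_fdr(list(table["p"]))
    return DEResult(table, config.fdr_alpha)


def bh_fdr(pvalues: list[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values (monotone, order-stable)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise InputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class PCAResult:
    scores: pd.DataFrame  # subjects x components
    explained_variance_ratio: np.ndarray
    groups: pd.Series


def pca_scores(ratios: LogRatioMatrix, n_components: int = 2) -> PCAResult:
    """PCA of per-subject responses (genes centred, not standardised)."""
    n_subj, n_genes = len(ratios.subject_ids), len(ratios.gene_ids)
    if n_subj < 2:
        raise InputError("PCA needs at least 2 subjects")
    if n_components > min(n_subj, n_genes):
        raise InputError(
            f"n_components={n_components} exceeds min(dims)={min(n_subj, n_genes)}"
        )
    X = ratios.data.to_numpy().T  # subjects x genes
    X = X - X.mean(axis=0)
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return PCAResult(
        pd.DataFrame(scores, index=ratios.subject_ids, columns=cols),
        pca.explained_variance_ratio_,
        ratios.groups,
    )
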