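"""Cohort comparison statistics for the clinical characteristics table.

Prevalence rows (a positive/negative split per clinical group) are
compared across groups by Pearson chi-square; continuous measures by
tie-corrected Kruskal–Wallis. When the overall test is significant,
pairwise post-hoc comparisons with multiplicity adjustment are
summarised as a compact letter display: groups sharing a letter do not
differ significantly at the chosen level. Published tables print
percentages rather than counts, so ``percent_to_count`` reconstructs
the underlying integers and guards against rows whose denominator is
not the stated group size.
"""
from __future__ import annotations

import string
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DenominatorMismatchError, InputError

#: Reconstruction guard: reconstructed percentage must match the printed
#: one within this many percentage points.
PCT_TOLERANCE = 0.05


@dataclass
class ContingencyTable:
    """r × c counts with group rows and category columns."""

    counts: np.ndarray
    group_labels: list[str]
    category_labels: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise InputError("contingency counts must be 2-dimensional")
        r, c = self.counts.shape
        if r < 2 or c < 2:
            raise InputError("contingency table needs >=2 rows and >=2 columns")
        if len(self.group_labels) != r or len(self.category_labels) != c:
            raise InputError("label lengths do not match table shape")
        if (self.counts < 0).any():
            raise InputError("counts must be non-negative")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise InputError("counts must be integers")
            self.counts = np.round(self.counts).astype(int)

    @classmethod
    def from_prevalence(
        cls, positives: list[int], totals: list[int], group_labels: list[str] | None = None
    ) -> "ContingencyTable":
        """Positive/negative table from per-group positive counts and ns."""
        if len(positives) != len(totals):
            raise InputError("positives and totals lengths differ")
        counts = np.array([[p, n - p] for p, n in zip(positives, totals)])
        if (counts < 0).any():
            raise InputError("positive count exceeds group total")
        labels = group_labels or [f"group{i + 1}" for i in range(len(totals))]
        return cls(counts, labels, ["positive", "negative"])


@dataclass
class GroupComparisonResult:
    statistic: float
    df: int
    p: float
    method: str
    pairwise: pd.DataFrame | None = None
    letters: dict[str, str] | None = None
    degenerate: bool = False
    extras: dict = field(default_factory=dict)


def percent_to_count(pct: float, n: int) -> int:
    """Integer count whose percentage of n rounds to the printed value.

    Rounds half away from zero and raises
    :class:`DenominatorMismatchError` when no integer count reproduces
    the printed percentage within 0.05 points — the signature of a row
    whose denominator differs from the stated group size (e.g. missing
    data).
    """
    if not 0 <= pct <= 100:
        raise InputError(f"percentage {pct} outside [0, 100]")
    if n < 1:
        raise InputError(f"group size must be positive, got {n}")
    count = int(np.floor(pct / 100 * n + 0.5))
    if abs(100 * count / n - pct) > PCT_TOLERANCE:
        raise DenominatorMismatchError(
            f"{pct}% of n={n} is not near an integer count "
            f"(closest: {count} -> {100 * count / n:.2f}%)"
        )
    return count


def chisq_test(table: ContingencyTable, yates: bool = False) -> GroupComparisonResult:
    """Pearson chi-square on an r × c table.

    Yates continuity correction is applied only when requested and the
    table is 2×2; multi-group tables are always uncorrected.
    """
    counts = table.counts
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise InputError("contingency table has a zero margin")
    correction = bool(yates) and counts.shape == (2, 2)
    stat, p, df, _ = stats.chi2_contingency(counts, correction=correction)
    return GroupComparisonResult(
        statistic=float(stat),
        df=int(df),
        p=float(p),
        method="chi-square" + (" (Yates)" if correction else ""),
    )


def kruskal_wallis(groups: list[list[float]]) -> GroupComparisonResult:
    """Tie-corrected Kruskal–Wallis H with a chi-square reference."""
    if len(groups) < 2:
        raise InputError("Kruskal-Wallis needs at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 1 for a in arrays):
        raise InputError("every group needs at least one value")
    total = sum(a.size for a in arrays)
    if total < 3:
        raise InputError("Kruskal-Wallis needs at least 3 values in total")
    df = len(arrays) - 1
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return GroupComparisonResult(
            statistic=0.0, df=df, p=1.0, method="kruskal-wallis", degenerate=True
        )
    stat, p = stats.kruskal(*arrays)
    return GroupComparisonResult(
        statistic=float(stat), df=df, p=float(p), method="kruskal-wallis"
    )


def _pairwise_p(
    groups, test: str
) -> tuple[list[tuple[int, int]], list[float]]:
    idx_pairs, pvals = [], []
    k = len(groups)
    for i in range(k):
        for j in range(i + 1, k):
            if test == "chi-square":
                sub = np.array([groups[i], groups[j]])
                if (sub.sum(axis=0) == 0).any():
                    # a category absent from both groups: no evidence of difference
                    p = 1.0
                else:
                    _, p, _, _ = stats.chi2_contingency(sub, correction=False)
            elif test == "rank-sum":
                a, b = np.asarray(groups[i]), np.asarray(groups[j])
                if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
                    p = 1.0
                else:
                    _, p = stats.mannwhitneyu(a, b, alternative="two-sided")
            else:
                raise InputError(f"unknown pairwise test {test!r}")
            idx_pairs.append((i, j))
            pvals.append(float(p))
    return idx_pairs, pvals


def pairwise_letters(
    groups,
    test: str = "rank-sum",
    alpha: float = 0.05,
    adjust: str = "bonferroni",
    group_labels: list[str] | None = None,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Compact letter display from adjusted pairwise comparisons.

    ``groups`` is a list of per-group value arrays (rank-sum) or
    per-group count vectors such as (positive, negative) (chi-square).
    Two groups share a letter iff their adjusted p >= alpha; overlap
    classes like "a,b" arise when a middle group differs from neither
    extreme while the extremes differ from each other. Letters are the
    maximal cliques of the "not significantly different" graph.
    """
    k = len(groups)
    if k < 2:
        raise InputError("letters need at least 2 groups")
    labels = group_labels or [f"group{i + 1}" for i in range(k)]
    if len(labels) != k:
        raise InputError("group_labels length does not match groups")
    idx_pairs, pvals = _pairwise_p(groups, test)
    adjusted = multipletests(pvals, method=adjust)[1]

    graph = nx.Graph()
    graph.add_nodes_from(range(k))
    for (i, j), p_adj in zip(idx_pairs, adjusted):
        if p_adj >= alpha:
            graph.add_edge(i, j)
    cliques = sorted(nx.find_cliques(graph), key=min)
    letters: dict[str, list[str]] = {lab: [] for lab in labels}
    for letter, clique in zip(string.ascii_lowercase, cliques):
        for i in sorted(clique):
            letters[labels[i]].append(letter)
    letter_map = {lab: ",".join(sorted(ls)) for lab, ls in letters.items()}

    pairwise = pd.DataFrame(
        {
            "group_a": [labels[i] for i, _ in idx_pairs],
            "group_b": [labels[j] for _, j in idx_pairs],
            "p": pvals,
            "p_adjusted": adjusted,
            "significant": adjusted < alpha,
        }
    )
    return letter_map, pairwise


def compare_prevalence(
    percentages: list[float],
    totals: list[int],
    group_labels: list[str] | None = None,
    alpha: float = 0.05,
    adjust: str = "bonferroni",
) -> GroupComparisonResult:
    """Full prevalence-row analysis from printed percentages.

    Reconstructs counts, runs the overall chi-square, and — when the
    overall p < alpha — adds pairwise letters.
    """
    positives = [percent_to_count(p, n) for p, n in zip(percentages, totals)]
    table = ContingencyTable.from_prevalence(positives, totals, group_labels)
    result = chisq_test(table)
    if result.p < alpha:
        rows = [list(r) for r in table.counts]
        letter_map, pairwise = pairwise_letters(
            rows, test="chi-square", alpha=alpha, adjust=adjust,
            group_labels=table.group_labels,
        )
        result.letters = letter_map
        result.pairwise = pairwise
    result.extras["counts"] = positives
    return result
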