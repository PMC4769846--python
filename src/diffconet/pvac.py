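"""Probe-set quality filtering by PVAC and probe-to-gene summarisation.

PVAC — the proportion of variation accounted for by the first principal
component of a probe set — scores how consistently the independent
probes of a set track a common signal. A set measuring real expression
has strongly correlated probes (PVAC near 1); a set measuring background
has independent probes (PVAC near 1/P). Scoring is done separately per
clinical group; a probe set is retained if it reaches the threshold in
at least one group.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .errors import DegenerateDataError, InputError
from .model import ExpressionMatrix, ProbeMatrix, SampleSheet

log = logging.getLogger(__name__)


@dataclass
class PvacReport:
    """Per-(probeset, group) scores and the retention decision."""

    scores: pd.DataFrame  # probesets x groups
    passed: pd.Series  # probeset -> bool
    retained: list[str]
    threshold: float

    def __post_init__(self) -> None:
        vals = self.scores.to_numpy()
        finite = vals[np.isfinite(vals)]
        assert ((finite >= 0) & (finite <= 1 + 1e-12)).all()


def pvac_score(probeset_values: np.ndarray) -> float:
    """PC1 variance fraction of the probe correlation matrix.

    Rows are probes, columns samples. Each probe is standardised across
    samples, so the score is invariant to per-probe affine rescaling.
    Zero-variance probes are dropped with a warning; a set left with no
    informative probe raises :class:`DegenerateDataError`. A single-probe
    set scores 1.0 (PC1 of one variable is all of its variance), with a
    warning that PVAC is uninformative there.
    """
    values = np.asarray(probeset_values, dtype=float)
    if values.ndim != 2 or values.shape[0] < 1:
        raise InputError("probeset values must be a probes x samples table")
    if values.shape[1] < 3:
        raise InputError("PVAC needs at least 3 samples")
    sd = values.std(axis=1)
    if (sd == 0).any():
        log.warning("dropping %d zero-variance probe(s)", int((sd == 0).sum()))
        values = values[sd > 0]
    if values.shape[0] == 0:
        raise DegenerateDataError("probe set has no probe with nonzero variance")
    if values.shape[0] == 1:
        log.warning("single-probe set: PVAC is uninformative, scoring 1.0")
        return 1.0
    corr = np.corrcoef(values)
    top = np.linalg.eigvalsh(corr)[-1]
    return float(min(max(top / values.shape[0], 0.0), 1.0))


def filter_probesets(
    probes: ProbeMatrix, sheet: SampleSheet, config: AnalysisConfig
) -> PvacReport:
    """Score every probe set within each clinical group (both conditions
    pooled) and retain sets reaching the threshold in >=1 group."""
    missing = [s for s in probes.sample_ids if s not in set(sheet.sample_ids)]
    if missing:
        raise InputError(f"probe matrix samples absent from sample sheet: {missing[:5]}")
    groups = sheet.groups
    group_samples: dict[str, list[str]] = {}
    for group in groups:
        samples = [s for s in sheet.samples_of_group(group) if s in probes.data.columns]
        if len(samples) < 3:
            raise InputError(f"group {group!r} has fewer than 3 samples with probe data")
        group_samples[group] = samples

    probesets = probes.probeset_ids()
    arr = probes.data.to_numpy()
    set_of = probes.probeset_of[probes.data.index].to_numpy()
    group_cols = {
        g: probes.data.columns.get_indexer(samples)
        for g, samples in group_samples.items()
    }
    out = np.empty((len(probesets), len(groups)))
    for i, ps in enumerate(probesets):
        block = arr[set_of == ps]
        for j, group in enumerate(groups):
            out[i, j] = pvac_score(block[:, group_cols[group]])
    scores = pd.DataFrame(out, index=probesets, columns=groups)
    passed = (scores >= config.pvac_threshold).any(axis=1)
    retained = list(scores.index[passed])
    log.info(
        "PVAC: %d/%d probe sets retained at threshold %.2f",
        len(retained), len(probesets), config.pvac_threshold,
    )
    return PvacReport(scores, passed, retained, config.pvac_threshold)


def summarize_probesets(probes: ProbeMatrix, retained: list[str]) -> ExpressionMatrix:
    """Collapse retained probe sets to one gene-level value per sample.

    Each probe is centred across samples (removing its fixed offset),
    probes of a set are averaged, and the probe set's grand mean is added
    back to restore the log2 scale.
    """
    if not retained:
        raise InputError("retained probeset list is empty")
    known = set(probes.probeset_of)
    unknown = [ps for ps in retained if ps not in known]
    if unknown:
        raise InputError(f"retained probesets absent from probe matrix: {unknown[:5]}")
    values = probes.data.to_numpy()
    set_of = probes.probeset_of[probes.data.index].to_numpy()
    out = np.empty((len(retained), values.shape[1]))
    for i, ps in enumerate(retained):
        block = values[set_of == ps]
        centered = block - block.mean(axis=1, keepdims=True)
        out[i] = centered.mean(axis=0) + block.mean()
    frame = pd.DataFrame(out, index=retained, columns=probes.data.columns)
    return ExpressionMatrix(frame)
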