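"""Core data containers.

Expression data live in pandas DataFrames (genes in rows, samples in
columns, log2 scale) wrapped in thin validating dataclasses. The sample
sheet carries the paired stimulated/unstimulated design that every
downstream contrast relies on.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import InputError

CONDITIONS = ("stimulated", "unstimulated")

#: Sign value for gene-set members without an annotated direction.
SIGN_UNSPECIFIED = 0


def _require_unique(values: Iterable, what: str) -> None:
    seen = set()
    for v in values:
        if v in seen:
            raise InputError(f"duplicate {what}: {v!r}")
        seen.add(v)


def _require_finite(frame: pd.DataFrame, what: str) -> None:
    arr = frame.to_numpy()
    if not np.isfinite(arr).all():
        i, j = np.argwhere(~np.isfinite(arr))[0]
        raise InputError(
            f"non-finite value in {what} at row {frame.index[i]!r}, "
            f"column {frame.columns[j]!r}"
        )


@dataclass
class ExpressionMatrix:
    """Log2 expression values, genes × samples."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _require_unique(self.data.index, "gene id")
        _require_unique(self.data.columns, "sample id")
        self.data = self.data.astype(float)
        _require_finite(self.data, "expression matrix")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def subset_samples(self, samples: Iterable[str]) -> "ExpressionMatrix":
        samples = list(samples)
        missing = [s for s in samples if s not in self.data.columns]
        if missing:
            raise InputError(f"samples absent from expression matrix: {missing}")
        return ExpressionMatrix(self.data[samples])


@dataclass
class ProbeMatrix:
    """Probe-level intensities plus the probe → probe-set mapping."""

    data: pd.DataFrame
    probeset_of: pd.Series  # index: probe_id, value: probeset_id

    def __post_init__(self) -> None:
        _require_unique(self.data.index, "probe id")
        _require_unique(self.data.columns, "sample id")
        self.data = self.data.astype(float)
        _require_finite(self.data, "probe matrix")
        self.probeset_of = pd.Series(self.probeset_of)
        unmapped = [p for p in self.data.index if p not in self.probeset_of.index]
        if unmapped:
            raise InputError(f"probes without a probeset assignment: {unmapped[:5]}")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def probeset_ids(self) -> list[str]:
        """Probe-set ids in order of first appearance."""
        return list(dict.fromkeys(self.probeset_of[self.data.index]))

    def probes_in(self, probeset_id: str) -> list[str]:
        mask = self.probeset_of[self.data.index] == probeset_id
        return list(self.data.index[mask.to_numpy()])


@dataclass
class SampleSheet:
    """Per-sample annotations defining pairing and group contrasts.

    Columns: sample_id, subject_id, group, condition, batch (optional).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["sample_id", "subject_id", "group", "condition"]
        missing = [c for c in required if c not in self.frame.columns]
        if missing:
            raise InputError(f"sample sheet missing columns: {missing}")
        if "batch" not in self.frame.columns:
            self.frame = self.frame.assign(batch=pd.NA)
        self.frame = self.frame.reset_index(drop=True)
        _require_unique(self.frame["sample_id"], "sample id")
        bad = set(self.frame["condition"]) - set(CONDITIONS)
        if bad:
            raise InputError(
                f"unknown condition labels {sorted(bad)}; expected {CONDITIONS}"
            )
        pairs = list(zip(self.frame["subject_id"], self.frame["condition"]))
        _require_unique(pairs, "(subject, condition) pair")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    @property
    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.frame["group"]))

    def samples_of_group(self, group: str) -> list[str]:
        sel = self.frame[self.frame["group"] == group]
        if sel.empty:
            raise InputError(f"unknown group {group!r}")
        return list(sel["sample_id"])

    def pairs(self, group: str | None = None) -> pd.DataFrame:
        """One row per paired subject: subject_id, group, stimulated,
        unstimulated (sample ids). Unpaired subjects are excluded."""
        frame = self.frame
        if group is not None:
            frame = frame[frame["group"] == group]
        wide = frame.pivot_table(
            index=["subject_id", "group"],
            columns="condition",
            values="sample_id",
            aggfunc="first",
        ).reset_index()
        for cond in CONDITIONS:
            if cond not in wide.columns:
                wide[cond] = pd.NA
        paired = wide.dropna(subset=list(CONDITIONS))
        return paired[["subject_id", "group", "stimulated", "unstimulated"]]

    def unpaired_subjects(self) -> list[str]:
        counts = self.frame.groupby("subject_id")["condition"].nunique()
        return list(counts.index[counts < 2])


@dataclass
class GeneSetCollection:
    """Named gene sets; each member carries a sign (+1, −1, or 0 for
    unspecified). Signed sets act as regulons for activation scoring."""

    sets: dict[str, dict[str, int]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            for gene, sign in members.items():
                if sign not in (-1, SIGN_UNSPECIFIED, 1):
                    raise InputError(
                        f"set {name!r}: invalid sign {sign!r} for {gene!r}"
                    )

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> dict[str, int]:
        return self.sets[name]

    def items(self):
        return self.sets.items()

    def members(self, name: str) -> set[str]:
        return set(self.sets[name])
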