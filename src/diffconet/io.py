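"""Readers and writers for the pipeline's text formats.

Expression and probe matrices are tab-separated, genes/probes in rows,
a header row of sample ids, first column holding identifiers. Gene sets
use standard GMT, optionally with the signed dialect ``GENE|+1`` /
``GENE|-1`` marking the expected direction of regulation.
"""
from __future__ import annotations

from pathlib import Path

import pandas as pd

from .errors import InputError
from .model import SIGN_UNSPECIFIED, ExpressionMatrix, GeneSetCollection, ProbeMatrix, SampleSheet


def _read_table(path, what: str, index_name: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputError(f"{what} file not found: {path}")
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    dup = frame.index[frame.index.duplicated()]
    if len(dup):
        raise InputError(f"duplicate {index_name} in {path}: {dup[0]!r}")
    dupc = frame.columns[frame.columns.duplicated()]
    if len(dupc):
        raise InputError(f"duplicate sample id in {path}: {dupc[0]!r}")
    return frame


def _to_float(frame: pd.DataFrame, path) -> pd.DataFrame:
    try:
        return frame.astype(float)
    except ValueError:
        for col in frame.columns:
            converted = pd.to_numeric(frame[col], errors="coerce")
            bad = converted.isna() & frame[col].notna()
            if bad.any():
                row = frame.index[bad.to_numpy()][0]
                raise InputError(
                    f"non-numeric value {frame.loc[row, col]!r} in {path} "
                    f"at row {row!r}, column {col!r}"
                ) from None
        raise


def read_expression(path) -> ExpressionMatrix:
    frame = _read_table(path, "expression", "gene id")
    return ExpressionMatrix(_to_float(frame, path))


def write_expression(expr: ExpressionMatrix, path) -> None:
    out = expr.data.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format="%.10g")


def read_probes(path) -> ProbeMatrix:
    """Probe matrix TSV: columns probe_id, probeset_id, then samples."""
    frame = _read_table(path, "probe matrix", "probe id")
    if "probeset_id" not in frame.columns:
        raise InputError(f"probe matrix {path} lacks a 'probeset_id' column")
    mapping = frame["probeset_id"]
    values = _to_float(frame.drop(columns="probeset_id"), path)
    return ProbeMatrix(values, mapping)


def write_probes(probes: ProbeMatrix, path) -> None:
    out = probes.data.copy()
    out.insert(0, "probeset_id", probes.probeset_of[out.index])
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t", float_format="%.10g")


def read_sample_sheet(path) -> SampleSheet:
    path = Path(path)
    if not path.exists():
        raise InputError(f"sample sheet not found: {path}")
    frame = pd.read_csv(path, sep="\t", dtype=str)
    return SampleSheet(frame)


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    sheet.frame.to_csv(path, sep="\t", index=False)


def read_gmt(path) -> GeneSetCollection:
    """Parse standard or signed GMT.

    Signed member tokens are split on the last ``|``; the suffix must be
    ``+1`` or ``-1``. Members without a pipe get sign "unspecified".
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"GMT file not found: {path}")
    sets: dict[str, dict[str, int]] = {}
    descriptions: dict[str, str] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise InputError(
                f"{path}:{lineno}: GMT line needs >=3 tab-separated fields"
            )
        name, desc, *tokens = fields
        if name in sets:
            raise InputError(f"{path}:{lineno}: duplicate set name {name!r}")
        members: dict[str, int] = {}
        for token in tokens:
            if not token:
                continue
            if "|" in token:
                gene, _, sign_token = token.rpartition("|")
                if sign_token not in ("+1", "-1"):
                    raise InputError(
                        f"{path}:{lineno}: bad sign token {sign_token!r} "
                        f"in {token!r} (expected +1 or -1)"
                    )
                sign = 1 if sign_token == "+1" else -1
            else:
                gene, sign = token, SIGN_UNSPECIFIED
            if gene in members:
                raise InputError(
                    f"{path}:{lineno}: duplicate member {gene!r} in set {name!r}"
                )
            members[gene] = sign
        sets[name] = members
        descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    lines = []
    for name, members in collection.items():
        desc = collection.descriptions.get(name, "")
        tokens = [
            gene if sign == SIGN_UNSPECIFIED else f"{gene}|{sign:+d}"
            for gene, sign in members.items()
        ]
        lines.append("\t".join([name, desc, *tokens]))
    Path(path).write_text("\n".join(lines) + "\n")
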