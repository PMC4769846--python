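"""Upstream-regulator statistics and gene-set over-representation.

Two regulator statistics are computed against user-supplied (signed)
gene sets: the overlap p-value — a hypergeometric upper tail measuring
enrichment of a regulator's targets among the differentially expressed
genes — and the activation Z-score, an unweighted pattern-match between
each target's predicted direction and its observed up/down call:

    Z = (n_agree − n_disagree) / sqrt(n_agree + n_disagree)

|Z| > 2 (strict) is flagged significant. Members without an annotated
sign contribute to the overlap test but not to Z.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom

from .config import AnalysisConfig
from .diffexpr import DEResult, bh_fdr
from .errors import InputError
from .model import SIGN_UNSPECIFIED, GeneSetCollection

log = logging.getLogger(__name__)

Z_SIGNIFICANT = 2.0


def hypergeom_enrichment(
    query: set[str], universe: set[str], sets: GeneSetCollection
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation per gene set.

    Sets are intersected with the universe before testing; sets disjoint
    from the universe are skipped with a warning.
    """
    query, universe = set(query), set(universe)
    offenders = query - universe
    if offenders:
        raise InputError(
            f"query genes absent from universe: {sorted(offenders)[:10]}"
        )
    M, N = len(universe), len(query)
    rows = []
    for name, members in sets.items():
        in_universe = set(members) & universe
        if not in_universe:
            log.warning("set %r disjoint from universe; skipped", name)
            continue
        K = len(in_universe)
        k = len(in_universe & query)
        p = float(hypergeom.sf(k - 1, M, K, N))
        rows.append(
            {"set": name, "set_size_in_universe": K, "overlap": k, "p": p}
        )
    out = pd.DataFrame(rows)
    if not out.empty:
        out = out.set_index("set")
        out["q"] = bh_fdr(list(out["p"]))
    return out


@dataclass
class RegulatorScore:
    regulator: str
    n_targets_in_universe: int
    n_overlap: int
    overlap_p: float | None
    n_agree: int
    n_disagree: int
    activation_z: float | None
    significant: bool

    def __post_init__(self) -> None:
        # scorable (signed) members are a subset of the overlapping targets
        assert self.n_agree + self.n_disagree <= self.n_overlap


def activation_zscore(
    regulon: dict[str, int],
    observed: dict[str, str],
    name: str = "regulon",
) -> RegulatorScore:
    """Activation Z for one signed regulon given up/down direction calls.

    ``observed`` maps gene → "up"/"down" for genes with a direction call
    (typically significant DE genes). Predicted +1 targets agree when
    called up; −1 targets agree when called down.
    """
    if not any(s != SIGN_UNSPECIFIED for s in regulon.values()):
        raise InputError(f"regulon {name!r} has no signed member")
    bad = {d for d in observed.values() if d not in ("up", "down")}
    if bad:
        raise InputError(f"direction calls must be 'up'/'down', got {sorted(bad)}")
    n_agree = n_disagree = 0
    for gene, sign in regulon.items():
        if sign == SIGN_UNSPECIFIED or gene not in observed:
            continue
        observed_sign = 1 if observed[gene] == "up" else -1
        if observed_sign == sign:
            n_agree += 1
        else:
            n_disagree += 1
    n = n_agree + n_disagree
    overlap = sum(1 for g in regulon if g in observed)
    if n == 0:
        log.warning("regulon %r has no scorable member; Z not applicable", name)
        z, significant = None, False
    else:
        z = (n_agree - n_disagree) / math.sqrt(n)
        significant = abs(z) > Z_SIGNIFICANT
    return RegulatorScore(
        regulator=name,
        n_targets_in_universe=len(regulon),
        n_overlap=overlap,
        overlap_p=None,
        n_agree=n_agree,
        n_disagree=n_disagree,
        activation_z=z,
        significant=significant,
    )


def direction_calls(
    de: DEResult, config: AnalysisConfig, use_q: bool = True
) -> dict[str, str]:
    """Up/down calls for genes significant at the FDR (or raw-p) level."""
    table = de.table
    sig = (table["q"] if use_q else table["p"]) < config.fdr_alpha
    calls = {}
    for gene in table.index[sig & (table["effect"] != 0)]:
        calls[gene] = "up" if table.loc[gene, "effect"] > 0 else "down"
    return calls


def score_regulators(
    de: DEResult, sets: GeneSetCollection, config: AnalysisConfig, use_q: bool = True
) -> pd.DataFrame:
    """Overlap p (vs the DE gene list) and activation Z per regulon."""
    universe = set(de.table.index)
    calls = direction_calls(de, config, use_q=use_q)
    query = set(calls)
    overlap = hypergeom_enrichment(query, universe, sets)
    rows = []
    for name, members in sets.items():
        if name not in overlap.index:
            continue
        members_in_universe = {g: s for g, s in members.items() if g in universe}
        signed = any(s != SIGN_UNSPECIFIED for s in members_in_universe.values())
        if signed:
            score = activation_zscore(members_in_universe, calls, name=name)
            z, sig, na, nd = (
                score.activation_z, score.significant, score.n_agree, score.n_disagree
            )
        else:
            z, sig, na, nd = None, False, 0, 0
        rows.append(
            {
                "regulator": name,
                "n_targets_in_universe": int(overlap.loc[name, "set_size_in_universe"]),
                "n_overlap": int(overlap.loc[name, "overlap"]),
                "overlap_p": float(overlap.loc[name, "p"]),
                "overlap_q": float(overlap.loc[name, "q"]),
                "n_agree": na,
                "n_disagree": nd,
                "activation_z": z,
                "significant": sig,
            }
        )
    return pd.DataFrame(rows).set_index("regulator")
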