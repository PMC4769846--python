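"""End-to-end pipeline orchestration.

Stage order: PVAC filtering → probe-to-gene summarisation → paired DE
per group → log-ratios → unpaired DE (case vs control) → per-group
signed networks → differential network sectoring with permutation null
→ optional regulator enrichment. Each stage logs its start, input
dimensions and item counts to standard error; results go to files and
the returned summary only. A fixed config (including the seed) makes
the numeric outputs byte-identical across runs.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import io
from .config import AnalysisConfig
from .coexpression import build_network, module_de_enrichment
from .diffexpr import compute_log_ratios, paired_de, pca_scores, unpaired_de
from .diffnet import permutation_test
from .enrichment import score_regulators
from .errors import InputError, PipelineStageError
from .model import ExpressionMatrix, GeneSetCollection, ProbeMatrix, SampleSheet
from .pvac import filter_probesets, summarize_probesets

log = logging.getLogger(__name__)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            log.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except Exception as exc:  # noqa: BLE001 - rewrapped with stage name
                raise PipelineStageError(name, exc) from exc
            log.info("stage %s: done", name)
            return out

        return wrapped

    return deco


def _validate_inputs(
    expr_samples: list[str], sheet: SampleSheet
) -> None:
    matrix_samples = set(expr_samples)
    missing = [s for s in sheet.sample_ids if s not in matrix_samples]
    if missing:
        raise InputError(
            f"sample sheet references samples absent from the matrix: {missing[:5]}"
        )


def run_pipeline(
    config: AnalysisConfig,
    sheet: SampleSheet,
    probes: ProbeMatrix | None = None,
    expression: ExpressionMatrix | None = None,
    gene_sets: GeneSetCollection | None = None,
    outdir: str | Path | None = None,
) -> dict:
    """Run all stages; returns (and optionally writes) a JSON-able summary.

    Provide either a probe matrix (PVAC filtering and summarisation run
    first) or a gene-level expression matrix. The diffnet contrast uses
    ``config.case_group`` / ``config.control_group``; unset, they default
    to the first two groups in the sheet.
    """
    if probes is None and expression is None:
        raise InputError("either a probe matrix or an expression matrix is required")
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config": config.to_dict(), "stages": {}}

    if probes is not None:
        _validate_inputs(probes.sample_ids, sheet)

        @_stage("pvac")
        def run_pvac():
            report = filter_probesets(probes, sheet, config)
            if outdir is not None:
                out = report.scores.copy()
                out["pass"] = report.passed
                out.index.name = "probeset"
                out.to_csv(outdir / "pvac_report.tsv", sep="\t", float_format="%.6g")
            return report

        report = run_pvac()
        summary["stages"]["pvac"] = {
            "n_probesets": int(report.scores.shape[0]),
            "n_retained": len(report.retained),
        }

        @_stage("summarize")
        def run_summarize():
            return summarize_probesets(probes, report.retained)

        expression = run_summarize()
        if outdir is not None:
            io.write_expression(expression, outdir / "expression.tsv")

    _validate_inputs(expression.sample_ids, sheet)

    groups = sheet.groups
    case = config.case_group or groups[0]
    control = config.control_group or groups[1]
    for g in (case, control):
        if g not in groups:
            raise InputError(f"contrast group {g!r} not present in sample sheet")
    config = config.replace(case_group=case, control_group=control)

    @_stage("paired_de")
    def run_paired():
        results = {}
        for group in groups:
            de = paired_de(expression, sheet, group, config)
            results[group] = de
            if outdir is not None:
                de.table.to_csv(
                    outdir / f"paired_de_{group}.tsv", sep="\t", float_format="%.6g"
                )
        return results

    paired = run_paired()
    summary["stages"]["paired_de"] = {
        g: {"n_up": de.n_up, "n_down": de.n_down} for g, de in paired.items()
    }

    @_stage("log_ratios")
    def run_ratios():
        ratios = compute_log_ratios(expression, sheet)
        pca = pca_scores(ratios, n_components=min(2, len(ratios.subject_ids) - 1))
        if outdir is not None:
            ratios.data.to_csv(outdir / "log_ratios.tsv", sep="\t", float_format="%.6g")
            scores = pca.scores.copy()
            scores["group"] = pca.groups
            scores.to_csv(outdir / "pca_scores.tsv", sep="\t", float_format="%.6g")
        return ratios, pca

    ratios, pca = run_ratios()
    summary["stages"]["pca"] = {
        "explained_variance_ratio": [float(v) for v in pca.explained_variance_ratio],
    }

    @_stage("unpaired_de")
    def run_unpaired():
        de = unpaired_de(ratios, case, control, config)
        if outdir is not None:
            de.table.to_csv(outdir / "unpaired_de.tsv", sep="\t", float_format="%.6g")
        return de

    unpaired = run_unpaired()
    summary["stages"]["unpaired_de"] = {
        "case": case, "control": control,
        "n_up": unpaired.n_up, "n_down": unpaired.n_down,
    }

    @_stage("networks")
    def run_networks():
        nets = {}
        for group in groups:
            subjects = ratios.subjects_of_group(group)
            nets[group] = build_network(ratios.data[subjects], config)
            if outdir is not None:
                out = pd.DataFrame(
                    {
                        "module": nets[group].module_labels,
                        "k": nets[group].connectivity,
                        "k_scaled": nets[group].scaled_connectivity,
                    }
                )
                out.index.name = "gene_id"
                out.to_csv(
                    outdir / f"network_{group}.tsv", sep="\t", float_format="%.6g"
                )
        return nets

    networks = run_networks()
    summary["stages"]["networks"] = {
        g: {
            "n_modules": int(net.module_labels[net.module_labels != "grey"].nunique()),
            "module_sizes": {
                str(m): int(c)
                for m, c in net.module_labels.value_counts().items()
            },
        }
        for g, net in networks.items()
    }

    @_stage("module_enrichment")
    def run_module_enrichment():
        enr = module_de_enrichment(networks[case].module_labels, unpaired)
        if outdir is not None:
            enr.to_csv(outdir / "module_enrichment.tsv", sep="\t", float_format="%.6g")
        return enr

    module_enr = run_module_enrichment()
    summary["stages"]["module_enrichment"] = {
        str(m): float(p) for m, p in module_enr["enrichment_p"].items()
    }

    @_stage("diffnet")
    def run_diffnet():
        case_data = ratios.data[ratios.subjects_of_group(case)]
        ctrl_data = ratios.data[ratios.subjects_of_group(control)]
        result = permutation_test(case_data, ctrl_data, config)
        if outdir is not None:
            result.table.to_csv(
                outdir / "diffnet_genes.tsv", sep="\t", float_format="%.6g"
            )
            sector_out = pd.DataFrame(
                {
                    "count": result.sector_counts,
                    "permutation_p": result.permutation_p.reindex(
                        result.sector_counts.index
                    ),
                }
            )
            sector_out.index.name = "sector"
            sector_out.to_csv(
                outdir / "diffnet_sectors.tsv", sep="\t", float_format="%.6g"
            )
        return result

    diffnet_result = run_diffnet()
    summary["stages"]["diffnet"] = diffnet_result.to_jsonable()

    if gene_sets is not None and len(gene_sets):

        @_stage("regulators")
        def run_regulators():
            scores = score_regulators(unpaired, gene_sets, config)
            if outdir is not None:
                scores.to_csv(
                    outdir / "regulator_scores.tsv", sep="\t", float_format="%.6g"
                )
            return scores

        reg = run_regulators()
        summary["stages"]["regulators"] = {
            name: {
                "overlap_p": float(row["overlap_p"]),
                "activation_z": (
                    None if row["activation_z"] is None or pd.isna(row["activation_z"])
                    else float(row["activation_z"])
                ),
                "significant": bool(row["significant"]),
            }
            for name, row in reg.iterrows()
        }

    if outdir is not None:
        (outdir / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True) + "\n"
        )
    return summary
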