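import numpy as np
import pandas as pd
import pytest

from diffconet.config import AnalysisConfig
from diffconet.model import ExpressionMatrix, SampleSheet
from diffconet.simulate import SimulationParams, generate_dataset

#: Canonical seed for every stochastic fixture in the suite.
SEED = 2016


@pytest.fixture
def config() -> AnalysisConfig:
    return AnalysisConfig(random_seed=SEED)


def two_group_params(
    n_subjects: int = 20,
    n_genes: int = 200,
    differential_loading: float = 0.8,
    response: float = 1.0,
    seed: int = SEED,
) -> SimulationParams:
    """Case/control design with a 50-gene differentially wired module
    (loading ``differential_loading`` in case, 0 in control), a 50-gene
    reference module shared by both groups, and a case-specific
    stimulation response on the differential module's genes."""
    response_effects = np.zeros(n_genes)
    response_effects[:50] = response
    return SimulationParams(
        group_labels=("case", "control"),
        group_sizes=(n_subjects, n_subjects),
        n_genes=n_genes,
        module_sizes=(50, 50),
        module_loadings=((differential_loading, 0.0), (0.8, 0.8)),
        response_effects=response_effects,
        response_group="case",
        seed=seed,
    )


def null_two_group_params(n_subjects: int = 20, n_genes: int = 200, seed: int = SEED) -> SimulationParams:
    """No planted effects: exchangeable case/control groups."""
    return SimulationParams(
        group_labels=("case", "control"),
        group_sizes=(n_subjects, n_subjects),
        n_genes=n_genes,
        seed=seed,
    )


@pytest.fixture
def small_study():
    """Compact three-group study with planted structure, probes included."""
    params = SimulationParams(
        group_labels=("case", "sens", "nonsens"),
        group_sizes=(8, 8, 8),
        n_genes=120,
        module_sizes=(40, 40),
        module_loadings=((0.8, 0.3, 0.3), (0.7, 0.7, 0.7)),
        response_effects=np.r_[np.full(40, 1.0), np.zeros(80)],
        response_group="case",
        fraction_noisy_probesets=0.2,
        seed=SEED,
    )
    return generate_dataset(params)


def toy_sheet(
    n_subjects_per_group: int = 3, groups: tuple[str, ...] = ("A", "B")
) -> SampleSheet:
    rows = []
    for g in groups:
        for j in range(n_subjects_per_group):
            subject = f"{g}{j + 1}"
            for cond, tag in (("stimulated", "s"), ("unstimulated", "u")):
                rows.append(
                    {
                        "sample_id": f"{subject}{tag}",
                        "subject_id": subject,
                        "group": g,
                        "condition": cond,
                    }
                )
    return SampleSheet(pd.DataFrame(rows))


def toy_expression(sheet: SampleSheet, n_genes: int = 5, seed: int = SEED) -> ExpressionMatrix:
    rng = np.random.default_rng(seed)
    data = pd.DataFrame(
        rng.normal(8.0, 1.0, (n_genes, len(sheet.sample_ids))),
        index=[f"G{i + 1}" for i in range(n_genes)],
        columns=sheet.sample_ids,
    )
    return ExpressionMatrix(data)
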