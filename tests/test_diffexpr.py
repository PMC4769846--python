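import numpy as np
import pandas as pd
import pytest
from scipy import stats

from diffconet.config import AnalysisConfig
from diffconet.diffexpr import (
    LogRatioMatrix,
    bh_fdr,
    compute_log_ratios,
    paired_de,
    pca_scores,
    unpaired_de,
)
from diffconet.errors import InputError
from diffconet.model import ExpressionMatrix, SampleSheet

from conftest import SEED, toy_expression, toy_sheet


def bh_oracle(p: np.ndarray) -> np.ndarray:
    """O(m^2) step-up: q_i = min over j with p_j >= p_i of p_j * m / rank_j."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for pos, i in enumerate(order):
        candidates = [
            p[order[k]] * m / (k + 1) for k in range(pos, m)
        ]
        q[i] = min(1.0, min(candidates))
    return q


class TestLogRatios:
    def test_equal_conditions_give_zero_column(self):
        sheet = toy_sheet(n_subjects_per_group=2, groups=("A",))
        expr = toy_expression(sheet)
        data = expr.data.copy()
        data["A1s"] = data["A1u"]
        ratios = compute_log_ratios(ExpressionMatrix(data), sheet)
        np.testing.assert_allclose(ratios.data["A1"], 0.0)

    def test_unit_shift_gives_column_of_ones(self):
        sheet = toy_sheet(n_subjects_per_group=2, groups=("A",))
        expr = toy_expression(sheet)
        data = expr.data.copy()
        data["A2s"] = data["A2u"] + 1.0
        ratios = compute_log_ratios(ExpressionMatrix(data), sheet)
        np.testing.assert_allclose(ratios.data["A2"], 1.0)

    def test_unpaired_subject_skipped_with_warning(self, caplog):
        sheet = toy_sheet(n_subjects_per_group=2, groups=("A",))
        dropped = SampleSheet(sheet.frame[sheet.frame["sample_id"] != "A1u"])
        expr = toy_expression(sheet)
        with caplog.at_level("WARNING"):
            ratios = compute_log_ratios(expr, dropped)
        assert "A1" in caplog.text
        assert list(ratios.data.columns) == ["A2"]

    def test_no_pairs_rejected(self):
        sheet = toy_sheet(n_subjects_per_group=2, groups=("A",))
        stim_only = SampleSheet(
            sheet.frame[sheet.frame["condition"] == "stimulated"]
        )
        with pytest.raises(InputError):
            compute_log_ratios(toy_expression(sheet), stim_only)


class TestPairedDE:
    def test_closed_form_example(self, config):
        """Differences (1,2,3): t = 2/(1/sqrt(3)) and p = 1 - t/sqrt(t^2+2)."""
        sheet = toy_sheet(n_subjects_per_group=3, groups=("A",))
        expr = toy_expression(sheet, n_genes=1)
        data = expr.data.copy()
        for subj, diff in zip(("A1", "A2", "A3"), (1.0, 2.0, 3.0)):
            data[f"{subj}s"] = data[f"{subj}u"] + diff
        result = paired_de(ExpressionMatrix(data), sheet, "A", config)
        row = result.table.iloc[0]
        assert row["t"] == pytest.approx(3.4641, abs=1e-4)
        assert row["df"] == 2
        assert row["p"] == pytest.approx(0.0742, abs=1e-4)

    def test_zero_differences_flagged_degenerate(self, config):
        sheet = toy_sheet(n_subjects_per_group=3, groups=("A",))
        expr = toy_expression(sheet, n_genes=2)
        data = expr.data.copy()
        for subj in ("A1", "A2", "A3"):
            data[f"{subj}s"] = data[f"{subj}u"]
        result = paired_de(ExpressionMatrix(data), sheet, "A", config)
        assert (result.table["effect"] == 0).all()
        assert result.table["degenerate"].all()
        assert (result.table["p"] == 1.0).all()

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_scipy_paired_oracle(self, seed, config):
        rng = np.random.default_rng(seed)
        sheet = toy_sheet(n_subjects_per_group=6, groups=("A",))
        expr = toy_expression(sheet, n_genes=20, seed=seed)
        result = paired_de(expr, sheet, "A", config)
        pairs = sheet.pairs()
        stim = expr.data[list(pairs["stimulated"])].to_numpy()
        unstim = expr.data[list(pairs["unstimulated"])].to_numpy()
        t_ref, p_ref = stats.ttest_rel(stim, unstim, axis=1)
        np.testing.assert_allclose(result.table["t"], t_ref, atol=1e-12)
        np.testing.assert_allclose(result.table["p"], p_ref, atol=1e-12)


class TestUnpairedDE:
    def test_closed_form_example(self, config):
        ratios = LogRatioMatrix(
            pd.DataFrame([[0.0, 1.0, 2.0, 3.0]], index=["G1"],
                         columns=["a1", "a2", "b1", "b2"]),
            pd.Series({"a1": "A", "a2": "A", "b1": "B", "b2": "B"}),
        )
        result = unpaired_de(ratios, "A", "B", config)
        row = result.table.iloc[0]
        assert row["t"] == pytest.approx(-2.8284, abs=1e-4)
        assert row["df"] == 2
        assert row["p"] == pytest.approx(0.1056, abs=1e-4)

    def test_identical_groups_give_t_zero(self, config):
        ratios = LogRatioMatrix(
            pd.DataFrame([[1.0, 1.0, 1.0, 1.0]], index=["G1"],
                         columns=["a1", "a2", "b1", "b2"]),
            pd.Series({"a1": "A", "a2": "A", "b1": "B", "b2": "B"}),
        )
        result = unpaired_de(ratios, "A", "B", config)
        assert result.table.iloc[0]["t"] == 0.0
        assert result.table.iloc[0]["p"] == 1.0

    def test_swapping_groups_negates_t(self, config):
        rng = np.random.default_rng(SEED)
        cols = [f"a{i}" for i in range(4)] + [f"b{i}" for i in range(5)]
        ratios = LogRatioMatrix(
            pd.DataFrame(rng.normal(size=(10, 9)), columns=cols),
            pd.Series({c: c[0].upper() for c in cols}),
        )
        ab = unpaired_de(ratios, "A", "B", config)
        ba = unpaired_de(ratios, "B", "A", config)
        np.testing.assert_allclose(ab.table["t"], -ba.table["t"], atol=1e-12)
        np.testing.assert_allclose(ab.table["p"], ba.table["p"], atol=1e-12)

    @pytest.mark.parametrize("welch", [False, True])
    def test_matches_scipy_two_sample_oracle(self, welch):
        config = AnalysisConfig(random_seed=SEED, welch=welch)
        rng = np.random.default_rng(SEED)
        cols = [f"a{i}" for i in range(6)] + [f"b{i}" for i in range(8)]
        ratios = LogRatioMatrix(
            pd.DataFrame(rng.normal(size=(15, 14)), columns=cols),
            pd.Series({c: c[0].upper() for c in cols}),
        )
        result = unpaired_de(ratios, "A", "B", config)
        a = ratios.data[[c for c in cols if c.startswith("a")]].to_numpy()
        b = ratios.data[[c for c in cols if c.startswith("b")]].to_numpy()
        t_ref, p_ref = stats.ttest_ind(a, b, axis=1, equal_var=not welch)
        np.testing.assert_allclose(result.table["t"], t_ref, atol=1e-12)
        np.testing.assert_allclose(result.table["p"], p_ref, atol=1e-12)

    def test_tiny_group_rejected(self, config):
        ratios = LogRatioMatrix(
            pd.DataFrame([[0.0, 1.0, 2.0]], columns=["a1", "b1", "b2"]),
            pd.Series({"a1": "A", "b1": "B", "b2": "B"}),
        )
        with pytest.raises(InputError):
            unpaired_de(ratios, "A", "B", config)


class TestBhFdr:
    def test_stepup_by_hand(self):
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert bh_fdr([0.3])[0] == pytest.approx(0.3)

    def test_constant_p_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.5] * 7), [0.5] * 7)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_quadratic_oracle_exactly(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=rng.integers(1, 40))
        np.testing.assert_allclose(bh_fdr(list(p)), bh_oracle(p), atol=1e-14)

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            bh_fdr([0.5, 1.2])
        with pytest.raises(InputError):
            bh_fdr([-0.1])


class TestPca:
    def test_mirrored_profiles_are_symmetric(self):
        x = np.array([1.0, -2.0, 3.0, 0.5, -1.5])
        ratios = LogRatioMatrix(
            pd.DataFrame({"s1": x, "s2": -x}),
            pd.Series({"s1": "A", "s2": "B"}),
        )
        result = pca_scores(ratios, n_components=1)
        scores = result.scores["PC1"].to_numpy()
        assert scores[0] == pytest.approx(-scores[1], abs=1e-10)

    def test_variance_fractions_nonincreasing_and_bounded(self):
        rng = np.random.default_rng(SEED)
        cols = [f"s{i}" for i in range(8)]
        ratios = LogRatioMatrix(
            pd.DataFrame(rng.normal(size=(30, 8)), columns=cols),
            pd.Series({c: "A" for c in cols}),
        )
        result = pca_scores(ratios, n_components=5)
        evr = result.explained_variance_ratio
        assert (np.diff(evr) <= 1e-12).all()
        assert evr.sum() <= 1.0 + 1e-12

    def test_excess_components_rejected(self):
        ratios = LogRatioMatrix(
            pd.DataFrame(np.eye(3), columns=["s1", "s2", "s3"]),
            pd.Series({f"s{i}": "A" for i in (1, 2, 3)}),
        )
        with pytest.raises(InputError):
            pca_scores(ratios, n_components=5)

    def test_planted_response_separates_groups_on_pc1(self):
        """A strong case-specific response dominates the leading axis."""
        rng = np.random.default_rng(SEED)
        n_genes, n = 100, 10
        case = rng.normal(0, 0.5, (n_genes, n))
        case[:40] += 2.0
        ctrl = rng.normal(0, 0.5, (n_genes, n))
        cols = [f"c{i}" for i in range(n)] + [f"x{i}" for i in range(n)]
        ratios = LogRatioMatrix(
            pd.DataFrame(np.hstack([case, ctrl]), columns=cols),
            pd.Series({c: ("case" if c.startswith("c") else "ctrl") for c in cols}),
        )
        result = pca_scores(ratios, n_components=2)
        pc1 = result.scores["PC1"]
        case_mean = pc1[[c for c in cols if c.startswith("c")]].mean()
        ctrl_mean = pc1[[c for c in cols if c.startswith("x")]].mean()
        assert abs(case_mean - ctrl_mean) > 3 * pc1.std() / np.sqrt(n)
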