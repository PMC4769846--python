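import numpy as np
import pandas as pd
import pytest

from diffconet.coexpression import (
    build_network,
    connectivity,
    module_de_enrichment,
    signed_similarity,
    soft_adjacency,
    tom,
)
from diffconet.diffexpr import DEResult
from diffconet.errors import InputError

from conftest import SEED


def tom_oracle(A: np.ndarray) -> np.ndarray:
    """Brute-force double loop over the topological overlap definition."""
    n = A.shape[0]
    k = A.sum(axis=1)
    T = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l_ij = sum(A[i, u] * A[u, j] for u in range(n))
            T[i, j] = (l_ij + A[i, j]) / (min(k[i], k[j]) + 1 - A[i, j])
    return T


def connectivity_oracle(S: np.ndarray, basis: str, beta: float) -> np.ndarray:
    n = S.shape[0]
    K = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            K[i] += S[i, j] if basis == "similarity" else S[i, j] ** beta
    return K


def block_data(seed: int = SEED, rho: float = 0.8, sizes=(50, 50), n_bg: int = 20,
               n_samples: int = 100) -> pd.DataFrame:
    """Two independent equicorrelated blocks plus background genes."""
    rng = np.random.default_rng(seed)
    rows = []
    for size in sizes:
        z = rng.normal(size=n_samples)
        rows.append(
            np.sqrt(rho) * z + np.sqrt(1 - rho) * rng.normal(size=(size, n_samples))
        )
    rows.append(rng.normal(size=(n_bg, n_samples)))
    data = np.vstack(rows)
    return pd.DataFrame(
        data, index=[f"G{i + 1:03d}" for i in range(data.shape[0])]
    )


class TestSignedSimilarity:
    def test_correlation_endpoints_map_to_unit_interval(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        X = np.vstack([x, 2 * x, -x, np.array([-1.0, 1.0, 1.0, -1.0])])
        S = signed_similarity(X)
        assert S[0, 1] == pytest.approx(1.0)  # cor +1
        assert S[0, 2] == pytest.approx(0.0)  # cor -1 pushed to zero
        assert S[0, 3] == pytest.approx(0.5, abs=1e-12)  # cor 0
        assert np.allclose(S, S.T) and np.allclose(np.diag(S), 1.0)

    def test_zero_variance_gene_gets_half(self, caplog):
        X = np.array([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]])
        with caplog.at_level("WARNING"):
            S = signed_similarity(X)
        assert S[0, 1] == pytest.approx(0.5)
        assert S[1, 1] == 1.0
        assert "zero-variance" in caplog.text


class TestSoftAdjacency:
    def test_powers_and_diagonal(self):
        S = np.array([[1.0, 0.5], [0.5, 1.0]])
        A = soft_adjacency(S, 2.0)
        assert A[0, 1] == pytest.approx(0.25)
        assert A[0, 0] == 0.0
        A1 = soft_adjacency(S, 1.0)
        assert A1[0, 1] == pytest.approx(0.5)
        assert soft_adjacency(np.ones((2, 2)), 7.3)[0, 1] == pytest.approx(1.0)

    def test_bad_beta_rejected(self):
        with pytest.raises(InputError):
            soft_adjacency(np.ones((2, 2)), 0.0)


class TestTom:
    def test_complete_graph_has_full_overlap(self):
        A = np.ones((3, 3)) - np.eye(3)
        T = tom(A)
        assert T[0, 1] == pytest.approx(1.0)  # (1+1)/(2+1-1)

    def test_empty_graph_has_no_overlap(self):
        T = tom(np.zeros((4, 4)))
        assert np.allclose(T - np.eye(4), 0.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_double_loop_oracle_and_stays_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        S = (1 + np.corrcoef(rng.normal(size=(12, 30)))) / 2
        A = soft_adjacency(S, 6.0)
        T = tom(A)
        np.testing.assert_allclose(T, tom_oracle(A), atol=1e-12)
        assert (T >= 0).all() and (T <= 1).all()


class TestConnectivity:
    def test_perfectly_correlated_genes(self, config):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        S = signed_similarity(np.vstack([x, x + 1, 2 * x]))
        K, Ks = connectivity(S, config, basis="similarity")
        np.testing.assert_allclose(K, [2.0, 2.0, 2.0])
        np.testing.assert_allclose(Ks, [1.0, 1.0, 1.0])

    def test_hand_computed_mixed_signs(self, config):
        # r12 = 1, r13 = r23 = -1  =>  s pairs (1, 0, 0)  =>  K = (1, 1, 0)
        x = np.array([1.0, 2.0, 3.0])
        S = signed_similarity(np.vstack([x, x, -x]))
        K, Ks = connectivity(S, config, basis="similarity")
        np.testing.assert_allclose(K, [1.0, 1.0, 0.0], atol=1e-12)
        np.testing.assert_allclose(Ks, [1.0, 1.0, 0.0], atol=1e-12)

    @pytest.mark.parametrize("basis", ["similarity", "adjacency"])
    def test_matches_double_loop_oracle(self, basis, config):
        rng = np.random.default_rng(SEED)
        S = (1 + np.corrcoef(rng.normal(size=(50, 40)))) / 2
        np.fill_diagonal(S, 1.0)
        K, Ks = connectivity(S, config, basis=basis)
        K_ref = connectivity_oracle(S, basis, config.soft_power)
        np.testing.assert_allclose(K, K_ref, atol=1e-10)
        assert Ks.max() == pytest.approx(1.0)
        assert (Ks >= 0).all() and (Ks <= 1.0 + 1e-12).all()


class TestDetectModules:
    def test_recovers_planted_blocks(self, config):
        data = block_data()
        net = build_network(data, config)
        labels = net.module_labels
        non_grey = labels[labels != "grey"]
        assert non_grey.nunique() == 2
        block1 = labels.iloc[:50]
        block2 = labels.iloc[50:100]
        top1 = block1.value_counts().idxmax()
        top2 = block2.value_counts().idxmax()
        assert top1 != "grey" and top2 != "grey" and top1 != top2
        assert (block1 == top1).mean() >= 0.95
        assert (block2 == top2).mean() >= 0.95

    def test_bigger_module_gets_first_colour(self, config):
        data = block_data(sizes=(60, 40), n_bg=10)
        labels = build_network(data, config).module_labels
        assert (labels.iloc[:60] == "turquoise").mean() >= 0.95
        assert (labels.iloc[60:100] == "blue").mean() >= 0.95

    def test_uncorrelated_genes_are_all_grey(self, config):
        rng = np.random.default_rng(SEED)
        data = pd.DataFrame(
            rng.normal(size=(50, 60)), index=[f"G{i}" for i in range(50)]
        )
        labels = build_network(data, config).module_labels
        assert (labels == "grey").all()

    def test_labels_partition_gene_set(self, config):
        data = block_data(n_bg=30)
        labels = build_network(data, config).module_labels
        assert set(labels.index) == set(data.index)
        assert labels.notna().all()

    def test_gene_permutation_permutes_labels(self, config):
        data = block_data(n_bg=10)
        rng = np.random.default_rng(7)
        perm = rng.permutation(len(data))
        shuffled = data.iloc[perm]
        labels = build_network(data, config).module_labels
        labels_shuffled = build_network(shuffled, config).module_labels
        assert (labels_shuffled.reindex(labels.index) == labels).all()


class TestModuleEnrichment:
    @staticmethod
    def _de_result(pvalues: np.ndarray, genes: list[str]) -> DEResult:
        table = pd.DataFrame(
            {
                "effect": np.zeros(len(genes)),
                "t": np.zeros(len(genes)),
                "df": 1.0,
                "p": pvalues,
                "q": pvalues,
                "degenerate": False,
            },
            index=genes,
        )
        return DEResult(table, 0.05)

    def test_de_rich_module_detected(self):
        genes = [f"G{i}" for i in range(60)]
        labels = pd.Series(["blue"] * 20 + ["grey"] * 40, index=genes)
        p = np.r_[np.full(20, 1e-6), np.full(40, 0.5)]
        out = module_de_enrichment(labels, self._de_result(p, genes))
        assert out.loc["blue", "enrichment_p"] < 0.01
        assert out.loc["blue", "median_neglog10_p"] == pytest.approx(6.0)
        assert out["n"].sum() == 60

    def test_identical_p_distribution_is_not_flagged(self):
        """Same p multiset inside and outside the module: medians equal
        and no enrichment."""
        genes = [f"G{i}" for i in range(80)]
        labels = pd.Series(["blue"] * 40 + ["grey"] * 40, index=genes)
        block = np.linspace(0.01, 0.99, 40)
        p = np.r_[block, block]
        out = module_de_enrichment(labels, self._de_result(p, genes))
        assert out.loc["blue", "enrichment_p"] > 0.4
        assert out.loc["blue", "median_neglog10_p"] == pytest.approx(
            out.loc["grey", "median_neglog10_p"]
        )

    def test_mismatched_genes_rejected(self):
        labels = pd.Series(["blue", "blue"], index=["G1", "G2"])
        with pytest.raises(InputError):
            module_de_enrichment(
                labels, self._de_result(np.array([0.5]), ["G1"])
            )
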