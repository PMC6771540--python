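"""Co-expression network chain: correlation, adjacency, TOM, clustering,
eigengenes, merging and module-trait statistics."""

import numpy as np
import pandas as pd
import pytest

from droughtcross.coexpression import (
    NetworkParams, UNASSIGNED, average_linkage_cluster, correlation_matrix,
    detect_modules, dynamic_cut, merge_modules, module_eigengenes,
    module_trait_correlation, soft_threshold_adjacency, topological_overlap,
)
from conftest import make_matrix, make_metadata


def brute_force_tom(A):
    """Independent oracle: triple-loop evaluation of the TOM formula."""
    n = A.shape[0]
    k = A.sum(axis=1)
    tom = np.ones((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l_ij = sum(A[i, u] * A[u, j] for u in range(n))
            tom[i, j] = (l_ij + A[i, j]) / (min(k[i], k[j]) + 1 - A[i, j])
    return tom


def random_adjacency(rng, n):
    A = rng.uniform(0, 1, size=(n, n))
    A = (A + A.T) / 2
    np.fill_diagonal(A, 0.0)
    return A


def frame(A):
    ids = [f"g{i}" for i in range(A.shape[0])]
    return pd.DataFrame(A, index=ids, columns=ids)


class TestCorrelationMatrix:
    def test_self_and_anticorrelation(self):
        meta = make_metadata(replicates=2)
        x = np.linspace(0, 1, len(meta))
        m = make_matrix(np.vstack([x, -x]), meta, scale="log2tpm")
        cor = correlation_matrix(m)
        assert cor.iloc[0, 0] == pytest.approx(1.0)
        assert cor.iloc[0, 1] == pytest.approx(-1.0)

    def test_matches_direct_pearson_formula(self, rng):
        meta = make_metadata(conditions=("WW",), timepoints=("T0", "T5"),
                             replicates=2)
        x = rng.normal(size=(3, 4))
        m = make_matrix(x, meta, scale="log2tpm")
        cor = correlation_matrix(m)
        for i in range(3):
            for j in range(3):
                xi, xj = x[i] - x[i].mean(), x[j] - x[j].mean()
                expected = (xi @ xj) / np.sqrt((xi @ xi) * (xj @ xj))
                assert cor.iloc[i, j] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_gene_warns_and_zeroed(self):
        meta = make_metadata(replicates=1)
        m = make_matrix(np.vstack([np.ones(8), np.arange(8.0)]), meta,
                        scale="log2tpm")
        with pytest.warns(UserWarning, match="zero-variance"):
            cor = correlation_matrix(m)
        assert cor.iloc[0, 1] == 0.0
        assert cor.iloc[0, 0] == 1.0


class TestSoftThresholdAdjacency:
    @pytest.mark.parametrize("r,expected", [
        (1.0, 1.0), (0.0, 0.0), (0.8, 0.8 ** 16),
    ])
    def test_unsigned_power(self, r, expected):
        cor = frame(np.array([[1.0, r], [r, 1.0]]))
        adj = soft_threshold_adjacency(cor, NetworkParams())
        assert adj.iloc[0, 1] == pytest.approx(expected, abs=1e-12)
        assert adj.iloc[0, 0] == 0.0  # diagonal zeroed

    def test_signed_transform(self):
        cor = frame(np.array([[1.0, -1.0], [-1.0, 1.0]]))
        adj = soft_threshold_adjacency(cor, NetworkParams(network_type="signed"))
        assert adj.iloc[0, 1] == pytest.approx(0.0)


class TestTopologicalOverlap:
    def test_two_node_saturated_edge(self):
        sim, dis = topological_overlap(frame(np.array([[0.0, 1.0], [1.0, 0.0]])))
        assert sim.iloc[0, 1] == pytest.approx(1.0)
        assert dis.iloc[0, 1] == pytest.approx(0.0)

    def test_zero_adjacency(self):
        sim, _ = topological_overlap(frame(np.zeros((3, 3))))
        assert sim.iloc[0, 1] == 0.0
        assert sim.iloc[0, 0] == 1.0

    def test_three_node_uniform_half(self):
        A = np.full((3, 3), 0.5)
        np.fill_diagonal(A, 0.0)
        sim, _ = topological_overlap(frame(A))
        # (0.25 + 0.5) / (1 + 1 - 0.5) by the direct formula
        assert sim.iloc[0, 1] == pytest.approx(0.5)

    def test_matches_brute_force_oracle(self, rng):
        for n in (2, 5, 9, 14, 20):
            A = random_adjacency(rng, n)
            sim, dis = topological_overlap(frame(A))
            expected = brute_force_tom(A)
            np.testing.assert_allclose(sim.to_numpy(), expected, atol=1e-12)
            assert sim.to_numpy().min() >= 0 and sim.to_numpy().max() <= 1
            np.testing.assert_allclose(sim.to_numpy(), sim.to_numpy().T, atol=0)

    def test_asymmetric_rejected(self):
        A = np.array([[0.0, 0.5], [0.4, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            topological_overlap(frame(A))


class TestAverageLinkage:
    def test_two_points_merge_at_distance(self):
        d = frame(np.array([[0.0, 0.4], [0.4, 0.0]]))
        Z = average_linkage_cluster(d)
        assert Z.shape == (1, 4)
        assert Z[0, 2] == pytest.approx(0.4)

    def test_last_merge_is_mean_inter_block_distance(self, rng):
        # two tight blocks far apart: final height = mean of the inter-block
        # submatrix (direct average oracle)
        n = 6
        D = np.zeros((2 * n, 2 * n))
        within = rng.uniform(0.0, 0.05, (n, n))
        between = rng.uniform(0.8, 1.0, (n, n))
        D[:n, :n] = (within + within.T) / 2
        D[n:, n:] = (within + within.T) / 2
        D[:n, n:] = between
        D[n:, :n] = between.T
        np.fill_diagonal(D, 0.0)
        Z = average_linkage_cluster(frame(D))
        assert Z[-1, 2] == pytest.approx(between.mean(), abs=1e-12)

    def test_permutation_gives_isomorphic_heights(self, rng):
        D = random_adjacency(rng, 8)  # symmetric zero-diagonal works as distances
        Z1 = average_linkage_cluster(frame(D))
        perm = rng.permutation(8)
        Z2 = average_linkage_cluster(frame(D[np.ix_(perm, perm)]))
        np.testing.assert_allclose(sorted(Z1[:, 2]), sorted(Z2[:, 2]), atol=1e-12)

    def test_non_finite_rejected(self):
        D = np.array([[0.0, np.nan], [np.nan, 0.0]])
        with pytest.raises(ValueError):
            average_linkage_cluster(frame(D))


class TestDynamicCut:
    def block_distance(self, sizes, within=0.1, between=0.95):
        n = sum(sizes)
        D = np.full((n, n), between)
        start = 0
        for s in sizes:
            D[start:start + s, start:start + s] = within
            start += s
        np.fill_diagonal(D, 0.0)
        return frame(D)

    def test_two_planted_blocks_recovered(self):
        d = self.block_distance([50, 50])
        Z = average_linkage_cluster(d)
        labels = dynamic_cut(Z, d, NetworkParams(min_module_size=30))
        assert labels.nunique() == 2
        assert (labels != UNASSIGNED).all()
        # perfect agreement with the planted split
        first = set(labels.iloc[:50])
        assert len(first) == 1 and set(labels.iloc[50:]) != first

    def test_small_branch_unassigned(self):
        d = self.block_distance([10, 40])
        Z = average_linkage_cluster(d)
        labels = dynamic_cut(Z, d, NetworkParams(min_module_size=30))
        assert (labels.iloc[:10] == UNASSIGNED).all()
        assert (labels.iloc[10:] == "M1").all()

    def test_homogeneous_noise_collapses(self, rng):
        D = random_adjacency(rng, 40) * 0.02 + 0.9
        np.fill_diagonal(D, 0.0)
        d = frame((D + D.T) / 2)
        Z = average_linkage_cluster(d)
        labels = dynamic_cut(Z, d, NetworkParams(min_module_size=30))
        assert labels[labels != UNASSIGNED].nunique() <= 1


class TestModuleEigengenes:
    def toy_matrix(self, x, meta):
        return make_matrix(x, meta, scale="log2tpm")

    def test_identical_profiles_full_variance(self):
        meta = make_metadata(replicates=1)
        profile = np.sin(np.arange(8.0))
        m = self.toy_matrix(np.tile(profile, (4, 1)), meta)
        labels = pd.Series(["M1"] * 4, index=m.feature_ids)
        eig, varex = module_eigengenes(m, labels)
        assert varex["M1"] == pytest.approx(1.0)
        z = (profile - profile.mean()) / profile.std()
        r = np.corrcoef(eig.loc["M1"], z)[0, 1]
        assert abs(r) == pytest.approx(1.0)
        assert r > 0  # oriented along the module mean profile

    def test_sign_symmetric_module(self):
        meta = make_metadata(replicates=1)
        x = np.arange(8.0)
        m = self.toy_matrix(np.vstack([x, -x]), meta)
        labels = pd.Series(["M1"] * 2, index=m.feature_ids)
        eig, varex = module_eigengenes(m, labels)
        assert varex["M1"] == pytest.approx(1.0)
        assert np.linalg.norm(eig.loc["M1"]) == pytest.approx(1.0)

    def test_matches_direct_eigendecomposition(self, rng):
        meta = make_metadata(replicates=1)
        x = rng.normal(size=(3, 8))
        m = self.toy_matrix(x, meta)
        labels = pd.Series(["M1"] * 3, index=m.feature_ids)
        eig, varex = module_eigengenes(m, labels)
        z = (x - x.mean(1, keepdims=True)) / x.std(1, keepdims=True)
        evals, evecs = np.linalg.eigh(z.T @ z)  # sample-space covariance oracle
        lead = evecs[:, -1]
        assert abs(np.corrcoef(eig.loc["M1"], lead)[0, 1]) == pytest.approx(1.0)
        assert varex["M1"] == pytest.approx(evals[-1] / evals.sum())

    def test_singleton_module(self):
        meta = make_metadata(replicates=1)
        m = self.toy_matrix(np.arange(8.0)[None, :], meta)
        labels = pd.Series(["M1"], index=m.feature_ids)
        eig, varex = module_eigengenes(m, labels)
        assert varex["M1"] == 1.0
        assert np.linalg.norm(eig.loc["M1"]) == pytest.approx(1.0)


class TestMergeModules:
    def test_identical_eigengenes_merged(self, rng):
        meta = make_metadata(replicates=1)
        base = rng.normal(size=8)
        x = np.vstack([base + rng.normal(0, 1e-6, 8) for _ in range(6)])
        m = make_matrix(x, meta, scale="log2tpm")
        labels = pd.Series(["A"] * 3 + ["B"] * 3, index=m.feature_ids)
        out = merge_modules(m, labels, NetworkParams(min_module_size=1))
        assert out.n_modules == 1

    def test_uncorrelated_not_merged(self, rng):
        meta = make_metadata(replicates=3)
        a, b = rng.normal(size=(2, 24))
        x = np.vstack([a, a, a, b, b, b]) + rng.normal(0, 1e-3, (6, 24))
        m = make_matrix(x, meta, scale="log2tpm")
        labels = pd.Series(["A"] * 3 + ["B"] * 3, index=m.feature_ids)
        out = merge_modules(m, labels, NetworkParams(min_module_size=1))
        assert out.n_modules == 2

    def test_idempotent(self, rng):
        meta = make_metadata(replicates=3)
        x = rng.normal(size=(9, 24))
        m = make_matrix(x, meta, scale="log2tpm")
        labels = pd.Series(["A"] * 3 + ["B"] * 3 + ["C"] * 3, index=m.feature_ids)
        once = merge_modules(m, labels, NetworkParams(min_module_size=1))
        twice = merge_modules(m, once.assignments, NetworkParams(min_module_size=1))
        assert (once.assignments == twice.assignments).all()


class TestModuleTraitCorrelation:
    def eig(self, rows, samples):
        return pd.DataFrame(rows, index=[f"M{i+1}" for i in range(len(rows))],
                            columns=samples)

    def test_perfect_correlation(self):
        samples = [f"s{i}" for i in range(4)]
        traits = pd.DataFrame({"wd": [0.0, 1.0, 0.0, 1.0]}, index=samples)
        eig = self.eig([[0.0, 1.0, 0.0, 1.0]], samples)
        out = module_trait_correlation(eig, traits)
        assert out["r"].iloc[0] == pytest.approx(1.0)
        assert out["p"].iloc[0] == pytest.approx(0.0)

    def test_known_r_two_group_trait(self):
        samples = [f"s{i}" for i in range(4)]
        traits = pd.DataFrame({"wd": [0.0, 0.0, 1.0, 1.0]}, index=samples)
        eig = self.eig([[1.0, 2.0, 3.0, 4.0]], samples)
        out = module_trait_correlation(eig, traits)
        assert out["r"].iloc[0] == pytest.approx(2 / np.sqrt(5))  # 0.8944...

    def test_constant_trait_flagged(self):
        samples = [f"s{i}" for i in range(4)]
        traits = pd.DataFrame({"flat": [1.0] * 4}, index=samples)
        eig = self.eig([[1.0, 2.0, 3.0, 4.0]], samples)
        out = module_trait_correlation(eig, traits)
        assert np.isnan(out["r"].iloc[0]) and out["note"].iloc[0] == "constant"

    def test_fdr_never_below_p(self, rng):
        samples = [f"s{i}" for i in range(10)]
        traits = pd.DataFrame(rng.normal(size=(10, 3)), index=samples,
                              columns=["t1", "t2", "t3"])
        eig = self.eig(rng.normal(size=(4, 10)), samples)
        out = module_trait_correlation(eig, traits)
        assert (out["fdr"] >= out["p"] - 1e-12).all()


class TestDetectModulesEndToEnd:
    def test_planted_blocks_recovered_with_unassigned_noise(self, rng):
        meta = make_metadata(replicates=3)
        latent1, latent2 = rng.normal(size=(2, 24))
        rows = []
        for latent in (latent1, latent2):
            for _ in range(40):
                rows.append(np.sqrt(0.8) * latent
                            + np.sqrt(0.2) * rng.normal(size=24))
        for _ in range(20):
            rows.append(rng.normal(size=24))
        m = make_matrix(np.array(rows), meta, scale="log2tpm")
        ms = detect_modules(m, NetworkParams(min_module_size=30))
        assert ms.n_modules == 2
        lab1 = set(ms.assignments.iloc[:40])
        lab2 = set(ms.assignments.iloc[40:80])
        assert len(lab1) == 1 and len(lab2) == 1 and lab1 != lab2
        noise_labels = ms.assignments.iloc[80:]
        assert (noise_labels == UNASSIGNED).mean() > 0.8
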