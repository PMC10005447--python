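import io
import itertools

import numpy as np
import pandas as pd
import pytest
from Bio import Phylo
from scipy.cluster.hierarchy import cophenet
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA as SKPCA
from sklearn.metrics import adjusted_rand_score

import pepdigest as pg
from pepdigest.multivariate import (
    hierarchical_cluster,
    pca,
    peptide_feature_matrix,
    residue_feature_matrix,
)
from pepdigest.peptide_mapping import ConfigError
from pepdigest.profiling import residue_profile

from conftest import make_obs


def sample_matrix(rows, row_keys=None):
    values = np.asarray(rows, dtype=float)
    index = pd.MultiIndex.from_tuples(
        row_keys or [("s", i) for i in range(len(values))], names=["substrate", "time_min"]
    )
    return pd.DataFrame(values, index=index, columns=[f"f{j}" for j in range(values.shape[1])])


def naive_average_agglomeration(X):
    """O(n^3) average-linkage agglomeration; returns the cophenetic matrix."""
    n = len(X)
    dist = squareform(pdist(X))
    clusters = {i: [i] for i in range(n)}
    coph = np.zeros((n, n))
    active = list(range(n))
    next_id = n
    cluster_dist = {(i, j): dist[i, j] for i in range(n) for j in range(i + 1, n)}
    while len(active) > 1:
        (a, b), height = min(
            ((pair, cluster_dist[pair]) for pair in itertools.combinations(sorted(active), 2)),
            key=lambda item: (item[1], item[0]),
        )
        for i in clusters[a]:
            for j in clusters[b]:
                coph[i, j] = coph[j, i] = height
        merged = clusters[a] + clusters[b]
        size_a, size_b = len(clusters[a]), len(clusters[b])
        clusters[next_id] = merged
        active = [c for c in active if c not in (a, b)]
        for c in active:
            d = (size_a * cluster_dist[tuple(sorted((a, c)))]
                 + size_b * cluster_dist[tuple(sorted((b, c)))]) / (size_a + size_b)
            cluster_dist[tuple(sorted((next_id, c)))] = d
        active.append(next_id)
        next_id += 1
    return coph


class TestResidueFeatureMatrix:
    def test_two_samples_one_protein(self):
        protein = pg.ProteinRecord(protein_id="X", sequence="ACDEFGHIKL")
        obs = [
            make_obs("ACDEF", 2.0, substrate="a", protein_id="X", start=1, end=5),
            make_obs("GHIKL", 3.0, substrate="b", protein_id="X", start=6, end=10),
        ]
        matrix = residue_feature_matrix(obs, [protein])
        assert matrix.shape == (2, 10)
        assert list(matrix.columns[:2]) == ["X:1", "X:2"]

    def test_cells_cross_check_residue_profile(self, mapped_study, caseins):
        matrix = residue_feature_matrix(mapped_study, caseins)
        key = ("hydrolysate", 45)
        subset = [o for o in mapped_study if (o.substrate, o.time_min) == key]
        for protein in caseins:
            expected = residue_profile(subset, protein, "intensity_sum").values
            block = matrix.loc[key, [f"{protein.protein_id}:{p}" for p in range(1, len(protein) + 1)]]
            assert np.allclose(block.to_numpy(), expected)

    def test_columns_cover_all_proteins(self, mapped_study, caseins):
        matrix = residue_feature_matrix(mapped_study, caseins)
        assert matrix.shape[1] == sum(len(p) for p in caseins)
        assert np.linalg.matrix_rank(matrix.to_numpy()) >= 2


class TestPCA:
    def test_two_exact_groups_put_all_variance_on_pc1(self):
        matrix = sample_matrix([[1, 2, 3]] * 3 + [[4, 0, 3]] * 3)
        result = pca(matrix)
        assert result.explained_ratio[0] == pytest.approx(1.0, abs=1e-12)

    def test_matches_brute_force_covariance_eigendecomposition(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            matrix = sample_matrix(rng.normal(size=(6, 20)))
            result = pca(matrix)
            X = matrix.to_numpy() - matrix.to_numpy().mean(axis=0)
            eigvals, eigvecs = np.linalg.eigh(X.T @ X / (len(X) - 1))
            eigvals = eigvals[::-1]
            eigvecs = eigvecs[:, ::-1]
            k = result.n_components
            assert np.allclose(
                result.explained_ratio, eigvals[:k] / eigvals.sum(), atol=1e-8
            )
            # loadings span the same axes (up to sign)
            for j in range(min(5, k)):
                dot = abs(result.loadings.iloc[:, j] @ eigvecs[:, j])
                assert dot == pytest.approx(1.0, abs=1e-8)

    def test_matches_sklearn(self):
        rng = np.random.default_rng(6)
        matrix = sample_matrix(rng.normal(size=(8, 12)))
        result = pca(matrix)
        sk = SKPCA().fit(matrix.to_numpy())
        assert np.allclose(result.explained_ratio, sk.explained_variance_ratio_, atol=1e-10)
        assert np.allclose(
            np.abs(result.scores.to_numpy()[:, :7]),
            np.abs(sk.transform(matrix.to_numpy()))[:, :7],
            atol=1e-8,
        )

    def test_reconstruction_from_all_components(self):
        rng = np.random.default_rng(7)
        matrix = sample_matrix(rng.normal(size=(5, 9)))
        result = pca(matrix)
        X = matrix.to_numpy() - matrix.to_numpy().mean(axis=0)
        assert np.allclose(
            result.scores.to_numpy() @ result.loadings.to_numpy().T, X, atol=1e-8
        )

    def test_loadings_are_orthonormal_with_positive_pivot(self):
        rng = np.random.default_rng(8)
        result = pca(sample_matrix(rng.normal(size=(6, 10))))
        L = result.loadings.to_numpy()
        assert np.allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-10)
        for j in range(L.shape[1]):
            assert L[np.argmax(np.abs(L[:, j])), j] > 0

    def test_explained_ratio_invariant_to_permutations(self):
        rng = np.random.default_rng(9)
        matrix = sample_matrix(rng.normal(size=(6, 10)))
        permuted = matrix.iloc[rng.permutation(6), rng.permutation(10)]
        assert np.allclose(
            pca(matrix).explained_ratio, pca(permuted).explained_ratio, atol=1e-10
        )

    def test_zero_variance_columns_dropped_under_scaling(self):
        matrix = sample_matrix([[1, 5, 2], [2, 5, 1], [3, 5, 4]])
        result = pca(matrix, scale=True)
        assert list(result.loadings.index) == ["f0", "f2"]

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            pca(sample_matrix([[1, 2, 3]]))

    def test_pc1_sign_separates_the_two_substrates(self, mapped_study, caseins):
        result = pca(residue_feature_matrix(mapped_study, caseins))
        pc1 = result.scores["PC1"]
        casein = pc1.xs("casein", level="substrate")
        hydrolysate = pc1.xs("hydrolysate", level="substrate")
        assert casein.min() > 0 > hydrolysate.max() or casein.max() < 0 < hydrolysate.min()


class TestPeptideFeatureMatrix:
    def test_presence_filter_excludes_single_time_peptides(self):
        obs = [
            make_obs("YPFPGPI", time_min=5),
            make_obs("YPFPGPI", time_min=10),
            make_obs("RYLGYLE", time_min=5),
        ]
        matrix = peptide_feature_matrix(obs, min_presence=2)
        assert list(matrix.columns) == ["YPFPGPI"]
        assert peptide_feature_matrix(obs, min_presence=1).shape[1] == 2

    def test_presence_is_scoped_within_substrate_by_default(self):
        obs = [
            make_obs("YPFPGPI", substrate="casein", time_min=5),
            make_obs("YPFPGPI", substrate="hydrolysate", time_min=10),
        ]
        assert peptide_feature_matrix(obs, min_presence=2).shape[1] == 0
        assert peptide_feature_matrix(obs, min_presence=2, scope="overall").shape[1] == 1

    def test_filter_count_matches_brute_force_tally(self, mapped_study):
        matrix = peptide_feature_matrix(mapped_study, min_presence=2)
        times_of = {}
        for o in mapped_study:
            if o.intensity > 0:
                times_of.setdefault((o.substrate, o.sequence), set()).add(o.time_min)
        expected = {
            seq for (sub, seq), times in times_of.items() if len(times) >= 2
        }
        assert set(matrix.columns) == expected

    def test_values_are_summed_intensities(self):
        obs = [
            make_obs("YPFPGPI", 2.0, time_min=5, animal_id="p1"),
            make_obs("YPFPGPI", 3.0, time_min=5, animal_id="p2"),
            make_obs("YPFPGPI", 4.0, time_min=10),
        ]
        matrix = peptide_feature_matrix(obs, min_presence=2)
        assert matrix.loc[("casein", 5), "YPFPGPI"] == 5.0

    def test_invalid_min_presence(self):
        with pytest.raises(ConfigError):
            peptide_feature_matrix([], min_presence=0)


class TestHierarchicalCluster:
    def test_duplicate_pairs_merge_first_at_height_zero(self):
        matrix = sample_matrix([[1, 2], [5, 6], [1, 2], [5, 6]])
        result = hierarchical_cluster(matrix, log_transform=False)
        Z = result.merge_tree
        assert Z[0, 2] == 0.0 and Z[1, 2] == 0.0
        assert {frozenset(Z[0, :2].astype(int)), frozenset(Z[1, :2].astype(int))} == {
            frozenset({0, 2}), frozenset({1, 3}),
        }

    def test_average_linkage_matches_naive_agglomeration(self):
        rng = np.random.default_rng(12)
        for n in (5, 8, 12):
            X = rng.normal(size=(n, 4))
            result = hierarchical_cluster(
                sample_matrix(X), linkage="average", log_transform=False
            )
            expected = naive_average_agglomeration(X)
            assert np.allclose(squareform(cophenet(result.merge_tree)), expected, atol=1e-8)

    def test_single_linkage_heights_are_mst_edges(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(10, 3))
        result = hierarchical_cluster(
            sample_matrix(X), linkage="single", log_transform=False
        )
        mst = minimum_spanning_tree(squareform(pdist(X))).toarray()
        assert np.allclose(
            np.sort(result.merge_tree[:, 2]), np.sort(mst[mst > 0]), atol=1e-10
        )

    def test_cut_recovers_planted_substrates(self, mapped_study):
        matrix = peptide_feature_matrix(mapped_study, min_presence=2)
        result = hierarchical_cluster(matrix)
        labels = result.cut(2)
        truth = [key[0] for key in result.row_keys]
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_row_permutation_changes_nothing_up_to_relabeling(self):
        rng = np.random.default_rng(14)
        matrix = sample_matrix(rng.normal(size=(9, 5)) ** 2)
        result = hierarchical_cluster(matrix)
        perm = rng.permutation(9)
        permuted = hierarchical_cluster(matrix.iloc[perm])
        labels = result.cut(3)
        assert adjusted_rand_score(labels[perm], permuted.cut(3)) == 1.0

    def test_merge_heights_monotone_for_ward(self, mapped_study):
        matrix = peptide_feature_matrix(mapped_study)
        Z = hierarchical_cluster(matrix).merge_tree
        assert np.all(np.diff(Z[:, 2]) >= -1e-12)

    def test_newick_round_trips_all_leaves(self, mapped_study):
        matrix = peptide_feature_matrix(mapped_study)
        result = hierarchical_cluster(matrix)
        tree = Phylo.read(io.StringIO(result.to_newick()), "newick")
        assert tree.count_terminals() == matrix.shape[0]

    def test_leaf_order_is_a_permutation(self, mapped_study):
        matrix = peptide_feature_matrix(mapped_study)
        result = hierarchical_cluster(matrix)
        assert sorted(result.leaf_order) == list(range(matrix.shape[0]))

    def test_correlation_distance_with_flat_rows_uses_fallback(self):
        matrix = sample_matrix([[1, 1, 1], [1, 1, 1], [1, 2, 3]])
        result = hierarchical_cluster(
            matrix, distance="correlation", linkage="average", log_transform=False
        )
        assert result.merge_tree[0, 2] == 0.0  # identical flat rows at distance 0

    def test_ward_requires_euclidean(self):
        with pytest.raises(ConfigError):
            hierarchical_cluster(sample_matrix([[1, 2], [3, 4]]), distance="correlation")
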