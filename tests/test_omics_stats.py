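"""Expression processing: quantile normalization, presence filter, DE t-tests,
hierarchical clustering against a brute-force oracle, and kNN imputation."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

import baxloc as bl
from baxloc.errors import DegenerateSampleError, LabelingError, UndefinedDistanceError
from baxloc.omics_stats import ExpressionMatrix


def matrix(values, mask=None, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    vdf = pd.DataFrame(values, index=genes, columns=samples)
    mdf = (pd.DataFrame(np.asarray(mask, bool), index=genes, columns=samples)
           if mask is not None else pd.DataFrame(False, index=genes, columns=samples))
    return ExpressionMatrix(values=vdf, mask=mdf)


class TestQuantileNormalize:
    def test_two_shifted_samples_meet_at_row_means(self):
        m = matrix([[1, 4], [2, 5], [3, 6]])
        out = bl.quantile_normalize(m)
        assert np.allclose(out.values.to_numpy(), [[2.5, 2.5], [3.5, 3.5], [4.5, 4.5]])

    def test_identical_multisets_unchanged(self):
        m = matrix([[3, 1], [1, 2], [2, 3]])
        out = bl.quantile_normalize(m)
        assert np.allclose(out.values.to_numpy(), m.values.to_numpy())

    def test_column_multisets_identical_afterwards(self):
        rng = np.random.default_rng(0)
        m = matrix(rng.normal(size=(40, 5)))
        out = bl.quantile_normalize(m).values.to_numpy()
        ref = np.sort(out[:, 0])
        for j in range(1, 5):
            assert np.allclose(np.sort(out[:, j]), ref)

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        m = matrix(rng.normal(size=(30, 4)))
        once = bl.quantile_normalize(m)
        twice = bl.quantile_normalize(once)
        assert np.allclose(once.values.to_numpy(), twice.values.to_numpy(),
                           atol=1e-12)

    def test_ranks_preserved_within_sample(self):
        rng = np.random.default_rng(2)
        m = matrix(rng.normal(size=(25, 3)))
        out = bl.quantile_normalize(m)
        for col in m.samples:
            assert np.array_equal(np.argsort(m.values[col].to_numpy()),
                                  np.argsort(out.values[col].to_numpy()))

    def test_all_missing_sample_rejected(self):
        m = matrix([[1, 2], [3, 4]], mask=[[False, True], [False, True]])
        with pytest.raises(DegenerateSampleError):
            bl.quantile_normalize(m)

    def test_matches_limma_reference(self, tmp_path):
        """Cross-check against limma::normalizeQuantiles via Rscript."""
        import shutil
        import subprocess
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        rng = np.random.default_rng(3)
        m = matrix(rng.normal(8, 2, size=(20, 4)))
        inp = tmp_path / "m.tsv"
        outp = tmp_path / "ref.tsv"
        m.values.to_csv(inp, sep="\t")
        script = (
            f"x <- as.matrix(read.delim('{inp}', row.names=1));"
            f"y <- limma::normalizeQuantiles(x);"
            f"write.table(y, '{outp}', sep='\\t', quote=FALSE)"
        )
        res = subprocess.run(["Rscript", "-e", script], capture_output=True)
        if res.returncode != 0:
            pytest.skip(f"limma unavailable: {res.stderr.decode()[:200]}")
        ref = pd.read_csv(outp, sep="\t").to_numpy()
        ours = bl.quantile_normalize(m).values.to_numpy()
        assert np.allclose(ours, ref, atol=1e-8)


class TestPresenceFilter:
    def test_boundaries_inclusive_at_80_percent(self):
        mask = np.zeros((2, 10), bool)
        mask[0, :2] = True   # 80% present: kept
        mask[1, :3] = True   # 70% present: removed
        m = matrix(np.ones((2, 10)), mask=mask)
        out = bl.presence_filter(m, 0.8)
        assert out.genes == ["g0"]

    def test_matches_direct_count_oracle(self):
        rng = np.random.default_rng(4)
        mask = rng.random((50, 12)) < 0.3
        m = matrix(rng.normal(size=(50, 12)), mask=mask)
        out = bl.presence_filter(m, 0.8)
        expected = [f"g{i}" for i in range(50)
                    if (~mask[i]).sum() / 12 >= 0.8]
        assert out.genes == expected

    def test_values_never_altered(self):
        rng = np.random.default_rng(5)
        m = matrix(rng.normal(size=(10, 5)), mask=rng.random((10, 5)) < 0.5)
        out = bl.presence_filter(m, 0.4)
        assert set(out.genes) <= set(m.genes)
        pd.testing.assert_frame_equal(out.values, m.values.loc[out.genes])


class TestDeGenes:
    def test_null_discovery_rate_matches_alpha(self):
        labels = [0] * 10 + [1] * 10
        m, _ = bl.simulate_expression(labels, n_genes=2000, n_de=0,
                                      effect_log2=0.0, seed=6)
        de = bl.de_genes(m, labels, alpha=0.05)
        rate = de["selected"].mean()
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / 2000) + 0.005

    def test_recovery_matches_independent_oracle(self):
        labels = [0] * 17 + [1] * 17
        m, planted = bl.simulate_expression(labels, n_genes=2000, n_de=50,
                                            effect_log2=2.0, sd_log2=0.5, seed=7)
        de = bl.de_genes(m, labels, alpha=0.05)
        selected = set(de.loc[de["selected"], "gene"])
        # oracle: per-gene pooled-variance t evaluated directly via scipy
        oracle = set()
        vals = m.values.to_numpy()
        for i, g in enumerate(m.genes):
            p = st.ttest_ind(vals[i, 17:], vals[i, :17], equal_var=True).pvalue
            if p < 0.05:
                oracle.add(g)
        assert selected == oracle
        assert len(set(planted) & selected) >= 48  # near-complete recovery

    def test_masked_values_excluded_and_thin_genes_skipped(self):
        values = np.array([[1.0, 2, 3, 4, 1, 2, 3, 4],
                           [1.0, 2, 3, 4, 5, 6, 7, 8]])
        mask = np.zeros((2, 8), bool)
        mask[0, :3] = True  # one observed value in class A: skipped
        m = matrix(values, mask=mask)
        labels = [0] * 4 + [1] * 4
        de = bl.de_genes(m, labels)
        assert list(de["gene"]) == ["g1"]

    def test_zero_variance_gene_skipped(self):
        m = matrix([[1.0, 1, 1, 2, 2, 2], [1.0, 2, 3, 4, 5, 6]])
        de = bl.de_genes(m, [0, 0, 0, 1, 1, 1])
        assert "g0" not in set(de["gene"])  # zero within-class variance

    def test_single_class_rejected(self):
        m = matrix(np.ones((3, 4)))
        with pytest.raises(LabelingError):
            bl.de_genes(m, [1, 1, 1, 1])

    def test_bh_adjustment_reported(self):
        rng = np.random.default_rng(8)
        m = matrix(rng.normal(size=(100, 10)))
        de = bl.de_genes(m, [0] * 5 + [1] * 5)
        assert (de["p_bh"] >= de["p"] - 1e-12).all()


def brute_force_complete_linkage(dist: np.ndarray):
    """Exhaustive agglomeration oracle: at each step recompute all pairwise
    complete-linkage distances and merge the closest pair.  Returns the
    partition after each merge and the merge heights."""
    clusters = [frozenset([i]) for i in range(dist.shape[0])]
    partitions, heights = [], []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            h = max(dist[i, j] for i in clusters[a] for j in clusters[b])
            if best is None or h < best[0]:
                best = (h, a, b)
        h, a, b = best
        merged = clusters[a] | clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [merged]
        partitions.append(frozenset(clusters))
        heights.append(h)
    return partitions, heights


class TestHierarchicalCluster:
    def test_identical_samples_merge_first_at_zero(self):
        m = matrix([[1, 1, 5], [2, 2, 6], [3, 3, 9]])
        dendro = bl.hierarchical_cluster(m, distance="euclidean")
        assert dendro.heights[0] == pytest.approx(0.0, abs=1e-12)
        _, labels = bl.hierarchical_cluster(m, distance="euclidean", k=2)
        assert labels["s0"] == labels["s1"] != labels["s2"]

    def test_anticorrelated_pair_has_pearson_distance_two(self):
        m = matrix([[1, -1], [2, -2], [3, -3]])
        dendro = bl.hierarchical_cluster(m, distance="pearson")
        assert dendro.heights[0] == pytest.approx(2.0, abs=1e-9)

    @pytest.mark.parametrize("metric", ["pearson", "euclidean"])
    def test_matches_brute_force_agglomeration(self, metric):
        rng = np.random.default_rng(9)
        m = matrix(rng.normal(size=(8, 5)))  # 5 sample items over 8 features
        dendro = bl.hierarchical_cluster(m, distance=metric)
        from baxloc.omics_stats import _pairwise_distance
        import scipy.spatial.distance as ssd
        dist = ssd.squareform(_pairwise_distance(m.observed().to_numpy().T, metric))
        partitions, heights = brute_force_complete_linkage(dist)
        assert np.allclose(dendro.heights, heights, rtol=1e-9)
        n = 5
        # replay scipy merges into partitions and compare step by step
        clusters = {i: frozenset([i]) for i in range(n)}
        for step, (a, b, h, _) in enumerate(dendro.merges):
            merged = clusters.pop(int(a)) | clusters.pop(int(b))
            clusters[n + step] = merged
            assert frozenset(clusters.values()) == partitions[step]

    def test_pairwise_complete_pearson_needs_three_shared(self):
        mask = np.array([[False, True], [False, True],
                         [True, False], [True, False]])
        m = matrix(np.arange(8, dtype=float).reshape(4, 2), mask=mask)
        with pytest.raises(UndefinedDistanceError):
            bl.hierarchical_cluster(m, distance="pearson")

    def test_newick_export_parses(self):
        from io import StringIO
        from Bio import Phylo
        rng = np.random.default_rng(10)
        m = matrix(rng.normal(size=(6, 4)))
        dendro = bl.hierarchical_cluster(m, distance="euclidean")
        tree = Phylo.read(StringIO(dendro.to_newick()), "newick")
        assert sorted(t.name for t in tree.get_terminals()) == sorted(m.samples)

    def test_signature_clustering_recovers_planted_groups(self):
        """Desk-scale signature workflow: cluster the DE submatrix, expect
        >= 90% agreement with planted groups at a 2-log2 effect."""
        labels = [0] * 17 + [1] * 17
        m, _ = bl.simulate_expression(labels, n_genes=400, n_de=40,
                                      effect_log2=2.0, sd_log2=0.5, seed=11)
        de = bl.de_genes(m, labels, alpha=0.05)
        sig = de.loc[de["selected"], "gene"].tolist()
        _, cl = bl.hierarchical_cluster(m.subset_genes(sig),
                                        distance="pearson", k=2)
        truth = np.array(labels)
        pred = cl.to_numpy()
        agree = max(np.mean(pred - 1 == truth), np.mean(2 - pred == truth))
        assert agree >= 0.9


class TestKnnImpute:
    def test_identical_neighbor_with_k1(self):
        vals = np.array([[1.0, 2, 3, 4], [1.0, 2, 3, 4], [9.0, 9, 9, 9]])
        mask = np.zeros((3, 4), bool)
        mask[0, 3] = True
        m = matrix(vals, mask=mask)
        out, missing = bl.knn_impute(m, k=1)
        assert out.values.iloc[0, 3] == pytest.approx(4.0)
        assert not missing
        assert not out.mask.to_numpy().any()

    def test_constant_matrix_holes_filled_with_constant(self):
        vals = np.full((5, 4), 7.0)
        mask = np.zeros((5, 4), bool)
        mask[1, 2] = mask[3, 0] = True
        out, _ = bl.knn_impute(matrix(vals, mask=mask), k=3)
        assert np.allclose(out.values.to_numpy(), 7.0)

    def test_toy_hole_equals_mean_of_two_nearest_rows(self):
        vals = np.array([
            [1.0, 2.0, 3.0, 4.0],   # hole at col 3
            [1.1, 2.1, 3.1, 4.1],   # nearest
            [0.9, 1.9, 2.9, 3.9],   # second nearest
            [5.0, 6.0, 7.0, 8.0],
            [1.5, 2.5, 3.5, 9.0],
            [9.0, 1.0, 0.0, 2.0],
        ])
        mask = np.zeros((6, 4), bool)
        mask[0, 3] = True
        out, _ = bl.knn_impute(matrix(vals, mask=mask), k=2)
        # distances on shared observed cols 0..2: rows 1 and 2 tie at ~0.173
        assert out.values.iloc[0, 3] == pytest.approx((4.1 + 3.9) / 2)

    def test_unimputable_entry_reported_and_left_masked(self):
        vals = np.array([[1.0, 2.0], [3.0, 4.0]])
        mask = np.array([[False, True], [False, True]])  # no donor for col 1
        out, missing = bl.knn_impute(matrix(vals, mask=mask), k=1)
        assert set(missing) == {("g0", "s1"), ("g1", "s1")}
        assert out.mask.iloc[0, 1] and out.mask.iloc[1, 1]
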