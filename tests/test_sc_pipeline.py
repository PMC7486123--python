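"""scRNA-seq stage: boundaries, normalisation identities, clustering, DE oracles."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from amygmap import sc_pipeline as sc
from amygmap.containers import CountMatrix, ExpressionMatrix


def enum_ranksum_p(x, y):
    """Independent exhaustive-enumeration two-sided rank-sum oracle."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n_x = len(x)
    obs = ranks[:n_x].sum()
    mean = ranks.sum() * n_x / len(pooled)
    dev = abs(obs - mean)
    hits = total = 0
    for comb in combinations(range(len(pooled)), n_x):
        total += 1
        if abs(ranks[list(comb)].sum() - mean) >= dev - 1e-12:
            hits += 1
    return hits / total


class TestQCAndCPM:
    def test_qc_boundary_is_strict(self, toy_counts_factory):
        m = toy_counts_factory([[9_999, 10_000, 12_000]])
        kept, report = sc.qc_filter(m)
        assert list(kept.cells) == ["c1", "c2"]
        assert report["removed_cells"] == ["c0"]

    def test_qc_empty_matrix(self, toy_counts_factory):
        m = toy_counts_factory(np.zeros((3, 0), dtype=int))
        kept, report = sc.qc_filter(m)
        assert kept.n_cells == 0 and report["n_removed"] == 0

    def test_qc_all_removed_warns_not_crashes(self, toy_counts_factory):
        m = toy_counts_factory([[5, 7]])
        kept, report = sc.qc_filter(m)
        assert kept.n_cells == 0 and "warning" in report

    def test_cpm_arithmetic(self, toy_counts_factory):
        m = toy_counts_factory([[10], [99_990]])
        e = sc.to_cpm(m)
        assert e.cpm.iloc[0, 0] == pytest.approx(100.0)

    def test_cpm_columns_sum_to_1e6(self, small_sim):
        cm, _ = small_sim
        e = sc.to_cpm(cm)
        np.testing.assert_allclose(e.cpm.sum(axis=0), 1e6, rtol=1e-9)

    def test_cpm_zero_total_cell_rejected(self, toy_counts_factory):
        m = toy_counts_factory([[0, 5]])
        with pytest.raises(ValueError):
            sc.to_cpm(m)


class TestGating:
    @pytest.fixture
    def gate_matrix(self):
        cpm = pd.DataFrame(
            {
                "c_non": [249.0, 0.0],
                "c_inh": [300.0, 150.0],
                "c_exc_edge": [300.0, 100.0],
                "c_exc": [250.0, 0.0],
            },
            index=["Snap25", "Gad1"],
        )
        return ExpressionMatrix(cpm)

    def test_gate_boundaries_strict(self, gate_matrix):
        classes = sc.gate_cell_classes(gate_matrix)
        assert list(classes["non_neuronal"]) == ["c_non"]
        assert list(classes["interneuron"]) == ["c_inh"]
        # Gad1 == 100 and Snap25 == 250 both stay excitatory
        assert set(classes["excitatory"]) == {"c_exc_edge", "c_exc"}

    def test_missing_gate_gene_named(self, gate_matrix):
        with pytest.raises(KeyError, match="Slc32a1"):
            sc.gate_cell_classes(gate_matrix, neuronal_gene="Slc32a1")


class TestVariableGenes:
    def test_hand_computed_toy(self):
        """Dispersion z-scores on a 3-gene toy, recomputed from first principles."""
        rng = np.random.default_rng(0)
        n = 60
        base = np.full(n, 3.0)
        quiet1 = base + rng.normal(0, 0.3, n)
        quiet2 = base + rng.normal(0, 0.3, n)
        wild = base + rng.choice([0.0, 12.0], n)  # overdispersed, same mean band
        cpm = pd.DataFrame(
            np.vstack([quiet1, quiet2, wild]).clip(0),
            index=["quiet1", "quiet2", "wild"],
            columns=[f"c{i}" for i in range(n)],
        )
        e = ExpressionMatrix(cpm)
        # independent recompute: all three genes fall in one mean bin, so the
        # overdispersed gene is the only one with z >= 1
        mean = cpm.mean(axis=1)
        disp = np.log(cpm.var(axis=1, ddof=1) / mean)
        z = (disp - disp.mean()) / disp.std(ddof=1)
        expect = set(cpm.index[(np.log1p(mean) >= 0.125) & (np.log1p(mean) <= 3) & (z >= 1)])
        got = set(sc.select_variable_genes(e, n_bins=1))
        assert got == expect == {"wild"}

    def test_constant_gene_excluded(self):
        cpm = pd.DataFrame([[2.0] * 10, list(range(10))], index=["const", "varies"],
                           columns=[f"c{i}" for i in range(10)])
        got = sc.select_variable_genes(ExpressionMatrix(cpm), n_bins=1, y_cutoff=-5)
        assert "const" not in got

    def test_alternative_cutoffs_honoured(self, small_sim):
        cm, _ = small_sim
        e = sc.to_cpm(cm)
        strict = sc.select_variable_genes(e, x_low=0.0125, x_high=3, y_cutoff=3)
        default = sc.select_variable_genes(e)
        assert len(strict) < len(default)


@pytest.fixture(scope="module")
def blobs():
    rng = np.random.default_rng(1)
    n = 150
    a = rng.normal(0, 1, (n, 30)) + 8
    b = rng.normal(0, 1, (n, 30)) - 8
    cpm = pd.DataFrame(np.vstack([a, b]).T.clip(0),
                       index=[f"g{i}" for i in range(30)],
                       columns=[f"c{i}" for i in range(2 * n)])
    labels = np.array([0] * n + [1] * n)
    return ExpressionMatrix(cpm), labels


@pytest.fixture(scope="module")
def separable():
    """Disjoint marker supports: perfectly separable classes."""
    rng = np.random.default_rng(9)
    n = 150
    a = np.zeros((20, n)); a[:10] = rng.uniform(50, 100, (10, n))
    b = np.zeros((20, n)); b[10:] = rng.uniform(50, 100, (10, n))
    cpm = pd.DataFrame(np.hstack([a, b]), index=[f"g{i}" for i in range(20)],
                       columns=[f"c{i}" for i in range(2 * n)])
    labels = pd.Series([0] * n + [1] * n, index=cpm.columns)
    return ExpressionMatrix(cpm), labels


class TestPCAAndClustering:
    def test_duplicate_cells_identical_scores(self):
        rng = np.random.default_rng(2)
        cpm = pd.DataFrame(rng.uniform(0, 50, (12, 6)),
                           index=[f"g{i}" for i in range(12)],
                           columns=[f"c{i}" for i in range(6)])
        cpm["c_dup"] = cpm["c0"]
        scores = sc.pca_embed(ExpressionMatrix(cpm), list(cpm.index), n_pcs=3)
        np.testing.assert_allclose(scores.loc["c0"], scores.loc["c_dup"], atol=1e-9)

    def test_pc1_separates_blobs(self, blobs):
        e, labels = blobs
        scores = sc.pca_embed(e, list(e.genes), n_pcs=5)
        pc1 = scores["PC1"].to_numpy()
        auc_split = (pc1[labels == 0].mean() - pc1[labels == 1].mean())
        # perfect separation: no overlap between the groups on PC1
        assert min(pc1[labels == 0]) > max(pc1[labels == 1]) or \
               min(pc1[labels == 1]) > max(pc1[labels == 0])
        assert abs(auc_split) > 0

    def test_variance_explained_non_increasing(self, small_sim):
        from sklearn.decomposition import PCA

        cm, _ = small_sim
        e = sc.to_cpm(cm)
        genes = sc.select_variable_genes(e)
        X = e.log.loc[genes].values.T
        X = (X - X.mean(0)) / X.std(0, ddof=1)
        var = PCA(n_components=10, svd_solver="full").fit(X).explained_variance_
        assert (np.diff(var) <= 1e-9).all()

    def test_two_blobs_two_clusters(self, blobs):
        e, labels = blobs
        scores = sc.pca_embed(e, list(e.genes), n_pcs=5)
        res = sc.cluster_graph(scores, resolution=0.2, seed=0)
        assert res.n_clusters == 2
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(labels, res.labels.values) == 1.0

    def test_single_blob_one_cluster(self):
        rng = np.random.default_rng(3)
        cpm = pd.DataFrame(rng.normal(20, 1, (20, 120)).clip(0),
                           index=[f"g{i}" for i in range(20)],
                           columns=[f"c{i}" for i in range(120)])
        scores = sc.pca_embed(ExpressionMatrix(cpm), list(cpm.index), n_pcs=5)
        res = sc.cluster_graph(scores, resolution=0.2, seed=0)
        assert res.n_clusters == 1

    def test_clustering_label_permutation_invariant(self, blobs):
        e, _ = blobs
        scores = sc.pca_embed(e, list(e.genes), n_pcs=5)
        res = sc.cluster_graph(scores, resolution=0.2, seed=0)
        perm = np.random.default_rng(4).permutation(len(scores))
        res_p = sc.cluster_graph(scores.iloc[perm], resolution=0.2, seed=0)
        aligned = res_p.labels.loc[scores.index]
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(res.labels.values, aligned.values) == 1.0


class TestDifferentialExpression:
    def test_bonferroni_arithmetic(self):
        rng = np.random.default_rng(5)
        cpm = pd.DataFrame(rng.uniform(1, 100, (10, 12)),
                           index=[f"g{i}" for i in range(10)],
                           columns=[f"c{i}" for i in range(12)])
        labels = pd.Series([0] * 6 + [1] * 6, index=cpm.columns)
        de = sc.differential_expression(ExpressionMatrix(cpm), labels, 0, 1)
        np.testing.assert_allclose(
            de.table["p_adj"], np.minimum(de.table["p_raw"] * de.n_tested, 1.0)
        )
        assert (de.table["p_adj"] >= de.table["p_raw"] - 1e-15).all()

    def test_small_cluster_rejected(self):
        cpm = pd.DataFrame(np.ones((4, 5)), index=list("abcd"),
                           columns=[f"c{i}" for i in range(5)])
        labels = pd.Series([0, 0, 1, 1, 1], index=cpm.columns)
        with pytest.raises(ValueError):
            sc.differential_expression(ExpressionMatrix(cpm), labels, 0, 1)

    @pytest.mark.parametrize("nx,ny", [(4, 4), (5, 7), (6, 6), (8, 8)])
    def test_exact_p_matches_enumeration(self, nx, ny):
        rng = np.random.default_rng(nx * 10 + ny)
        x = rng.normal(0, 1, nx)
        y = rng.normal(1.2, 1, ny)
        assert sc.rank_sum_test(x, y) == pytest.approx(enum_ranksum_p(x, y), abs=1e-12)

    def test_screen_matches_scipy_asymptotic(self):
        """The vectorised screen equals the tie-corrected normal rank-sum test."""
        rng = np.random.default_rng(8)
        X = np.round(rng.gamma(1.0, 10.0, (40, 60)))  # integer ties included
        a = np.arange(25)
        b = np.arange(25, 60)
        mine = sc._ranksum_screen(X, a, b)
        ref = np.array([
            stats.mannwhitneyu(X[i, a], X[i, b], alternative="two-sided",
                               method="asymptotic").pvalue
            for i in range(X.shape[0])
        ])
        np.testing.assert_allclose(mine, ref, rtol=1e-10)

    def test_shifted_toy_direction(self):
        cpm = pd.DataFrame(
            np.vstack([
                np.r_[np.full(6, 200.0), np.full(6, 10.0)],
                np.full(12, 50.0) + np.arange(12) * 1e-3,
            ]),
            index=["marker", "flat"],
            columns=[f"c{i}" for i in range(12)],
        )
        labels = pd.Series([0] * 6 + [1] * 6, index=cpm.columns)
        de = sc.differential_expression(ExpressionMatrix(cpm), labels, 0, 1)
        assert de.table.loc["marker", "enriched_in"] == 0
        assert de.table.loc["marker", "p_raw"] < de.table.loc["flat", "p_raw"]


class TestRandomForestExperiment:
    def test_separable_toy_perfect_accuracy(self, separable):
        e, labels = separable
        rf = sc.rf_subsample_experiment(e, labels, list(e.genes),
                                        n_train_grid=[50], n_reps=3, n_trees=50, seed=0)
        assert rf.mean_accuracy(50) == 1.0

    def test_shuffled_labels_give_chance_accuracy(self, separable):
        e, labels = separable
        shuffled = pd.Series(
            np.random.default_rng(10).permutation(labels.values), index=labels.index
        )
        rf = sc.rf_subsample_experiment(e, shuffled, list(e.genes),
                                        n_train_grid=[50], n_reps=5, n_trees=50, seed=0)
        majority = max(shuffled.mean(), 1 - shuffled.mean())
        assert abs(rf.mean_accuracy(50) - majority) < 0.12

    def test_n_train_too_large_rejected(self, separable):
        e, labels = separable
        with pytest.raises(ValueError):
            sc.rf_subsample_experiment(e, labels, list(e.genes),
                                       n_train_grid=[300], n_reps=1)


class TestEmbed2D:
    def test_reproducible_and_perplexity_guard(self):
        rng = np.random.default_rng(11)
        scores = pd.DataFrame(rng.normal(0, 1, (60, 5)),
                              index=[f"c{i}" for i in range(60)])
        a = sc.embed_2d(scores, perplexity=10, seed=1)
        b = sc.embed_2d(scores, perplexity=10, seed=1)
        np.testing.assert_allclose(a.values, b.values)
        with pytest.raises(ValueError):
            sc.embed_2d(scores, perplexity=30)
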