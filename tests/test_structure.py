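import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import norm
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import calinski_harabasz_score

from polyssr import (
    AlleleColumn,
    AlleleMatrix,
    DistanceMatrix,
    calinski_harabasz,
    fit_au,
    hclust_average,
    kmeans_cascade,
    multiscale_bootstrap_support,
    pca_binary,
)
from polyssr.structure import _merge_masks

from _oracles import calinski_two_pass, upgma_naive
from conftest import random_binary_matrix


def _dist(ids, D):
    return DistanceMatrix(list(ids), np.asarray(D, dtype=float), "euclidean", 1)


class TestHclustAverage:
    def test_forced_topology(self):
        d = _dist("ABC", [[0, 1, 4], [1, 0, 4], [4, 4, 0]])
        Z = hclust_average(d)
        assert set(Z[0, :2].astype(int)) == {0, 1}
        assert Z[0, 2] == pytest.approx(1.0)
        assert Z[1, 2] == pytest.approx(4.0)

    def test_ultrametric_input_reproduced(self):
        # cophenetic distances of a UPGMA tree on ultrametric input equal the input
        D = np.array(
            [[0, 2, 6, 6], [2, 0, 6, 6], [6, 6, 0, 4], [6, 6, 4, 0]], dtype=float
        )
        Z = hclust_average(_dist("abcd", D))
        coph = squareform(hierarchy.cophenet(Z))
        assert np.allclose(coph, D)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=20, derandomize=True, deadline=None)
    def test_matches_naive_upgma(self, seed):
        rng = np.random.default_rng(seed)
        n = 8
        D = squareform(rng.uniform(1, 10, size=n * (n - 1) // 2))
        Z = hclust_average(_dist([str(i) for i in range(n)], D))
        merges = upgma_naive(D)
        got_sets = []
        masks = [frozenset([i]) for i in range(n)]
        for a, b in Z[:, :2].astype(int):
            masks.append(masks[a] | masks[b])
            got_sets.append(masks[-1])
        assert got_sets == [s for s, _ in merges]
        assert np.allclose(Z[:, 2], [h for _, h in merges])

    def test_rejects_bad_linkage(self):
        with pytest.raises(ValueError):
            hclust_average(_dist("ab", [[0, 1], [1, 0]]), method="single")


class TestFitAu:
    SCALES = np.round(np.arange(0.5, 1.45, 0.1), 1)

    def test_flat_half_bp_gives_half_au(self):
        fit = fit_au(self.SCALES, np.full(len(self.SCALES), 0.5), B=1000)
        assert fit.v == pytest.approx(0.0, abs=1e-9)
        assert fit.c == pytest.approx(0.0, abs=1e-9)
        assert fit.au == pytest.approx(0.5)

    def test_recovers_exact_model(self):
        v, c = 1.0, 0.3
        s = np.sqrt(1.0 / self.SCALES)
        bp = 1.0 - norm.cdf(v * s + c / s)
        fit = fit_au(self.SCALES, bp, B=100000)
        assert fit.v == pytest.approx(v, abs=1e-6)
        assert fit.c == pytest.approx(c, abs=1e-6)
        assert fit.au == pytest.approx(1.0 - norm.cdf(0.7), abs=1e-6)

    def test_zero_curvature_means_au_equals_corrected_bp(self):
        v = 0.8
        s = np.sqrt(1.0 / self.SCALES)
        bp = 1.0 - norm.cdf(v * s)
        fit = fit_au(self.SCALES, bp, B=100000)
        assert abs(fit.c) < 1e-6
        assert fit.au == pytest.approx(fit.bp_corrected, abs=1e-6)

    def test_single_scale_rejected(self):
        with pytest.raises(ValueError, match="distinct scales"):
            fit_au([1.0], [0.8], B=1000)

    def test_identical_scales_rejected(self):
        with pytest.raises(ValueError, match="distinct scales"):
            fit_au([1.0, 1.0, 1.0], [0.8, 0.7, 0.9], B=1000)

    def test_never_observed_cluster_degenerates_to_zero(self):
        fit = fit_au(self.SCALES, np.zeros(len(self.SCALES)), B=1000)
        assert fit.degenerate
        assert fit.au == 0.0

    def test_always_observed_cluster_degenerates_to_one(self):
        fit = fit_au(self.SCALES, np.ones(len(self.SCALES)), B=1000)
        assert fit.degenerate
        assert fit.au == 1.0


def _two_block_panel(copies=3, block_len=30):
    """Individuals are exact copies of two very different profiles."""
    rng = np.random.default_rng(0)
    p1 = rng.integers(0, 2, size=block_len)
    p2 = 1 - p1
    p1[0] = p2[0] = 1  # keep every column observed
    X = np.vstack([p1] * copies + [p2] * copies)
    cols = [AlleleColumn(f"L{j // 3 + 1}", 100 + 2 * j) for j in range(block_len)]
    ids = [f"x{i}" for i in range(copies)] + [f"y{i}" for i in range(copies)]
    return AlleleMatrix(ids, cols, X)


class TestMultiscaleBootstrap:
    def test_certain_clusters_get_full_support(self):
        m = _two_block_panel()
        dendro = multiscale_bootstrap_support(m, B=100, seed=11)
        for members in (["x0", "x1", "x2"], ["y0", "y1", "y2"]):
            sup = dendro.support_for(members)
            assert sup is not None
            assert np.all(sup.bp_by_scale == 1.0)
            assert sup.au == 1.0

    def test_single_scale_refused(self):
        m = _two_block_panel()
        with pytest.raises(ValueError, match="distinct scales"):
            multiscale_bootstrap_support(m, scales=[1.0], B=100, seed=0)

    def test_small_b_refused(self):
        with pytest.raises(ValueError, match="at least 100"):
            multiscale_bootstrap_support(_two_block_panel(), B=10, seed=0)

    def test_seed_reproducibility(self):
        m = _two_block_panel()
        a = multiscale_bootstrap_support(m, B=100, seed=5)
        b = multiscale_bootstrap_support(m, B=100, seed=5)
        for sa, sb in zip(a.nodes, b.nodes):
            assert np.array_equal(sa.bp_by_scale, sb.bp_by_scale)
            assert sa.au == sb.au

    def test_marker_block_resampling_unit(self):
        m = _two_block_panel()
        dendro = multiscale_bootstrap_support(m, B=100, seed=3, unit="marker")
        sup = dendro.support_for(["x0", "x1", "x2"])
        assert sup is not None and sup.au == 1.0

    def test_au_close_to_bp_when_curvature_small(self, default_panel):
        matrix, _ = default_panel
        dendro = multiscale_bootstrap_support(matrix, B=200, seed=2)
        ref = int(np.argmin(np.abs(dendro.scales - 1.0)))
        for node in dendro.nodes:
            if node.degenerate or abs(node.c) >= 0.01:
                continue
            mc_se = np.sqrt(max(node.bp * (1 - node.bp), 1e-12) / dendro.B)
            assert abs(node.au - node.bp) <= max(2 * mc_se, 0.05)

    def test_newick_contains_support_labels(self):
        m = _two_block_panel()
        dendro = multiscale_bootstrap_support(m, B=100, seed=1)
        nwk = dendro.to_newick()
        assert nwk.endswith(";")
        assert "[au=100,bp=100]" in nwk
        for ind in m.individuals:
            assert ind in nwk


class TestCalinski:
    def test_hand_example(self):
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        labels = [1, 1, 2, 2]
        assert calinski_harabasz(X, labels) == pytest.approx(200.0)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=30, derandomize=True)
    def test_matches_brute_force_and_sklearn(self, seed):
        rng = np.random.default_rng(seed)
        n, p, k = 12, 3, int(rng.integers(2, 5))
        X = rng.normal(size=(n, p))
        labels = np.concatenate([np.arange(k), rng.integers(0, k, size=n - k)])
        got = calinski_harabasz(X, labels)
        assert got == pytest.approx(calinski_two_pass(X, labels))
        assert got == pytest.approx(calinski_harabasz_score(X, labels))

    def test_two_point_cluster_boundary(self):
        X = np.array([[0.0], [0.1], [5.0], [9.0], [9.1]])
        labels = [0, 0, 1, 2, 2]  # k = n - 2, includes a singleton
        assert calinski_harabasz(X, labels) == pytest.approx(calinski_two_pass(X, labels))

    def test_zero_within_scatter_flagged_infinite(self):
        X = np.array([[0.0], [0.0], [1.0], [1.0]])
        assert calinski_harabasz(X, [0, 0, 1, 1]) == float("inf")

    def test_requires_two_clusters(self):
        with pytest.raises(ValueError):
            calinski_harabasz(np.zeros((3, 1)), [0, 0, 0])


class TestKmeansCascade:
    def test_two_separated_groups(self, default_panel):
        matrix, truth = default_panel
        part = kmeans_cascade(matrix, seed=0)
        assert part.best_k == 2
        labels = part.assignments_by_k[2]
        y = np.asarray([truth.group_labels[i] for i in matrix.individuals])
        # perfect two-group recovery up to label swap
        assert len(set(zip(labels.tolist(), y.tolist()))) == 2

    def test_three_blobs(self):
        rng = np.random.default_rng(1)
        centers = np.array([[0, 0], [40, 0], [0, 40]])
        X = np.vstack([c + rng.normal(scale=0.5, size=(6, 2)) for c in centers])
        part = kmeans_cascade(X, k_min=2, k_max=6, restarts=5, seed=2)
        assert part.best_k == 3

    def test_identical_points_degenerate(self):
        X = np.ones((8, 3))
        part = kmeans_cascade(X, k_min=2, k_max=4, seed=0)
        assert part.degenerate
        assert part.best_k == 2

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError):
            kmeans_cascade(np.zeros((5, 2)), k_min=2, k_max=5)

    def test_objective_competitive_with_sklearn(self, default_panel):
        matrix, _ = default_panel
        X = matrix.X.astype(float)
        part = kmeans_cascade(matrix, k_min=2, k_max=4, restarts=10, seed=0)
        for k in (2, 3, 4):
            sk = KMeans(n_clusters=k, n_init=10, random_state=0).fit(X)
            assert part.inertia_by_k[k] <= sk.inertia_ * 1.05

    def test_labels_are_one_based_and_dense(self, default_panel):
        part = kmeans_cascade(default_panel[0], k_min=2, k_max=5, seed=3)
        for k in part.k_range:
            labels = part.assignments_by_k[k]
            assert labels.min() >= 1 and labels.max() <= k


class TestPcaBinary:
    def test_pct_var_sums_to_100(self, default_panel):
        res = pca_binary(default_panel[0])
        assert res.pct_var.sum() == pytest.approx(100.0)
        assert np.all(np.diff(res.pct_var) <= 1e-9)

    def test_duplicated_individual_identical_scores(self):
        rng = np.random.default_rng(4)
        m = random_binary_matrix(rng, n=6, n_loci=5)
        X = np.vstack([m.X, m.X[0]])
        dup = AlleleMatrix(m.individuals + ["dup"], m.alleles, X)
        res = pca_binary(dup)
        assert np.allclose(res.scores[0], res.scores[-1])

    def test_scores_preserve_centered_distances(self, default_panel):
        matrix, _ = default_panel
        res = pca_binary(matrix)
        Xc = matrix.X.astype(float) - matrix.X.mean(axis=0)
        from scipy.spatial.distance import pdist

        assert np.allclose(pdist(res.scores), pdist(Xc))

    def test_matches_sklearn_variance_ratio(self, default_panel):
        matrix, _ = default_panel
        res = pca_binary(matrix)
        sk = PCA().fit(matrix.X.astype(float))
        assert np.allclose(res.pct_var[:5], 100 * sk.explained_variance_ratio_[:5], atol=1e-8)

    def test_constant_matrix_rejected(self):
        m = AlleleMatrix(["a", "b", "c"], [AlleleColumn("M1", 100)], np.ones((3, 1)))
        with pytest.raises(ValueError, match="zero variance"):
            pca_binary(m)

    def test_needs_three_individuals(self):
        m = AlleleMatrix(["a", "b"], [AlleleColumn("M1", 100)], np.array([[1], [1]]))
        with pytest.raises(ValueError):
            pca_binary(m)


def test_merge_masks_cover_all_leaves():
    rng = np.random.default_rng(0)
    D = squareform(rng.uniform(1, 5, size=15))
    Z = hierarchy.linkage(squareform(D, checks=False), method="average")
    masks = _merge_masks(Z, 6)
    assert masks[-1] == (1 << 6) - 1
    assert len(masks) == 5
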