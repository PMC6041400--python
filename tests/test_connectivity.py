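import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from optonet import (
    build_adjacency,
    connectivity_map,
    infer_connectivity,
    mean_global_connectivity,
    pairwise_xcorr,
    reshuffle_null,
)
from optonet.segmentation import RoiSet


class TestPairwiseXcorr:
    def test_identical_traces_correlate_at_one(self, rng):
        x = rng.normal(size=600)
        corr = pairwise_xcorr(np.column_stack([x, x]), frame_rate=10.0)
        assert corr[0, 1] == pytest.approx(1.0)
        assert np.allclose(np.diag(corr), 1.0)

    def test_shifted_copy_within_lag_window_correlates_at_one(self, rng):
        x = rng.normal(size=600)
        data = np.column_stack([x, np.roll(x, 4)])  # 0.4 s shift at 10 Hz
        corr = pairwise_xcorr(data, max_lag=0.5, frame_rate=10.0)
        assert corr[0, 1] == pytest.approx(1.0)

    def test_independent_noise_correlates_weakly(self, rng):
        data = rng.normal(size=(600, 10))
        corr = pairwise_xcorr(data, frame_rate=10.0)
        off = corr[np.triu_indices(10, k=1)]
        assert np.percentile(off, 95) < 0.5  # far below a genuine shifted pair

    def test_matrix_is_symmetric(self, rng):
        corr = pairwise_xcorr(rng.normal(size=(400, 6)), frame_rate=10.0)
        assert np.allclose(corr, corr.T)

    def test_zero_variance_trace_has_zero_correlation(self, rng):
        data = np.column_stack([np.full(300, 2.0), rng.normal(size=300)])
        corr = pairwise_xcorr(data, frame_rate=10.0)
        assert corr[0, 1] == 0.0
        assert corr[0, 0] == 1.0


class TestReshuffleNull:
    def test_null_of_zero_traces_is_zero(self):
        data = np.zeros((300, 3))
        q = reshuffle_null(data, frame_rate=10.0, seed=0)
        iu = np.triu_indices(3, k=1)
        assert np.allclose(q[iu], 0.0)
        assert np.all(np.isinf(np.diag(q)))

    def test_cutoff_is_order_statistic_of_null_sample(self, rng):
        # with alpha=0.05 and 100 shuffles the cutoff is the 96th order stat
        data = rng.normal(size=(600, 2))
        q = reshuffle_null(data, n_shuffles=100, alpha=0.05, seed=1, frame_rate=10.0)
        assert 0.0 < q[0, 1] < 1.0

    def test_seed_reproducibility(self, rng):
        data = rng.normal(size=(600, 5))
        a = reshuffle_null(data, seed=7, frame_rate=10.0)
        b = reshuffle_null(data, seed=7, frame_rate=10.0)
        assert np.array_equal(a, b)

    def test_type_one_error_near_alpha(self):
        # independent noise: edge rate ~ alpha within Monte-Carlo tolerance
        edges = pairs = 0
        for rep in range(5):
            data = np.random.default_rng(rep).normal(size=(600, 12))
            res = infer_connectivity(data, frame_rate=10.0, seed=100 + rep)
            edges += res.adjacency[np.triu_indices(12, k=1)].sum()
            pairs += 66
        rate = edges / pairs
        assert rate < 0.05 + 3 * np.sqrt(0.05 * 0.95 / pairs)


class TestBuildAdjacency:
    def test_subthreshold_correlation_gives_empty_graph(self):
        corr = np.full((4, 4), 0.2)
        np.fill_diagonal(corr, 1.0)
        q = np.full((4, 4), 0.5)
        assert build_adjacency(corr, q).sum() == 0

    def test_suprathreshold_correlation_gives_complete_graph(self):
        corr = np.full((4, 4), 0.9)
        q = np.full((4, 4), 0.5)
        np.fill_diagonal(q, np.inf)
        A = build_adjacency(corr, q)
        assert A.sum() == 4 * 3
        assert np.all(np.diag(A) == 0)

    def test_single_significant_pair_yields_one_symmetric_edge(self):
        corr = np.full((3, 3), 0.1)
        corr[0, 1] = corr[1, 0] = 0.9
        q = np.full((3, 3), 0.5)
        np.fill_diagonal(q, np.inf)
        A = build_adjacency(corr, q)
        assert A[0, 1] == A[1, 0] == 1
        assert A.sum() == 2


class TestMeanGlobalConnectivity:
    @pytest.mark.parametrize("n", [2, 5, 10, 60])
    def test_complete_graph_scores_one(self, n):
        A = np.ones((n, n), dtype=int) - np.eye(n, dtype=int)
        assert mean_global_connectivity(A) == 1.0

    def test_empty_graph_scores_zero(self):
        assert mean_global_connectivity(np.zeros((8, 8), dtype=int)) == 0.0

    def test_star_graph_hand_enumeration(self):
        A = np.zeros((4, 4), dtype=int)
        A[0, 1:] = A[1:, 0] = 1  # degrees 3,1,1,1 -> mean 1.5 -> mgc 0.5
        assert mean_global_connectivity(A) == 0.5

    def test_single_node_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            mean_global_connectivity(np.zeros((1, 1), dtype=int))

    @given(st.integers(3, 12), st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_invariant_under_node_permutation(self, n, seed):
        rng = np.random.default_rng(seed)
        A = np.triu((rng.random((n, n)) < 0.4).astype(int), k=1)
        A = A + A.T
        perm = rng.permutation(n)
        assert mean_global_connectivity(A[np.ix_(perm, perm)]) == pytest.approx(
            mean_global_connectivity(A)
        )


class TestInferConnectivity:
    def test_fixed_seed_gives_identical_results(self, rng):
        data = rng.normal(size=(600, 8))
        a = infer_connectivity(data, frame_rate=10.0, seed=3)
        b = infer_connectivity(data, frame_rate=10.0, seed=3)
        assert np.array_equal(a.adjacency, b.adjacency)
        assert a.mgc == b.mgc

    def test_planted_common_signal_detected(self, rng):
        # two neurons sharing transients vs six independent noise channels
        from optonet.simulate import SpikeRaster, spikes_to_calcium

        ca = spikes_to_calcium(
            SpikeRaster([np.array([5.0, 12.3, 28.1, 47.6])] * 2, 60.0), frame_rate=10.0
        )
        data = np.column_stack([ca.data + rng.normal(0, 0.05, ca.data.shape),
                                rng.normal(0, 0.05, (600, 6))])
        res = infer_connectivity(data, frame_rate=10.0, seed=5)
        assert res.adjacency[0, 1] == 1
        assert res.mgc <= 0.2

    def test_edge_list_matches_adjacency_and_positions(self, rng):
        data = rng.normal(size=(400, 5))
        res = infer_connectivity(data, frame_rate=10.0, seed=2)
        rois = RoiSet(centers=rng.uniform(0, 100, (5, 2)), radii=np.full(5, 3.0),
                      pixel_size=5.2)
        edges = connectivity_map(res, rois)
        assert len(edges) == res.adjacency[np.triu_indices(5, k=1)].sum()
        if edges:
            assert edges[0][0] in [tuple(p) for p in rois.centers_um]
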