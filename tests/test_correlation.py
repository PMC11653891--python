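import numpy as np
import pytest

import caimetrics as cm
from caimetrics.binarize import BinaryRaster
from caimetrics.correlation import CorrelationGraph


def raster_from(states):
    return BinaryRaster(np.asarray(states, dtype=np.uint8), method="spike", fps=15.0)


def graph_from(matrix, ids=None):
    matrix = np.asarray(matrix, float)
    return CorrelationGraph(matrix, np.ones_like(matrix, bool),
                            ids or [f"n{i}" for i in range(matrix.shape[0])])


class TestPairwisePearson:
    def test_identical_columns_correlate_fully(self):
        col = np.array([0, 1, 1, 0, 1, 0], dtype=np.uint8)
        g = cm.pairwise_pearson(raster_from(np.column_stack([col, col])))
        assert g.matrix[0, 1] == pytest.approx(1.0)

    def test_hand_computed_zero(self):
        a = [1, 1, 0, 0]
        b = [1, 0, 1, 0]
        g = cm.pairwise_pearson(raster_from(np.column_stack([a, b])))
        assert g.matrix[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_complement_is_minus_one(self):
        a = [1, 0, 1, 0]
        b = [0, 1, 0, 1]
        g = cm.pairwise_pearson(raster_from(np.column_stack([a, b])))
        assert g.matrix[0, 1] == pytest.approx(-1.0)

    def test_constant_column_flagged_undefined(self):
        states = np.column_stack([[0, 1, 0, 1], [0, 0, 0, 0], [1, 1, 0, 0]])
        g = cm.pairwise_pearson(raster_from(states))
        assert not g.defined[0, 1] and not g.defined[1, 2]
        assert g.defined[0, 2]
        assert g.n_undefined_pairs == 2
        assert g.matrix[0, 1] == 0.0  # stored as zero but excluded from stats
        assert g.pair_values().size == 1

    def test_single_neuron_rejected(self):
        with pytest.raises(ValueError):
            cm.pairwise_pearson(raster_from(np.ones((10, 1))))


class TestMeanCorrelationAbove:
    def test_uniform_entries(self):
        g = graph_from(np.full((3, 3), 0.5) + np.eye(3) * 0.5)
        assert cm.mean_correlation_above(g, 0.3) == pytest.approx(0.5)

    def test_selection_then_mean(self):
        m = np.eye(3)
        m[0, 1] = m[1, 0] = 0.1
        m[0, 2] = m[2, 0] = 0.2
        m[1, 2] = m[2, 1] = 0.4
        assert cm.mean_correlation_above(graph_from(m), 0.3) == pytest.approx(0.4)

    def test_empty_selection_is_nan(self):
        g = graph_from(np.eye(3))
        assert np.isnan(cm.mean_correlation_above(g, 1.0))


class TestNetworkDegree:
    def test_all_zero_graph(self):
        deg = cm.network_degree(graph_from(np.eye(4)))
        assert all(v == 0.0 for v in deg.values())

    def test_counting(self):
        m = np.eye(3)
        m[0, 1] = m[1, 0] = 0.1
        m[0, 2] = m[2, 0] = 0.2
        m[1, 2] = m[2, 1] = 0.4
        deg = cm.network_degree(graph_from(m), thresholds=[0.0, 0.15, 0.3])
        assert deg[0.0] == pytest.approx(1.0)
        assert deg[0.15] == pytest.approx(2 / 3)
        assert deg[0.3] == pytest.approx(1 / 3)

    def test_degree_at_minus_one_is_one(self, rng):
        states = (rng.random((200, 8)) < 0.2).astype(np.uint8)
        g = cm.pairwise_pearson(raster_from(states))
        if g.n_undefined_pairs == 0:
            assert cm.network_degree(g, thresholds=[-1.0])[-1.0] == 1.0


class TestStrongThreshold:
    def test_uniform_graph_rounds_up_to_grid(self):
        g = graph_from(np.full((4, 4), 0.28) + np.eye(4) * 0.72)
        assert cm.strong_threshold([g]) == pytest.approx(0.30)

    def test_mean_of_two_recordings(self):
        g1 = graph_from(np.full((4, 4), 0.22) + np.eye(4) * 0.78)
        g2 = graph_from(np.full((4, 4), 0.24) + np.eye(4) * 0.76)
        # mean percentile 0.23 snaps upward to 0.25 (tie-up rule at 0.225)
        assert cm.strong_threshold([g1, g2]) == pytest.approx(0.25)

    def test_all_zero_graphs(self):
        assert cm.strong_threshold([graph_from(np.eye(5))]) == 0.0

    def test_tie_rounds_up(self):
        g = graph_from(np.full((4, 4), 0.225) + np.eye(4) * 0.775)
        assert cm.strong_threshold([g]) == pytest.approx(0.25)

    def test_interpolated_percentile(self):
        m = np.eye(4)
        vals = iter([0.1, 0.2, 0.3, 0.4, 0.15, 0.25])
        for i in range(4):
            for j in range(i + 1, 4):
                m[i, j] = m[j, i] = next(vals)
        # 95th percentile (linear interpolation) of the six pair values = 0.375
        assert cm.strong_threshold([graph_from(m)], grid_step=0.05) == pytest.approx(0.40)

    def test_empty_input(self):
        with pytest.raises(ValueError):
            cm.strong_threshold([])


class TestConnectivity:
    def test_fully_connected(self):
        g = graph_from(np.full((4, 4), 0.9) + np.eye(4) * 0.1)
        assert all(v == 100.0 for v in cm.connectivity(g, 0.3).values())

    def test_star_graph(self):
        m = np.eye(4)
        for j in range(1, 4):
            m[0, j] = m[j, 0] = 0.8
        conn = cm.connectivity(graph_from(m), 0.3)
        assert conn["n0"] == 100.0
        assert conn["n1"] == pytest.approx(100 / 3)

    def test_no_edges(self):
        assert all(v == 0.0 for v in cm.connectivity(graph_from(np.eye(3)), 0.3).values())


class TestClusters:
    def test_degenerate_ties_leave_all_unclustered(self):
        g = graph_from(np.full((5, 5), 0.4) + np.eye(5) * 0.6)
        assignment = cm.cluster_assign(g)
        assert all(lab is None for lab in assignment.labels.values())

    def test_six_pair_percentile_cut_keeps_top_edge(self):
        # 80th percentile of 6 values interpolates to the 2nd largest (0.85):
        # only the strictly larger 0.9 edge survives
        m = np.eye(4)
        pairs = {(0, 1): 0.9, (2, 3): 0.85, (0, 2): 0.2, (0, 3): 0.1,
                 (1, 2): 0.15, (1, 3): 0.05}
        for (i, j), v in pairs.items():
            m[i, j] = m[j, i] = v
        assignment = cm.cluster_assign(graph_from(m))
        clusters = {frozenset(v) for v in assignment.clusters().values()}
        assert clusters == {frozenset({"n0", "n1"})}
        assert assignment.cutoff == pytest.approx(0.85)

    def test_two_top_edges_form_two_clusters(self):
        # with 10 pairs the 80th-percentile cut (0.49) sits below both top
        # edges, which link two disjoint pairs into two clusters
        m = np.eye(5)
        pairs = {(0, 1): 0.9, (2, 3): 0.85, (0, 2): 0.05, (0, 3): 0.1,
                 (0, 4): 0.15, (1, 2): 0.2, (1, 3): 0.25, (1, 4): 0.3,
                 (2, 4): 0.35, (3, 4): 0.4}
        for (i, j), v in pairs.items():
            m[i, j] = m[j, i] = v
        assignment = cm.cluster_assign(graph_from(m))
        clusters = {frozenset(v) for v in assignment.clusters().values()}
        assert clusters == {frozenset({"n0", "n1"}), frozenset({"n2", "n3"})}

    def test_relabeling_invariance(self, rng):
        states = (rng.random((300, 8)) < 0.15).astype(np.uint8)
        g = cm.pairwise_pearson(raster_from(states))
        perm = rng.permutation(8)
        g_perm = cm.pairwise_pearson(raster_from(states[:, perm]))
        c1 = cm.cluster_assign(g)
        c2 = cm.cluster_assign(g_perm)
        sets1 = {frozenset(v) for v in c1.clusters().values()}
        # column k of the permuted raster is original neuron perm[k]
        sets2 = {frozenset(f"n{perm[int(n[1:])]}" for n in v)
                 for v in c2.clusters().values()}
        assert sets1 == sets2


class TestIntraInter:
    def test_pair_cluster_means(self):
        m = np.eye(4)
        pairs = {(0, 1): 0.8, (0, 2): 0.1, (0, 3): 0.1, (1, 2): 0.1,
                 (1, 3): 0.1, (2, 3): 0.05}
        for (i, j), v in pairs.items():
            m[i, j] = m[j, i] = v
        g = graph_from(m)
        assignment = cm.cluster_assign(g)
        intra, inter = cm.intra_inter_cluster(g, assignment)
        assert list(intra.values()) == [pytest.approx(0.8)]
        assert inter["n0"] == pytest.approx(0.1)
        assert inter["n1"] == pytest.approx(0.1)

    def test_no_clusters_empty_outputs(self):
        g = graph_from(np.full((3, 3), 0.2) + np.eye(3) * 0.8)
        intra, inter = cm.intra_inter_cluster(g, cm.cluster_assign(g))
        assert intra == {} and inter == {}


class TestCouplingDrivesCorrelation:
    def test_pearson_increases_with_sharing(self):
        fractions = [0.0, 0.25, 0.5, 1.0]
        pairs = [(2 * k, 2 * k + 1, f) for k, f in enumerate(fractions) if f > 0]
        cfg = cm.SimConfig(n_neurons=8, duration_s=300, rate_per_min=3.0,
                           noise_sd=0.05, coupled_pairs=pairs, seed=77)
        traces, _ = cm.simulate_recording(cfg)
        g = cm.pairwise_pearson(cm.binarize_matrix(traces, "spike"))
        rs = [g.matrix[2 * k, 2 * k + 1] for k in range(4)]
        assert rs == sorted(rs)
        assert rs[-1] > 0.9
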