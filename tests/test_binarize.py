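import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import caimetrics as cm
from caimetrics.binarize import SpikeParams, TraceTooShortError, _runs


def spike(trace, **kw):
    return cm.binarize_spike(np.asarray(trace, float), SpikeParams(**kw))


class TestSpike:
    def test_monotone_decreasing_all_zeros(self):
        trace = np.linspace(10, 0, 200)
        assert spike(trace).sum() == 0

    def test_single_transient_one_run_near_onset(self, clean_transient):
        trace, _ = clean_transient
        out = spike(trace)
        runs = _runs(out.astype(bool))
        assert len(runs) == 1
        assert 95 <= runs[0][0] <= 105

    def test_single_transient_matches_derivative_oracle(self, clean_transient):
        """Noise floor is zero on a clean trace: active = rising smoothed trace."""
        trace, _ = clean_transient
        out = spike(trace, warm=0, cold=0)
        kernel = np.ones(10)
        smooth = np.convolve(trace, kernel, "same") / np.convolve(
            np.ones_like(trace), kernel, "same")
        expected = np.zeros(trace.size, dtype=np.uint8)
        expected[1:] = np.diff(smooth) > 0
        np.testing.assert_array_equal(out, expected)

    def test_warm_merges_close_transients(self):
        cfg = cm.SimConfig(n_neurons=1, duration_s=30, rate_per_min=0,
                           noise_sd=0, amplitude_sigma=0.0, seed=0)
        truth = cm.GroundTruth([np.array([100, 130])],
                               cm.NeuronMap(["n0"], [[0, 0]]), np.zeros(1), {})
        trace = cm.render_traces(truth, cfg).values[:, 0]
        assert cm.count_activations(spike(trace, warm=50)) == 1
        assert cm.count_activations(spike(trace, warm=0)) == 2

    def test_cold_deletes_short_runs(self):
        trace = np.zeros(100)
        trace[50:52] = [0.5, 1.0]  # two-frame rise
        out_strict = spike(trace, window=1, warm=0, cold=10)
        out_lenient = spike(trace, window=1, warm=0, cold=0)
        assert out_strict.sum() == 0
        assert out_lenient.sum() > 0

    def test_too_short_trace_rejected(self):
        with pytest.raises(TraceTooShortError):
            spike(np.zeros(5), window=10)

    @given(st.integers(0, 80), st.integers(0, 80))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_warm_monotonicity(self, w1, w2):
        """With cold at its default 0, more gap-merging never adds runs."""
        rng = np.random.default_rng(123)
        trace = np.cumsum(rng.normal(size=400))
        lo, hi = sorted((w1, w2))
        n_hi = cm.count_activations(spike(trace, warm=hi))
        n_lo = cm.count_activations(spike(trace, warm=lo))
        assert n_hi <= n_lo

    @given(st.integers(0, 30), st.integers(0, 30))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_cold_monotonicity(self, c1, c2):
        """With warm at 0, raising the minimum run length never adds runs."""
        rng = np.random.default_rng(321)
        trace = np.cumsum(rng.normal(size=400))
        lo, hi = sorted((c1, c2))
        n_hi = cm.count_activations(spike(trace, warm=0, cold=hi))
        n_lo = cm.count_activations(spike(trace, warm=0, cold=lo))
        assert n_hi <= n_lo


class TestFull:
    def test_constant_trace_all_zeros(self):
        assert cm.binarize_full(np.full(100, 3.3)).sum() == 0

    def test_boxcar_detected_exactly(self):
        """Zero baseline has MAD 0; the mean+k*SD fallback cuts between
        baseline and a brief boxcar, marking exactly the boxcar frames."""
        trace = np.zeros(200)
        trace[80:85] = 10.0  # mean + 3 SD ~ 4.9, strictly below the boxcar
        out = cm.binarize_full(trace)
        np.testing.assert_array_equal(np.flatnonzero(out), np.arange(80, 85))

    def test_full_runs_contain_spike_runs_on_clean_transient(self, clean_transient):
        trace, _ = clean_transient
        full_len = max((b - a) for a, b in _runs(cm.binarize_full(trace).astype(bool)))
        spike_len = max((b - a) for a, b in _runs(spike(trace).astype(bool)))
        assert full_len >= spike_len


class TestSignal:
    def test_constant_trace_all_zeros(self):
        assert cm.binarize_signal(np.ones(50)).sum() == 0

    def test_gaussian_tail_fraction(self):
        rng = np.random.default_rng(7)
        trace = rng.normal(size=100_000)
        frac = cm.binarize_signal(trace, z=2.0).mean()
        p = 0.02275  # P(Z > 2)
        se = np.sqrt(p * (1 - p) / trace.size)
        assert abs(frac - p) < 3 * se

    def test_clean_transient_single_contiguous_run(self, clean_transient):
        trace, _ = clean_transient
        out = cm.binarize_signal(trace, z=2.0)
        assert len(_runs(out.astype(bool))) == 1

    @pytest.mark.parametrize("z_pair", [(1.0, 2.0), (2.0, 3.0), (0.5, 2.5)])
    def test_active_set_shrinks_with_z(self, z_pair, rng):
        trace = rng.normal(size=2000)
        lo, hi = z_pair
        a_hi = cm.binarize_signal(trace, z=hi).astype(bool)
        a_lo = cm.binarize_signal(trace, z=lo).astype(bool)
        assert (a_hi & ~a_lo).sum() == 0  # hi-z actives are a subset


class TestDiff:
    def test_linear_ramp_all_zeros(self):
        assert cm.binarize_diff(np.arange(100.0)).sum() == 0

    def test_rise_phase_only(self, clean_transient):
        trace, cfg = clean_transient
        out = cm.binarize_diff(trace)
        active = np.flatnonzero(out)
        assert active.size > 0
        tail_start = 100 + int(3 * cfg.decay_tau_s * cfg.fps)
        assert (active < tail_start).all()

    def test_diff_actives_within_spike_candidates(self, clean_transient):
        trace, _ = clean_transient
        diff_active = cm.binarize_diff(trace).astype(bool)
        spike_candidates = spike(trace, warm=0, cold=0).astype(bool)
        # smoothing widens the rise, so the sharp-derivative frames sit inside it
        assert (diff_active & ~spike_candidates).sum() == 0

    def test_too_short(self):
        with pytest.raises(TraceTooShortError):
            cm.binarize_diff(np.array([1.0]))


class TestActiveAccuracy:
    def test_identical_vectors(self):
        v = np.array([0, 1, 1, 0, 1])
        assert cm.active_accuracy(v, v) == 1.0

    def test_disjoint_sets(self):
        assert cm.active_accuracy([1, 1, 0, 0], [0, 0, 1, 1]) == 0.0

    def test_partial_overlap(self):
        a = np.zeros(6, int)
        a[[1, 2, 3]] = 1
        b = np.zeros(6, int)
        b[[3, 4]] = 1
        assert cm.active_accuracy(a, b) == pytest.approx(0.25)

    def test_empty_union_is_zero(self):
        assert cm.active_accuracy(np.zeros(5), np.zeros(5)) == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            cm.active_accuracy(np.zeros(3), np.zeros(4))

    @given(st.lists(st.integers(0, 1), min_size=1, max_size=40),
           st.data())
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_bounded_and_symmetric(self, a, data):
        b = data.draw(st.lists(st.integers(0, 1), min_size=len(a), max_size=len(a)))
        x = cm.active_accuracy(np.array(a), np.array(b))
        assert 0.0 <= x <= 1.0
        assert x == cm.active_accuracy(np.array(b), np.array(a))


class TestCountActivations:
    @pytest.mark.parametrize("pattern,expected", [
        ([0, 0, 0], 0),
        ([0, 1, 1, 0, 1, 0], 2),
        ([1, 1, 1], 1),
        ([1, 0, 1, 0, 1], 3),
    ])
    def test_examples(self, pattern, expected):
        assert cm.count_activations(np.array(pattern)) == expected


class TestMatrixDispatch:
    @pytest.mark.parametrize("method", ["spike", "full", "signal", "diff"])
    def test_shape_and_determinism(self, method, small_recording):
        traces, _, _ = small_recording
        r1 = cm.binarize_matrix(traces, method=method)
        r2 = cm.binarize_matrix(traces, method=method)
        assert r1.states.shape == traces.values.shape
        np.testing.assert_array_equal(r1.states, r2.states)
        assert r1.method == method

    def test_unknown_method(self, small_recording):
        traces, _, _ = small_recording
        with pytest.raises(ValueError, match="unknown binarization method"):
            cm.binarize_trace(traces.values[:, 0], "wavelet")
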