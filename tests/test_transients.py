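import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from neurocal import (
    TraceSet, SpikingSimParams, simulate_spiking, fluo4_epoch_plan,
)
from neurocal.transients import (
    DetectionParams, normalize, first_derivative, estimate_threshold,
    detect_events, summarize_activity, bin_amplitudes,
)
from conftest import make_nt
from oracles import brute_force_events


def detect_pipeline(trace, plan, params=None, k_sd=2.0):
    params = params or DetectionParams(k_sd=k_sd)
    nt = normalize(trace, plan.epochs[0].start_frame)
    d = first_derivative(nt, smooth_window=params.smooth_window)
    baseline = np.arange(plan.epochs[0].start_frame,
                         plan.epochs[0].end_frame - 1)
    thr = estimate_threshold(d, params, baseline_frames=baseline, nt=nt)
    events = detect_events(nt, d, thr, params)
    return nt, d, thr, events


class TestNormalize:
    def test_constant_trace(self):
        ts = TraceSet(times=np.arange(5.0), values=np.full((5, 2), 7.0),
                      cell_ids=["a", "b"])
        nt = normalize(ts)
        np.testing.assert_array_equal(nt.norm, 1.0)
        np.testing.assert_array_equal(nt.dff, 0.0)
        np.testing.assert_array_equal(nt.f0, 7.0)

    def test_arithmetic_identity(self):
        ts = TraceSet(times=np.arange(2.0), values=[[100.0], [150.0]],
                      cell_ids=["a"])
        nt = normalize(ts, reference_frame=0)
        assert nt.norm[1, 0] == pytest.approx(1.5)
        assert nt.dff[1, 0] == pytest.approx(0.5)

    def test_reference_frame_pinned_to_one(self):
        rng = np.random.default_rng(0)
        ts = TraceSet(times=np.arange(10.0),
                      values=rng.uniform(50, 150, (10, 6)), cell_ids=list("abcdef"))
        nt = normalize(ts, reference_frame=3)
        np.testing.assert_allclose(nt.norm[3, :], 1.0, rtol=1e-15)

    def test_nonpositive_reference_excludes_cell_with_reason(self):
        ts = TraceSet(times=np.arange(3.0), values=[[1.0, 0.0], [1, 1], [1, 1]],
                      cell_ids=["good", "dead"])
        nt = normalize(ts)
        assert nt.cell_ids == ["good"]
        assert "dead" in nt.excluded

    def test_spike_peak_dff_equals_truth_amplitude(self):
        """Noise- and bleach-free forward model: dF/F0 at an isolated spike
        frame equals the drawn amplitude."""
        p = SpikingSimParams(n_cells=8, noise_sd=0.0, seed=21)
        trace, truth = simulate_spiking(p)
        nt = normalize(trace, 0)
        checked = 0
        for c in range(p.n_cells):
            frames = truth.spike_frames(p.dt)[c]
            for i, (f, a) in enumerate(zip(frames, truth.spike_amplitudes[c])):
                # isolated: no other spike within 10 decay constants before
                if i == 0 or f - frames[i - 1] > 10 * p.decay_tau:
                    assert nt.dff[f, c] == pytest.approx(a, rel=1e-4)
                    checked += 1
        assert checked >= 10


class TestFirstDerivative:
    @pytest.mark.parametrize("dff,expected", [
        ([0.0, 0.5, 0.2], [0.5, -0.3]),
        ([1.0, 1.0, 1.0, 1.0], [0.0, 0.0, 0.0]),
        ([0.0, 0.25, 0.5, 0.75], [0.25, 0.25, 0.25]),   # ramp slope m
    ])
    def test_finite_difference(self, dff, expected):
        nt = make_nt(np.array(dff))
        np.testing.assert_allclose(first_derivative(nt)[:, 0], expected)

    def test_length_is_frames_minus_one(self):
        nt = make_nt(np.zeros((17, 3)))
        assert first_derivative(nt).shape == (16, 3)


class TestEstimateThreshold:
    def test_hand_computed_quiet_set(self):
        d = np.array([-0.05, 0.05, -0.05, 0.05, 0.0])[:, None]
        params = DetectionParams(quiet_region=np.arange(5))
        thr = estimate_threshold(d, params)
        # mean 0, population SD sqrt(0.002) = 0.04472 -> 2 sigma
        assert thr[0] == pytest.approx(2 * np.sqrt(0.002), abs=1e-12)
        assert thr[0] == pytest.approx(0.0894, abs=1e-4)

    def test_all_zero_derivative_gives_zero(self):
        d = np.zeros((10, 2))
        thr = estimate_threshold(d, DetectionParams(quiet_region=np.arange(10)))
        np.testing.assert_array_equal(thr, 0.0)

    def test_insufficient_quiet_frames(self):
        d = np.zeros((10, 1))
        with pytest.raises(ValueError, match="insufficient quiet frames"):
            estimate_threshold(d, DetectionParams(quiet_region=np.arange(3)))

    def test_population_not_sample_sd(self):
        x = np.array([-0.05, 0.05, -0.05, 0.05, 0.0])
        pop = estimate_threshold(x[:, None],
                                 DetectionParams(quiet_region=np.arange(5)))[0]
        sample = 2 * np.std(x, ddof=1)
        assert pop < sample  # and differs by the documented n/(n-1) factor

    def test_auto_mode_excludes_spike_and_matches_explicit(self):
        rng = np.random.default_rng(42)
        dff = rng.normal(0, 0.01, 120)
        dff[60:64] += [0.8, 0.6, 0.45, 0.34]    # one large transient
        nt = make_nt(dff)
        d = first_derivative(nt)
        auto = estimate_threshold(d, DetectionParams(quiet_region="auto"))
        # the transient contributes a single supra-threshold derivative frame
        # (the rise into frame 60, i.e. derivative index 59); the converged
        # quiet set is everything else, so auto == explicit exactly
        quiet = np.setdiff1d(np.arange(d.shape[0]), [59])
        explicit = estimate_threshold(d, DetectionParams(quiet_region=quiet))
        assert auto[0] == pytest.approx(explicit[0], abs=1e-12)
        assert d[59, 0] > auto[0]

    def test_zero_sd_with_signal_elsewhere_warns(self):
        d = np.concatenate([np.zeros(6), [0.5, -0.5]])[:, None]
        with pytest.warns(UserWarning, match="quiet SD is 0"):
            estimate_threshold(d, DetectionParams(quiet_region=np.arange(6)))


class TestDetectEvents:
    def test_flat_trace_yields_no_events(self):
        nt = make_nt(np.zeros(30))
        d = first_derivative(nt)
        assert detect_events(nt, d, np.array([0.0])) == []

    def test_toy_hand_traced_event(self):
        dff = np.array([0, 0, 0, 0.6, 1.0, 0.5, 0.2, 0, 0, 0], dtype=float)
        nt = make_nt(dff)
        d = first_derivative(nt)
        params = DetectionParams(local_baseline_window=3)
        (ev,) = detect_events(nt, d, np.array([0.1]), params)
        assert ev.onset_frame == 3
        assert ev.peak_frame == 4
        assert ev.amplitude == pytest.approx(1.0)

    def test_zero_noise_zero_spike_sim_any_ksd(self):
        p = SpikingSimParams(n_cells=3, epoch_rates={"baseline": 0, "treatment": 0},
                             noise_sd=0.0, seed=2)
        trace, _ = simulate_spiking(p)
        plan = fluo4_epoch_plan()
        for k_sd in (0.5, 2.0, 10.0):
            _, _, _, events = detect_pipeline(trace, plan, k_sd=k_sd)
            assert events == []

    def test_events_per_cell_non_overlapping(self):
        p = SpikingSimParams(n_cells=10, seed=8)
        trace, _ = simulate_spiking(p)
        _, _, _, events = detect_pipeline(trace, fluo4_epoch_plan())
        by_cell = {}
        for ev in events:
            by_cell.setdefault(ev.cell_id, []).append(ev)
        for evs in by_cell.values():
            evs.sort(key=lambda e: e.onset_frame)
            for a, b in zip(evs, evs[1:]):
                assert a.onset_frame + a.duration <= b.onset_frame

    def test_event_count_nondecreasing_in_rate(self):
        # noise-free battery: detected-event count tracks the simulated rate
        counts = []
        for rate in (0.5, 1.0, 2.0, 4.0):
            total = 0
            for seed in (1, 2, 3):
                p = SpikingSimParams(
                    n_cells=20, seed=seed, noise_sd=0.0,
                    epoch_rates={"baseline": rate, "treatment": 0.0})
                trace, _ = simulate_spiking(p)
                _, _, _, events = detect_pipeline(trace, fluo4_epoch_plan())
                total += len(events)
            counts.append(total)
        assert counts == sorted(counts)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(data=st.data())
    def test_detector_matches_brute_force_oracle(self, data):
        """Property: on short random traces the vectorised detector agrees
        exactly with an independent loop-based run enumeration."""
        n = data.draw(st.integers(6, 50))
        dff = np.array(data.draw(st.lists(
            st.floats(-2, 2, allow_nan=False, allow_infinity=False),
            min_size=n, max_size=n)))
        thr = data.draw(st.floats(0.01, 1.0))
        min_sep = data.draw(st.integers(1, 4))
        min_len = data.draw(st.integers(1, 3))
        window = data.draw(st.integers(1, 8))
        params = DetectionParams(min_separation=min_sep,
                                 min_event_frames=min_len,
                                 local_baseline_window=window)
        nt = make_nt(dff)
        d = first_derivative(nt)
        got = detect_events(nt, d, np.array([thr]), params)
        want = brute_force_events(list(dff), list(d[:, 0]), thr,
                                  min_sep, min_len, window)
        assert len(got) == len(want)
        for g, w in zip(got, want):
            assert g.onset_frame == w["onset_frame"]
            assert g.peak_frame == w["peak_frame"]
            assert g.duration == w["duration"]
            assert g.amplitude == pytest.approx(w["amplitude"], abs=1e-12)


class TestSummarizeActivity:
    def _summary(self, events, nt, plan, **kw):
        thr = np.zeros(len(nt.cell_ids))
        return summarize_activity(events, plan, nt, thr, **kw)

    def test_counts_events_in_240s_window(self):
        from neurocal.transients import TransientEvent
        nt = make_nt(np.zeros((480, 1)))
        events = [TransientEvent("c0", onset, onset, 0.5, 1)
                  for onset in (10, 100, 230)]
        (s,) = self._summary(events, nt, fluo4_epoch_plan())
        assert s.spikes_per_4min == 3

    def test_abolished_when_treatment_silent(self):
        from neurocal.transients import TransientEvent
        nt = make_nt(np.zeros((480, 1)))
        events = [TransientEvent("c0", o, o, 0.5, 1) for o in range(10, 60, 10)]
        (s,) = self._summary(events, nt, fluo4_epoch_plan())
        assert s.abolished["treatment"] is True

    def test_not_abolished_when_treatment_active(self):
        from neurocal.transients import TransientEvent
        nt = make_nt(np.zeros((480, 1)))
        events = [TransientEvent("c0", 10, 10, 0.5, 1),
                  TransientEvent("c0", 300, 300, 0.5, 1)]
        (s,) = self._summary(events, nt, fluo4_epoch_plan())
        assert s.abolished["treatment"] is False

    def test_window_longer_than_epoch_rejected(self):
        nt = make_nt(np.zeros((480, 1)))
        with pytest.raises(ValueError, match="exceeds epoch"):
            self._summary([], nt, fluo4_epoch_plan(), window_s=300.0)

    def test_full_pipeline_abolition_at_zero_noise(self):
        """Post-treatment rate 0, zero noise: every cell is called abolished."""
        p = SpikingSimParams(n_cells=15, noise_sd=0.0, seed=6)
        trace, _ = simulate_spiking(p)
        plan = fluo4_epoch_plan()
        nt, d, thr, events = detect_pipeline(trace, plan)
        summaries = summarize_activity(events, plan, nt, thr)
        assert all(s.abolished["treatment"] for s in summaries)


class TestBinAmplitudes:
    def test_worked_example(self):
        hist = bin_amplitudes({"DIV30": np.array([0.2, 0.2, 0.8])},
                              np.array([0.0, 0.5, 1.0]))
        np.testing.assert_allclose(hist.proportions["DIV30"],
                                   [0.0, 2 / 3, 1 / 3, 0.0])

    def test_single_amplitude(self):
        hist = bin_amplitudes({"x": np.array([0.3])}, np.array([0.0, 0.5, 1.0]))
        np.testing.assert_array_equal(hist.proportions["x"], [0, 1, 0, 0])

    def test_overflow_bins_capture_extremes(self):
        hist = bin_amplitudes({"x": np.array([-0.1, 0.2, 5.0])},
                              np.array([0.0, 1.0]))
        np.testing.assert_allclose(hist.proportions["x"], [1 / 3, 1 / 3, 1 / 3])

    def test_proportions_sum_to_one(self):
        rng = np.random.default_rng(0)
        amps = rng.lognormal(np.log(0.5), 0.4, 500)
        hist = bin_amplitudes({"a": amps}, np.linspace(0.1, 1.5, 8))
        assert hist.proportions["a"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_unsorted_edges_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            bin_amplitudes({"x": np.array([0.5])}, np.array([1.0, 0.0]))

    def test_empty_condition_rejected(self):
        with pytest.raises(ValueError, match="no events"):
            bin_amplitudes({"x": np.array([])}, np.array([0.0, 1.0]))
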