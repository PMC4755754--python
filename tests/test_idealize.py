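"""Idealization: baseline, half-amplitude detection, classes, NPo."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import tjpatch as tj
from tjpatch.idealize import (
    AmbiguousBaselineWarning,
    IdealizedRecord,
    classify_events,
    compute_npo,
    detect_events,
    estimate_baseline,
    npo_reduction,
)
from tjpatch.protocol import hold
from tjpatch.recording import CurrentTrace

FS = 25_000.0


def trace_from(samples, v=-100.0):
    samples = np.asarray(samples, dtype=float)
    return CurrentTrace(samples, FS, hold(v, len(samples) / FS))


def square_pulse_trace(durations_ms, amp=-9.0, gap_ms=5.0, offset=0.0):
    chunks = [np.zeros(int(gap_ms / 1000 * FS))]
    for d in durations_ms:
        chunks.append(np.full(int(round(d / 1000 * FS)), amp))
        chunks.append(np.zeros(int(gap_ms / 1000 * FS)))
    return trace_from(np.concatenate(chunks) + offset)


class TestBaseline:
    def test_all_zero(self):
        assert estimate_baseline(trace_from(np.zeros(1000))) == 0.0

    def test_leak_offset_with_brief_openings(self):
        trace = square_pulse_trace([0.6, 0.8], offset=-3.3)
        assert abs(estimate_baseline(trace) + 3.3) < 0.05

    def test_gaussian_noise_mean_zero(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0.0, 0.6, 100_000)
        se = 0.6 / np.sqrt(x.size)
        assert abs(estimate_baseline(trace_from(x))) < 3 * se + 0.05

    def test_ambiguous_baseline_warns_and_falls_back_to_median(self):
        x = np.linspace(0.0, 10.0, 10_000)  # no dominant level
        with pytest.warns(AmbiguousBaselineWarning):
            b = estimate_baseline(trace_from(x))
        assert abs(b - np.median(x)) < 1e-9


class TestDetect:
    def test_flat_trace_empty_record(self):
        rec = detect_events(trace_from(np.zeros(5000)), amplitude=9.0)
        assert rec.n_events == 0

    def test_noiseless_square_pulses_recovered_exactly(self):
        durations = [0.6, 0.8, 2.0]
        rec = detect_events(square_pulse_trace(durations), amplitude=9.0)
        opens = rec.open_dwells
        assert len(opens) == 3
        assert np.allclose(sorted(opens["duration_s"] * 1000), durations)
        assert np.allclose(opens["mean_amplitude_pA"], -9.0)

    def test_min_duration_below_sample_interval_rejected(self):
        with pytest.raises(ValueError):
            detect_events(trace_from(np.zeros(100)), 9.0, min_duration=1e-6)

    def test_offset_invariance(self):
        t1 = square_pulse_trace([0.6, 2.0])
        t2 = trace_from(t1.samples + 5.0)
        r1, r2 = detect_events(t1, 9.0), detect_events(t2, 9.0)
        pd.testing.assert_frame_equal(r1.dwells, r2.dwells)
        assert abs((r2.baseline - r1.baseline) - 5.0) < 0.05

    def test_scenario_events_recovered_against_ground_truth(self, induced_scenario):
        trace, truth = induced_scenario
        rec = detect_events(trace, 9.0, 0.2e-3)
        opens = rec.open_dwells
        starts = opens["start_s"].to_numpy()
        ends = starts + opens["duration_s"].to_numpy()
        cldn2 = truth[(truth["channel_class"] == "cldn2") & (truth["duration_s"] >= 0.4e-3)]
        hit = 0
        for _, ev in cldn2.iterrows():
            t0, t1 = ev["start_s"], ev["start_s"] + ev["duration_s"]
            if np.any((starts < t1) & (ends > t0)):
                hit += 1
        assert hit / len(cldn2) >= 0.90
        # no detected event where the ground truth is closed for >= 5 ms around
        all_truth = truth.to_numpy()
        t_starts = truth["start_s"].to_numpy()
        t_ends = t_starts + truth["duration_s"].to_numpy()
        for s, e in zip(starts, ends):
            assert np.any((t_starts < e + 5e-3) & (t_ends > s - 5e-3))


class TestClassify:
    @staticmethod
    def record_from_amplitudes(amps):
        rows = [(1, 0.01 + 0.01 * i, 1e-3, a) for i, a in enumerate(amps)]
        d = pd.DataFrame(rows, columns=["level", "start_s", "duration_s", "mean_amplitude_pA"])
        return IdealizedRecord(d, total_time=1.0)

    def test_one_event_per_class(self):
        rec = self.record_from_amplitudes([9.0, 4.3])
        classes = classify_events(rec, cut=6.0)
        assert classes["cldn2"].n_events == 1
        assert classes["independent"].n_events == 1

    def test_empty_record(self):
        rec = IdealizedRecord(
            pd.DataFrame(columns=["level", "start_s", "duration_s", "mean_amplitude_pA"]),
            total_time=1.0,
        )
        classes = classify_events(rec)
        assert classes["cldn2"].n_events == 0
        assert classes["independent"].n_events == 0

    def test_simulated_mixture_agreement(self):
        rng = np.random.default_rng(8)
        labels = rng.random(100) < 0.5
        amps = np.where(labels, rng.normal(-9.0, 0.5, 100), rng.normal(-4.3, 0.5, 100))
        rec = self.record_from_amplitudes(amps)
        classes = classify_events(rec, cut=6.0)
        big = classes["cldn2"].open_dwells["mean_amplitude_pA"].to_numpy()
        predicted_big = np.isin(amps, big)
        assert (predicted_big == labels).mean() >= 0.98


class TestNPo:
    def make(self, rows, total):
        d = pd.DataFrame(rows, columns=["level", "start_s", "duration_s", "mean_amplitude_pA"])
        return IdealizedRecord(d, total_time=total)

    def test_hand_examples(self):
        assert compute_npo(self.make([(1, 0.0, 1.0, -9.0)], 10.0)) == pytest.approx(0.1)
        rec = self.make([(1, 0.0, 2.0, -9.0), (2, 3.0, 1.0, -18.0)], 10.0)
        assert compute_npo(rec) == pytest.approx(0.4)

    def test_zero_total_time_rejected(self):
        empty = IdealizedRecord(
            pd.DataFrame(columns=["level", "start_s", "duration_s", "mean_amplitude_pA"]),
            total_time=0.0,
        )
        with pytest.raises(ValueError):
            compute_npo(empty)

    def test_npo_equals_brute_force_sample_oracle(self):
        # noiseless, unfiltered superposition of three channels
        model = tj.two_state_model(2e-3, 6e-3, 90.0)
        t = np.arange(int(FS * 20)) / FS
        levels = sum(
            (tj.simulate_state_path(model, 20.0, seed=30 + i).state_at(t) == 1).astype(int)
            for i in range(3)
        )
        trace = trace_from(-9.0 * levels)
        rec = detect_events(trace, 9.0, min_duration=1.0 / FS, baseline=0.0, polarity=-1)
        oracle = levels.mean()  # per-sample open-channel count, averaged
        assert compute_npo(rec) == pytest.approx(oracle, rel=1e-9)

    def test_superposition_scales_single_channel_npo(self):
        model = tj.two_state_model(2e-3, 6e-3, 90.0)
        t = np.arange(int(FS * 50)) / FS
        single = (tj.simulate_state_path(model, 50.0, seed=40).state_at(t) == 1).mean()
        levels = sum(
            (tj.simulate_state_path(model, 50.0, seed=40 + i).state_at(t) == 1).astype(int)
            for i in range(4)
        )
        rec = detect_events(
            trace_from(-9.0 * levels), 9.0, 0.2e-3, baseline=0.0, polarity=-1
        )
        assert compute_npo(rec) == pytest.approx(4 * single, rel=0.15)


class TestReduction:
    def test_examples(self):
        assert npo_reduction(0.4, 0.05) == pytest.approx(87.5)
        assert npo_reduction(0.3, 0.3) == 0.0
        assert npo_reduction(0.3, 0.0) == 100.0

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            npo_reduction(0.0, 0.1)

    @given(st.floats(1e-6, 10), st.floats(0, 10))
    def test_bounded_above_by_100(self, a, b):
        assert npo_reduction(a, b) <= 100.0
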