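"""Amplitude histograms, Gaussian mixtures, dwell-time ML fits."""
import numpy as np
import pytest
from hypothesis import given, strategies as st

import tjpatch as tj
from tjpatch.kinetics import (
    all_points_histogram,
    classify_kinetic_states,
    compare_dwell_models,
    dwell_histogram,
    fit_dwell_exponentials,
    fit_gaussian_mixture,
)
from tjpatch.protocol import hold
from tjpatch.recording import CurrentTrace

FS = 25_000.0


def trace_from(samples):
    samples = np.asarray(samples, dtype=float)
    return CurrentTrace(samples, FS, hold(-100.0, len(samples) / FS))


class TestAllPointsHistogram:
    def test_constant_trace_single_bin(self):
        h = all_points_histogram(trace_from(np.zeros(1000)))
        assert (h.counts > 0).sum() == 1
        assert h.counts.sum() == 1000

    def test_two_level_split_is_exact(self):
        x = np.concatenate([np.zeros(7000), np.full(3000, -9.0)])
        h = all_points_histogram(trace_from(x))
        occupied = h.counts[h.counts > 0]
        assert len(occupied) == 2
        assert set(occupied) == {7000, 3000}

    def test_mass_normalization_identity(self):
        rng = np.random.default_rng(1)
        trace = trace_from(rng.normal(0, 0.6, 50_000))
        h = all_points_histogram(trace)
        # total density x sample interval = record duration... i.e. counts sum to n
        assert h.counts.sum() == trace.n_samples
        assert h.density.sum() * (1.0 / FS) * trace.duration_s == pytest.approx(
            trace.duration_s
        )


class TestGaussianMixture:
    def test_three_component_recovery(self):
        rng = np.random.default_rng(2)
        n = 1_000_000
        comp = rng.choice(3, n, p=[0.7, 0.2, 0.1])
        means = np.array([0.0, -4.3, -9.0])
        x = rng.normal(means[comp], 0.6)
        h = all_points_histogram(trace_from(x))
        fit = fit_gaussian_mixture(h, k=3)
        got = sorted(m for m, _, _ in fit)
        assert np.allclose(got, sorted(means), atol=0.1)

    def test_single_component_equals_sample_mean(self):
        rng = np.random.default_rng(3)
        x = rng.normal(-3.0, 0.5, 100_000)
        h = all_points_histogram(trace_from(x))
        (mu, sd, w), = fit_gaussian_mixture(h, k=1)
        assert mu == pytest.approx(x.mean(), abs=0.05)
        assert w == pytest.approx(1.0)

    def test_degenerate_data_floors_sd_and_flags(self):
        h = all_points_histogram(trace_from(np.full(1000, -9.0)))
        (mu, sd, _), = fit_gaussian_mixture(h, k=1)
        assert mu == pytest.approx(-9.0, abs=0.1)
        assert sd == pytest.approx(0.1, abs=1e-6)
        assert h.degenerate

    def test_too_few_occupied_bins_rejected(self):
        x = np.concatenate([np.zeros(500), np.full(500, -9.0)])
        with pytest.raises(ValueError):
            fit_gaussian_mixture(all_points_histogram(trace_from(x)), k=3)


class TestDwellHistogram:
    def test_three_decades_occupied(self):
        edges, counts = dwell_histogram(np.array([1e-3, 1e-2, 1e-1]))
        assert counts.sum() == 3
        assert (counts > 0).sum() == 3

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            dwell_histogram(np.array([1e-3, 0.0]))

    @given(
        st.lists(st.floats(1e-6, 1e3, allow_nan=False), min_size=1, max_size=200)
    )
    def test_counts_conserved(self, durations):
        _, counts = dwell_histogram(np.asarray(durations))
        assert counts.sum() == len(durations)

    def test_exponential_sample_peaks_near_tau(self):
        rng = np.random.default_rng(4)
        d = rng.exponential(0.6e-3, 10_000)
        edges, counts = dwell_histogram(d)
        peak = np.argmax(counts)
        lo, hi = edges[peak], edges[peak + 1]
        assert lo <= 0.6e-3 * 2 and hi >= 0.6e-3 / 3


class TestDwellFits:
    def test_single_exponential_ml_is_sample_mean(self):
        rng = np.random.default_rng(5)
        d = rng.exponential(1.5e-3, 500)
        fit = fit_dwell_exponentials(d, 1)
        assert fit.taus[0] == d.mean()  # closed-form ML, exact

    def test_two_component_recovery_fixed_seed(self):
        rng = np.random.default_rng(6)
        n = 5000
        slow = rng.random(n) < 0.1
        d = np.where(slow, rng.exponential(3.0, n), rng.exponential(1.2e-3, n))
        fit = fit_dwell_exponentials(d, 2)
        taus = fit.taus
        assert abs(taus[0] - 1.2e-3) / 1.2e-3 < 0.15
        assert abs(taus[1] - 3.0) / 3.0 < 0.15

    def test_two_component_median_error_over_replicates(self):
        errs_fast, errs_slow = [], []
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            n = 5000
            slow = rng.random(n) < 0.1
            d = np.where(slow, rng.exponential(3.0, n), rng.exponential(1.2e-3, n))
            taus = fit_dwell_exponentials(d, 2).taus
            errs_fast.append(abs(taus[0] - 1.2e-3) / 1.2e-3)
            errs_slow.append(abs(taus[1] - 3.0) / 3.0)
        assert np.median(errs_fast) <= 0.10
        assert np.median(errs_slow) <= 0.10

    def test_insufficient_events_rejected(self):
        with pytest.raises(ValueError):
            fit_dwell_exponentials(np.full(5, 1e-3), 1)
        with pytest.raises(ValueError):
            fit_dwell_exponentials(np.full(20, 1e-3), 2)

    def test_dead_time_shift_preserves_tau(self):
        rng = np.random.default_rng(7)
        d = rng.exponential(2e-3, 20_000)
        detected = d[d > 0.2e-3]
        fit = fit_dwell_exponentials(detected, 1, dead_time_s=0.2e-3)
        assert fit.taus[0] == pytest.approx(2e-3, rel=0.05)


class TestStateClassification:
    def test_default_channel_has_one_open_two_closed_states(
        self, long_single_channel_record
    ):
        _, _, record = long_single_channel_record
        result = classify_kinetic_states(
            record.open_durations(), record.closed_durations(), dead_time_s=0.2e-3
        )
        assert result["n_open_states"] == 1
        assert result["n_closed_states"] == 2
        assert result["tau_open_s"] < 1e-3
        assert result["tau_closed_transient_s"] < 2e-3
        assert result["tau_closed_stable_s"] > 1.0

    def test_pure_two_state_channel(self):
        rng = np.random.default_rng(9)
        opens = rng.exponential(1e-3, 2000)
        closeds = rng.exponential(5e-3, 2000)
        result = classify_kinetic_states(opens, closeds)
        assert result["n_open_states"] == 1
        assert result["n_closed_states"] == 1

    def test_single_exponential_closed_durations_collapse(self):
        rng = np.random.default_rng(10)
        closeds = rng.exponential(2e-3, 3000)
        fit, _, p = compare_dwell_models(closeds, "closed")
        assert len([f for _, f in fit.components if f > 1e-6]) == 1
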