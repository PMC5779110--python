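"""Spike-train reconstruction and firing statistics.

The reconstruction tests compare the greedy matching-pursuit solution to an
independent exhaustive-enumeration oracle (minimum SSE over all binary
event placements on the 100 Hz grid) on short traces.
"""

import itertools

import numpy as np
import pytest

from magnetherm import calcium, synthetic, thermometry
from magnetherm.calcium import (
    LatencySet,
    SpikeTrain,
    default_template,
    fit_hill_rate_curve,
    fit_latency_distribution,
)

from conftest import make_norm_trace


# ---------------------------------------------------------------- oracle


def contribution_matrix(n_samples, fs, waveform):
    """C[p, j]: value the template of an event at 100 Hz position p adds to
    trace sample j. Written independently of the implementation."""
    u = int(round(100.0 / fs))
    n_pos = (n_samples - 1) * u + 1
    C = np.zeros((n_pos, n_samples))
    for p in range(n_pos):
        for j in range(n_samples):
            k = j * u - p
            if 0 <= k < waveform.size:
                C[p, j] = waveform[k]
    return C


def enumerate_best_train(y, fs, waveform, max_events=3, tol=1e-6):
    """Global minimum-SSE placement of up to ``max_events`` unit events, by
    exhaustive enumeration (vectorized over pairs/triples). Ties (including
    float-rounding ties from zero-contribution placements) break toward
    fewer events: a larger set must improve the SSE by more than ``tol``."""
    C = contribution_matrix(y.size, fs, waveform)
    n_pos = C.shape[0]
    b = C @ y
    G = C @ C.T
    yy = float(y @ y)
    best_sse, best_set = yy, ()

    d = np.diag(G)
    sse1 = yy - 2.0 * b + d
    i = int(np.argmin(sse1))
    if sse1[i] < best_sse - tol:
        best_sse, best_set = float(sse1[i]), (i,)

    if max_events >= 2:
        pair = yy - 2.0 * (b[:, None] + b[None, :]) + d[:, None] + d[None, :] \
            + 2.0 * G
        pair[np.tril_indices(n_pos)] = np.inf
        ij = np.unravel_index(np.argmin(pair), pair.shape)
        if pair[ij] < best_sse - tol:
            best_sse, best_set = float(pair[ij]), tuple(ij)

    if max_events >= 3:
        iu = np.triu_indices(n_pos, k=1)
        pair_core = (
            -2.0 * (b[:, None] + b[None, :]) + d[:, None] + d[None, :] + 2.0 * G
        )
        best3, best3_set = np.inf, ()
        for i in range(n_pos - 2):
            js, ks = iu
            sel = js > i
            js, ks = js[sel], ks[sel]
            sse3 = (
                yy
                - 2.0 * b[i]
                + d[i]
                + pair_core[js, ks]
                + 2.0 * (G[i, js] + G[i, ks])
            )
            m = int(np.argmin(sse3))
            if sse3[m] < best3:
                best3, best3_set = float(sse3[m]), (i, int(js[m]), int(ks[m]))
        if best3 < best_sse - tol:
            best_sse, best_set = best3, best3_set
    return best_sse, tuple(sorted(best_set))


def greedy_sse(norm, result):
    return float(result.residual @ result.residual)


# ------------------------------------------------------------- template


class TestSpikeTemplate:
    def test_default_template_invariants(self, template):
        w = template.waveform
        assert template.sample_rate == 100.0
        assert template.peak_amplitude == pytest.approx(5.0)
        assert abs(w[0]) < 0.1 * w.max() and abs(w[-1]) < 0.1 * w.max()

    def test_extraction_from_identical_transients(self, template):
        """Traces containing copies of one transient average back to that
        transient shape (within 10 Hz -> 100 Hz interpolation error)."""
        fs = 10.0
        t = np.arange(601) / fs
        dff = np.zeros_like(t)
        for t0 in (5.0, 20.0, 40.0):
            rel = (t - t0) * 100.0
            k = np.round(rel).astype(int)
            ok = (k >= 0) & (k < template.waveform.size)
            dff[ok] += template.waveform[k[ok]]
        norm = make_norm_trace(dff)
        out = calcium.extract_spike_template([norm], peak_threshold=5.0)
        assert out.peak_amplitude == pytest.approx(5.0, rel=0.1)
        # same rise/decay support at the shared 100 Hz rate
        assert abs(out.waveform.size - template.waveform.size) < 60

    def test_two_population_mean_amplitude(self):
        """4% and 6% transient populations average to a ~5% template."""
        fs = 10.0
        t = np.arange(601) / fs
        dff = np.zeros_like(t)
        for t0, amp in [(5.0, 4.0), (15.0, 6.0), (30.0, 4.0), (45.0, 6.0)]:
            tmpl = default_template(peak_amplitude=amp)
            rel = (t - t0) * 100.0
            k = np.round(rel).astype(int)
            ok = (k >= 0) & (k < tmpl.waveform.size)
            dff[ok] += tmpl.waveform[k[ok]]
        out = calcium.extract_spike_template([make_norm_trace(dff)])
        assert out.peak_amplitude == pytest.approx(5.0, rel=0.1)

    def test_too_few_peaks_raises(self):
        norm = make_norm_trace(np.zeros(300))
        with pytest.raises(ValueError, match="template"):
            calcium.extract_spike_template([norm])

    def test_interpolation_grid_size(self, template):
        """A native-rate profile of L seconds yields ~100·L+1 samples."""
        fs = 10.0
        t = np.arange(601) / fs
        dff = np.zeros_like(t)
        for t0 in (5.0, 20.0, 40.0):
            rel = (t - t0) * 100.0
            k = np.round(rel).astype(int)
            ok = (k >= 0) & (k < template.waveform.size)
            dff[ok] += template.waveform[k[ok]]
        out = calcium.extract_spike_template([make_norm_trace(dff)],
                                             pre_window=0.3, post_window=1.2)
        assert out.waveform.size == 100 * 15 // 10 + 1  # 1.5 s at 100 Hz


# -------------------------------------------------------- reconstruction


class TestReconstruction:
    def test_flat_trace_yields_empty_train(self, template):
        rng = np.random.default_rng(0)
        norm = make_norm_trace(rng.normal(0.0, 0.3, 101))
        res = calcium.reconstruct_spike_train(norm, template)
        assert res.train.n_events == 0
        assert res.residual_sigma == pytest.approx(0.3, abs=0.15)
        assert res.success

    def test_single_noiseless_event_exact(self, template):
        trace, truth = synthetic.gen_gcamp_trace(
            [3.0], duration=10.0, noise_sigma=0.0, bleach_tau=None, seed=0
        )
        norm = thermometry.delta_f_over_f(
            thermometry.subtract_dark_noise(trace), (0.0, 2.0)
        )
        res = calcium.reconstruct_spike_train(norm, template)
        assert np.allclose(res.train.event_times, [3.0])
        assert res.residual_sigma < 1e-6

    def test_two_close_events_with_noise(self, template):
        trace, truth = synthetic.gen_gcamp_trace(
            [3.0, 3.5], duration=10.0, noise_sigma=0.5, bleach_tau=None, seed=2
        )
        norm = thermometry.delta_f_over_f(
            thermometry.subtract_dark_noise(trace), (0.0, 2.0)
        )
        res = calcium.reconstruct_spike_train(norm, template)
        assert res.train.n_events == 2
        assert np.allclose(res.train.event_times, [3.0, 3.5], atol=0.05)
        assert res.residual_sigma < 2.0

    def test_noiseless_multi_event_exact_recovery(self, template):
        """For gaps larger than the template width and zero noise, the
        reconstruction equals the generating train exactly."""
        rng = np.random.default_rng(7)
        for trial in range(10):
            n = int(rng.integers(1, 6))
            while True:
                times = np.round(np.sort(rng.uniform(1.0, 18.0, n)), 2)
                if n < 2 or np.min(np.diff(times)) >= 1.6:
                    break
            trace, _ = synthetic.gen_gcamp_trace(
                times, duration=20.0, noise_sigma=0.0, bleach_tau=None, seed=trial
            )
            norm = thermometry.delta_f_over_f(
                thermometry.subtract_dark_noise(trace), (0.0, 1.0)
            )
            res = calcium.reconstruct_spike_train(norm, template)
            assert np.allclose(res.train.event_times, times, atol=1e-9)

    def test_failure_is_flagged_not_silent(self, template):
        """A trace the template cannot explain returns success=False."""
        rng = np.random.default_rng(1)
        norm = make_norm_trace(rng.normal(0.0, 5.0, 101))
        res = calcium.reconstruct_spike_train(norm, template)
        assert not res.success
        assert res.residual_sigma >= 2.0

    @pytest.mark.parametrize("seed", [11, 23, 35])
    def test_greedy_matches_enumeration_oracle(self, template, seed):
        """On short traces with <=3 events the greedy solution attains the
        global minimum-SSE placement found by exhaustive enumeration."""
        rng = np.random.default_rng(seed)
        n_ev = int(rng.integers(1, 4))
        while True:
            times = np.round(np.sort(rng.uniform(0.3, 2.4, n_ev)), 2)
            if n_ev < 2 or np.min(np.diff(times)) >= 0.3:
                break
        duration = 4.0
        trace, _ = synthetic.gen_gcamp_trace(
            times, duration=duration, noise_sigma=0.3, bleach_tau=None, seed=seed
        )
        norm = thermometry.delta_f_over_f(
            thermometry.subtract_dark_noise(trace), (2.8, 4.0)
        )
        res = calcium.reconstruct_spike_train(norm, template)
        oracle_sse, oracle_set = enumerate_best_train(
            norm.dff, norm.sample_rate, template.waveform, max_events=3
        )
        got_positions = tuple(
            sorted(int(round(t * 100)) for t in res.train.event_times)
        )
        assert greedy_sse(norm, res) == pytest.approx(oracle_sse, abs=1e-9)
        assert got_positions == oracle_set


# ------------------------------------------------------------ statistics


class TestBinning:
    def test_empty_train(self):
        train = SpikeTrain(event_times=[], duration=20.0)
        rs = calcium.bin_spike_counts(train)
        assert rs.counts.sum() == 0

    def test_enumerated_counts(self):
        train = SpikeTrain(event_times=[1.0, 2.0, 3.0, 6.0], duration=10.0)
        rs = calcium.bin_spike_counts(train, bin_width=5.0)
        assert rs.counts.tolist() == [3, 1, 0]

    def test_edge_event_goes_right(self):
        train = SpikeTrain(event_times=[5.0], duration=10.0)
        rs = calcium.bin_spike_counts(train, bin_width=5.0)
        assert rs.counts.tolist() == [0, 1, 0]

    @pytest.mark.parametrize("origin", [0.0, -1.3, 2.7])
    def test_total_conserved_for_any_origin(self, origin):
        rng = np.random.default_rng(3)
        times = np.sort(rng.uniform(0, 60, 40))
        times = times[np.concatenate([[True], np.diff(times) > 0.011])]
        train = SpikeTrain(event_times=times, duration=60.0)
        rs = calcium.bin_spike_counts(train, origin=origin)
        assert rs.counts.sum() == train.n_events


class TestLatency:
    def test_event_at_onset(self):
        train = SpikeTrain(event_times=[5.0], duration=10.0)
        assert calcium.first_spike_latency(train, 5.0) == 0.0

    def test_pre_onset_events_ignored(self):
        train = SpikeTrain(event_times=[4.0, 7.2], duration=10.0)
        assert calcium.first_spike_latency(train, 5.0) == pytest.approx(2.2)

    def test_censored_when_silent_after_onset(self):
        train = SpikeTrain(event_times=[4.0], duration=10.0)
        assert calcium.first_spike_latency(train, 5.0) is None

    def test_poisson_lambda_recovery(self):
        lats = synthetic.gen_latencies(2.18, 10000, seed=5)
        fit = fit_latency_distribution(lats)
        assert abs(fit.lam - 2.18) < 0.05

    def test_stderr_shrinks_with_n(self):
        errs = []
        for n in (200, 5000):
            fit = fit_latency_distribution(synthetic.gen_latencies(2.18, n, seed=9))
            errs.append(fit.lam_stderr)
        assert errs[1] < errs[0]

    def test_degenerate_histogram_raises(self):
        lats = LatencySet(latencies=np.full(20, 0.5))
        with pytest.raises(ValueError):
            fit_latency_distribution(lats)


class TestHillFit:
    def test_seeded_recovery(self):
        rng = np.random.default_rng(11)
        T = np.linspace(32, 40, 17)
        truth = calcium.HillFit(
            midpoint_T50=37.7, hill_coefficient=40.0, rate_min=1.5, rate_max=13.0
        )
        rates = truth.rate(T) + rng.normal(0, 0.5, T.size)
        fit = fit_hill_rate_curve(T, rates)
        assert abs(fit.midpoint_T50 - 37.7) < 0.2

    def test_noiseless_exact(self):
        T = np.linspace(33, 40, 15)
        truth = calcium.HillFit(
            midpoint_T50=37.7, hill_coefficient=40.0, rate_min=1.5, rate_max=13.0
        )
        fit = fit_hill_rate_curve(T, truth.rate(T))
        assert fit.midpoint_T50 == pytest.approx(37.7, abs=1e-3)
        assert fit.rate_min == pytest.approx(1.5, abs=0.01)
        assert fit.rate_max == pytest.approx(13.0, abs=0.01)

    def test_midpoint_identity(self):
        T = np.linspace(33, 40, 15)
        truth = calcium.HillFit(
            midpoint_T50=37.7, hill_coefficient=40.0, rate_min=1.5, rate_max=13.0
        )
        fit = fit_hill_rate_curve(T, truth.rate(T))
        mid = fit.rate(np.array([fit.midpoint_T50]))[0]
        assert mid == pytest.approx((fit.rate_min + fit.rate_max) / 2.0, rel=1e-6)


class TestActiveFraction:
    def test_no_active(self):
        trains = [SpikeTrain(event_times=[], duration=10.0) for _ in range(5)]
        frac, se = calcium.active_fraction(trains, (0.0, 5.0))
        assert frac == 0.0

    @pytest.mark.parametrize("n_active, expected", [(22, 53.7), (33, 80.5)])
    def test_measured_cohort_fractions(self, n_active, expected):
        trains = [
            SpikeTrain(event_times=[1.0] if i < n_active else [], duration=10.0)
            for i in range(41)
        ]
        frac, se = calcium.active_fraction(trains, (0.0, 5.0))
        assert frac == pytest.approx(expected, abs=0.05)

    def test_empty_list_raises(self):
        with pytest.raises(ValueError):
            calcium.active_fraction([], (0.0, 5.0))
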