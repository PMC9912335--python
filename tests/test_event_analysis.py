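"""Event detection, dwell MLE, bootstrap and rate estimation."""

import numpy as np
import pandas as pd
import pytest

from neotrap.event_analysis import (
    bootstrap_sd,
    capture_rate,
    detect_events,
    estimate_baseline_sigma,
    event_scatter,
    find_levels,
    fit_dwell_exponential,
)
from neotrap.trace_synthesis import (
    STATE_TRAPPED,
    AcquisitionSpec,
    KineticScheme,
    NoiseModel,
    make_fixture,
    render_trace,
    simulate_state_path,
)


def square_trace(levels, widths):
    return np.concatenate([np.full(w, l, dtype=float) for l, w in zip(levels, widths)])


class TestFindLevels:
    def test_noise_free_two_level_square_wave(self):
        x = square_trace([100, 80] * 10, [500, 500] * 10)
        levels = find_levels(x)
        assert levels == pytest.approx([100.0, 80.0])

    def test_noisy_mixture_means_recovered(self):
        rng = np.random.default_rng(1)
        x = square_trace([100, 80] * 50, [10_000, 10_000] * 50)
        x = x + rng.normal(0, 2.0, size=x.size)
        levels = find_levels(x)
        assert len(levels) == 2
        assert abs(levels[0] - 100.0) < 0.1
        assert abs(levels[1] - 80.0) < 0.1

    def test_single_constant_level(self):
        assert find_levels(np.full(1000, 42.0)) == pytest.approx([42.0])

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            find_levels(np.array([]))


class TestDetector:
    def make_dipped(self, n=30_000, depth=50.0, baseline=100.0,
                    dips=((5000, 5500), (12_000, 12_800), (20_000, 20_100))):
        x = np.full(n, baseline)
        for s, e in dips:
            x[s:e] = baseline - depth
        return x, dips

    def test_noise_free_rectangular_dips_exact(self):
        x, dips = self.make_dipped()
        table = detect_events(x, baseline=100.0, sigma=1.0, sample_rate=1e4)
        assert len(table) == 3
        for (s, e), row in zip(dips, table.events.itertuples()):
            assert (row.start, row.end) == (s, e)
            assert row.dwell_s == pytest.approx((e - s) / 1e4)
            assert row.blockade == pytest.approx(0.5)

    def test_robust_to_noise_below_half_depth(self):
        rng = np.random.default_rng(2)
        x, dips = self.make_dipped(depth=50.0)
        x = x + rng.normal(0, 3.0, x.size)  # 5 sigma = 15 << 50
        table = detect_events(x, baseline=100.0, sigma=3.0, sample_rate=1e4)
        assert len(table) == 3
        for (s, e), row in zip(dips, table.events.itertuples()):
            assert abs(row.start - s) <= 2
            assert abs(row.end - e) <= 2

    def test_subthreshold_dip_ignored(self):
        x, _ = self.make_dipped(depth=4.0)
        table = detect_events(x, baseline=100.0, sigma=1.0, k=5.0, sample_rate=1e4)
        assert len(table) == 0

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            detect_events(np.zeros(100), baseline=1.0, sigma=0.1, k=0.0, sample_rate=1e4)

    def test_boundary_truncated_events_censored(self):
        x = np.full(10_000, 100.0)
        x[:500] = 50.0      # open at trace start
        x[4000:4300] = 50.0  # complete event
        x[9800:] = 50.0      # open at trace end
        table = detect_events(x, baseline=100.0, sigma=1.0, sample_rate=1e4)
        assert len(table) == 1
        assert table.n_censored == 2
        assert table.events.iloc[0].start == 4000
        # censored spans still count as occupied time
        assert table.unoccupied_time == pytest.approx((10_000 - 300 - 500 - 200) / 1e4)

    def test_matches_ground_truth_state_path(self):
        scheme = KineticScheme(capture_rate=5.0, escape_rate=30.0)
        acq = AcquisitionSpec(duration_s=20.0, sample_rate_hz=50e3)
        path = simulate_state_path(scheme, 20.0, 3)
        trace = render_trace(path, scheme, NoiseModel(), acq, seed=3, apply_filter=False)
        docked = scheme.open_current_pA * scheme.docked_level
        table = detect_events(trace, baseline=docked, sigma=1.0,
                              min_duration_samples=1)
        truth = path.dwell_times(STATE_TRAPPED)
        # sampling quantizes sub-sample sojourns away; compare to the
        # sampled ground truth
        t = np.arange(len(trace.samples)) / acq.sample_rate_hz
        sampled = path.state_at(t) == STATE_TRAPPED
        n_truth = np.count_nonzero(np.diff(sampled.astype(int)) == 1) + sampled[0]
        if sampled[-1]:
            n_truth -= 1  # censored at trace end
        assert len(table) == n_truth


class TestDwellFit:
    def test_mle_equals_mean(self):
        fit = fit_dwell_exponential([1.0, 1.0, 1.0])
        assert fit.tau == 1.0 and fit.rate == 1.0
        rng = np.random.default_rng(4)
        d = rng.exponential(0.2, 400)
        assert fit_dwell_exponential(d).tau == d.mean()

    def test_recovery_from_exponential_draws(self):
        rng = np.random.default_rng(5)
        d = rng.exponential(1 / 11.0, 5000)
        fit = fit_dwell_exponential(d)
        se = (1 / 11.0) / np.sqrt(5000)
        assert abs(fit.tau - 1 / 11.0) < 3 * se

    def test_empty_and_invalid_rejected(self):
        with pytest.raises(ValueError):
            fit_dwell_exponential([])
        with pytest.raises(ValueError):
            fit_dwell_exponential([0.1, -0.2])


class TestBootstrap:
    def test_constant_data_gives_zero_sd(self):
        assert bootstrap_sd([0.5] * 50, np.mean, B=200, seed=1) == 0.0

    def test_matches_analytic_se_of_exponential_mean(self):
        rng = np.random.default_rng(6)
        tau = 0.09
        d = rng.exponential(tau, 1000)
        sd = bootstrap_sd(d, np.mean, B=1000, seed=2)
        assert sd == pytest.approx(tau / np.sqrt(1000), rel=0.15)

    def test_stable_under_doubling_B(self):
        rng = np.random.default_rng(7)
        d = rng.exponential(0.1, 500)
        sd1 = bootstrap_sd(d, np.mean, B=1000, seed=3)
        sd2 = bootstrap_sd(d, np.mean, B=2000, seed=3)
        assert abs(sd2 - sd1) / sd1 < 0.05

    def test_input_validation(self):
        with pytest.raises(ValueError):
            bootstrap_sd([1.0], np.mean, B=200)
        with pytest.raises(ValueError):
            bootstrap_sd([1.0, 2.0], np.mean, B=50)


class TestRates:
    def test_capture_rate_arithmetic(self):
        x = np.full(20_000, 100.0)
        # 10 events of 1000 samples each -> 1 s occupied, 1 s unoccupied at 10 kHz
        for k in range(10):
            s = 1000 + k * 1900
            x[s: s + 1000] = 50.0
        table = detect_events(x, baseline=100.0, sigma=1.0, sample_rate=1e4)
        assert len(table) == 10
        rates = capture_rate(table, bootstrap=0)
        assert rates.capture == pytest.approx(10.0)

    def test_parameter_recovery_from_preset_trace(self):
        trace = make_fixture("vertical_avidin", seed=11, duration_s=120.0,
                             sample_rate_hz=50e3)
        baseline, sigma = estimate_baseline_sigma(trace)
        table = detect_events(trace, baseline, sigma)
        rates = capture_rate(table, bootstrap=500, seed=1)
        assert abs(rates.capture - 7.7) < 3 * rates.capture_sd
        assert abs(rates.escape - 11.0) < 3 * rates.escape_sd

    def test_capture_rate_linear_in_generator_rate(self):
        caps = {}
        for kc in (4.0, 8.0):
            scheme = KineticScheme(capture_rate=kc, escape_rate=50.0)
            acq = AcquisitionSpec(duration_s=150.0, sample_rate_hz=25e3)
            path = simulate_state_path(scheme, 150.0, 12)
            trace = render_trace(path, scheme, NoiseModel(), acq, seed=12,
                                 apply_filter=False)
            docked = scheme.open_current_pA * scheme.docked_level
            table = detect_events(trace, baseline=docked, sigma=2.0)
            caps[kc] = capture_rate(table, bootstrap=200, seed=2)
        ratio = caps[8.0].capture / caps[4.0].capture
        sd = ratio * np.sqrt(
            (caps[8.0].capture_sd / caps[8.0].capture) ** 2
            + (caps[4.0].capture_sd / caps[4.0].capture) ** 2
        )
        assert abs(ratio - 2.0) < 3 * sd


class TestScatter:
    def test_single_event_point(self):
        x = np.full(10_000, 100.0)
        x[2000:2500] = 80.0  # 20% blockade, 50 ms at 10 kHz
        table = detect_events(x, baseline=100.0, sigma=1.0, sample_rate=1e4)
        pts = event_scatter(table)
        assert len(pts) == 1
        assert pts.iloc[0].dwell_s == pytest.approx(0.05)
        assert pts.iloc[0].blockade == pytest.approx(0.20)

    def test_short_filtered_events_flagged_unreliable(self):
        scheme = KineticScheme(capture_rate=3.0, escape_rate=2.0)
        acq = AcquisitionSpec(duration_s=30.0, sample_rate_hz=50e3, cutoff_hz=10e3)
        path = simulate_state_path(scheme, 30.0, 13)
        trace = render_trace(path, scheme, NoiseModel(), acq, seed=13)
        docked = scheme.open_current_pA * scheme.docked_level
        table = detect_events(trace, baseline=docked, sigma=1.0)
        pts = event_scatter(table)
        rise = 0.34 / acq.cutoff_hz
        assert (pts.dwell_s[~pts.reliable] < 3 * rise).all()
        assert (pts.dwell_s[pts.reliable] >= 3 * rise).all()

    def test_empty_table_rejected(self):
        x = np.full(1000, 1.0)
        table = detect_events(x, baseline=1.0, sigma=0.01, sample_rate=1e4)
        with pytest.raises(ValueError):
            event_scatter(table)
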