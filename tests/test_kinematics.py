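import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from penkin.io import PenTrace
from penkin.kinematics import (
    SegmentationParams,
    count_velocity_peaks,
    dysfluency_speed,
    path_length,
    resample_uniform,
    segment_strokes,
    smooth_trace,
    velocity_profile,
)
from penkin.simulate import GeneratorConfig, generate_trial

from conftest import brute_force_peak_count, noiseless_config


def trace_from(t, x, y, p=None, rate=None):
    p = np.full(len(t), 0.6) if p is None else np.asarray(p, float)
    return PenTrace(t=np.asarray(t, float), x=np.asarray(x, float),
                    y=np.asarray(y, float), p=p, nominal_rate=rate)


class TestResample:
    def test_identity_on_uniform(self):
        t = np.arange(100) / 200
        tr = trace_from(t, np.sin(t), np.cos(t), rate=200)
        out = resample_uniform(tr, 200)
        np.testing.assert_allclose(out.x, tr.x, atol=1e-9)
        np.testing.assert_allclose(out.y, tr.y, atol=1e-9)

    def test_preserves_linear_signals(self):
        t = np.sort(np.random.default_rng(0).uniform(0, 1, 50))
        t[0], t[-1] = 0.0, 1.0
        tr = trace_from(t, 3 * t + 1, -2 * t)
        out = resample_uniform(tr, 137)
        np.testing.assert_allclose(out.x, 3 * out.t + 1, atol=1e-12)

    def test_grid_point_count(self):
        tr = trace_from([0.0, 0.1], [0, 1], [0, 1])
        assert len(resample_uniform(tr, 100)) == 11

    def test_rejects_bad_rate(self):
        tr = trace_from([0, 0.1], [0, 1], [0, 1])
        with pytest.raises(ValueError):
            resample_uniform(tr, 0)


class TestSmoothing:
    def test_dc_passes(self):
        t = np.arange(200) / 200
        tr = trace_from(t, np.full(200, 3.7), np.full(200, -1.2), rate=200)
        out = smooth_trace(tr, 10)
        np.testing.assert_allclose(out.x, tr.x, atol=1e-9)

    @pytest.mark.parametrize("freq, max_loss, min_loss", [
        (2.0, 0.01, 0.0),     # passband: attenuation < 1%
        (40.0, 1.0, 0.99),    # stopband: attenuation > 99%
    ])
    def test_butterworth_band_edges(self, freq, max_loss, min_loss):
        t = np.arange(2000) / 200
        y = np.sin(2 * np.pi * freq * t)
        tr = trace_from(t, np.zeros_like(t), y, rate=200)
        out = smooth_trace(tr, 10)
        mid = slice(500, 1500)  # avoid filter edge transients
        amp = np.max(np.abs(out.y[mid]))
        assert 1 - amp <= max_loss
        assert 1 - amp >= min_loss

    def test_cutoff_above_nyquist_rejected(self):
        t = np.arange(100) / 200
        tr = trace_from(t, t, t, rate=200)
        with pytest.raises(ValueError, match="Nyquist"):
            smooth_trace(tr, 100)


class TestVelocityProfile:
    def test_exact_for_linear_motion(self):
        t = np.arange(100) / 200
        tr = trace_from(t, 2.5 * t, -1.5 * t, rate=200)
        prof = velocity_profile(tr)
        np.testing.assert_allclose(prof.vx, 2.5, atol=1e-9)
        np.testing.assert_allclose(prof.vy, -1.5, atol=1e-9)

    def test_stationary_pen_zero_speed(self):
        t = np.arange(50) / 200
        tr = trace_from(t, np.full(50, 1.0), np.full(50, 2.0), rate=200)
        np.testing.assert_allclose(velocity_profile(tr).speed, 0, atol=1e-12)

    def test_circle_constant_speed(self):
        # uniform circular motion: analytic speed = omega * R
        rate, R, omega = 200.0, 1.0, 2 * np.pi
        t = np.arange(int(rate)) / rate
        tr = trace_from(t, R * np.cos(omega * t), R * np.sin(omega * t), rate=rate)
        speed = velocity_profile(tr).speed[2:-2]
        np.testing.assert_allclose(speed, omega * R, rtol=5e-3)


class TestSegmentation:
    def test_sine_period_three_strokes(self, params):
        # y = A sin(2 pi t / T): vy zero crossings at T/4 and 3T/4
        rate, T = 200.0, 0.8
        t = np.arange(int(T * rate) + 1) / rate
        tr = trace_from(t, 0.1 * t, 0.8 * np.sin(2 * np.pi * t / T), rate=rate)
        strokes = segment_strokes(velocity_profile(tr), tr, params)
        assert [s.direction for s in strokes] == ["US", "DS", "US"]
        assert strokes[1].duration_s == pytest.approx(T / 2, abs=1.5 / rate)

    def test_monotone_rise_single_upstroke(self, params):
        t = np.arange(100) / 200
        tr = trace_from(t, 0.1 * t, t, rate=200)
        strokes = segment_strokes(velocity_profile(tr), tr, params)
        assert len(strokes) == 1 and strokes[0].direction == "US"

    def test_pen_up_gap_splits_runs(self, params):
        t = np.arange(200) / 200
        y = t.copy()
        p = np.full(200, 0.6)
        p[90:110] = 0.0
        tr = trace_from(t, 0.1 * t, y, p=p, rate=200)
        strokes = segment_strokes(velocity_profile(tr), tr, params)
        assert len(strokes) == 2
        assert all(s.direction == "US" for s in strokes)
        assert strokes[0].end < strokes[1].start

    def test_no_pen_down_is_error(self, params):
        t = np.arange(50) / 200
        tr = trace_from(t, t, t, p=np.zeros(50), rate=200)
        with pytest.raises(ValueError, match="pen-down"):
            segment_strokes(velocity_profile(tr), tr, params)

    @pytest.mark.parametrize("seed", range(6))
    def test_partition_and_alternation(self, params, seed):
        """Strokes partition each pen-down run and alternate direction."""
        rng = np.random.default_rng(seed)
        g, b = [("CTRL", "ll"), ("SCZ", "ln")][seed % 2]
        tr, _ = generate_trial(g, b, 0.0, 0.0, GeneratorConfig(seed=0), rng,
                               subject_id="s", trial=1)
        uni = resample_uniform(tr, params.resample_rate)
        sm = smooth_trace(uni, params.lowpass_cutoff)
        strokes = segment_strokes(velocity_profile(sm), sm, params)
        assert strokes, "expected at least one stroke"
        prev = None
        for s in strokes:
            assert s.end > s.start
            if prev is not None and prev.end == s.start:  # same pen-down run
                assert prev.direction != s.direction
            prev = s


class TestPathLength:
    def test_straight_segment(self):
        from penkin.kinematics import Stroke
        y = np.linspace(0, 1.0, 37)
        s = Stroke(0, "US", 0, 37, 37 / 200, x=np.zeros(37), y=y)
        assert path_length(s) == pytest.approx(1.0, abs=1e-12)

    def test_semicircle_arc_length(self):
        from penkin.kinematics import Stroke
        theta = np.linspace(0, np.pi, 1000)
        r = 0.5
        s = Stroke(0, "US", 0, 1000, 5.0, x=r * np.cos(theta), y=r * np.sin(theta))
        assert path_length(s) == pytest.approx(np.pi * r, abs=1e-4)

    def test_single_sample_zero(self):
        from penkin.kinematics import Stroke
        s = Stroke(0, "US", 0, 1, 0.005, x=np.array([1.0]), y=np.array([2.0]))
        assert path_length(s) == 0.0

    @settings(derandomize=True, max_examples=25)
    @given(st.floats(0, 2 * np.pi), st.floats(-5, 5), st.floats(-5, 5),
           st.integers(0, 2 ** 31 - 1))
    def test_rigid_motion_invariance(self, angle, dx, dy, seed):
        from penkin.kinematics import Stroke
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=20), rng.normal(size=20)
        c, s_ = np.cos(angle), np.sin(angle)
        xr, yr = c * x - s_ * y + dx, s_ * x + c * y + dy
        a = path_length(Stroke(0, "US", 0, 20, 0.1, x=x, y=y))
        b = path_length(Stroke(0, "US", 0, 20, 0.1, x=xr, y=yr))
        assert b == pytest.approx(a, abs=1e-9, rel=1e-9)


class TestPeakCounting:
    def test_single_bell_is_one_peak(self, params):
        t = np.linspace(0, 1, 101)
        assert count_velocity_peaks(np.sin(np.pi * t), params, 200) == 1

    def test_two_separated_bells(self, params):
        t = np.linspace(0, 1, 201)
        x = np.exp(-((t - 0.25) / 0.05) ** 2) + np.exp(-((t - 0.75) / 0.05) ** 2)
        assert count_velocity_peaks(x, params, 200) == 2

    def test_monotone_ramp_no_peaks(self, params):
        assert count_velocity_peaks(np.linspace(0, 1, 100), params, 200) == 0

    def test_plateau_counts_once(self, params):
        x = np.array([0, 1, 2, 2, 2, 1, 0], dtype=float)
        assert count_velocity_peaks(x, params, 200) == 1

    def test_edge_maxima_never_count(self, params):
        x = np.array([5, 1, 0.5, 1, 5], dtype=float)  # maxima only at edges
        assert count_velocity_peaks(x, params, 200) == 0

    def test_empty_span_is_error(self, params):
        with pytest.raises(ValueError):
            count_velocity_peaks(np.array([]), params, 200)

    @pytest.mark.parametrize("family", ["walk", "waves", "uniform"])
    def test_matches_brute_force_oracle(self, params, family):
        """Exhaustive O(n^2) prominence oracle agreement on 1,000 random
        speed profiles per family."""
        rng = np.random.default_rng({"walk": 1, "waves": 2, "uniform": 3}[family])
        gap = max(1, int(round(params.min_peak_separation * 200)))
        for _ in range(1000):
            n = int(rng.integers(5, 400))
            if family == "walk":
                x = np.abs(np.cumsum(rng.normal(0, 1, n)))
            elif family == "waves":
                t = np.linspace(0, 1, n)
                x = np.abs(np.sin(2 * np.pi * rng.uniform(1, 6) * t)
                           + 0.4 * rng.normal(0, 1, n))
            else:
                x = rng.uniform(0, 1, n)
            assert count_velocity_peaks(x, params, 200) == \
                brute_force_peak_count(x, params.peak_prominence_frac, gap)


class TestRobustness:
    def test_jitter_does_not_change_peak_counts(self, params):
        """Position jitter at the digitiser scale (sigma = 0.002 cm) leaves
        the per-stroke peak count unchanged on generator strokes."""
        cfg_clean = noiseless_config()
        cfg_noise = noiseless_config(position_jitter_sd=0.002)
        changed = 0
        total = 0
        for seed in range(60):
            g, b = [("SCZ", "ln"), ("SCZ", "ll"), ("CTRL", "ln")][seed % 3]
            counts = []
            for cfg in (cfg_clean, cfg_noise):
                tr, _ = generate_trial(g, b, 0, 0, cfg,
                                       np.random.default_rng(seed),
                                       subject_id="s", trial=1)
                uni = resample_uniform(tr, params.resample_rate)
                sm = smooth_trace(uni, params.lowpass_cutoff)
                strokes = segment_strokes(velocity_profile(sm), sm, params)[:2]
                spd = dysfluency_speed(uni, params)
                counts.append([count_velocity_peaks(spd[s.start:s.end], params,
                                                    params.resample_rate)
                               for s in strokes])
            total += len(counts[0])
            changed += sum(a != b for a, b in zip(*counts))
        assert total >= 100
        assert changed == 0

    def test_duration_stable_under_rate_doubling(self, params):
        """Doubling the resample rate moves each measured stroke duration by
        at most one original sample period."""
        import dataclasses
        cfg = noiseless_config()
        tr, _ = generate_trial("CTRL", "ln", 0, 0, cfg,
                               np.random.default_rng(0), subject_id="s", trial=1)

        def durations(rate):
            p = dataclasses.replace(params, resample_rate=rate)
            uni = resample_uniform(tr, rate)
            sm = smooth_trace(uni, p.lowpass_cutoff)
            return [s.duration_s for s in
                    segment_strokes(velocity_profile(sm), sm, p)[:2]]

        base = durations(200.0)
        fine = durations(400.0)
        for a, b in zip(base, fine):
            assert abs(a - b) <= 1.0 / 200.0 + 1e-9
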