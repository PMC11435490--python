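import numpy as np
import pytest

from trunkgait import RunConfig, SyntheticSpec, detect_events, generate_trace, temporal_parameters
from trunkgait.errors import InsufficientGaitError, InsufficientStridesError, LengthError
from trunkgait.gait_events import (
    assign_sides,
    detect_final_contacts,
    detect_initial_contacts,
    preprocess_vertical,
    segment_and_trim,
)

FS = 100.0


class TestPreprocess:
    def test_constant_input_zeroed(self):
        out = preprocess_vertical(np.full(1000, 9.81), FS)
        np.testing.assert_allclose(out, 0.0, atol=1e-9)

    def test_linear_ramp_zeroed(self):
        out = preprocess_vertical(np.linspace(0, 5, 1000), FS)
        np.testing.assert_allclose(out, 0.0, atol=1e-8)

    def test_filter_response(self):
        # 1 Hz preserved within 5 %, 10 Hz attenuated >= 40 dB
        t = np.arange(4000) / FS
        low = np.sin(2 * np.pi * 1.0 * t)
        high = np.sin(2 * np.pi * 10.0 * t)
        out = preprocess_vertical(low + high, FS)
        mid = slice(1000, 3000)

        def amp(x, f):
            return 2 * np.abs(np.sum(x[mid] * np.exp(-2j * np.pi * f * t[mid]))) / len(t[mid])

        assert amp(out, 1.0) == pytest.approx(1.0, rel=0.05)
        assert amp(out, 10.0) < 10 ** (-40 / 20)

    def test_too_short_signal(self):
        with pytest.raises(LengthError):
            preprocess_vertical(np.zeros(100), FS)


class TestInitialContacts:
    def test_programmed_steps_recovered(self, clean_walk, config):
        trace, truth = clean_walk
        ics = detect_initial_contacts(trace.v, FS, config)
        # one detection within 30 ms of every truth IC, no duplicates
        dist = np.abs(ics[:, None] - truth.ic_times[None, :])
        nearest = dist.min(axis=0)
        assert np.all(nearest < 0.030)
        claimed = dist.argmin(axis=1)[dist.min(axis=1) < 0.030]
        assert len(claimed) == len(set(claimed))

    def test_all_zero_trace_rejected(self):
        with pytest.raises(InsufficientGaitError):
            detect_initial_contacts(np.zeros(3000), FS)

    def test_white_noise_rejected(self):
        rng = np.random.default_rng(12)
        with pytest.raises(InsufficientGaitError):
            detect_initial_contacts(rng.standard_normal(3000), FS)

    def test_shift_equivariance(self, clean_walk, config):
        trace, _ = clean_walk
        k = 37
        ics = detect_initial_contacts(trace.v, FS, config)
        shifted = detect_initial_contacts(
            np.concatenate([trace.v[:1], np.repeat(trace.v[:1], k - 1), trace.v]), FS, config)
        # interior events shift by exactly k samples
        core = ics[2:-2]
        moved = shifted[2:-2][: len(core)]
        np.testing.assert_allclose(moved - core, k / FS, atol=1.5 / FS)

    def test_amplitude_invariance(self, clean_walk, config):
        trace, _ = clean_walk
        a = detect_initial_contacts(trace.v, FS, config)
        b = detect_initial_contacts(trace.v * 7.3, FS, config)
        np.testing.assert_allclose(a, b)


class TestAssignSides:
    def test_square_wave_alternation(self):
        ic_times = np.arange(10) * 0.55 + 0.3
        t = np.arange(3000) / FS
        ml = np.sign(np.sin(2 * np.pi * (t - 0.3) / 1.1 + 1e-9))
        labels, warnings = assign_sides(ic_times, ml, FS)
        assert labels[0] == "left"
        assert all(a != b for a, b in zip(labels[:-1], labels[1:]))
        assert not warnings

    def test_generator_truth(self, clean_walk, clean_events):
        _, truth = clean_walk
        dist = np.abs(clean_events.ic_times[:, None] - truth.ic_times[None, :])
        idx = dist.argmin(axis=0)
        matched = [clean_events.ic_sides[j] for j in idx]
        assert matched == truth.ic_sides

    def test_flat_ml_falls_back_with_warning(self):
        ic_times = np.arange(10) * 0.55 + 0.3
        labels, warnings = assign_sides(ic_times, np.zeros(3000), FS)
        assert warnings and "ambig" in warnings[0]
        assert all(a != b for a, b in zip(labels[:-1], labels[1:]))


class TestFinalContacts:
    def test_programmed_stance_recovered(self, config):
        spec = SyntheticSpec(stride_time=1.1, n_strides=26, stance_left=0.60,
                             stance_right=0.60, paretic_side="left", seed=0)
        trace, truth = generate_trace(spec)
        ev = detect_events(trace, config)
        tp = temporal_parameters(ev, trace.walk_distance)
        mean_stance = 0.5 * (tp.stance["left"] + tp.stance["right"])
        assert mean_stance == pytest.approx(0.6 * 1.1, rel=0.05)

    def test_symmetric_gait_sides_equal(self, config):
        spec = SyntheticSpec(stride_time=1.2, n_strides=26, stance_left=0.63,
                             stance_right=0.63, paretic_side="left", seed=1)
        trace, _ = generate_trace(spec)
        ev = detect_events(trace, config)
        tp = temporal_parameters(ev, trace.walk_distance)
        assert abs(tp.stance["left"] - tp.stance["right"]) <= 1.5 / FS

    def test_corrupted_interval_drops_stride_with_warning(self, clean_walk, config):
        trace, _ = clean_walk
        ics = detect_initial_contacts(trace.v, FS, config)
        sides = ["left" if i % 2 == 0 else "right" for i in range(len(ics))]
        v = trace.v.copy()
        lo = int(ics[4] * FS) + 1
        hi = int(ics[5] * FS)
        v[lo:hi] = 5.0  # no negative trough in this interval
        fc_times, fc_sides, warnings = detect_final_contacts(v, FS, ics, sides, config)
        assert len(fc_times) < len(ics) - 1
        assert any("trough" in w for w in warnings)


class TestSegmentAndTrim:
    def _ics(self, n_strides):
        return np.arange(2 * n_strides + 1) * 0.55

    def test_26_detected_22_retained(self):
        windows, n = segment_and_trim(self._ics(26), RunConfig())
        assert n == 26
        assert len(windows) == 22

    def test_exact_minimum_passes(self):
        windows, _ = segment_and_trim(self._ics(24), RunConfig())
        assert len(windows) == 20

    def test_insufficient_names_count(self):
        with pytest.raises(InsufficientStridesError, match="18 < 20"):
            segment_and_trim(self._ics(22), RunConfig())

    def test_windows_in_time_order(self):
        windows, _ = segment_and_trim(self._ics(30), RunConfig())
        starts = [w[0] for w in windows]
        assert starts == sorted(starts)


class TestTemporalParameters:
    def test_stance_plus_swing_is_stride(self, clean_events):
        tp = temporal_parameters(clean_events, 30.0)
        for side in ("left", "right"):
            total = tp.stance[side] + tp.swing[side]
            assert total == pytest.approx(tp.stride_time, abs=0.015)

    def test_symmetric_programmed_stance(self, config):
        spec = SyntheticSpec(stride_time=1.2, n_strides=26, stance_left=0.62,
                             stance_right=0.62, paretic_side="left", seed=2)
        trace, _ = generate_trace(spec)
        tp = temporal_parameters(detect_events(trace, config), trace.walk_distance)
        for side in ("left", "right"):
            assert tp.stance[side] == pytest.approx(0.62 * 1.2, rel=0.04)

    def test_corridor_speed_division(self, clean_events):
        # distance / IC-span division: 0.70 m/s times the span gives 0.70 back
        span = clean_events.ic_times[-1] - clean_events.ic_times[0]
        tp = temporal_parameters(clean_events, walk_distance=0.70 * span)
        assert tp.gait_speed == pytest.approx(0.70, rel=1e-9)
        # the printed cohort arithmetic: 30 m in 42.9 s is 0.70 m/s
        assert 30.0 / 42.9 == pytest.approx(0.70, abs=0.001)

    def test_generator_speed_recovered(self, clean_walk, clean_events):
        trace, truth = clean_walk
        tp = temporal_parameters(clean_events, trace.walk_distance)
        assert tp.gait_speed == pytest.approx(truth.gait_speed, rel=0.02)


def test_detection_invariant_50_draws():
    """>= 95 % of truth ICs matched within 30 ms across seeded preset draws."""
    from trunkgait import COHORT_PRESETS
    from trunkgait.synthetic_gait import draw_subject_spec

    cfg = RunConfig()
    rng = np.random.default_rng(42)
    fractions = []
    for i in range(50):
        preset = COHORT_PRESETS[("HS", "IC", "SII")[i % 3]]
        spec = draw_subject_spec(preset, f"s{i}", rng)
        trace, truth = generate_trace(spec)
        ev = detect_events(trace, cfg)
        dist = np.abs(ev.ic_times[:, None] - truth.ic_times[None, :])
        nearest = dist.min(axis=0)
        fractions.append(np.mean(nearest < 0.030))
        claimed = dist.argmin(axis=1)[dist.min(axis=1) < 0.030]
        assert len(claimed) == len(set(claimed)), "duplicate ICs for one step"
    assert np.mean(fractions) >= 0.95
    assert min(fractions) >= 0.9
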