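"""Event detection, temporal metrics and the inverted-pendulum spatial model."""

import numpy as np
import pytest

from pedgait.gait import (
    GaitParams,
    analyze_pass,
    detect_contact_events,
    find_vertical_axis,
    prune_close_events,
    spatial_metrics,
    step_length_from_excursion,
    temporal_metrics,
    vertical_acceleration,
)
from pedgait.records import AccelRecording, ContactEvent
from pedgait.synth import SimConfig, simulate_walk_pass


def _const_recording(vec, n=256, fs=64.0):
    return AccelRecording(data=np.tile(vec, (n, 1)), fs_hz=fs)


class TestVerticalAxis:
    def test_pure_gravity_z(self):
        assert find_vertical_axis(_const_recording([0, 0, 1.0])) == (2, 1)

    def test_sign_flip(self):
        assert find_vertical_axis(_const_recording([0, 0, -1.0])) == (2, -1)

    def test_planted_axis_recovered(self, profile):
        cfg = SimConfig(noise_sd_g=0.02, seed=0, vertical_axis=0, vertical_sign=1)
        rec, truth = simulate_walk_pass(profile, "natural", 10.0, cfg)
        axis, sign = find_vertical_axis(rec)
        assert (axis, sign) == (truth.vertical_axis, truth.vertical_sign)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            find_vertical_axis(_const_recording([0, 0, 0]))


class TestEventDetection:
    def test_no_motion_no_events(self):
        vert = np.ones(64 * 10)
        assert detect_contact_events(vert, 64.0) == []

    def test_planted_ics_recovered(self, clean_pass):
        rec, truth = clean_pass
        events = detect_contact_events(vertical_acceleration(rec), rec.fs_hz)
        ics = np.array([e.time_s for e in events if e.kind == "IC"])
        planted = truth.ic_times[1:-1]  # ignore first/last partial steps
        matched = [np.min(np.abs(ics - t)) for t in planted]
        assert max(matched) <= 0.1
        assert abs(ics.size - truth.ic_times.size) <= 2

    def test_events_strictly_increasing_and_feet_alternate(self, clean_pass):
        rec, _ = clean_pass
        events = detect_contact_events(vertical_acceleration(rec), rec.fs_hz)
        times = [e.time_s for e in events]
        assert all(b > a for a, b in zip(times, times[1:]))
        ic_feet = [e.foot for e in events if e.kind == "IC"]
        assert all(a != b for a, b in zip(ic_feet, ic_feet[1:]))

    def test_min_step_bound_prunes_close_pair(self):
        # candidate ICs 0.1 s apart at 64 Hz with min step time 0.25 s
        idx = np.array([100, 106, 132])
        prom = np.array([1.0, 2.0, 1.5])
        kept = prune_close_events(idx, prom, min_gap=16)
        assert kept == [106, 132]  # deeper minimum of the close pair survives

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError):
            detect_contact_events(np.ones(32), 64.0)
        with pytest.raises(ValueError):
            detect_contact_events(np.ones(6400), 10.0)


class TestTemporalMetrics:
    def test_arithmetic_on_stated_times(self):
        events = [
            ContactEvent(t, "IC", f)
            for t, f in zip((0.0, 0.5, 1.0, 1.5), "LRLR")
        ]
        strides = temporal_metrics(events)
        assert len(strides) == 2
        assert strides[0].stride_time_s == pytest.approx(1.0)
        assert strides[0].cadence_spm == pytest.approx(120.0)
        assert strides[0].step_time_s == pytest.approx(0.5)

    def test_three_ics_one_stride(self):
        events = [ContactEvent(t, "IC", f) for t, f in zip((0.0, 0.55, 1.1), "LRL")]
        assert len(temporal_metrics(events)) == 1

    def test_fewer_than_three_ics_empty(self):
        events = [ContactEvent(0.0, "IC", "L"), ContactEvent(0.5, "IC", "R")]
        assert temporal_metrics(events) == []

    def test_gap_breaks_stride_formation(self):
        times = [0.0, 0.5, 1.0, 4.0, 4.5, 5.0]
        events = [ContactEvent(t, "IC", "LR"[i % 2]) for i, t in enumerate(times)]
        strides = temporal_metrics(events)
        assert all(not (s.start_ic_s < 1.0 < s.end_ic_s > 4.0) for s in strides)
        assert len(strides) == 2  # one on each side of the gap

    def test_recovers_planted_stride_time(self, clean_pass):
        rec, truth = clean_pass
        events = detect_contact_events(vertical_acceleration(rec), rec.fs_hz)
        strides = temporal_metrics(events)
        mean_st = np.mean([s.stride_time_s for s in strides])
        assert abs(mean_st - truth.stride_times_s[0]) <= 1.0 / rec.fs_hz

    def test_double_support_positive(self, clean_pass):
        rec, truth = clean_pass
        events = detect_contact_events(vertical_acceleration(rec), rec.fs_hz)
        ds = [s.double_support_s for s in temporal_metrics(events) if s.double_support_s]
        assert ds and all(0 < d < truth.stride_times_s[0] for d in ds)


class TestSpatialMetrics:
    def test_closed_form_limits(self):
        assert step_length_from_excursion(0.0, 0.9) == 0.0
        assert step_length_from_excursion(0.05, 0.9) == pytest.approx(
            2 * np.sqrt(2 * 0.9 * 0.05 - 0.0025)
        )
        with pytest.raises(ValueError):
            step_length_from_excursion(1.9, 0.9)

    def test_recovers_planted_length(self, profile, clean_pass):
        rec, truth = clean_pass
        strides = analyze_pass(rec, profile.height_m)
        mean_len = np.mean([s.stride_length_m for s in strides])
        assert mean_len == pytest.approx(truth.stride_lengths_m[0], rel=0.10)

    def test_speed_identity_exact(self, profile, clean_pass):
        rec, _ = clean_pass
        for s in analyze_pass(rec, profile.height_m):
            assert s.speed_mps * s.stride_time_s == pytest.approx(s.stride_length_m, rel=1e-12)

    def test_requires_positive_height(self, clean_pass):
        rec, _ = clean_pass
        with pytest.raises(ValueError):
            spatial_metrics([], np.ones(640), 64.0, -1.0)
        # empty strides with valid height is fine
        assert spatial_metrics([], np.ones(640), 64.0, 1.3) == []


class TestScaleProperties:
    def test_cadence_equivariance(self, profile):
        """Doubling planted cadence halves the estimated stride time."""
        out = {}
        for cad in (60.0, 120.0):
            cfg = SimConfig(noise_sd_g=0.0, seed=2)
            rec, _ = simulate_walk_pass(profile, "natural", 30.0, cfg, cadence_spm=cad)
            strides = analyze_pass(rec, profile.height_m)
            out[cad] = np.median([s.stride_time_s for s in strides])
        assert out[60.0] / out[120.0] == pytest.approx(2.0, rel=0.05)

    @pytest.mark.parametrize("speed_class", ["natural", "fast", "slow"])
    def test_bounded_relative_error_across_speeds(self, profile, speed_class):
        cfg = SimConfig(noise_sd_g=0.05, seed=11)
        rec, truth = simulate_walk_pass(profile, speed_class, 30.0, cfg)
        strides = analyze_pass(rec, profile.height_m)
        est = np.median([s.speed_mps for s in strides])
        assert est == pytest.approx(truth.speeds_mps[0], rel=0.15)
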