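import math
import warnings

import numpy as np
import pytest

from lungeforge.kinematics import (
    DetectionThresholds,
    LungeEvent,
    SegmentationError,
    TagTrace,
    TraceError,
    detect_lunges,
    final_oscillation,
    integrate_speed,
    sample_middle_lunges,
    sample_size_stability,
    segment_dives,
    speed_from_ocdr,
    tailbeat_periods,
)
from lungeforge.synthetic import default_profile, simulate_deployment

from conftest import SPECIES, match_truth

EVENT_TIMES = ("T_fluke", "T_accel", "T_max", "T_MO", "T_MC", "T_min")


class TestSpeedFromOCDR:
    def test_vertical_descent(self):
        assert speed_from_ocdr(2.0, math.pi / 2)[0] == pytest.approx(2.0)

    def test_thirty_degrees(self):
        assert speed_from_ocdr(1.0, math.pi / 6)[0] == pytest.approx(2.0)

    def test_shallow_pitch_excluded_not_zero(self):
        out = speed_from_ocdr(1.0, 0.01, min_pitch=0.35)
        assert out.mask[0]

    def test_zero_pitch_never_divides(self):
        out = speed_from_ocdr(np.array([1.0, 1.0]), np.array([0.0, 1.0]))
        assert out.mask[0] and not out.mask[1]
        assert np.isfinite(out[1])


class TestTagTrace:
    def _chan(self, n):
        return dict(depth=np.full(n, 10.0), pitch=np.zeros(n),
                    speed=np.full(n, 2.0), gyro_y=np.zeros(n))

    def test_irregular_interval_rejected(self):
        t = np.array([0.0, 0.1, 0.25, 0.3])
        with pytest.raises(TraceError, match="interval"):
            TagTrace(t=t, **self._chan(4))

    def test_channel_length_mismatch(self):
        t = np.arange(5) * 0.1
        bad = self._chan(5)
        bad["speed"] = np.zeros(4)
        with pytest.raises(TraceError, match="speed"):
            TagTrace(t=t, **bad)

    def test_nan_becomes_masked_gap(self):
        t = np.arange(50) * 0.1
        ch = self._chan(50)
        ch["speed"][10:12] = np.nan
        tr = TagTrace(t=t, **ch)
        assert not tr.valid[10] and tr.valid[9]

    def test_long_gap_splits_segments(self):
        t = np.arange(600) * 0.1
        ch = self._chan(600)
        ch["speed"][300:320] = np.nan   # 2 s gap
        tr = TagTrace(t=t, **ch)
        assert len(tr.segments()) == 2


class TestIntegrateSpeed:
    def test_linear_ramp_closed_form(self):
        # mean speed x duration, to machine precision
        t = np.arange(0, 10, 0.1)
        speed = 4.0 - (2.0 / 3.0) * np.clip(t - 2.0, 0.0, 3.0)
        d = integrate_speed(t, speed, 2.0, 5.0)
        assert d == pytest.approx(9.0, rel=1e-12)

    def test_constant(self):
        t = np.arange(0, 5, 0.1)
        assert integrate_speed(t, np.full_like(t, 2.0), 1.0, 3.0) == pytest.approx(4.0)

    def test_empty_window_rejected(self):
        t = np.arange(0, 5, 0.1)
        with pytest.raises(SegmentationError):
            integrate_speed(t, np.full_like(t, 2.0), 3.0, 3.0)


class TestDetection:
    def test_recovery_per_species(self, deployments, detected):
        for sp in SPECIES:
            truth = deployments[sp].truth
            events = detected[sp]
            matched = [match_truth(events, tr) for tr in truth]
            assert len(events) == len(truth), sp
            n_good = sum(
                1 for tr, m in zip(truth, matched)
                if m is not None and abs(m.T_MO - tr.T_MO) <= 0.2)
            assert n_good / len(truth) >= 0.95, sp

    def test_constant_speed_trace_empty(self, rng):
        n = 4000
        t = np.arange(n) * 0.1
        tr = TagTrace(t=t, depth=np.full(n, 40.0) + rng.normal(0, 0.05, n),
                      pitch=rng.normal(0, 0.01, n),
                      speed=np.maximum(2.0 + rng.normal(0, 0.02, n), 0),
                      gyro_y=rng.normal(0, 0.02, n))
        assert detect_lunges(tr) == []

    def test_rising_speed_rejected(self, rng):
        # speed only rises through the would-be engulfment window
        n = 2000
        t = np.arange(n) * 0.1
        speed = 1.0 + np.clip(t - 60.0, 0, 20) * 0.15
        tr = TagTrace(t=t, depth=np.full(n, 40.0), pitch=np.zeros(n),
                      speed=speed + rng.normal(0, 0.02, n),
                      gyro_y=rng.normal(0, 0.02, n))
        assert detect_lunges(tr) == []

    def test_event_ordering_invariants(self, detected):
        for events in detected.values():
            for ev in events:
                assert ev.T_fluke <= ev.T_accel < ev.T_max <= ev.T_MO
                assert ev.T_MO < ev.T_MC <= ev.T_min <= ev.T_MC + 5.0 + 1e-9
                assert ev.U_MO > ev.U_MC
                assert ev.dT_adjust >= 0 and ev.dT_decel > 0

    def test_phase_durations_recovered(self, deployments, detected):
        for sp in SPECIES:
            for tr in deployments[sp].truth:
                m = match_truth(detected[sp], tr)
                assert m is not None
                assert m.dT_decel == pytest.approx(tr.dT_decel, abs=0.3)
                assert m.dT_adjust == pytest.approx(tr.dT_adjust, abs=0.4)

    def test_distance_decel_matches_injected(self, deployments, detected):
        for sp in SPECIES:
            for tr in deployments[sp].truth:
                m = match_truth(detected[sp], tr)
                # boundary jitter of ~0.1 s dominates on short decelerations
                tol = max(0.15 * tr.distance_decel, 0.25 * tr.U_MO)
                assert m.distance_decel == pytest.approx(
                    tr.distance_decel, abs=tol), sp


class TestFinalOscillation:
    def test_period_recovered(self, deployments, detected):
        for sp in SPECIES:
            errs = []
            for tr in deployments[sp].truth:
                m = match_truth(detected[sp], tr)
                assert m.has_final_oscillation, sp
                errs.append(abs(m.dT_finOs - tr.dT_finOs))
            errs = np.sort(errs)
            assert np.median(errs) <= 0.2, sp
            assert errs[int(0.9 * (len(errs) - 1))] <= 0.35, sp

    def test_ratio_exceeds_one(self, detected):
        # the long oscillation outlasts the deceleration for every species
        for sp, events in detected.items():
            ratios = [ev.dT_finOs / ev.dT_decel for ev in events
                      if ev.dT_finOs is not None]
            assert np.median(ratios) > 1.0, sp

    def test_ratio_within_five_percent(self, deployments, detected):
        for sp in SPECIES:
            mult = default_profile(sp).finos_multiplier
            rec = []
            for tr in deployments[sp].truth:
                m = match_truth(detected[sp], tr)
                if m.dT_finOs is not None:
                    rec.append(m.dT_finOs / m.dT_decel)
            assert np.median(rec) == pytest.approx(mult, rel=0.08), sp

    def test_pure_noise_gyro_flagged_absent(self, deployments, rng):
        dep = deployments["humpback"]
        noisy = TagTrace(
            t=dep.trace.t.copy(), depth=dep.trace.depth.copy(),
            pitch=dep.trace.pitch.copy(), speed=dep.trace.speed.copy(),
            gyro_y=rng.normal(0, 0.02, len(dep.trace)))
        events = detect_lunges(noisy)
        assert events, "speed-based detection should still fire"
        assert all(not ev.has_final_oscillation for ev in events)


class TestTailbeats:
    def test_periods_positive_and_final_last(self, deployments, detected):
        dep = deployments["minke"]
        ev = match_truth(detected["minke"], dep.truth[0])
        rec = tailbeat_periods(dep.trace, ev)
        assert all(p > 0 for p in rec.periods)
        if ev.dT_finOs is not None:
            assert rec.final_oscillation_period == ev.dT_finOs


def _middle_pool(events):
    return [ev for ev in events if ev.position_in_dive == "middle"]


class TestSampling:
    def test_seeded_determinism(self, detected):
        events = detected["blue"]
        a = sample_middle_lunges(events, n=5, seed=3)
        b = sample_middle_lunges(events, n=5, seed=3)
        assert [e.T_MO for e in a] == [e.T_MO for e in b]
        assert len(a) == min(5, len(_middle_pool(events)))

    def test_small_pool_returned_whole(self, detected):
        events = detected["blue"]
        pool = _middle_pool(events)
        out = sample_middle_lunges(events, n=1000, seed=0)
        assert len(out) == len(pool)

    def test_solitary_never_sampled(self, detected):
        for events in detected.values():
            out = sample_middle_lunges(events, n=1000, seed=0)
            assert all(e.position_in_dive == "middle" for e in out)

    def test_empty_pool_warns(self):
        dep = simulate_deployment(default_profile("minke"), n_dives=1, seed=5)
        solo = [ev for ev in dep.truth][:1]
        solo[0].position_in_dive = "solitary"
        with pytest.warns(UserWarning):
            assert sample_middle_lunges(solo, n=5, seed=0) == []


class TestStability:
    def test_sd_decreases_with_size(self, detected):
        events = [ev for evs in detected.values() for ev in evs]
        table = sample_size_stability(events, [5, 10, 20], replicates=200, seed=0)
        sds = table[table.parameter == "U_MO"].sort_values("size")["sd"].to_numpy()
        assert sds[0] > sds[-1]

    def test_single_replicate_sd_absent(self, detected):
        table = sample_size_stability(detected["blue"], [5], replicates=1, seed=0)
        assert table["sd"].isna().all()

    def test_seeded_reproducibility(self, detected):
        t1 = sample_size_stability(detected["blue"], [5, 8], replicates=20, seed=4)
        t2 = sample_size_stability(detected["blue"], [5, 8], replicates=20, seed=4)
        assert t1.equals(t2)

    def test_oversized_request_capped_with_warning(self, detected):
        with pytest.warns(UserWarning, match="capped"):
            table = sample_size_stability(detected["blue"], [10_000],
                                          replicates=3, seed=0)
        assert (table["effective_size"] <= 10_000).all()


class TestDives:
    def test_dive_segmentation_counts(self, deployments):
        for sp, dep in deployments.items():
            dives = segment_dives(dep.trace)
            assert len(dives) == 3, sp

    def test_positions_assigned(self, detected):
        for events in detected.values():
            for ev in events:
                assert ev.position_in_dive in ("first", "middle", "last", "solitary")
                assert ev.dive_id >= 0


class TestLungeEventValidation:
    def test_ordering_violation_raises(self):
        with pytest.raises(SegmentationError, match="ordering"):
            LungeEvent(T_fluke=0, T_accel=5, T_max=4, T_MO=3, T_MC=8, T_min=9,
                       U_fluke=1, U_accel=1, U_max=4, U_MO=4, U_MC=2, U_min=1.5)

    def test_inclusion_rule(self):
        with pytest.raises(SegmentationError, match="inclusion"):
            LungeEvent(T_fluke=0, T_accel=1, T_max=8, T_MO=8, T_MC=10, T_min=11,
                       U_fluke=1, U_accel=1, U_max=4, U_MO=2, U_MC=3, U_min=1.5)

    def test_t_min_window(self):
        with pytest.raises(SegmentationError, match="5 s"):
            LungeEvent(T_fluke=0, T_accel=1, T_max=8, T_MO=8, T_MC=10, T_min=16,
                       U_fluke=1, U_accel=1, U_max=4, U_MO=4, U_MC=2, U_min=1.5)
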