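"""Track detection geometry, orientation, scoring and event calling."""

import numpy as np
import pytest

import forktrace as ft
from forktrace.tracks import DetectionParams, rescale

from conftest import make_profile, track_profile


def rdp_oracle(values, epsilon):
    """Plain recursive max-deviation simplification (independent oracle)."""
    x = np.arange(values.size, dtype=float)
    y = np.asarray(values, dtype=float)

    def recurse(i, j):
        if j - i < 2:
            return {i, j}
        dx, dy = x[j] - x[i], y[j] - y[i]
        norm = np.hypot(dx, dy)
        best, bestd = -1, -1.0
        for k in range(i + 1, j):
            d = abs(dy * (x[k] - x[i]) - dx * (y[k] - y[i])) / norm
            if d > bestd:
                best, bestd = k, d
        if bestd > epsilon:
            return recurse(i, best) | recurse(best, j)
        return {i, j}

    return np.array(sorted(recurse(0, values.size - 1)))


class TestSegmentProfile:
    def test_collinear_points_reduce_to_endpoints(self):
        bp = ft.segment_profile(np.linspace(0, 1, 50), 0.01)
        assert bp.tolist() == [0, 49]

    def test_triangle_keeps_apex(self):
        y = np.concatenate([np.linspace(0, 1, 11), np.linspace(1, 0, 11)[1:]])
        bp = ft.segment_profile(y, 0.05)
        assert bp.tolist() == [0, 10, 20]

    def test_fewer_than_three_points(self):
        assert ft.segment_profile(np.array([1.0, 2.0]), 0.1).tolist() == [0, 1]

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_recursive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        y = np.cumsum(rng.normal(0, 0.1, 50))
        eps = rng.uniform(0.02, 0.3)
        assert np.array_equal(ft.segment_profile(y, eps), rdp_oracle(y, eps))

    def test_max_deviation_bounded(self):
        rng = np.random.default_rng(99)
        y = np.cumsum(rng.normal(0, 0.2, 200))
        eps = 0.25
        bp = ft.segment_profile(y, eps)
        fit = np.interp(np.arange(y.size), bp, y[bp])
        # vertical deviation bounds perpendicular deviation from above
        assert np.max(np.abs(y - fit)) <= eps * np.hypot(1, 50)


class TestFilterReads:
    def test_flat_profile_rejected(self):
        p = make_profile(np.full(800, 0.5), raw_sd=0.0)
        assert ft.filter_reads([p], DetectionParams.for_tm()) == []

    def test_strong_cnn_profile_kept(self):
        rng = np.random.default_rng(0)
        values = np.clip(0.25 + 0.25 * np.sin(np.arange(2000) / 60), 0, 1)
        p = make_profile(values, spacing=10)  # 20 kb, sd ~0.18, amp 0.5
        assert ft.filter_reads([p], DetectionParams.for_cnn()) == [p]

    def test_short_read_rejected_regardless_of_signal(self):
        values = np.clip(0.25 + 0.3 * np.sin(np.arange(490) / 30), 0, 1)
        p = make_profile(values, spacing=10, raw_sd=0.45)  # 4.9 kb
        qc = []
        assert ft.filter_reads([p], DetectionParams.for_tm(), qc=qc) == []
        assert qc[0]["rejected"] == "short read"

    def test_tm_path_uses_raw_call_sd(self):
        values = np.full(800, 0.2)
        values[300:400] = 0.8
        p = make_profile(values, raw_sd=0.35)
        assert ft.filter_reads([p], DetectionParams.for_tm()) == [p]
        p_low = make_profile(values, raw_sd=0.2)
        assert ft.filter_reads([p_low], DetectionParams.for_tm()) == []


class TestDetectTracks:
    def test_minimal_amplitudes_detect_one_track(self):
        y = np.concatenate([np.full(20, 0.2), np.linspace(0.2, 0.65, 10),
                            np.full(10, 0.65), np.linspace(0.65, 0.38, 10),
                            np.full(20, 0.38)])
        tracks = ft.detect_tracks(make_profile(y), DetectionParams.for_tm())
        assert len(tracks) == 1  # rise 0.45 > 0.44, fall 0.27 > 0.26

    def test_insufficient_rise_detects_nothing(self):
        y = np.concatenate([np.full(20, 0.2), np.linspace(0.2, 0.63, 10),
                            np.linspace(0.63, 0.0, 20), np.full(20, 0.0)])
        tracks = ft.detect_tracks(make_profile(y), DetectionParams.for_tm())
        assert tracks == []  # rise 0.43 < 0.44 despite a huge fall

    def test_two_separated_pulses_give_two_tracks(self):
        p = np.concatenate([
            track_profile().content, track_profile().content])
        tracks = ft.detect_tracks(make_profile(p), DetectionParams.for_tm())
        assert len(tracks) == 2
        assert tracks[0].end <= tracks[1].start
        first = track_profile()
        single = ft.detect_tracks(first, DetectionParams.for_tm())
        assert len(single) == 1
        # extents agree with the constructed geometry: rise foot near the
        # end of the leading baseline, fall tail near the chase floor
        t = single[0]
        assert abs(t.start - 300) <= 30  # 30 baseline points at spacing 10
        assert t.min_p == pytest.approx(0.0, abs=0.05)
        assert t.min_f == pytest.approx(0.1, abs=0.08)

    def test_open_ended_track_only_with_flag(self):
        y = np.concatenate([np.full(30, 0.1), np.linspace(0.1, 0.7, 10),
                            np.full(40, 0.7)])
        p = make_profile(y)
        assert ft.detect_tracks(p, DetectionParams.for_tm()) == []
        tracks = ft.detect_tracks(p, DetectionParams.for_tm(),
                                  allow_open_end=True)
        assert len(tracks) == 1 and tracks[0].open_ended


def _track(slope_up, slope_down, min_p=0.0, min_f=0.1, rise=0.6, fall=0.55,
           resid=0.1, start=1000, end=16000):
    return ft.ReplicationTrack("chrT", start, end, None, slope_up, slope_down,
                               min_p, min_f, rise_amp=rise, fall_amp=fall,
                               resid_sd=resid)


class TestOrientation:
    def test_steep_rise_means_rightward(self):
        t = ft.orient_track(_track(0.9, -0.3), DetectionParams.for_tm())
        assert t.orientation == "right"

    def test_steep_fall_means_leftward(self):
        t = ft.orient_track(_track(0.3, -0.9, min_p=0.1, min_f=0.0),
                            DetectionParams.for_tm())
        assert t.orientation == "left"

    def test_level_rule_on_symmetric_slopes(self):
        t = ft.orient_track(_track(0.5, -0.5, min_p=0.02, min_f=0.12),
                            DetectionParams.for_tm())
        assert t.orientation == "right"

    def test_symmetric_slopes_equal_minima_unoriented(self):
        t = ft.orient_track(_track(0.5, -0.5, min_p=0.1, min_f=0.1),
                            DetectionParams.for_tm())
        assert t.orientation is None

    def test_contradictory_rules_abstain(self):
        # slope says left, level says right: a real fork satisfies both
        t = ft.orient_track(_track(0.3, -0.9, min_p=0.02, min_f=0.4),
                            DetectionParams.for_tm())
        assert t.orientation is None

    def test_elevated_pre_pulse_flank_abstains(self):
        t = ft.orient_track(_track(0.9, -0.3, min_p=0.3, min_f=0.45),
                            DetectionParams.for_tm())
        assert t.orientation is None

    def test_zero_denominator_slope_is_infinite_ratio(self):
        t = ft.orient_track(_track(0.9, 0.0), DetectionParams.for_tm())
        assert t.orientation == "right"


class TestScores:
    def test_ascore_is_signed_slope_ratio(self):
        t = _track(0.9, -0.3)
        ft.orient_track(t, DetectionParams.for_tm())
        a, j = ft.score_track(t)
        assert a == pytest.approx(3.0)

    def test_jscore_is_jump_over_noise(self):
        t = _track(0.9, -0.3, rise=0.5, resid=0.1)
        ft.orient_track(t, DetectionParams.for_tm())
        _, j = ft.score_track(t)
        assert j == pytest.approx(5.0)

    def test_mirrored_track_negates_ascore_keeps_jscore(self):
        t = _track(0.9, -0.3, rise=0.5, fall=0.5, resid=0.1)
        ft.orient_track(t, DetectionParams.for_tm())
        a1, j1 = ft.score_track(t)
        m = _track(0.3, -0.9, min_p=0.1, min_f=0.0, rise=0.5, fall=0.5,
                   resid=0.1)
        ft.orient_track(m, DetectionParams.for_tm())
        a2, j2 = ft.score_track(m)
        assert a2 == pytest.approx(-a1)
        assert j2 == pytest.approx(j1)

    def test_unoriented_track_cannot_be_scored(self):
        with pytest.raises(ValueError):
            ft.score_track(_track(0.5, -0.5, min_p=0.1, min_f=0.1))


def _scored(orientation, start, end, ascore=3.0, jscore=5.0):
    t = ft.ReplicationTrack("chrT", start, end, orientation, 1.0, -0.3,
                            0.0, 0.1, rise_amp=0.6, fall_amp=0.5, resid_sd=0.1)
    t.ascore = ascore if orientation == "right" else -ascore
    t.jscore = jscore
    return t


def _flat_profile(level=0.05, n=4000, spacing=10):
    return make_profile(np.full(n, level), spacing=spacing)


class TestCallEvents:
    def test_diverging_pair_yields_initiation_at_fork_start_midpoint(self):
        tracks = [_scored("left", 2000, 9000), _scored("right", 10200, 17000)]
        events = ft.call_events(tracks, DetectionParams.for_cnn(),
                                _flat_profile(0.10))
        assert len(events) == 1
        ev = events[0]
        assert ev.type == "initiation"
        assert ev.midpoint == (9000 + 10200) // 2  # gap 1.2 kb >= 1 kb

    def test_small_fork_gap_voids_initiation(self):
        tracks = [_scored("left", 2000, 9000), _scored("right", 9800, 17000)]
        events = ft.call_events(tracks, DetectionParams.for_cnn(),
                                _flat_profile(0.05))
        assert events == []  # 0.8 kb < 1 kb

    def test_high_plateau_voids_initiation(self):
        tracks = [_scored("left", 2000, 9000), _scored("right", 10500, 17000)]
        events = ft.call_events(tracks, DetectionParams.for_cnn(),
                                _flat_profile(0.20))
        assert events == []

    def test_converging_pair_yields_termination(self):
        tracks = [_scored("right", 2000, 9000), _scored("left", 9500, 17000)]
        events = ft.call_events(tracks, DetectionParams.for_cnn(),
                                _flat_profile(0.05))
        assert len(events) == 1
        assert events[0].type == "termination"
        assert events[0].midpoint == (2000 + 17000) // 2

    def test_high_fork_start_value_voids_termination(self):
        tracks = [_scored("right", 2000, 9000), _scored("left", 9500, 17000)]
        events = ft.call_events(tracks, DetectionParams.for_cnn(),
                                _flat_profile(0.20))
        assert events == []  # 0.2 > 0.14

    def test_low_score_track_voids_the_pair(self):
        tracks = [_scored("left", 2000, 9000, ascore=1.5),
                  _scored("right", 10500, 17000)]
        events = ft.call_events(tracks, DetectionParams.for_cnn(),
                                _flat_profile(0.05))
        assert events == []

    def test_intervening_track_voids_adjacency(self):
        mid = _scored("right", 9300, 9900, ascore=1.0)
        mid.orientation = None
        tracks = [_scored("left", 2000, 9000), mid,
                  _scored("right", 10500, 17000)]
        events = ft.call_events(tracks, DetectionParams.for_cnn(),
                                _flat_profile(0.05))
        assert events == []


class TestMergeMethodEvents:
    def _ev(self, mid, method, type_="initiation", read="r1"):
        return ft.ReplicationEvent(type_, "chrT", mid, mid - 2000, mid + 2000,
                                   read_id=read, method=method)

    def test_nearby_events_shared_and_pooled_once(self):
        pooled, shared = ft.merge_method_events(
            [self._ev(10_000, "CNN")], [self._ev(11_500, "TM")])
        assert shared == 1 and len(pooled) == 1
        assert pooled[0].shared

    def test_distant_events_both_retained(self):
        pooled, shared = ft.merge_method_events(
            [self._ev(10_000, "CNN")], [self._ev(12_500, "TM")])
        assert shared == 0 and len(pooled) == 2

    def test_empty_list_passthrough(self):
        pooled, shared = ft.merge_method_events([], [self._ev(5_000, "TM")])
        assert shared == 0 and len(pooled) == 1

    def test_greedy_matching_prefers_smallest_distance(self):
        cnn = [self._ev(10_000, "CNN"), self._ev(13_000, "CNN")]
        tm = [self._ev(11_000, "TM")]
        pooled, shared = ft.merge_method_events(cnn, tm)
        assert shared == 1 and len(pooled) == 2
        assert pooled[0].midpoint == 10_000 or pooled[1].midpoint == 10_000


class TestMirrorSymmetry:
    def test_mirrored_profile_gives_mirrored_same_type_events(self):
        """Left/right symmetry: mirroring mirrors tracks (flipping their
        orientation) and maps events to same-type events at mirrored
        midpoints — a diverging pair stays diverging under reflection."""
        left = track_profile(mirror=True)  # leftward-shaped track
        right = track_profile(mirror=False, start=left.positions[-1] + 1500)
        content = np.concatenate([left.content, np.full(150, 0.0),
                                  right.content])
        profile = make_profile(content, raw_sd=0.4)
        params = DetectionParams.for_tm()
        tracks, events = ft.analyze_profile(profile, params)
        n = profile.content.size
        mirrored = make_profile(content[::-1].copy(), raw_sd=0.4)
        mtracks, mevents = ft.analyze_profile(mirrored, params)
        assert len(tracks) == len(mtracks) == 2
        assert [t.orientation for t in tracks] == ["left", "right"]
        assert [t.orientation for t in mtracks] == ["left", "right"]
        assert len(events) == len(mevents) == 1
        assert events[0].type == mevents[0].type == "initiation"
        total_span = profile.positions[-1] + profile.positions[0]
        assert mevents[0].midpoint == pytest.approx(
            total_span - events[0].midpoint, abs=6 * 10)


class TestZeroFalsePositives:
    def test_native_reads_yield_no_tracks_or_events(self, matrices):
        """BrdU-free reads must produce neither tracks nor events."""
        cfg = ft.SimulationConfig(seed=17, read_length_range=(8_000, 25_000))
        rng = cfg.rng()
        profiles = []
        for k in range(40):
            n = int(rng.integers(*cfg.read_length_range))
            ref = ft.random_genome({"c": n}, seed=500 + k)["c"]
            read = ft.simulate_read(ref, 0.0, matrices, config=cfg, rng=rng)
            profiles.append(ft.profile_to_fraction(ft.call_tm(read, *matrices)))
        tracks, events = ft.detect_all(profiles, DetectionParams.for_tm())
        assert tracks == [] and events == []
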