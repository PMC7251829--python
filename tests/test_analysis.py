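"""Event clustering, randomization controls, annotation comparisons and the
motif scan."""

import numpy as np
import pytest

import forktrace as ft
from forktrace.analysis import dimension_class


def _events(positions, chrom="chrA", type_="initiation"):
    return [ft.ReplicationEvent(type_, chrom, int(p), int(p) - 1, int(p) + 1)
            for p in positions]


class TestClusterEvents:
    def test_strict_gap_rule(self):
        clusters = ft.cluster_events(_events([0, 1000, 3000]), mied=1500)
        dims = sorted(c.dimension for c in clusters)
        assert dims == [1, 2]
        big = max(clusters, key=lambda c: c.dimension)
        assert big.width == 1000

    def test_gap_exactly_at_mied_splits(self):
        clusters = ft.cluster_events(_events([0, 1500]), mied=1500)
        assert len(clusters) == 2

    def test_all_large_gaps_give_singletons(self):
        clusters = ft.cluster_events(_events(range(0, 50_000, 5_000)), 1500)
        assert all(c.dimension == 1 for c in clusters)

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_connected_components_oracle(self, seed):
        import networkx as nx

        rng = np.random.default_rng(seed)
        pos = np.sort(rng.integers(0, 200_000, 100))
        mied = float(rng.integers(500, 10_000))
        events = _events(pos)
        clusters = ft.cluster_events(events, mied)

        g = nx.Graph()
        g.add_nodes_from(range(len(pos)))
        for i in range(len(pos)):
            for j in range(i + 1, len(pos)):
                if abs(int(pos[i]) - int(pos[j])) < mied:
                    g.add_edge(i, j)
        oracle = sorted(
            tuple(sorted(int(pos[i]) for i in comp))
            for comp in nx.connected_components(g)
        )
        ours = sorted(tuple(sorted(e.midpoint for e in c.events))
                      for c in clusters)
        assert ours == oracle

    def test_membership_and_width_invariants(self):
        rng = np.random.default_rng(4)
        events = _events(np.sort(rng.integers(0, 100_000, 60)))
        for mied in (200, 1500, 8000):
            clusters = ft.cluster_events(events, mied)
            assert sum(c.dimension for c in clusters) == len(events)
            for c in clusters:
                assert c.width <= (c.dimension - 1) * mied


class TestClusterSweep:
    def test_limit_behaviours(self):
        rng = np.random.default_rng(5)
        events = _events(np.sort(rng.integers(0, 300_000, 80)))
        sweep = ft.cluster_sweep(events, [1e-9, 1500, 1e9])
        assert sweep.iloc[0]["n_singleton"] == 80  # mIED -> 0
        assert sweep.iloc[-1]["n_clusters"] == 1  # one cluster per chromosome
        assert (sweep["total_events"] == 80).all()
        assert (np.diff(sweep["n_singleton"]) <= 0).all()

    def test_clustered_events_show_a_plateau_absent_after_shuffling(self):
        rng = np.random.default_rng(6)
        centers = np.arange(10_000, 300_000, 30_000)
        clustered = _events(np.sort(np.concatenate(
            [c + rng.integers(-400, 400, 8) for c in centers])))
        grid = [1_000, 2_000, 3_000, 4_000, 5_000]
        sweep = ft.cluster_sweep(clustered, grid)
        assert sweep["n_clusters"].nunique() == 1  # stable plateau
        shuffled = ft.shuffle_events(clustered, {"chrA": 300_000}, seed=1)
        sweep_shuffled = ft.cluster_sweep(shuffled, grid)
        assert sweep_shuffled["n_clusters"].nunique() > 1


class TestShuffleEvents:
    def test_per_chromosome_counts_preserved(self):
        events = _events([100, 200, 300]) + _events([50, 60], chrom="chrB")
        out = ft.shuffle_events(events, {"chrA": 10_000, "chrB": 5_000}, seed=2)
        assert sum(e.chrom == "chrA" for e in out) == 3
        assert sum(e.chrom == "chrB" for e in out) == 2

    def test_seed_reproducibility(self):
        events = _events(range(0, 5_000, 500))
        a = ft.shuffle_events(events, {"chrA": 100_000}, seed=9)
        b = ft.shuffle_events(events, {"chrA": 100_000}, seed=9)
        assert [e.midpoint for e in a] == [e.midpoint for e in b]

    def test_nearest_origin_distance_matches_uniform_model(self):
        """The ECDF of shuffled-event distances to fixed origin centres must
        match the analytic ECDF of uniform positions (interval-union measure)."""
        length = 1_000_000
        centers = np.array([100_000, 400_000, 650_000, 910_000])
        events = _events(range(0, length, 2_000))

        def analytic(d):
            ivs = [(max(0, c - d), min(length, c + d)) for c in centers]
            ivs.sort()
            total, end = 0, -1
            for s, e in ivs:
                s = max(s, end)
                total += max(0, e - s)
                end = max(end, e)
            return total / length

        dists = []
        for seed in range(5):
            shuffled = ft.shuffle_events(events, {"chrA": length}, seed=seed)
            pts = [(e.chrom, e.midpoint) for e in shuffled]
            dists.append(ft.distance_to_nearest(
                pts, [(
                    "chrA", c - 1, c + 1) for c in centers]))
        dists = np.concatenate(dists)
        for d in (5_000, 20_000, 60_000):
            empirical = float(np.mean(dists <= d))
            se = np.sqrt(analytic(d) * (1 - analytic(d)) / dists.size)
            assert empirical == pytest.approx(analytic(d), abs=5 * se + 1e-3)


class TestDistances:
    def test_query_at_center_is_zero(self):
        d = ft.distance_to_nearest([("chrA", 5_000)], [("chrA", 4_000, 6_000)])
        assert d[0] == 0.0

    def test_midpoint_to_center_distance(self):
        d = ft.distance_to_nearest([("chrA", 7_000)], [("chrA", 4_000, 6_000)])
        assert d[0] == 2_000.0

    def test_fraction_within_two_kb_on_fixture(self):
        queries = [("chrA", p) for p in (1_000, 4_000, 10_500, 50_000)]
        anns = [("chrA", 0, 2_000), ("chrA", 10_000, 12_000)]
        d = ft.distance_to_nearest(queries, anns)
        assert float(np.mean(d <= 2_000)) == pytest.approx(0.5)

    def test_empty_annotations_rejected(self):
        with pytest.raises(ValueError):
            ft.distance_to_nearest([("chrA", 1)], [])

    def test_ecdf_is_monotone_and_terminates_at_one(self):
        x, y = ft.ecdf(np.array([3.0, 1.0, 2.0, 2.0]))
        assert (np.diff(x) >= 0).all()
        assert (np.diff(y) > 0).all()
        assert y[-1] == 1.0


class TestOverlapFraction:
    def test_identical_sets_fully_overlap(self):
        ivs = [("chrA", 1_000, 1_200), ("chrA", 9_000, 9_400)]
        assert ft.overlap_fraction(ivs, list(ivs)) == (1.0, 1.0)

    def test_resized_windows_just_missing(self):
        a = [("chrA", 10_000, 10_000)]
        b = [("chrA", 12_100, 12_100)]  # centres 2100 apart; resized to 2 kb
        assert ft.overlap_fraction(a, b, resize=2_000) == (0.0, 0.0)

    def test_asymmetric_fixture_matches_brute_force(self):
        rng = np.random.default_rng(8)
        a = [("chrA", int(s), int(s + rng.integers(100, 3_000)))
             for s in rng.integers(0, 80_000, 12)]
        b = [("chrA", int(s), int(s + rng.integers(100, 3_000)))
             for s in rng.integers(0, 80_000, 7)]
        fa, fb = ft.overlap_fraction(a, b, resize=2_000)

        def resized(iv):
            mid = (iv[1] + iv[2]) / 2
            return mid - 1_000, mid + 1_000

        def brute(q, s):
            hits = 0
            for iv in q:
                s1, e1 = resized(iv)
                if any(s1 < e2 and s2 < e1 for s2, e2 in map(resized, s)):
                    hits += 1
            return hits / len(q)

        assert fa == pytest.approx(brute(a, b))
        assert fb == pytest.approx(brute(b, a))


class TestMeanProfileAround:
    def test_constant_signal_gives_flat_profile(self):
        sig = ft.GenomeSignal("RFD", 100, {"chrA": np.full(500, 0.3)})
        offsets, prof = ft.mean_profile_around([("chrA", 25_000)], sig,
                                               flank=5_000)
        assert np.allclose(prof, 0.3)
        assert offsets[0] == -5_000 and offsets[-1] == 5_000

    def test_antisymmetric_signal_stays_antisymmetric(self):
        n = 500
        points = [("chrA", 20_000), ("chrA", 30_000)]
        arr = np.zeros(n)
        for _, p in points:
            arr += np.sign(np.arange(n) * 100 - p)
        sig = ft.GenomeSignal("RFD", 100, {"chrA": arr})
        offsets, prof = ft.mean_profile_around(points, sig, flank=3_000)
        assert np.allclose(prof + prof[::-1], 2 * prof[offsets == 0])

    def test_no_defined_flank_rejected(self):
        sig = ft.GenomeSignal("RFD", 100, {"chrA": np.full(100, np.nan)})
        with pytest.raises(ValueError):
            ft.mean_profile_around([("chrA", 5_000)], sig, flank=1_000)

    def test_rfd_shift_amplitude_of_step(self):
        arr = np.concatenate([np.full(250, -0.8), np.full(250, 0.8)])
        sig = ft.GenomeSignal("RFD", 100, {"chrA": arr})
        amp = ft.rfd_shift_amplitude([("chrA", 25_000)], sig, flank=5_000)
        assert amp == pytest.approx(1.6)


class TestAssignTiming:
    def _timing(self):
        return ft.GenomeSignal("timing", 1_000,
                               {"chrA": np.linspace(0, 1, 100)})

    def test_earliest_bin_is_zero(self):
        vals, excluded = ft.assign_timing(_events([500]), self._timing())
        assert vals[0] == 0.0 and not excluded

    def test_uniform_events_match_genome_density(self):
        events = _events(range(500, 100_000, 1_000))
        vals, _ = ft.assign_timing(events, self._timing())
        assert np.mean(vals) == pytest.approx(0.5, abs=0.01)

    def test_events_at_early_origins_are_left_shifted(self):
        early = _events([1_000, 2_500, 4_800])
        vals, _ = ft.assign_timing(early, self._timing())
        assert np.mean(vals) < 0.1

    def test_missing_timing_bins_excluded(self):
        sig = ft.GenomeSignal("timing", 1_000, {"chrA": np.array([0.1, np.nan])})
        vals, excluded = ft.assign_timing(_events([500, 1_500]), sig)
        assert vals.size == 1 and len(excluded) == 1


class TestDimensionClasses:
    def test_published_grouping(self):
        assert dimension_class(1) == "d=1"
        assert dimension_class(3) == "d=2-4"
        assert dimension_class(12) == "d=5-12"
        assert dimension_class(45) == "d>12"


class TestPwmScan:
    def _pwm(self):
        m = np.full((4, 4), 0.05)
        for i, base in enumerate("ACGT"):
            m[i, "ACGT".index(base)] = 0.85
        return ft.Pwm(m, threshold=0.8)

    def test_consensus_scores_maximally_at_origin(self):
        pwm = self._pwm()
        matches = ft.pwm_scan({"chrA": "ACGT"}, pwm)
        fwd = [m for m in matches if m[2] == "+"]
        assert fwd[0][1] == 0 and fwd[0][3] == pytest.approx(pwm.max_score)

    def test_reverse_strand_match_reported_in_forward_coordinates(self):
        pwm = self._pwm()
        seq = "GGGGACGTGGGG"
        rc_hit = "ACGT"  # revcomp(ACGT) == ACGT: palindromic consensus
        matches = ft.pwm_scan({"chrA": seq}, pwm)
        assert ("chrA", 4, "+") in {(c, p, s) for c, p, s, _ in matches}
        assert ("chrA", 4, "-") in {(c, p, s) for c, p, s, _ in matches}

    def test_threshold_one_keeps_only_consensus_score(self):
        pwm = ft.Pwm(self._pwm().matrix, threshold=1.0)
        matches = ft.pwm_scan({"chrA": "AACGTA"}, pwm)
        assert all(m[3] == pytest.approx(pwm.max_score) for m in matches)
        assert any(m[1] == 1 and m[2] == "+" for m in matches)

    def test_motif_longer_than_sequence_gives_nothing(self):
        assert ft.pwm_scan({"chrA": "AC"}, self._pwm()) == []

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_per_position_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), 300))
        m = rng.random((6, 4))
        pwm = ft.Pwm(m, threshold=0.85)
        ours = set(ft.pwm_scan({"c": seq}, pwm))

        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        brute = set()
        for strand in "+-":
            s = seq if strand == "+" else "".join(
                comp[b] for b in reversed(seq))
            for i in range(len(s) - 6 + 1):
                score = sum(m[k, "ACGT".index(s[i + k])] for k in range(6))
                if score >= 0.85 * pwm.max_score:
                    pos = i if strand == "+" else len(seq) - 6 - i
                    brute.add(("c", pos, strand, round(score, 9)))
        assert {(c, p, s, round(v, 9)) for c, p, s, v in ours} == brute


class TestMotifFraction:
    def test_matches_everywhere_give_fraction_one(self):
        matches = [("chrA", p, "+", 1.0) for p in range(0, 50_000, 100)]
        windows = [("chrA", w, w + 2_000) for w in range(0, 40_000, 10_000)]
        out = ft.motif_fraction(windows, matches, {"chrA": 50_000},
                                n_shuffles=50, seed=1)
        assert out["observed"] == 1.0

    def test_no_matches_give_zero(self):
        windows = [("chrA", 0, 2_000)]
        out = ft.motif_fraction(windows, [], {"chrA": 50_000},
                                n_shuffles=20, seed=1)
        assert out["observed"] == 0.0

    def test_planted_motif_windows_beat_shuffled_band(self):
        rng = np.random.default_rng(10)
        sites = np.sort(rng.choice(np.arange(0, 500_000, 1_000), 30,
                                   replace=False))
        matches = [("chrA", int(s), "+", 1.0) for s in sites]
        windows = [("chrA", int(s) - 1_000, int(s) + 1_000) for s in sites]
        out = ft.motif_fraction(windows, matches, {"chrA": 500_000},
                                n_shuffles=200, seed=2)
        assert out["observed"] == 1.0
        assert out["observed"] > out["null_band"][1]
        assert out["percentile"] == 1.0
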