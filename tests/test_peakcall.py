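"""Peak-calling cascade: score2, windows, winScore, summit, score1, KO
filter, indices, IDENT-score."""

import numpy as np
import pytest

from hybridm6a import peakcall, reference
from hybridm6a.peakcall import (
    M6ASite,
    PeakCallParams,
    detect_windows,
    fragment_coverage,
    gene_index,
    ident_score,
    ko_filter,
    sample_index,
    score1,
    score2_profile,
    summit_and_motif,
    winscore_filter,
)


class TestScore2:
    def test_uniform_coverage_gives_ones_everywhere(self):
        prof = score2_profile(np.full(100, 7.0), window=51)
        assert np.allclose(prof, 1.0)

    def test_hand_computed_center_value(self):
        prof = score2_profile(np.array([1, 1, 10, 1, 1.0]), gene_median=1.0,
                              window=3)
        assert prof[2] == pytest.approx((1 + 10 + 1) / 3)

    def test_scale_invariance(self, rng):
        cov = rng.poisson(20, 200).astype(float) + 1
        p1 = score2_profile(cov, window=51)
        p2 = score2_profile(2 * cov, window=51)
        assert np.allclose(p1, p2)

    def test_zero_median_gene_is_skipped(self):
        assert score2_profile(np.zeros(50), window=5) is None

    def test_edges_use_truncated_windows(self):
        prof = score2_profile(np.array([4, 2, 2, 2, 2.0]), gene_median=2.0,
                              window=3)
        assert prof[0] == pytest.approx((4 + 2) / 2 / 2)


class TestDetectWindows:
    def params(self, min_len=15):
        return PeakCallParams(min_window_len=min_len)

    def test_all_below_threshold_gives_empty(self):
        assert detect_windows(np.ones(100), self.params()) == []

    def test_toy_profile_single_window(self):
        wins = detect_windows(np.array([1, 5, 6, 5, 1.0]),
                              PeakCallParams(min_window_len=2))
        assert [(w.start, w.end) for w in wins] == [(1, 4)]

    def test_run_of_exactly_min_length_rejected(self):
        profile = np.ones(50)
        profile[10:25] = 5.0  # run of exactly 15
        assert detect_windows(profile, self.params(15)) == []
        profile[10:26] = 5.0  # 16 > 15
        assert len(detect_windows(profile, self.params(15))) == 1

    def test_equals_run_length_oracle_on_random_profiles(self, rng):
        params = PeakCallParams(min_window_len=3)
        for _ in range(300):
            prof = rng.uniform(0, 8, int(rng.integers(1, 200)))
            got = [(w.start, w.end) for w in detect_windows(prof, params)]
            want = reference.brute_force_windows(prof, 4.0, 3)
            assert got == want


class TestWinscoreFilter:
    def _win(self):
        from hybridm6a.peakcall import EnrichmentWindow
        return [EnrichmentWindow(gene="g", start=0, end=4)]

    def test_ratio_three_retained(self):
        ip = [np.full(4, 6.0)] * 3
        inp = [np.full(4, 2.0)] * 3
        kept = winscore_filter(self._win(), ip, inp, PeakCallParams())
        assert len(kept) == 1 and kept[0].winscores == [3.0, 3.0, 3.0]

    def test_any_replicate_below_threshold_rejects(self):
        ip = [np.full(4, 6.0), np.full(4, 6.0), np.full(4, 3.8)]
        inp = [np.full(4, 2.0)] * 3
        assert winscore_filter(self._win(), ip, inp, PeakCallParams()) == []

    def test_identical_tracks_rejected(self):
        ip = [np.full(4, 2.0)] * 3
        assert winscore_filter(self._win(), ip, ip, PeakCallParams()) == []

    def test_zero_input_score_treated_as_infinite(self):
        ip = [np.full(4, 6.0)]
        inp = [np.zeros(4)]
        kept = winscore_filter(self._win(), ip, inp, PeakCallParams())
        assert len(kept) == 1 and kept[0].winscores == [np.inf]


class TestSummitAndMotif:
    def _window(self, start, end):
        from hybridm6a.peakcall import EnrichmentWindow
        return EnrichmentWindow(gene="g", start=start, end=end)

    def test_peak_exactly_on_motif_a(self):
        seq = "UUUUUGGACUUUUUU"
        cov = np.zeros(len(seq))
        cov[7] = 10  # the A of GGACU
        summit, a, d = summit_and_motif(self._window(4, 12), cov, seq,
                                        PeakCallParams())
        assert (summit, a, d) == (7, 7, 0)

    def test_summit_one_nt_right_of_a(self):
        seq = "UUUUUGGACUUUUUU"
        cov = np.zeros(len(seq))
        cov[8] = 10
        summit, a, d = summit_and_motif(self._window(4, 12), cov, seq,
                                        PeakCallParams())
        assert (summit, a, d) == (8, 7, 1)

    def test_equidistant_motifs_pick_upstream(self):
        #      A at 6          A at 16, summit at 11 equidistant
        seq = "UUUUGGACUUUUUUGGACUUUU"
        cov = np.zeros(len(seq))
        cov[11] = 5
        summit, a, d = summit_and_motif(self._window(5, 18), cov, seq,
                                        PeakCallParams())
        assert summit == 11 and a == 6 and d == 5

    def test_tied_summit_takes_leftmost(self):
        seq = "UUUUGGACUUUUUU"
        cov = np.zeros(len(seq))
        cov[[6, 9]] = 7
        summit, _, _ = summit_and_motif(self._window(4, 12), cov, seq,
                                        PeakCallParams())
        assert summit == 6

    def test_no_motif_within_limit_returns_null_assignment(self):
        seq = "U" * 30
        cov = np.zeros(30)
        cov[15] = 4
        summit, a, d = summit_and_motif(
            self._window(10, 20), cov, seq,
            PeakCallParams(max_motif_distance=5))
        assert summit == 15 and a is None and d is None


class TestScore1:
    def test_hand_computed_ratio(self):
        assert score1(np.array([2, 8, 2.0]), np.array([1, 2, 1.0]), 1,
                      window=3) == pytest.approx(3.0)

    def test_identical_tracks_give_one(self, rng):
        cov = rng.poisson(30, 101).astype(float) + 1
        assert score1(cov, cov, 50, window=81) == pytest.approx(1.0)

    def test_zero_input_returns_none(self):
        assert score1(np.ones(10), np.zeros(10), 5, window=3) is None

    def test_exact_threshold_not_reported(self):
        # reporting rule is strict ">": a site at exactly the threshold fails
        params = PeakCallParams()
        assert not (3.0 > params.score1_threshold)


class TestKoFilter:
    def test_clear_wt_ko_separation_passes(self):
        ok, p = ko_filter([5, 5, 5], [1, 1, 1], [5, 5, 5], [1, 1, 1],
                          PeakCallParams())
        assert ok and p == 0.0

    def test_equal_groups_fail(self):
        ok, _ = ko_filter([4, 4, 4], [4, 4, 4], [4, 4, 4], [4, 4, 4],
                          PeakCallParams())
        assert not ok

    def test_ratio_rule_is_strict(self):
        # ratio 2 <= 3 fails regardless of the t-test
        ok, _ = ko_filter([4, 4, 4], [2, 2, 2], [4, 4, 4], [2, 2, 2],
                          PeakCallParams())
        assert not ok

    def test_other_species_ratio_can_rescue(self):
        ok, _ = ko_filter([4, 4.5, 4], [2, 2.2, 2], [9, 9.5, 9], [2, 2.1, 2],
                          PeakCallParams(),
                          wt_scores1_other=[9, 9.5, 9],
                          ko_scores1_other=[2, 2.1, 2])
        assert ok


class TestIndices:
    def test_sample_index_doubled_ip(self):
        ip = {"g": np.full(200, 4.0)}
        inp = {"g": np.full(200, 2.0)}
        sites = [M6ASite(gene="g", summit=100, motif_a_position=100,
                         motif_distance=0, score1=2, score2_at_summit=1,
                         window=(60, 140))]
        assert sample_index(ip, inp, sites, window=81) == pytest.approx(2.0)

    def test_sample_index_two_site_pooling(self):
        # window sums IP {10, 30}, input {10, 10} -> SI = 40/20 = 2
        ip = {"g": np.zeros(400)}
        inp = {"g": np.zeros(400)}
        ip["g"][60:141] = 10 / 81
        ip["g"][260:341] = 30 / 81
        inp["g"][60:141] = 10 / 81
        inp["g"][260:341] = 10 / 81
        sites = [
            M6ASite(gene="g", summit=100, motif_a_position=100,
                    motif_distance=0, score1=1, score2_at_summit=1,
                    window=(60, 141)),
            M6ASite(gene="g", summit=300, motif_a_position=300,
                    motif_distance=0, score1=3, score2_at_summit=1,
                    window=(260, 341)),
        ]
        assert sample_index(ip, inp, sites, window=81) == pytest.approx(2.0)

    def test_empty_site_list_is_an_error(self):
        with pytest.raises(ValueError):
            sample_index({}, {}, [])

    def test_gene_index_values(self):
        assert gene_index(100, 100) == pytest.approx(1.0)
        assert gene_index(300, 100) == pytest.approx(3.0)
        assert gene_index(10, 0) is None

    def test_gene_index_library_normalization(self):
        assert gene_index(100, 100, ip_libsize=2.0,
                          input_libsize=1.0) == pytest.approx(0.5)


class TestFragmentsAndIdent:
    def test_pileup_matches_per_base_counting(self, rng):
        frags = [(int(s), int(s + rng.integers(5, 40)))
                 for s in rng.integers(0, 160, 60)]
        got = fragment_coverage(frags, 200)
        want = reference.brute_force_pileup(frags, 200)
        assert np.array_equal(got, want)

    def test_no_variants_equals_plain_score1_on_covering_fragments(self):
        ip = [(0, 100), (20, 120), (40, 140), (150, 190)]
        inp = [(0, 100), (30, 130)]
        got = ident_score(ip, inp, 60, [], 200, window=81)
        ip_cov = fragment_coverage([f for f in ip if f[0] <= 60 < f[1]], 200)
        inp_cov = fragment_coverage([f for f in inp if f[0] <= 60 < f[1]], 200)
        assert got == pytest.approx(score1(ip_cov, inp_cov, 60, window=81))

    def test_all_fragments_variant_tainted_gives_missing(self):
        ip = [(0, 100), (20, 120)]
        assert ident_score(ip, ip, 60, [50], 200) is None

    def test_variant_excludes_only_overlapping_fragments(self):
        # one IP fragment excluded by an upstream variant; the ratio equals
        # a brute-force pileup of the surviving fragments
        ip = [(0, 100), (55, 155), (58, 130), (59, 161)]
        inp = [(10, 110), (50, 150)]
        variant = [30]  # excludes IP (0, 100) and input (10, 110)
        got = ident_score(ip, inp, 60, variant, 200, window=81)
        keep = [(55, 155), (58, 130), (59, 161)]
        ip_cov = reference.brute_force_pileup(keep, 200)
        inp_cov = reference.brute_force_pileup([(50, 150)], 200)
        want = score1(ip_cov, inp_cov, 60, window=81)
        assert got == pytest.approx(want)


class TestReportedSitesInvariant:
    def test_every_reported_site_passes_declared_thresholds(self, default_run):
        params = PeakCallParams()
        # score1 is recomputed per background; every called site must exceed
        # the reporting threshold in at least one background
        df = default_run.sites
        best = df[[c for c in df.columns if c.startswith("score1_")]].max(axis=1)
        assert (best > params.score1_threshold).all()
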