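import numpy as np
import pytest

from backgen.composition import gc_bin, gc_window_profile
from backgen.match import (
    EmptyPoolError,
    GCBinMatcher,
    MatchConfig,
    WindowedGCMatcher,
    build_gc_index,
    generate_matched_set,
    match_gc_bin,
    match_windowed,
    windowed_acceptance_band,
)
from backgen.seqio import SequenceRecord
from backgen.synthetic import pool_spanning_gc_bins, random_foregrounds


def rec(residues, ident="r"):
    return SequenceRecord(ident, "", residues)


class TestGCBinIndex:
    def test_bin_assignment(self):
        pool = [rec("AATT", "s1"), rec("ACGT", "s2"), rec("GGCC", "s3")]
        index = build_gc_index(pool)
        assert {b: [r.identifier for r in v] for b, v in index.bins.items()} == {
            0: ["s1"],
            50: ["s2"],
            100: ["s3"],
        }
        assert index.pool_size == 3

    def test_floor_rule_on_fractional_gc(self):
        # 101 strong residues out of 200 -> 0.505 -> bin 50
        index = build_gc_index([rec("G" * 101 + "A" * 99)])
        assert list(index.bins) == [50]

    def test_identical_pool_shares_one_bin(self):
        index = build_gc_index([rec("ACGT", f"s{i}") for i in range(5)])
        assert set(index.bins) == {50}
        assert len(index.bins[50]) == 5

    def test_empty_pool_rejected(self):
        with pytest.raises(EmptyPoolError):
            build_gc_index([])


class TestMatchGCBin:
    def test_forced_choice_is_distance_zero(self, rng):
        index = build_gc_index([rec("ACGT", "only")])
        res = match_gc_bin(rec("GTAC", "fg"), index, MatchConfig(), rng)
        assert res.accepted and res.bin_distance == 0
        assert res.background.identifier == "only"

    def test_ring_search_reports_distance(self, rng):
        # foreground in bin 50; nearest occupied bin is 52
        pool = [rec("G" * 52 + "A" * 48, "b52")]
        index = build_gc_index(pool)
        res = match_gc_bin(rec("G" * 50 + "A" * 50, "fg"), index, MatchConfig(), rng)
        assert res.accepted
        assert res.bin_distance == 2
        assert res.background.identifier == "b52"

    def test_without_replacement_exhausts_pool(self, rng):
        index = build_gc_index([rec("ACGT", "only")])
        cfg = MatchConfig(with_replacement=False, max_bin_distance=0)
        first = match_gc_bin(rec("GTAC", "f1"), index, cfg, rng)
        second = match_gc_bin(rec("CATG", "f2"), index, cfg, rng)
        assert first.accepted
        assert not second.accepted and second.background is None

    def test_max_bin_distance_zero_disables_fallback(self, rng):
        index = build_gc_index([rec("GGCC", "hi")])  # bin 100
        cfg = MatchConfig(max_bin_distance=0)
        res = match_gc_bin(rec("AATT", "fg"), index, cfg, rng)  # bin 0
        assert not res.accepted

    def test_distance_zero_matches_agree_on_bin(self, rng):
        """Saturated pool: every foreground finds its exact 1%-GC bin."""
        pool = pool_spanning_gc_bins(per_bin=3, length=100, seed=1)
        index = build_gc_index(pool)
        foregrounds = random_foregrounds(200, (80, 120), gc=0.45, seed=2)
        cfg = MatchConfig()
        for fg in foregrounds:
            res = match_gc_bin(fg, index, cfg, rng)
            assert res.bin_distance == 0
            assert gc_bin(res.background) == gc_bin(fg)


class TestMatchWindowed:
    def _fg_with_windows_40_50_60(self):
        # three disjoint 10 bp windows with 4, 5 and 6 strong residues
        return rec("GGGGAAAAAA" + "GGGGGAAAAA" + "GGGGGGAAAA", "fg")

    def test_band_from_mean_and_population_sd(self):
        fg = self._fg_with_windows_40_50_60()
        cfg = MatchConfig(window_size=10, step=10)
        lo, hi = windowed_acceptance_band(fg, cfg)
        assert lo == pytest.approx(50 - 2.6 * 8.16496580927726, abs=1e-9)
        assert hi == pytest.approx(50 + 2.6 * 8.16496580927726, abs=1e-9)

    def test_candidate_window_containment_decides_acceptance(self, rng):
        fg = self._fg_with_windows_40_50_60()
        cfg = MatchConfig(window_size=10, step=10)
        inside = rec("GGGAAAAAAA" + "GGGGGGGAAA", "in")  # windows 30, 70
        outside = rec("GGAAAAAAAA" + "GGGGGAAAAA", "out")  # windows 20, 50
        res = match_windowed(fg, [inside], cfg, rng)
        assert res.accepted
        res = match_windowed(fg, [outside], cfg, rng)
        assert not res.accepted

    def test_degenerate_band_requires_exact_window_match(self, rng):
        fg = rec("GCGCGCGCGC" * 2, "fg")  # every window exactly 100 %GC
        cfg = MatchConfig(window_size=10, step=10)
        exact = rec("GGGGGGGGGG" * 2, "exact")
        off = rec("GGGGGGGGGA" * 2, "off")  # windows at 90
        assert match_windowed(fg, [exact], cfg, rng).accepted
        assert not match_windowed(fg, [off], cfg, rng).accepted

    def test_self_match_always_accepted(self, rng):
        fg = rec("ACGTACGTACGTACGTACGT", "fg")
        res = match_windowed(fg, [fg], MatchConfig(window_size=5, step=5), rng)
        assert res.accepted and res.bin_distance == 0

    def test_acceptance_monotone_in_sd_multiplier(self, rng):
        """The accepted candidate set can only grow with m."""
        foregrounds = random_foregrounds(
            10, (100, 200), gc=0.5, gc_gradient=(0.3, 0.7), seed=7
        )
        pool = random_foregrounds(40, (100, 200), gc=0.5, seed=8, prefix="bg")
        for fg in foregrounds:
            previous = set()
            for m in (0.5, 1.0, 2.6, 5.0):
                cfg = MatchConfig(sd_multiplier=m, window_size=50, step=25)
                lo, hi = windowed_acceptance_band(fg, cfg)
                accepted = {
                    c.identifier
                    for c in pool
                    if all(
                        lo <= v <= hi
                        for v in gc_window_profile(c, 50, 25).values
                    )
                }
                assert previous <= accepted
                previous = accepted
                # the matcher draws from exactly this set
                res = match_windowed(fg, pool, cfg, rng)
                if accepted:
                    assert res.accepted and res.background.identifier in accepted
                else:
                    assert not res.accepted


class TestGenerateMatchedSet:
    def test_all_matchable_yields_one_background_per_foreground(self):
        pool = pool_spanning_gc_bins(per_bin=2, length=100, seed=3)
        fgs = random_foregrounds(30, (90, 110), gc=0.5, seed=4)
        backgrounds, unmatched = generate_matched_set(
            fgs, pool, MatchConfig(seed=0), mode="global"
        )
        assert len(backgrounds) == len(fgs)
        assert unmatched == []

    def test_same_seed_identical_selection(self):
        pool = pool_spanning_gc_bins(per_bin=2, length=100, seed=3)
        fgs = random_foregrounds(20, (90, 110), gc=0.5, seed=4)
        cfg = MatchConfig(seed=42)
        a, _ = generate_matched_set(fgs, pool, cfg, mode="global")
        b, _ = generate_matched_set(fgs, pool, cfg, mode="global")
        assert [(r.identifier, r.residues) for r in a] == [
            (r.identifier, r.residues) for r in b
        ]

    def test_disjoint_pool_with_no_fallback_reports_all_unmatched(self):
        pool = [rec("GGCC", "hi")]
        fgs = [rec("AATT", f"f{i}") for i in range(3)]
        backgrounds, unmatched = generate_matched_set(
            fgs, pool, MatchConfig(max_bin_distance=0, seed=0), mode="global"
        )
        assert backgrounds == []
        assert unmatched == ["f0", "f1", "f2"]

    def test_without_replacement_never_reuses_a_pool_record(self):
        pool = pool_spanning_gc_bins(per_bin=5, length=100, seed=5)
        fgs = random_foregrounds(80, (100, 100), gc=0.5, seed=6)
        backgrounds, _ = generate_matched_set(
            fgs, pool, MatchConfig(with_replacement=False, seed=1), mode="global"
        )
        ids = [r.identifier for r in backgrounds]
        assert len(ids) == len(set(ids))

    def test_empty_pool_is_an_error(self):
        with pytest.raises(EmptyPoolError):
            generate_matched_set([rec("ACGT")], [], MatchConfig(), mode="global")


class TestEstimators:
    def test_gc_bin_matcher_fit_transform(self):
        pool = pool_spanning_gc_bins(per_bin=2, length=100, seed=9)
        fgs = random_foregrounds(25, (90, 110), gc=0.5, seed=10)
        est = GCBinMatcher(random_state=0).fit(pool)
        out = est.transform(fgs)
        assert len(out) == len(fgs)
        assert est.unmatched_ids_ == []
        assert all(r.accepted and r.bin_distance == 0 for r in est.results_)

    def test_windowed_matcher_self_pool(self):
        fgs = random_foregrounds(5, (120, 120), gc=0.5, seed=11)
        est = WindowedGCMatcher(window_size=40, step=20, random_state=0).fit(fgs)
        out = est.transform(fgs)
        assert len(out) == len(fgs)  # each foreground matches at least itself

    def test_transform_before_fit_raises(self):
        with pytest.raises(RuntimeError):
            GCBinMatcher().transform([rec("ACGT")])
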