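"""Candidate calling arithmetic, local background, tier filtering, and the
AID-independent path, on constructed fixtures and the small simulation."""
import numpy as np
import pytest

from dsbmap.intervals import ChromSizes, GenomeInterval
from dsbmap.peakcalling import (
    EXP1_TIERS,
    EXP2_TIERS,
    CandidatePeak,
    FilterTier,
    apply_tier_filter,
    call_aid_independent,
    call_candidates,
    local_background,
    read_tier_table,
    tier_profile,
    write_tier_table,
)
from dsbmap.preprocess import TagLibrary
from dsbmap.simulate import evaluate_recovery

SIZES = ChromSizes({"chr1": 100_000})


def _lib(plus=(), minus=(), fragment_length=0, chrom="chr1"):
    return TagLibrary(
        tags={
            chrom: {
                "+": np.array(plus, dtype=np.int64),
                "-": np.array(minus, dtype=np.int64),
            }
        },
        fragment_length=fragment_length,
    )


def _uniform_control(n=200, spacing=500, offset=250):
    return _lib(plus=[offset + i * spacing for i in range(n)])


class TestCallCandidates:
    def test_fold_against_scaled_control(self):
        # 40 WT tags within 300 bp; control uniform at 1 tag per 500-bp
        # window and equal library size -> fold = 40 / (1 + 0.5)
        site = [5000 + 7 * i for i in range(40)]
        background = [20_000 + 500 * i for i in range(160)]
        wt = _lib(plus=site + background)
        cands = call_candidates(wt, _uniform_control(), SIZES)
        assert len(cands) == 1
        assert cands[0].wt_tags == 40
        assert cands[0].fold_vs_control == pytest.approx(40 / 1.5, rel=1e-6)
        assert abs(cands[0].center - 5150) <= 250

    def test_wt_as_its_own_control_yields_nothing(self):
        wt = _uniform_control(n=200)
        wt.fragment_length = 0
        assert call_candidates(wt, wt, SIZES) == []

    def test_two_sites_two_nonoverlapping_candidates(self):
        site1 = [5000 + 5 * i for i in range(30)]
        site2 = [15_000 + 5 * i for i in range(30)]
        wt = _lib(plus=site1 + site2)
        cands = call_candidates(wt, _uniform_control(), SIZES)
        assert len(cands) == 2
        assert abs(cands[0].center - 5075) <= 50
        assert abs(cands[1].center - 15_075) <= 50
        assert not cands[0].window.overlaps(cands[1].window)

    def test_missing_control_directs_to_independent_path(self):
        with pytest.raises(ValueError, match="call_aid_independent"):
            call_candidates(_lib(plus=[1]), None, SIZES)

    def test_empty_wt_library_empty_result(self):
        assert call_candidates(_lib(), _uniform_control(), SIZES) == []


class TestLocalBackground:
    def test_isolated_peak_ratio(self):
        # 20 tags in the window, 0 outside: (20/500) / ((0+0.5)/9500) = 760
        wt = _lib(plus=[50_000] * 20)
        peak = CandidatePeak(
            window=GenomeInterval("chr1", 49_750, 50_250),
            center=50_000, wt_tags=20, control_tags_norm=0.0,
            fold_vs_control=np.inf, local_background_ratio=np.nan,
        )
        assert local_background(peak, wt, SIZES) == pytest.approx(760.0)

    def test_uniform_density_near_one(self):
        wt = _lib(plus=list(range(45_000, 55_000, 25)))  # 1 tag per 25 bp
        peak = CandidatePeak(
            window=GenomeInterval("chr1", 49_750, 50_250),
            center=50_000, wt_tags=20, control_tags_norm=0.0,
            fold_vs_control=np.inf, local_background_ratio=np.nan,
        )
        assert local_background(peak, wt, SIZES) == pytest.approx(1.0, rel=0.1)

    def test_clamped_span_renormalizes_denominator(self):
        # window [0, 500): span region [0, 5250), outside length 4750
        wt = _lib(plus=[100] * 20)
        peak = CandidatePeak(
            window=GenomeInterval("chr1", 0, 500),
            center=250, wt_tags=20, control_tags_norm=0.0,
            fold_vs_control=np.inf, local_background_ratio=np.nan,
        )
        expected = (20 / 500) / (0.5 / 4750)
        assert local_background(peak, wt, SIZES) == pytest.approx(expected)


def _cand(tags, ratio, background):
    return CandidatePeak(
        window=GenomeInterval("chr1", 10_000, 10_500),
        center=10_250,
        wt_tags=tags,
        control_tags_norm=1.0,
        fold_vs_control=ratio,
        local_background_ratio=background,
    )


class TestTierFilter:
    wt = _lib(fragment_length=0)

    def _survives(self, tiers, tags, ratio, background):
        sites = apply_tier_filter([_cand(tags, ratio, background)], tiers, self.wt, SIZES)
        return len(sites) == 1

    @pytest.mark.parametrize(
        "tags,ratio,background,expected",
        [
            (18, 2.0, 3.0, True),    # top tier is an OR rule
            (18, 1.0, 6.0, True),
            (18, 1.9, 5.9, False),
            (16, 2.6, 3.9, False),   # AND tier fails background >= 4.0
            (16, 2.5, 4.0, True),
            (14, 3.6, 4.0, True),
            (14, 3.5, 50.0, False),
            (13, 9.0, 8.0, True),
            (13, 8.9, 50.0, False),
            (12, 50.0, 50.0, False),  # below the lowest tier
        ],
    )
    def test_exp1_printed_thresholds(self, tags, ratio, background, expected):
        assert self._survives(EXP1_TIERS, tags, ratio, background) is expected

    @pytest.mark.parametrize(
        "tags,ratio,background,expected",
        [
            (53, 2.2, 0.0, True),    # >52 is an OR rule
            (53, 0.0, 6.0, True),
            (52, 2.2, 5.9, False),   # 22-52 requires both
            (52, 2.2, 6.0, True),
            (22, 2.2, 6.0, True),
            (21, 4.0, 10.0, True),
            (21, 2.2, 20.0, False),
            (19, 4.0, 10.0, True),
            (18, 50.0, 50.0, False),  # below the lowest tier
        ],
    )
    def test_exp2_printed_thresholds(self, tags, ratio, background, expected):
        assert self._survives(EXP2_TIERS, tags, ratio, background) is expected

    def test_survivors_are_extended_aid_dependent_sites(self):
        sites = apply_tier_filter([_cand(20, 5.0, 10.0)], EXP1_TIERS, self.wt, SIZES)
        assert sites[0].aid_dependent and not sites[0].aid_independent
        assert sites[0].extended.length == 2000
        assert sites[0].extended.start == 10_250 - 1000

    def test_overlapping_tiers_rejected(self):
        tiers = (FilterTier(10, 20, 2.0, 2.0), FilterTier(15, None, 2.0, 2.0))
        with pytest.raises(ValueError, match="overlap"):
            apply_tier_filter([_cand(18, 5, 5)], tiers, self.wt, SIZES)

    def test_tier_table_round_trip(self, tmp_path):
        path = tmp_path / "tiers.tsv"
        write_tier_table(EXP1_TIERS, path)
        assert read_tier_table(path) == EXP1_TIERS
        assert tier_profile(path) == EXP1_TIERS
        assert tier_profile("exp2") == EXP2_TIERS


class TestThresholdMonotonicity:
    def test_raising_fold_threshold_never_adds_sites(self, small_study):
        s = small_study
        counts = [
            len(call_candidates(s.wt, s.control, s.chrom_sizes, fold_threshold=f))
            for f in (2.0, 4.0, 8.0, 16.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_scaling_tier_thresholds_never_adds_sites(self, small_study):
        s = small_study
        cands = call_candidates(s.wt, s.control, s.chrom_sizes)
        counts = []
        for factor in (1.0, 2.0, 4.0):
            tiers = tuple(
                FilterTier(
                    t.min_tags, t.max_tags,
                    t.ratio_threshold * factor,
                    t.background_threshold * factor,
                    t.combine,
                )
                for t in EXP1_TIERS
            )
            counts.append(len(apply_tier_filter(cands, tiers, s.wt, s.chrom_sizes)))
        assert counts == sorted(counts, reverse=True)


class TestCalledSiteProperties:
    def test_called_windows_never_overlap(self, study):
        for sites in (study.dep, study.indep):
            by_chrom = {}
            for site in sites:
                by_chrom.setdefault(site.chrom, []).append(site.called_window)
            for windows in by_chrom.values():
                windows.sort(key=lambda w: w.start)
                for a, b in zip(windows, windows[1:]):
                    assert a.end <= b.start

    def test_planted_independent_sites_never_called_dependent(self, study):
        recovery = evaluate_recovery(study.dep, study.truth)
        if len(recovery.confusion):
            assert "aid_independent" not in recovery.confusion.index

    def test_independent_path_recovers_planted_independent_sites(self, study):
        recovery = evaluate_recovery(study.indep, study.truth)
        assert recovery.recall_by_type["aid_independent"] >= 0.9
        # and the dependent WT-only sites are excluded by the 1.4 ratio cap
        if len(recovery.confusion):
            assert "aid_dep_two_ended" not in recovery.confusion.index


class TestAidIndependent:
    def test_uniform_libraries_yield_nothing(self):
        wt = _uniform_control(n=150)
        wt.fragment_length = 0
        control = _uniform_control(n=150, offset=300)
        control.fragment_length = 0
        assert call_aid_independent(wt, control, SIZES) == []

    def test_requires_control(self):
        with pytest.raises(ValueError, match="control"):
            call_aid_independent(_lib(plus=[1]), None, SIZES)
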