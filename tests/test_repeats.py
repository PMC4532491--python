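"""WGCW motif scanning, TRF-style tandem-repeat detection against the
brute-force oracle, repeat classification, and per-site summaries."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dsbmap.intervals import ChromSizes, GenomeInterval
from dsbmap.repeats import (
    TandemRepeat,
    accumulation_curve,
    ca_step_fraction,
    classify_repeat,
    count_wgcw,
    find_tandem_repeats,
    genome_background,
    summarize_interval,
)
from tests.oracles import brute_force_repeats, regex_wgcw_count

COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(COMP)[::-1]


class TestCountWgcw:
    @pytest.mark.parametrize(
        "seq,count,positions",
        [
            ("AGCAAGCAAGCA", 3, [0, 4, 8]),
            ("CCCCGGGG", 0, []),
            ("TGCT", 1, [0]),
            ("NGCA", 0, []),
            ("", 0, []),
        ],
    )
    def test_examples(self, seq, count, positions):
        n, pos = count_wgcw(seq)
        assert n == count
        assert list(pos) == positions

    def test_pentamer_array_density_matches_switch_region_scale(self):
        # 20 tandem CAGCA copies = 100 bp with 20 motifs: the same order as
        # the IgH donor switch region's 19 WGCW per 100 bp
        seq = "CAGCA" * 20
        n, _ = count_wgcw(seq)
        assert n == 20
        assert 100.0 * n / len(seq) == 20.0

    def test_matches_regex_oracle_on_random_sequences(self):
        rng = np.random.default_rng(0)
        for _ in range(500):
            seq = "".join(rng.choice(list("ACGTN"), 200, p=[0.3, 0.2, 0.2, 0.25, 0.05]))
            assert count_wgcw(seq)[0] == regex_wgcw_count(seq)

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(st.text(alphabet="ACGTN", max_size=60))
    def test_self_complementary_pattern(self, seq):
        # WGCW is its own reverse complement, so both strands agree
        assert count_wgcw(seq)[0] == count_wgcw(revcomp(seq))[0]


class TestFindTandemRepeats:
    def test_ca_array_hand_score(self):
        reps = find_tandem_repeats("CA" * 30, min_score=60)
        assert len(reps) == 1
        rep = reps[0]
        assert (rep.period, rep.start, rep.end, rep.score) == (2, 0, 60, 116)
        assert rep.ca_fraction == 1.0
        assert rep.consensus in ("CA", "AC")
        assert rep.copy_number == 30

    def test_pentamer_array_hand_score(self):
        reps = find_tandem_repeats("CAGCA" * 100, min_score=100)
        assert len(reps) == 1
        rep = reps[0]
        assert (rep.period, rep.start, rep.end, rep.score) == (5, 0, 500, 990)
        assert rep.wgcw_density == pytest.approx(20.0)

    def test_pure_array_score_formula(self):
        # exactly one repeat with score 2 * (L - p) for a pure (M)k array
        for motif, copies in [("CAT", 40), ("AGGCT", 30), ("T", 80)]:
            seq = motif * copies
            reps = find_tandem_repeats(seq, min_score=20)
            assert len(reps) == 1
            assert reps[0].score == 2 * (len(seq) - reps[0].period)

    def test_random_sequence_no_call(self):
        rng = np.random.default_rng(42)
        seq = "".join(rng.choice(list("ACGT"), 60))
        assert find_tandem_repeats(seq, min_score=60) == []

    def test_short_sequence_no_error(self):
        assert find_tandem_repeats("A", min_score=10) == []

    def test_min_score_must_be_positive(self):
        with pytest.raises(ValueError):
            find_tandem_repeats("ACGT", min_score=0)

    def test_matches_bruteforce_oracle_on_short_sequences(self):
        rng = np.random.default_rng(7)
        for _ in range(300):
            length = int(rng.integers(2, 31))
            seq = "".join(
                rng.choice(list("ACGTN"), length, p=[0.24, 0.24, 0.24, 0.24, 0.04])
            )
            got = sorted(
                (r.period, r.start, r.end, r.score)
                for r in find_tandem_repeats(seq, min_score=8)
            )
            assert got == brute_force_repeats(seq, min_score=8), seq

    def test_mutated_array_still_one_call_with_mismatch_penalty(self):
        seq = list("CAGCA" * 100)
        seq[250] = "T" if seq[250] != "T" else "G"
        reps = find_tandem_repeats("".join(seq), min_score=100)
        assert len(reps) == 1
        # one substitution converts two +2 positions into two -7
        assert reps[0].score == 990 - 18


class TestClassifyRepeat:
    def _rep(self, ca, density):
        return TandemRepeat(
            start=0, end=100, period=2, consensus="CA", score=100,
            ca_fraction=ca, wgcw_count=int(density), wgcw_density=density,
        )

    def test_pure_ca_is_ca(self):
        assert classify_repeat(self._rep(1.0, 0.0)) == "CA"

    def test_wgcw_dense_is_wgcw(self):
        assert classify_repeat(self._rep(0.6, 20.0)) == "WGCW"

    def test_att_array_is_other(self):
        reps = find_tandem_repeats("ATT" * 30, min_score=20)
        assert reps[0].repeat_class == "OTHER"

    def test_ca_precedence_no_repeat_is_both(self):
        # >= 90% CA steps wins even at high WGCW density
        assert classify_repeat(self._rep(0.95, 5.0)) == "CA"

    def test_boundary_thresholds(self):
        assert classify_repeat(self._rep(0.90, 0.0)) == "CA"
        assert classify_repeat(self._rep(0.89, 2.0)) == "WGCW"
        assert classify_repeat(self._rep(0.89, 1.99)) == "OTHER"

    def test_ca_step_fraction(self):
        assert ca_step_fraction("CACACA") == 1.0
        assert ca_step_fraction("TGTG") == 1.0
        assert ca_step_fraction("AATT") == 0.0


def _random_genome(rng, length):
    return "".join(rng.choice(list("ACGT"), length, p=[0.29, 0.21, 0.21, 0.29]))


class TestSummarizeInterval:
    def test_planted_pentamer_array_sets_wgcw_flag(self):
        rng = np.random.default_rng(1)
        seq = _random_genome(rng, 2000)
        seq = seq[:700] + "CAGCA" * 90 + seq[700 + 450:]
        genome = {"chr1": seq}
        summary = summarize_interval(GenomeInterval("chr1", 0, 2000), genome)
        assert summary.has_wgcw and not summary.has_ca
        assert summary.wgcw_repeat_bp >= 400
        assert summary.max_wgcw_density >= 2.0

    def test_planted_short_ca_array_sets_ca_flag_only(self):
        rng = np.random.default_rng(2)
        seq = _random_genome(rng, 2000)
        seq = seq[:900] + "CA" * 60 + seq[900 + 120:]
        genome = {"chr1": seq}
        summary = summarize_interval(GenomeInterval("chr1", 0, 2000), genome)
        assert summary.has_ca and not summary.has_wgcw
        assert summary.ca_repeat_bp >= 100

    def test_plain_background_has_neither(self):
        rng = np.random.default_rng(3)
        genome = {"chr1": _random_genome(rng, 2000)}
        summary = summarize_interval(GenomeInterval("chr1", 0, 2000), genome)
        assert not summary.has_wgcw and not summary.has_ca

    def test_missing_sequence_names_interval(self):
        with pytest.raises(ValueError, match="chr9:0-100"):
            summarize_interval(GenomeInterval("chr9", 0, 100), {"chr9": "ACGT"})


class TestAccumulationCurve:
    def test_fraction_at_threshold(self):
        curve = accumulation_curve([0, 100, 400, 400], thresholds=[400])
        assert curve["fraction"].iloc[0] == 0.5

    def test_all_zero_curve(self):
        curve = accumulation_curve([0, 0, 0], thresholds=[0, 1, 100])
        assert list(curve["fraction"]) == [1.0, 0.0, 0.0]

    def test_non_increasing(self):
        rng = np.random.default_rng(0)
        curve = accumulation_curve(rng.integers(0, 500, 50))
        assert (np.diff(curve["fraction"]) <= 0).all()

    def test_consistent_with_site_flags(self, study):
        lengths = [0, 120, 450, 500, 390]
        curve = accumulation_curve(lengths, thresholds=[400])
        assert curve["fraction"].iloc[0] == pytest.approx(
            np.mean([v >= 400 for v in lengths])
        )


class TestGenomeBackground:
    def test_repeat_free_genome_fractions_zero(self):
        rng = np.random.default_rng(5)
        genome = {"chrZ": _random_genome(rng, 200_000)}
        sizes = ChromSizes({"chrZ": 200_000})
        result = genome_background(genome, sizes, n_intervals=50, seed=0)
        assert result["fraction_wgcw"] == 0.0
        assert result["fraction_ca"] == 0.0

    def test_same_seed_identical_output(self):
        rng = np.random.default_rng(6)
        genome = {"chrZ": _random_genome(rng, 100_000)}
        sizes = ChromSizes({"chrZ": 100_000})
        a = genome_background(genome, sizes, n_intervals=30, seed=3)
        b = genome_background(genome, sizes, n_intervals=30, seed=3)
        assert a["intervals"].equals(b["intervals"])

    def test_sampled_ca_fraction_matches_tiling_oracle(self):
        """Plant CA arrays over ~5% of a genome; the sampled background CA
        fraction must agree with exhaustive non-overlapping tiling."""
        rng = np.random.default_rng(8)
        length = 400_000
        seq = list(_random_genome(rng, length))
        array = "CA" * 100  # 200 bp each
        starts = np.arange(1000, length - 1000, 4000)  # 100 arrays = 5%
        for s in starts:
            seq[s : s + 200] = array
        genome = {"chrZ": "".join(seq)}
        sizes = ChromSizes({"chrZ": length})

        tile_hits = [
            summarize_interval(GenomeInterval("chrZ", s, s + 2000), genome).has_ca
            for s in range(0, length - 2000 + 1, 2000)
        ]
        expected = float(np.mean(tile_hits))

        result = genome_background(
            genome, sizes, n_intervals=400, length=2000, seed=1
        )
        assert result["fraction_ca"] == pytest.approx(expected, abs=0.08)
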