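import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from loopferret.insulation import BoundaryCall
from loopferret.motifs import (
    CBSAnnotation,
    PWM,
    compose_boundaries,
    composition_summary,
    count_divergent_pairs,
    read_cbs_bed,
    scan_peak,
    write_cbs_bed,
)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def brute_force_best_hit(seq, pwm):
    """Exhaustive enumeration over all offsets and strands; same tie rule."""
    L = len(pwm)
    best = None
    for offset in range(len(seq) - L + 1):
        window = seq[offset : offset + L]
        rc = window.translate(_COMPLEMENT)[::-1]
        for rank, w in ((0, window), (1, rc)):
            s = pwm.score(w)
            key = (-s, offset, rank)
            if best is None or key < best:
                best = key
    return -best[0], best[1], best[2]


def sharp_pwm(consensus):
    """A PWM strongly preferring one sequence."""
    letters = "ACGT"
    probs = np.full((len(consensus), 4), 0.04)
    for i, c in enumerate(consensus):
        probs[i, letters.index(c)] = 0.88
    return PWM(probs)


JASPAR_TEXT = """>MA0000.1 TESTCTCF
A [ 10  0  0  5 ]
C [  0 10  0  5 ]
G [  0  0 10  0 ]
T [  0  0  0  0 ]
"""


class TestPWM:
    def test_jaspar_counts_to_probabilities_with_pseudocount(self):
        pwm = PWM.from_jaspar(JASPAR_TEXT)
        assert len(pwm) == 4
        np.testing.assert_allclose(pwm.probs.sum(axis=1), 1.0)
        # column 0: A count 10 + 0.25 over total 10 + 1
        assert pwm.probs[0, 0] == pytest.approx(10.25 / 11.0)
        assert pwm.consensus() == "ACGA"

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError):
            PWM(np.array([[0.5, 0.5, 0.5, 0.5]]))

    def test_n_scores_minus_infinity(self):
        pwm = sharp_pwm("ACG")
        assert pwm.score("ANG") == float("-inf")


class TestScanPeak:
    def test_consensus_embedded_at_offset_seven(self):
        pwm = sharp_pwm("ACGTA")
        seq = "GGGGGGG" + "ACGTA" + "GGGG"
        hit = scan_peak(seq, pwm)
        assert hit.start == 7 and hit.end == 12
        assert hit.orientation == "forward"
        expected = sum(math.log2(0.88 / 0.25) for _ in range(5))
        assert hit.log_odds_score == pytest.approx(expected)

    def test_reverse_complement_flips_orientation_keeps_score(self):
        pwm = sharp_pwm("ACGTT")
        seq = "GGGGACGTTGGGG"
        fwd = scan_peak(seq, pwm)
        rev = scan_peak(seq.translate(_COMPLEMENT)[::-1], pwm)
        assert fwd.orientation == "forward"
        assert rev.orientation == "reverse"
        assert fwd.log_odds_score == pytest.approx(rev.log_odds_score)

    def test_palindromic_tie_prefers_plus_strand(self):
        # ACGT is its own reverse complement: equal scores on both strands
        pwm = sharp_pwm("ACGT")
        hit = scan_peak("ACGT", pwm)
        assert hit.orientation == "forward"

    def test_below_threshold_returns_none(self):
        pwm = sharp_pwm("AAAA")
        assert scan_peak("CCCCCCC", pwm, threshold=0.0) is None

    def test_short_sequence_is_an_error(self):
        with pytest.raises(ValueError):
            scan_peak("AC", sharp_pwm("ACGT"))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        seq=st.text(alphabet="ACGT", min_size=3, max_size=30),
        seed=st.integers(0, 10_000),
    )
    def test_matches_exhaustive_enumeration(self, seq, seed):
        rng = np.random.default_rng(seed)
        probs = rng.dirichlet(np.ones(4), size=3)
        pwm = PWM(probs)
        hit = scan_peak(seq, pwm, threshold=-math.inf)
        score, offset, rank = brute_force_best_hit(seq, pwm)
        assert hit.log_odds_score == pytest.approx(score)
        assert hit.start == offset
        assert hit.orientation == ("forward" if rank == 0 else "reverse")


def cbs_at(positions_orientations, chrom="c", width=19):
    return [
        CBSAnnotation(chrom=chrom, start=p, end=p + width,
                      orientation=o, source_peak=f"p{k}")
        for k, (p, o) in enumerate(positions_orientations)
    ]


class TestComposition:
    @pytest.mark.parametrize(
        "orientations,expected_pairs",
        [
            (["reverse", "reverse", "forward", "reverse", "forward", "reverse"], 5),
            (["forward", "forward", "forward"], 0),
            (["reverse", "forward", "reverse", "forward"], 3),
        ],
    )
    def test_divergent_pair_counting(self, orientations, expected_pairs):
        assert count_divergent_pairs(orientations) == expected_pairs

    def test_ep_like_boundary_composition(self):
        # six sites ordered R,R,F,R,F,R straddling the boundary
        orients = ["reverse", "reverse", "forward", "reverse", "forward", "reverse"]
        sites = cbs_at([(100_000 + 3000 * k, o) for k, o in enumerate(orients)])
        boundary = BoundaryCall(bin=10, boundary_score=1.2)  # bin 10 @ 10 kb
        comps = compose_boundaries([boundary], sites, flank_bp=100_000,
                                   bin_size=10_000)
        assert comps[0].n_cbs == 6
        assert comps[0].divergent is True
        assert comps[0].n_divergent_pairs == 5
        assert comps[0].boundary_score == pytest.approx(1.2)

    def test_flag_invariant_to_coordinate_translation(self):
        orients = ["reverse", "forward", "reverse"]
        for shift in (0, 1_000_000):
            sites = cbs_at([(100_000 + shift + 5000 * k, o)
                            for k, o in enumerate(orients)])
            b = BoundaryCall(bin=(100_000 + shift) // 10_000, boundary_score=1.0)
            comps = compose_boundaries([b], sites, bin_size=10_000)
            assert comps[0].divergent is True
            assert comps[0].n_divergent_pairs == 1

    def test_negative_flank_rejected(self):
        with pytest.raises(ValueError):
            compose_boundaries([], [], flank_bp=-1)

    def test_summary_quantiles_linear_interpolation(self):
        comps = [
            # five boundaries in one (n_cbs, class) bucket
            *[_comp(bs) for bs in (1.0, 2.0, 3.0, 4.0, 5.0)],
        ]
        table = composition_summary(comps)
        row = table.iloc[0]
        assert row["count"] == 5
        assert row["median_bs"] == pytest.approx(3.0)
        assert row["q1"] == pytest.approx(2.0)
        assert row["q3"] == pytest.approx(4.0)

    def test_summary_single_composition(self):
        table = composition_summary([_comp(0.8)])
        row = table.iloc[0]
        assert row["median_bs"] == row["q1"] == row["q3"] == pytest.approx(0.8)


def _comp(bs):
    from loopferret.motifs import BoundaryComposition

    return BoundaryComposition(
        boundary_id="b", n_cbs=3, n_divergent_pairs=1, divergent=True,
        boundary_score=bs,
    )


class TestScanPeaks:
    def test_best_hit_per_peak_from_fasta(self, tmp_path):
        from loopferret.motifs import scan_peaks

        fasta = tmp_path / "genome.fa"
        fasta.write_text(">chr1\n" + "G" * 20 + "ACGTA" + "G" * 20 + "\n")
        pwm = sharp_pwm("ACGTA")
        hits = scan_peaks(fasta, [("chr1", 10, 35)], pwm)
        assert len(hits) == 1
        assert (hits[0].chrom, hits[0].start, hits[0].orientation) == (
            "chr1", 20, "forward",
        )


class TestBedIO:
    def test_round_trip(self, tmp_path):
        sites = cbs_at([(100, "forward"), (500, "reverse")])
        path = tmp_path / "cbs.bed"
        write_cbs_bed(sites, path)
        back = read_cbs_bed(path)
        assert [(c.start, c.orientation) for c in back] == [
            (100, "forward"), (500, "reverse"),
        ]
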