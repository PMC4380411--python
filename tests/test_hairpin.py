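"""Window extraction, star location, complementarity, criteria, refinement."""

import numpy as np
import pytest

from mircam.fold import FoldResult, fold_mfe
from mircam.hairpin import (
    Window,
    apply_hairpin_criteria,
    complementarity_pct,
    evaluate_precursor,
    extract_window,
    locate_star,
    refine_precursor,
)
from mircam.io import dna_to_rna, revcomp
from mircam.seqmatch import GenomeAnchor
from mircam.synthdata import build_hairpin_locus, random_locus


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


class TestExtractWindow:
    def test_interior_anchor(self, rng):
        genome = {"c1": random_dna(rng, 2000)}
        anchor = GenomeAnchor(genome["c1"][499:520], "c1", 500, 520, "+")
        window = extract_window(anchor, genome)
        assert len(window.sequence) == 421  # 200 + 21 + 200
        assert window.mature_offset == 201
        assert window.sequence[200:221] == anchor.tag

    def test_clamped_at_contig_start(self, rng):
        genome = {"c1": random_dna(rng, 2000)}
        anchor = GenomeAnchor(genome["c1"][0:21], "c1", 1, 21, "+")
        window = extract_window(anchor, genome)
        assert len(window.sequence) == 221
        assert window.mature_offset == 1

    def test_minus_strand_is_reverse_complement_of_plus(self, rng):
        genome = {"c1": random_dna(rng, 2000)}
        tag_plus = genome["c1"][499:520]
        plus = extract_window(GenomeAnchor(tag_plus, "c1", 500, 520, "+"), genome)
        minus = extract_window(
            GenomeAnchor(revcomp(tag_plus), "c1", 500, 520, "-"), genome
        )
        assert minus.sequence == revcomp(plus.sequence)
        mo = minus.mature_offset - 1
        assert minus.sequence[mo : mo + 21] == revcomp(tag_plus)

    def test_contig_shorter_than_mature_errors(self):
        genome = {"c1": "ACGT"}
        anchor = GenomeAnchor("ACGTACGTACGTACGTACGTA", "c1", 1, 21, "+")
        with pytest.raises(ValueError):
            extract_window(anchor, genome)


class TestLocateStar:
    def test_perfect_stem_star_matches_design(self, rng):
        locus = build_hairpin_locus(random_dna(rng, 21), 15, 0, rng)
        fold = fold_mfe(dna_to_rna(locus.precursor))
        star = locate_star(fold, locus.mature_offset, 21)
        assert star == (locus.star_offset, len(locus.star))

    def test_mature_in_terminal_loop_has_no_star(self):
        # a hairpin whose loop contains the "mature": unpaired region
        stem5 = "GGCGGCGGCGGC"
        loop = "AACAACAACAACAACAACAAC"  # 21-nt unpairable loop
        pre = stem5 + loop + revcomp(stem5)
        fold = fold_mfe(dna_to_rna(pre))
        assert locate_star(fold, len(stem5), 21) is None

    def test_3p_mature_swaps_arms(self, rng):
        locus = build_hairpin_locus(random_dna(rng, 21), 15, 0, rng, arm="3p")
        cand = evaluate_precursor(locus.precursor, locus.mature_offset, 21)
        assert cand.arm == "3p"
        assert cand.star_offset is not None
        assert cand.star_offset < cand.mature_offset


class TestComplementarity:
    @staticmethod
    def _fold_with_pairs(n, pair_map):
        pairs = np.full(n, -1, dtype=np.int32)
        for i, j in pair_map.items():
            pairs[i] = j
            pairs[j] = i
        structure = "".join(
            "." if pairs[k] < 0 else ("(" if pairs[k] > k else ")") for k in range(n)
        )
        return FoldResult("A" * n, structure, -30.0, pairs)

    def test_fully_paired_mature_is_100(self):
        fold = self._fold_with_pairs(80, {i: 79 - i for i in range(21)})
        assert complementarity_pct(fold, 0, 21, (59, 21)) == 100.0

    def test_15_of_20_is_exactly_75(self):
        fold = self._fold_with_pairs(80, {i: 79 - i for i in range(15)})
        assert complementarity_pct(fold, 0, 20, (60, 20)) == 75.0

    def test_14_of_20_is_70(self):
        fold = self._fold_with_pairs(80, {i: 79 - i for i in range(14)})
        assert complementarity_pct(fold, 0, 20, (60, 20)) == 70.0


class TestCriteria:
    @pytest.mark.parametrize(
        "mfe,length,comp,ok,failed",
        [
            (-20.1, 209, 80.0, True, ()),
            (-19.9, 100, 100.0, False, ("mfe",)),
            (-20.0, 100, 100.0, False, ("mfe",)),  # strictly below -20
            (-50.0, 211, 100.0, False, ("length",)),
            (-50.0, 210, 100.0, True, ()),  # inclusive at 210
            (-50.0, 100, 75.0, True, ()),  # inclusive at 75
            (-50.0, 100, 74.9, False, ("complementarity",)),
            (-50.0, 100, None, False, ("complementarity",)),
        ],
    )
    def test_boundaries(self, mfe, length, comp, ok, failed):
        verdict, reasons = apply_hairpin_criteria(mfe, length, comp)
        assert verdict is ok
        assert reasons == failed


class TestRefinePrecursor:
    def test_recovers_implanted_hairpin_span(self, rng):
        for _ in range(3):
            locus = random_locus(rng)
            pre_len = len(locus.precursor)
            left = random_dna(rng, 200)
            right = random_dna(rng, 200)
            window_seq = left + locus.precursor + right
            window = Window(
                window_seq, "c1", 1, len(window_seq), "+",
                mature_offset=200 + locus.mature_offset + 1,
                mature_len=len(locus.mature),
            )
            cand = refine_precursor(window)
            assert cand is not None
            true_start, true_end = 201, 200 + pre_len
            assert abs(cand.start - true_start) <= 10
            assert abs(cand.end - true_end) <= 10
            assert 52 <= cand.stem_loop_len <= 240

    def test_minus_strand_span_maps_back_to_genome(self, rng):
        locus = random_locus(rng)
        genome_seq = (
            random_dna(rng, 300) + revcomp(locus.precursor) + random_dna(rng, 300)
        )
        genome = {"c1": genome_seq}
        pre_start, pre_end = 301, 300 + len(locus.precursor)
        # genomic span of the mature on the minus strand
        m_hi = pre_end - locus.mature_offset
        m_lo = m_hi - len(locus.mature) + 1
        anchor = GenomeAnchor(locus.mature, "c1", m_lo, m_hi, "-")
        assert revcomp(genome_seq[m_lo - 1 : m_hi]) == locus.mature
        window = extract_window(anchor, genome)
        cand = refine_precursor(window)
        assert cand is not None
        assert abs(cand.start - pre_start) <= 10
        assert abs(cand.end - pre_end) <= 10

    def test_background_windows_rarely_pass(self, rng):
        """Random 421-nt windows around a random 21-nt 'mature' should
        essentially never yield a passing precursor (25-window panel)."""
        passes = 0
        for _ in range(25):
            seq = random_dna(rng, 421)
            window = Window(seq, "c1", 1, 421, "+", 201, 21)
            if refine_precursor(window) is not None:
                passes += 1
        assert passes <= 1  # < 5%
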