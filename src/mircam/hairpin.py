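"""Precursor extraction and the three structural miRNA criteria.

Around each genome anchor a +/-200-nt window is extracted (oriented so the
mature reads 5'->3'), folded with the package's MFE dynamic program, and
judged on the criteria a plant miRNA precursor must meet: folding energy
below -20 kcal/mol, stem-loop no longer than 210 nt, and at least 75% of the
mature's bases paired to the star arm of the duplex.  Because the 421-nt
window is much longer than a real precursor (tens to ~200 nt), the window is
refined to the minimal passing sub-window with the best energy density.

DNA goes in; T->U conversion happens here, at the folding boundary, only.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._util import round_half_up
from .fold import FoldResult, fold_mfe
from .io import dna_to_rna, revcomp
from .seqmatch import GenomeAnchor

FLANK = 200
MIN_MFE = -20.0
MAX_PRECURSOR_LEN = 210
MIN_COMPLEMENTARITY = 75.0
#: refinement search space: precursor lengths tried within the window.
REFINE_MIN_LEN = 52
REFINE_MAX_LEN = 240
REFINE_GRID = 10
#: a miRNA/miRNA* duplex has arms of near-equal length; a "star" span that
#: deviates from the mature length by more than this is not a duplex.
STAR_LEN_SLACK = 8


@dataclass(frozen=True)
class Window:
    """Genomic window around an anchor, oriented mature-5'->3'."""

    sequence: str  # DNA, already reverse-complemented for - anchors
    contig: str
    start: int  # 1-based genomic span of the window (plus-strand coords)
    end: int
    strand: str
    mature_offset: int  # 1-based offset of the mature within sequence
    mature_len: int


@dataclass
class HairpinCandidate:
    """A candidate precursor with structure, arms, and criteria verdict."""

    sequence: str  # DNA precursor, mature-oriented
    contig: str
    start: int
    end: int
    strand: str
    fold: FoldResult
    mature_offset: int  # 0-based within sequence
    mature_len: int
    star_offset: int | None
    star_len: int | None
    arm: str  # 5p / 3p: side of the stem carrying the mature
    complementarity: float | None
    verdict: bool = False
    failed: tuple[str, ...] = ()

    @property
    def stem_loop_len(self) -> int:
        return len(self.sequence)

    @property
    def mfe(self) -> float:
        return self.fold.mfe

    @property
    def mature_seq(self) -> str:
        return self.sequence[self.mature_offset : self.mature_offset + self.mature_len]

    @property
    def star_seq(self) -> str | None:
        if self.star_offset is None:
            return None
        return self.sequence[self.star_offset : self.star_offset + self.star_len]


def extract_window(anchor: GenomeAnchor, genome: dict[str, str], flank: int = FLANK) -> Window:
    """Window of ``flank`` nt up- and downstream of the anchor, clamped at
    contig edges; minus-strand anchors are reverse-complemented so the
    mature always reads 5'->3' in the returned sequence."""
    contig_seq = genome[anchor.contig]
    if len(contig_seq) < len(anchor.tag):
        raise ValueError(f"contig {anchor.contig} shorter than the mature tag")
    gs = max(1, anchor.start - flank)
    ge = min(len(contig_seq), anchor.end + flank)
    raw = contig_seq[gs - 1 : ge]
    if anchor.strand == "+":
        return Window(raw, anchor.contig, gs, ge, "+", anchor.start - gs + 1, len(anchor.tag))
    return Window(
        revcomp(raw), anchor.contig, gs, ge, "-", ge - anchor.end + 1, len(anchor.tag)
    )


def locate_star(
    fold: FoldResult, mature_offset: int, mature_len: int
) -> tuple[int, int] | None:
    """Star arm (0-based offset, length) implied by the fold, or None.

    The star spans the partners of the mature's outermost paired bases,
    shifted by +2 for the 2-nt 3' overhangs of a miRNA/miRNA* duplex and
    clamped at the sequence ends.  Absent when fewer than half of the mature
    bases are paired, when the implied span overlaps the mature, or when its
    length is incompatible with a two-armed duplex.
    """
    n = len(fold.sequence)
    positions = range(mature_offset, min(mature_offset + mature_len, n))
    paired = [p for p in positions if fold.pairs[p] >= 0]
    if len(paired) < 0.5 * mature_len:
        return None
    lo = int(fold.pairs[paired[-1]]) + 2
    hi = int(fold.pairs[paired[0]]) + 2
    if lo > hi:
        return None
    lo = max(0, lo)
    hi = min(n - 1, hi)
    length = hi - lo + 1
    if not (mature_len - STAR_LEN_SLACK <= length <= mature_len + STAR_LEN_SLACK):
        return None
    if lo <= mature_offset + mature_len - 1 and hi >= mature_offset:
        return None  # overlaps the mature
    return lo, length


def complementarity_pct(
    fold: FoldResult, mature_offset: int, mature_len: int, star: tuple[int, int]
) -> float:
    """Percent of mature bases paired into the star span (1 decimal)."""
    star_lo, star_len = star
    star_hi = star_lo + star_len - 1
    paired_into_star = sum(
        1
        for p in range(mature_offset, mature_offset + mature_len)
        if p < len(fold.sequence) and star_lo <= fold.pairs[p] <= star_hi and fold.pairs[p] >= 0
    )
    return round_half_up(100.0 * paired_into_star / mature_len, 1)


def apply_hairpin_criteria(
    mfe: float,
    stem_loop_len: int,
    complementarity: float | None,
    min_mfe: float = MIN_MFE,
    max_len: int = MAX_PRECURSOR_LEN,
    min_complementarity: float = MIN_COMPLEMENTARITY,
) -> tuple[bool, tuple[str, ...]]:
    """The three-structure gate: MFE strictly below ``min_mfe`` kcal/mol,
    stem-loop length at most ``max_len`` nt, mature/star complementarity at
    least ``min_complementarity`` percent (missing star fails)."""
    failed = []
    if not mfe < min_mfe:
        failed.append("mfe")
    if stem_loop_len > max_len:
        failed.append("length")
    if complementarity is None or complementarity < min_complementarity:
        failed.append("complementarity")
    return not failed, tuple(failed)


def evaluate_precursor(
    sequence: str,
    mature_offset: int,
    mature_len: int,
    contig: str = ".",
    start: int = 1,
    strand: str = "+",
    min_mfe: float = MIN_MFE,
    max_len: int = MAX_PRECURSOR_LEN,
    min_complementarity: float = MIN_COMPLEMENTARITY,
) -> HairpinCandidate:
    """Fold a precursor-sized DNA sequence and apply the criteria."""
    fold = fold_mfe(dna_to_rna(sequence.upper()))
    star = locate_star(fold, mature_offset, mature_len)
    comp = (
        complementarity_pct(fold, mature_offset, mature_len, star)
        if star is not None
        else None
    )
    verdict, failed = apply_hairpin_criteria(
        fold.mfe, len(sequence), comp, min_mfe, max_len, min_complementarity
    )
    arm = "5p"
    if star is not None and star[0] < mature_offset:
        arm = "3p"
    return HairpinCandidate(
        sequence=sequence.upper(),
        contig=contig,
        start=start,
        end=start + len(sequence) - 1,
        strand=strand,
        fold=fold,
        mature_offset=mature_offset,
        mature_len=mature_len,
        star_offset=None if star is None else star[0],
        star_len=None if star is None else star[1],
        arm=arm,
        complementarity=comp,
        verdict=verdict,
        failed=failed,
    )


def _genomic_span(window: Window, lo: int, hi: int) -> tuple[int, int]:
    """Map a 0-based [lo, hi] slice of the (oriented) window back to 1-based
    plus-strand genomic coordinates."""
    if window.strand == "+":
        return window.start + lo, window.start + hi
    return window.end - hi, window.end - lo


def refine_precursor(
    window: Window,
    min_mfe: float = MIN_MFE,
    max_len: int = MAX_PRECURSOR_LEN,
    min_complementarity: float = MIN_COMPLEMENTARITY,
    min_len: int = REFINE_MIN_LEN,
    max_search_len: int = REFINE_MAX_LEN,
    grid: int = REFINE_GRID,
) -> HairpinCandidate | None:
    """Minimal passing precursor inside the window, or None.

    Sub-windows containing the mature are scanned on a ``grid``-nt grid over
    lengths ``min_len``..``max_search_len``; among those passing the three
    criteria the smallest wins (a real precursor does not grow by absorbing
    flank sequence), with MFE density (mfe / length) breaking length ties.
    The winning ends are then polished at 1-nt resolution.
    """
    seq = window.sequence
    n = len(seq)
    ms = window.mature_offset - 1  # 0-based
    me = ms + window.mature_len - 1

    def evaluate(lo: int, hi: int) -> HairpinCandidate | None:
        g_start, g_end = _genomic_span(window, lo, hi)
        cand = evaluate_precursor(
            seq[lo : hi + 1],
            ms - lo,
            window.mature_len,
            contig=window.contig,
            start=g_start,
            strand=window.strand,
            min_mfe=min_mfe,
            max_len=max_len,
            min_complementarity=min_complementarity,
        )
        cand.end = g_end
        return cand if cand.verdict else None

    def key(c: HairpinCandidate) -> tuple[int, float]:
        return (c.stem_loop_len, c.mfe / c.stem_loop_len)

    best: HairpinCandidate | None = None
    best_span: tuple[int, int] | None = None
    for lo in range(max(0, me + 1 - max_search_len), ms + 1, grid):
        hi_min = max(me, lo + min_len - 1)
        for hi in range(hi_min, min(n, lo + max_search_len), grid):
            cand = evaluate(lo, hi)
            if cand is not None and (best is None or key(cand) < key(best)):
                best = cand
                best_span = (lo, hi)
    if best is None:
        return None
    # 1-nt polish, one end at a time
    lo, hi = best_span
    for d in range(-(grid // 2), grid // 2 + 1):
        nlo = lo + d
        if d == 0 or not (0 <= nlo <= ms) or not (min_len <= hi - nlo + 1 <= max_search_len):
            continue
        cand = evaluate(nlo, hi)
        if cand is not None and key(cand) < key(best):
            best, lo = cand, nlo
    for d in range(-(grid // 2), grid // 2 + 1):
        nhi = hi + d
        if d == 0 or not (me <= nhi < n) or not (min_len <= nhi - lo + 1 <= max_search_len):
            continue
        cand = evaluate(lo, nhi)
        if cand is not None and key(cand) < key(best):
            best, hi = cand, nhi
    return best
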