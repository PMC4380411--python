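"""miRNA target prediction by complementarity alignment against a CDS set.

Plant miRNAs bind coding sequence with near-perfect complementarity, so the
reverse complement of each miRNA is locally aligned to every transcript
(match +2, mismatch -3, gap open -5, gap extend -2; G:U not rewarded).  A
perfect ~21-nt site scores ~42; the default reporting gate of 25 keeps
near-perfect sites, and a relaxed gate of 20 is used when scanning a
focussed gene list (e.g. lipid-pathway genes) for additional candidates.

Alignment itself is delegated to Bio.Align.PairwiseAligner; the scoring
convention is fixed here and validated in the test suite against an
independent textbook DP.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from Bio import Align

from .io import revcomp

MATCH = 2
MISMATCH = -3
GAP_OPEN = -5
GAP_EXTEND = -2
MIN_SCORE = 25
LIPID_MIN_SCORE = 20


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = MATCH
    aligner.mismatch_score = MISMATCH
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    return aligner


_ALIGNER = _aligner()


@dataclass
class TargetHit:
    """One miRNA -> transcript complementarity site."""

    mirna_id: str
    transcript_id: str
    start: int  # 1-based alignment span on the transcript
    end: int
    score: float
    matches: int
    mismatches: int
    gaps: int
    annotation: str = ""
    go_terms: tuple[str, ...] = field(default_factory=tuple)


def score_target(mirna: str, transcript: str) -> tuple[float, dict]:
    """Best local alignment of the miRNA's reverse complement vs the
    transcript sense strand; returns (score, details).

    ``details`` carries the 1-based span and match/mismatch/gap counts of
    the first co-optimal alignment (deterministic DP order).
    """
    if not transcript:
        raise ValueError("empty transcript")
    if not 15 <= len(mirna) <= 27:
        raise ValueError(f"miRNA length must be 15-27 nt, got {len(mirna)}")
    query = revcomp(mirna.upper().replace("U", "T"))
    target = transcript.upper().replace("U", "T")
    score = _ALIGNER.score(query, target)
    if score <= 0:
        return 0.0, {"start": 0, "end": 0, "matches": 0, "mismatches": 0, "gaps": 0}
    aln = _ALIGNER.align(query, target)[0]
    q_blocks, t_blocks = aln.aligned
    matches = mismatches = 0
    for (qs, qe), (ts, te) in zip(q_blocks, t_blocks):
        for k in range(qe - qs):
            if query[qs + k] == target[ts + k]:
                matches += 1
            else:
                mismatches += 1
    gap_len = 0
    for k in range(1, len(q_blocks)):
        gap_len += (q_blocks[k][0] - q_blocks[k - 1][1]) + (
            t_blocks[k][0] - t_blocks[k - 1][1]
        )
    details = {
        "start": int(t_blocks[0][0]) + 1,
        "end": int(t_blocks[-1][1]),
        "matches": matches,
        "mismatches": mismatches,
        "gaps": gap_len,
    }
    return float(score), details


def scan_targets(
    mirnas: dict[str, str],
    cds: dict[str, str],
    min_score: float = MIN_SCORE,
    restrict_to: set[str] | None = None,
) -> list[TargetHit]:
    """All hits with score >= min_score, per miRNA sorted by score
    (descending) then transcript id.  ``restrict_to`` optionally limits the
    transcript space (e.g. a lipid-pathway gene list)."""
    hits: list[TargetHit] = []
    for mid in sorted(mirnas):
        per_mirna = []
        for tid in sorted(cds):
            if restrict_to is not None and tid not in restrict_to:
                continue
            score, details = score_target(mirnas[mid], cds[tid])
            if score >= min_score:
                per_mirna.append(
                    TargetHit(
                        mid, tid, details["start"], details["end"], score,
                        details["matches"], details["mismatches"], details["gaps"],
                    )
                )
        per_mirna.sort(key=lambda h: (-h.score, h.transcript_id))
        hits.extend(per_mirna)
    return hits


def annotate_hits(hits: list[TargetHit], annotation: pd.DataFrame | None) -> list[TargetHit]:
    """Left-join functional annotation onto hits.

    ``annotation`` columns: transcript_id, ortholog_id, description,
    go_terms (pipe-separated).  Hits without annotation are kept with empty
    fields.
    """
    if annotation is None or annotation.empty:
        return hits
    table = annotation.set_index("transcript_id")
    for hit in hits:
        if hit.transcript_id in table.index:
            row = table.loc[hit.transcript_id]
            hit.annotation = str(row.get("description", "") or "")
            raw = str(row.get("go_terms", "") or "")
            hit.go_terms = tuple(t.strip() for t in raw.split("|") if t.strip())
    return hits


def tally_go(hits: list[TargetHit]) -> pd.Series:
    """Hits per GO term, sorted by count (desc) then term (alphabetical)."""
    counts: dict[str, int] = {}
    for hit in hits:
        for term in hit.go_terms:
            counts[term] = counts.get(term, 0) + 1
    series = pd.Series(counts, dtype=int)
    if series.empty:
        return series
    return series.sort_index().sort_values(ascending=False, kind="stable")


def hits_table(hits: list[TargetHit]) -> pd.DataFrame:
    """Hits as a flat DataFrame for TSV export."""
    return pd.DataFrame(
        [
            {
                "mirna": h.mirna_id, "transcript": h.transcript_id,
                "start": h.start, "end": h.end, "score": h.score,
                "matches": h.matches, "mismatches": h.mismatches,
                "gaps": h.gaps, "annotation": h.annotation,
                "go_terms": "|".join(h.go_terms),
            }
            for h in hits
        ],
        columns=["mirna", "transcript", "start", "end", "score", "matches",
                 "mismatches", "gaps", "annotation", "go_terms"],
    )
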