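"""Exact and mismatch-tolerant matching of collapsed tags.

Three reference spaces: the genome (exact matching on both strands via a
k-mer seed index, with a multi-mapping cap), the known mature miRNA set
(identity in both size and sequence — the conservative definition of a
"known" miRNA), and reference matures/precursors at <= 3 mismatches for
homology-based novel candidates.  A decoy ncRNA set (tRNA/rRNA/snRNA-like)
disqualifies candidate precursors that share a long exact block with it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .io import revcomp

SEED_K = 12
MULTIMAP_CAP = 20
DECOY_BLOCK = 18


@dataclass(frozen=True)
class GenomeAnchor:
    """Exact placement of a tag in the genome (1-based inclusive)."""

    tag: str
    contig: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.tag):
            raise ValueError("anchor span does not match tag length")


@dataclass(frozen=True)
class ReferenceHit:
    """Best reference-set match for one tag."""

    tag: str
    ref_id: str
    mismatches: int
    family: str


_FAMILY_RE = re.compile(r"(?:^|[-_])(mir|miR|MIR)(f?)(\d+)", re.IGNORECASE)


def parse_family(ref_id: str) -> str:
    """Family label from a miRBase-style id: species prefix stripped,
    'miR' + number kept, member letters and arm suffixes ignored
    (ath-miR166a-5p -> miR166).  Falls back to the id itself."""
    m = _FAMILY_RE.search(ref_id)
    if not m:
        return ref_id
    return f"miR{m.group(2).lower()}{m.group(3)}"


class GenomeIndex:
    """K-mer seed index over a genome for exact tag placement."""

    def __init__(self, genome: dict[str, str], k: int = SEED_K):
        self.genome = {c: s.upper() for c, s in genome.items()}
        self.k = k
        self._seeds: dict[str, list[tuple[str, int]]] = {}
        for contig, seq in sorted(self.genome.items()):
            for pos in range(len(seq) - k + 1):
                self._seeds.setdefault(seq[pos : pos + k], []).append((contig, pos))

    def _exact_hits(self, query: str) -> list[tuple[str, int]]:
        out = []
        for contig, pos in self._seeds.get(query[: self.k], ()):
            if self.genome[contig][pos : pos + len(query)] == query:
                out.append((contig, pos))
        return out

    def anchor(self, tag: str, cap: int = MULTIMAP_CAP) -> list[GenomeAnchor]:
        """All exact occurrences of the tag on both strands, sorted by
        (contig, coordinate, strand) and truncated at the multi-map cap."""
        if len(tag) < self.k or "N" in tag:
            return []
        anchors = [
            GenomeAnchor(tag, contig, pos + 1, pos + len(tag), "+")
            for contig, pos in self._exact_hits(tag)
        ]
        anchors += [
            GenomeAnchor(tag, contig, pos + 1, pos + len(tag), "-")
            for contig, pos in self._exact_hits(revcomp(tag))
        ]
        anchors.sort(key=lambda a: (a.contig, a.start, a.strand))
        return anchors[:cap]


def anchor_to_genome(
    tags: list[str], genome: dict[str, str] | GenomeIndex, cap: int = MULTIMAP_CAP
) -> tuple[dict[str, list[GenomeAnchor]], list[str]]:
    """Anchor every tag; returns (anchors per tag, tags with >= 1 anchor)."""
    index = genome if isinstance(genome, GenomeIndex) else GenomeIndex(genome)
    anchors = {tag: index.anchor(tag, cap) for tag in tags}
    anchored = [tag for tag in tags if anchors[tag]]
    return anchors, anchored


def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


def match_known(
    tags: list[str], mature_ref: dict[str, str]
) -> dict[str, ReferenceHit]:
    """Tags identical (size and sequence) to a reference mature.

    U/T differences are normalized on both sides.  When several reference
    matures share the sequence, the lexicographically smallest id wins.
    """
    by_seq: dict[str, str] = {}
    for rid in sorted(mature_ref):
        seq = _normalize(mature_ref[rid])
        by_seq.setdefault(seq, rid)
    out = {}
    for tag in tags:
        rid = by_seq.get(_normalize(tag))
        if rid is not None:
            out[tag] = ReferenceHit(tag, rid, 0, parse_family(rid))
    return out


def _encode_batch(seqs: list[str]) -> np.ndarray:
    return np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(len(seqs), -1)


def match_homolog(
    tags: list[str],
    mature_ref: dict[str, str],
    precursor_ref: dict[str, str] | None = None,
    max_mm: int = 3,
) -> dict[str, ReferenceHit]:
    """Best reference hit per tag within ``max_mm`` mismatches.

    Equal-length Hamming distance against matures and windowed Hamming
    against precursors (tag slid along the precursor).  Ties are broken by
    the lexicographically smallest reference id.  Tags already classified
    known should not be passed in.
    """
    candidates: dict[int, list[tuple[str, str]]] = {}

    def add(rid: str, seq: str) -> None:
        candidates.setdefault(len(seq), []).append((rid, seq))

    for rid in sorted(mature_ref):
        add(rid, _normalize(mature_ref[rid]))
    lengths = sorted({len(t) for t in tags})
    if precursor_ref:
        for rid in sorted(precursor_ref):
            pre = _normalize(precursor_ref[rid])
            for length in lengths:
                for off in range(0, len(pre) - length + 1):
                    add(rid, pre[off : off + length])

    out: dict[str, ReferenceHit] = {}
    for length in lengths:
        bucket_tags = [t for t in tags if len(t) == length]
        refs = candidates.get(length, [])
        if not bucket_tags or not refs:
            continue
        tag_mat = _encode_batch([_normalize(t) for t in bucket_tags])
        ref_mat = _encode_batch([seq for _, seq in refs])
        # mismatches[i, j] = Hamming(tag i, candidate j)
        mismatches = (tag_mat[:, None, :] != ref_mat[None, :, :]).sum(axis=2)
        ref_ids = [rid for rid, _ in refs]
        for i, tag in enumerate(bucket_tags):
            row = mismatches[i]
            best = int(row.min())
            if best > max_mm:
                continue
            rid = min(ref_ids[j] for j in np.nonzero(row == best)[0])
            hit = ReferenceHit(tag, rid, best, parse_family(rid))
            prev = out.get(tag)
            if prev is None or (hit.mismatches, hit.ref_id) < (prev.mismatches, prev.ref_id):
                out[tag] = hit
    return out


def match_decoys(
    precursors: dict[str, str], decoys: dict[str, str], block: int = DECOY_BLOCK
) -> set[str]:
    """Ids of candidate precursors sharing an exact >= ``block``-nt stretch
    with any decoy ncRNA (either orientation)."""
    kmers: set[str] = set()
    for seq in decoys.values():
        seq = _normalize(seq)
        for s in (seq, revcomp(seq)):
            for pos in range(len(s) - block + 1):
                kmers.add(s[pos : pos + block])
    if not kmers:
        return set()
    flagged = set()
    for pid, pre in precursors.items():
        pre = _normalize(pre)
        for pos in range(len(pre) - block + 1):
            if pre[pos : pos + block] in kmers:
                flagged.add(pid)
                break
    return flagged
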