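"""Independent brute-force oracles used to validate the fast implementations.

These deliberately share only the *parameter tables* with the package (the
model is the contract), never the algorithms: structures are enumerated
exhaustively and scored by direct loop decomposition, alignments by a
textbook Gotoh DP plus gapless-substring enumeration, and sequence matching
by all-pairs scans.
"""

from __future__ import annotations

from functools import lru_cache

from mircam._energy import (
    BULGE,
    HAIRPIN,
    INTERNAL,
    MULTI_BRANCH,
    MULTI_CLOSE,
    MULTI_UNPAIRED,
    PAIRS,
    STACK,
)

_CAN_PAIR = {tuple(p) for p in PAIRS}
_PAIR_INDEX = {tuple(p): k for k, p in enumerate(PAIRS)}


def enumerate_structures(seq: str):
    """Yield every pseudoknot-free pair set (tuples of (i, j)) with hairpin
    loops >= 3 nt and canonical pairs only."""

    @lru_cache(maxsize=None)
    def region(i: int, j: int):
        # all structures of seq[i..j] inclusive
        if j - i < 4:
            return [()]
        out = list(region(i + 1, j))  # i unpaired
        for k in range(i + 4, j + 1):
            if (seq[i], seq[k]) in _CAN_PAIR:
                for inner in region(i + 1, k - 1):
                    for rest in region(k + 1, j):
                        out.append(((i, k),) + inner + rest)
        return out

    yield from region(0, len(seq) - 1)


def structure_energy(seq: str, pairs) -> int:
    """Score a pair set by loop decomposition, in 0.1 kcal/mol (exact ints)."""
    partner = {}
    for i, j in pairs:
        partner[i] = j
        partner[j] = i
    total = 0
    pair_list = sorted(pairs)

    def children_of(i: int, j: int):
        out = []
        k = i + 1
        while k < j:
            if k in partner and partner[k] > k:
                out.append((k, partner[k]))
                k = partner[k] + 1
            else:
                k += 1
        return out

    for (i, j) in pair_list:
        ch = children_of(i, j)
        unpaired = (j - i - 1) - sum(l - k + 1 for k, l in ch)
        if not ch:
            total += int(HAIRPIN[j - i - 1])
        elif len(ch) == 1:
            (k, l) = ch[0]
            s1, s2 = k - i - 1, j - l - 1
            if s1 == 0 and s2 == 0:
                total += int(
                    STACK[_PAIR_INDEX[(seq[i], seq[j])], _PAIR_INDEX[(seq[k], seq[l])]]
                )
            elif s1 == 0 or s2 == 0:
                total += int(BULGE[s1 + s2])
            else:
                total += int(INTERNAL[s1 + s2])
        else:
            total += (
                MULTI_CLOSE
                + MULTI_BRANCH * (len(ch) + 1)
                + MULTI_UNPAIRED * unpaired
            )
    return total


def brute_force_mfe(seq: str) -> int:
    """Exhaustive minimum over all structures, 0.1 kcal/mol."""
    return min(structure_energy(seq, p) for p in enumerate_structures(seq))


def hamming(a: str, b: str) -> int:
    assert len(a) == len(b)
    return sum(x != y for x, y in zip(a, b))


def all_pairs_best_hit(tag: str, references: dict[str, str], max_mm: int):
    """Best reference hit for a tag by exhaustive scan.

    Equal-length Hamming against every reference; ties broken by
    lexicographically smallest reference id.  Returns (ref_id, mismatches)
    or None.
    """
    best = None
    for rid in sorted(references):
        ref = references[rid]
        if len(ref) != len(tag):
            continue
        d = hamming(tag, ref)
        if d <= max_mm and (best is None or d < best[1]):
            best = (rid, d)
    return best


def naive_genome_scan(genome: str, tag: str):
    """All exact occurrences of tag on the + strand by naive scanning."""
    hits = []
    start = genome.find(tag)
    while start != -1:
        hits.append(start)
        start = genome.find(tag, start + 1)
    return hits


def gotoh_local(query: str, target: str, match=2, mismatch=-3, open_=-5, extend=-2):
    """Textbook affine-gap local alignment (Gotoh), returning the best score.

    The first base of a gap costs ``open_`` and each further base ``extend``,
    matching the package's scoring convention.
    """
    n, m = len(query), len(target)
    NEG = -(10 ** 9)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in target (consume query)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in query (consume target)
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i - 1][j] + open_, E[i - 1][j] + extend)
            F[i][j] = max(H[i][j - 1] + open_, F[i][j - 1] + extend)
            s = match if query[i - 1] == target[j - 1] else mismatch
            H[i][j] = max(0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return best


def best_gapless_score(query: str, target: str, match=2, mismatch=-3) -> int:
    """Best local alignment score over all gapless substring alignments."""
    best = 0
    n, m = len(query), len(target)
    for qs in range(n):
        for ts in range(m):
            score = 0
            run_best = 0
            for k in range(min(n - qs, m - ts)):
                score += match if query[qs + k] == target[ts + k] else mismatch
                if score < 0:
                    break
                run_best = max(run_best, score)
            best = max(best, run_best)
    return best
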