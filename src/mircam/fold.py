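"""Minimum-free-energy RNA secondary structure prediction.

A Zuker-style dynamic program over the nearest-neighbor model declared in
:mod:`mircam._energy`: stacking energies for Watson-Crick and G:U pairs,
affine hairpin/bulge/internal-loop penalties (loop size capped at 30 nt, the
standard nearest-neighbor cap), linear multiloop penalties, minimum hairpin
loop of 3 nt, no pseudoknots.  Energies are integers in 0.1 kcal/mol so the
optimum is exact and reproducible.

Tie-breaking is deterministic: the traceback prefers structures that pair the
leftmost 5' base, and within a paired region prefers stacked/smallest-span
continuations, so identical sequences always yield identical structures.

The matrix fill and traceback are compiled with numba when available and fall
back to the identical pure-Python code otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._energy import (
    BULGE,
    ENCODE,
    HAIRPIN,
    INF,
    INTERNAL,
    MAXLOOP,
    MAXSEQ,
    MULTI_BRANCH,
    MULTI_CLOSE,
    MULTI_UNPAIRED,
    PAIR_TABLE,
    STACK,
)

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(func):
            return func

        return wrap


@dataclass(frozen=True)
class FoldResult:
    """Predicted minimum-free-energy structure of one RNA sequence."""

    sequence: str
    structure: str
    mfe: float
    #: partner index per position (-1 = unpaired), 0-based.
    pairs: np.ndarray

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.structure):
            raise ValueError("sequence/structure length mismatch")


@njit(cache=True)
def _fill(enc, ptab, stack, hairpin, bulge, internal):
    n = enc.shape[0]
    V = np.full((n, n), INF, dtype=np.int32)
    M = np.full((n, n), INF, dtype=np.int32)
    for span in range(4, n):
        for i in range(n - span):
            j = i + span
            pt = ptab[enc[i], enc[j]]
            if pt >= 0:
                best = hairpin[span - 1]
                kmax = min(i + 1 + MAXLOOP, j - 4)
                for k in range(i + 1, kmax + 1):
                    s1 = k - i - 1
                    lmin = j - 1 - (MAXLOOP - s1)
                    if lmin < k + 4:
                        lmin = k + 4
                    for l in range(lmin, j):
                        vkl = V[k, l]
                        if vkl >= INF:
                            continue
                        s2 = j - l - 1
                        if s1 == 0 and s2 == 0:
                            e = stack[pt, ptab[enc[k], enc[l]]] + vkl
                        elif s1 == 0 or s2 == 0:
                            e = bulge[s1 + s2] + vkl
                        else:
                            e = internal[s1 + s2] + vkl
                        if e < best:
                            best = e
                for k in range(i + 2, j - 1):
                    a = M[i + 1, k]
                    b = M[k + 1, j - 1]
                    if a < INF and b < INF:
                        e = MULTI_CLOSE + MULTI_BRANCH + a + b
                        if e < best:
                            best = e
                V[i, j] = best
            m = INF
            if V[i, j] < INF:
                m = V[i, j] + MULTI_BRANCH
            if M[i + 1, j] < INF and M[i + 1, j] + MULTI_UNPAIRED < m:
                m = M[i + 1, j] + MULTI_UNPAIRED
            if M[i, j - 1] < INF and M[i, j - 1] + MULTI_UNPAIRED < m:
                m = M[i, j - 1] + MULTI_UNPAIRED
            for k in range(i + 4, j - 4):
                a = M[i, k]
                b = M[k + 1, j]
                if a < INF and b < INF and a + b < m:
                    m = a + b
            M[i, j] = m
    W = np.zeros(n + 1, dtype=np.int32)
    for i in range(n - 1, -1, -1):
        w = W[i + 1]
        for j in range(i + 4, n):
            if V[i, j] < INF:
                e = V[i, j] + W[j + 1]
                if e < w:
                    w = e
        W[i] = w
    return V, M, W


@njit(cache=True)
def _traceback(enc, ptab, stack, hairpin, bulge, internal, V, M, W):
    n = enc.shape[0]
    pairs = np.full(n, -1, dtype=np.int32)
    # explicit stack of (i, j, mode); mode 0 = V (i pairs j), 1 = M region
    cap = 4 * n + 8
    st_i = np.empty(cap, dtype=np.int32)
    st_j = np.empty(cap, dtype=np.int32)
    st_m = np.empty(cap, dtype=np.int32)
    top = 0
    # external loop, preferring to pair the leftmost base on ties
    i = 0
    while i < n:
        paired = False
        for j in range(i + 4, n):
            if V[i, j] < INF and V[i, j] + W[j + 1] == W[i]:
                st_i[top] = i
                st_j[top] = j
                st_m[top] = 0
                top += 1
                i = j + 1
                paired = True
                break
        if not paired:
            i += 1
    while top > 0:
        top -= 1
        i = st_i[top]
        j = st_j[top]
        mode = st_m[top]
        if mode == 0:
            pairs[i] = j
            pairs[j] = i
            pt = ptab[enc[i], enc[j]]
            v = V[i, j]
            if v == hairpin[j - i - 1]:
                hp = True
            else:
                hp = False
            done = False
            kmax = min(i + 1 + MAXLOOP, j - 4)
            for k in range(i + 1, kmax + 1):
                if done:
                    break
                s1 = k - i - 1
                lmin = j - 1 - (MAXLOOP - s1)
                if lmin < k + 4:
                    lmin = k + 4
                for l in range(j - 1, lmin - 1, -1):
                    vkl = V[k, l]
                    if vkl >= INF:
                        continue
                    s2 = j - l - 1
                    if s1 == 0 and s2 == 0:
                        e = stack[pt, ptab[enc[k], enc[l]]] + vkl
                    elif s1 == 0 or s2 == 0:
                        e = bulge[s1 + s2] + vkl
                    else:
                        e = internal[s1 + s2] + vkl
                    if e == v:
                        st_i[top] = k
                        st_j[top] = l
                        st_m[top] = 0
                        top += 1
                        done = True
                        break
            if done:
                continue
            if hp:
                continue
            for k in range(i + 2, j - 1):
                a = M[i + 1, k]
                b = M[k + 1, j - 1]
                if a < INF and b < INF and MULTI_CLOSE + MULTI_BRANCH + a + b == v:
                    st_i[top] = i + 1
                    st_j[top] = k
                    st_m[top] = 1
                    top += 1
                    st_i[top] = k + 1
                    st_j[top] = j - 1
                    st_m[top] = 1
                    top += 1
                    break
        else:
            m = M[i, j]
            if V[i, j] < INF and V[i, j] + MULTI_BRANCH == m:
                st_i[top] = i
                st_j[top] = j
                st_m[top] = 0
                top += 1
                continue
            if M[i + 1, j] < INF and M[i + 1, j] + MULTI_UNPAIRED == m:
                st_i[top] = i + 1
                st_j[top] = j
                st_m[top] = 1
                top += 1
                continue
            if M[i, j - 1] < INF and M[i, j - 1] + MULTI_UNPAIRED == m:
                st_i[top] = i
                st_j[top] = j - 1
                st_m[top] = 1
                top += 1
                continue
            for k in range(i + 4, j - 4):
                a = M[i, k]
                b = M[k + 1, j]
                if a < INF and b < INF and a + b == m:
                    st_i[top] = i
                    st_j[top] = k
                    st_m[top] = 1
                    top += 1
                    st_i[top] = k + 1
                    st_j[top] = j
                    st_m[top] = 1
                    top += 1
                    break
    return pairs


def encode_rna(sequence: str) -> np.ndarray:
    """Encode an RNA string (A/C/G/U) as an int8 array; raise on other characters."""
    try:
        return np.array([ENCODE[b] for b in sequence], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"invalid RNA base {exc.args[0]!r}") from None


def fold_mfe(sequence: str) -> FoldResult:
    """Fold one RNA sequence, returning the MFE structure.

    Parameters
    ----------
    sequence : str
        RNA, uppercase A/C/G/U, 1..450 nt.  DNA callers must convert T to U
        first (the pipeline does this at the folding boundary only).
    """
    if not 1 <= len(sequence) <= MAXSEQ:
        raise ValueError(f"sequence length must be in [1, {MAXSEQ}]")
    enc = encode_rna(sequence)
    n = len(enc)
    if n < 5:
        return FoldResult(sequence, "." * n, 0.0, np.full(n, -1, dtype=np.int32))
    V, M, W = _fill(enc, PAIR_TABLE, STACK, HAIRPIN, BULGE, INTERNAL)
    pairs = _traceback(enc, PAIR_TABLE, STACK, HAIRPIN, BULGE, INTERNAL, V, M, W)
    structure = "".join(
        "." if p < 0 else ("(" if p > k else ")") for k, p in enumerate(pairs)
    )
    return FoldResult(sequence, structure, W[0] / 10.0, pairs)


def fold_energy(sequence: str) -> float:
    """MFE in kcal/mol without the traceback (cheaper for gating scans)."""
    if not 1 <= len(sequence) <= MAXSEQ:
        raise ValueError(f"sequence length must be in [1, {MAXSEQ}]")
    enc = encode_rna(sequence)
    if len(enc) < 5:
        return 0.0
    _, _, W = _fill(enc, PAIR_TABLE, STACK, HAIRPIN, BULGE, INTERNAL)
    return W[0] / 10.0
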