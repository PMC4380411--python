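"""Nearest-neighbor free-energy parameters for RNA secondary structure.

All energies are 37 degC free energies in units of 0.1 kcal/mol (integers),
so the dynamic program and the exhaustive-enumeration oracle used in the test
suite do exact integer arithmetic on the identical parameter set.

The model is deliberately compact: Watson-Crick and G:U wobble pairs,
stacking energies (Turner-2004-style values), affine penalties for hairpin,
bulge and internal loops with Jacobson-Stockmayer logarithmic extrapolation,
and a linear multiloop penalty.  No dangling ends, no coaxial stacking, no
terminal-AU penalty, no tetraloop bonuses: the pipeline only uses the folding
energy as a stability gate (pass/fail at -20 kcal/mol), not as a quantitative
thermodynamic prediction.
"""

from __future__ import annotations

import math

import numpy as np

#: Base encoding used throughout the folding code.
BASE_ORDER = "ACGU"
ENCODE = {b: i for i, b in enumerate(BASE_ORDER)}

#: Pair-type indices.  -1 marks an unpairable base combination.
PAIRS = ["AU", "CG", "GC", "UA", "GU", "UG"]
AU, CG, GC, UA, GU, UG = range(6)

PAIR_TABLE = np.full((4, 4), -1, dtype=np.int8)
for _idx, _p in enumerate(PAIRS):
    PAIR_TABLE[ENCODE[_p[0]], ENCODE[_p[1]]] = _idx

#: Stacking free energies S[outer][inner] where ``outer`` is the pair (i, j)
#: and ``inner`` the pair (i+1, j-1), both read 5'->3' on the first strand.
#: Units 0.1 kcal/mol.  The table satisfies the physical symmetry
#: S[p][q] == S[rev(q)][rev(p)] with rev(XY) = YX.
STACK = np.array(
    [
        #  AU    CG    GC    UA    GU    UG
        [-9, -22, -21, -11, -6, -14],   # AU
        [-21, -33, -24, -21, -14, -21], # CG
        [-24, -34, -33, -22, -15, -25], # GC
        [-13, -24, -21, -9, -13, -10],  # UA
        [-10, -25, -21, -14, -5, 13],   # GU
        [-13, -15, -14, -6, 3, -5],     # UG
    ],
    dtype=np.int32,
)

#: Largest loop size for which internal/bulge loops are searched explicitly.
MAXLOOP = 30

#: Longest sequence the folding routines accept.
MAXSEQ = 450

#: 1.75 * R * T at 310.15 K, kcal/mol, for loop-size extrapolation.
_LOG_COEF = 1.75 * 0.0019872 * 310.15


def _extrapolate(table: dict[int, float], ref: int, n_max: int) -> np.ndarray:
    """Expand a sparse loop-initiation table to an int array of length n_max+1."""
    out = np.full(n_max + 1, 2 ** 20, dtype=np.int32)
    for size, dg in table.items():
        out[size] = round(dg * 10)
    for size in range(ref + 1, n_max + 1):
        if out[size] >= 2 ** 20:
            out[size] = out[ref] + round(10 * _LOG_COEF * math.log(size / ref))
    return out


# Hairpin loops of size < 3 are sterically forbidden (left at the sentinel).
HAIRPIN = _extrapolate(
    {3: 5.4, 4: 5.6, 5: 5.7, 6: 5.4, 7: 6.0, 8: 5.5, 9: 6.4}, 9, MAXSEQ
)
BULGE = _extrapolate({1: 3.8, 2: 2.8, 3: 3.2, 4: 3.6, 5: 4.0, 6: 4.4}, 6, MAXSEQ)
INTERNAL = _extrapolate({2: 1.7, 3: 1.8, 4: 2.0, 5: 2.0, 6: 2.2}, 6, MAXSEQ)

#: Multiloop penalty: MULTI_CLOSE + MULTI_BRANCH per branch (the closing pair
#: counts as a branch) + MULTI_UNPAIRED per unpaired loop base.
MULTI_CLOSE = 34
MULTI_BRANCH = 4
MULTI_UNPAIRED = 0

INF = 1 << 28


def _check_symmetry() -> None:
    rev = {AU: UA, UA: AU, CG: GC, GC: CG, GU: UG, UG: GU}
    for p in range(6):
        for q in range(6):
            assert STACK[p, q] == STACK[rev[q], rev[p]], (p, q)


_check_symmetry()
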