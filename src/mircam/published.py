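"""Published camelina small-RNA read-count tables used as worked examples.

These are the printed per-library totals and per-family read counts from a
deep-sequencing study of *Camelina sativa* leaves, flower buds and two
seed-development stages (13 and 19 days after flowering).  They serve as
fixed inputs: the package's arithmetic (retention percentages, signed fold
changes) must reproduce the study's printed derived values from these
counts.  Only counts are stored here — every derived number is recomputed.
"""

from __future__ import annotations

import pandas as pd

LIBRARIES = ("leaves", "buds", "seed13", "seed19")

#: per-library raw and filtered read totals.
RAW_FILTERED_COUNTS: dict[str, tuple[int, int]] = {
    "leaves": (9_856_027, 7_951_133),
    "buds": (9_857_386, 8_321_249),
    "seed13": (9_148_826, 8_938_448),
    "seed19": (10_596_879, 9_135_921),
}

#: per-family read counts (leaves, buds, seed13, seed19) for the families
#: the study reported as tissue-variable.
FAMILY_COUNTS: dict[str, tuple[int, int, int, int]] = {
    "miR156": (1627, 777, 5536, 10364),
    "miR159": (18462, 21199, 16976, 34027),
    "miR160": (277, 530, 32, 179),
    "miR164": (107, 89, 150, 50),
    "miR165": (40625, 179353, 185703, 214186),
    "miR166": (236851, 528018, 634519, 1110941),
    "miR167": (3253, 1726, 13362, 6405),
    "miR168": (656, 1407, 2373, 1180),
    "miR169": (269, 183, 213, 109),
    "miR170": (46, 61, 73, 93),
    "miR171": (388, 453, 193, 355),
    "miR172": (817, 948, 594, 223),
    "miR173": (422, 557, 868, 1031),
    "miR319": (69, 3988, 378, 2514),
    "miR393": (74, 38, 68, 30),
    "miR395": (74, 63, 344, 32),
    "miR396": (2995, 1486, 710, 923),
    "miR398": (12, 11, 796, 479),
    "miR403": (5775, 4245, 2018, 3251),
    "miR408": (4, 8, 173, 23),
    "miR825": (5261, 4227, 1198, 2593),
    "miR824": (82, 92, 157, 698),
    "miR827": (7, 196, 239, 647),
    "miR858": (13, 74, 211, 500),
    "miR2910": (2667, 1824, 1408, 835),
    "miR4995": (228, 95, 9, 7),
    "miR6300": (4981, 89137, 7872, 12800),
    "miR6173": (75, 7, 1, 1),
}


def family_count_table() -> pd.DataFrame:
    """The published family counts as a families x libraries DataFrame."""
    return pd.DataFrame.from_dict(
        FAMILY_COUNTS, orient="index", columns=list(LIBRARIES)
    ).rename_axis("family")


def raw_filtered_table() -> pd.DataFrame:
    """The published per-library raw/filtered totals as a DataFrame."""
    return pd.DataFrame.from_dict(
        RAW_FILTERED_COUNTS, orient="index", columns=["unfiltered", "filtered"]
    ).rename_axis("library")
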