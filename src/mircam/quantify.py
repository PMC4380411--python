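"""Expression tables, family aggregation, normalization and fold changes.

Counts are raw collapsed-tag read counts per library.  Families aggregate by
exact integer summation of their member rows.  Fold changes follow the
signed convention of published read-count tables: the raw-count ratio
rounded half-up to one decimal, reported as a negative reciprocal when the
second library is lower, and only shown when the magnitude reaches 2-fold.
Counts-per-million normalization (against the total miRNA-assigned reads of
each library) is provided as an alternative basis via ``fc_on="normalized"``
for the report builder; the default is raw counts, which is what the
published ratios reproduce exactly.
"""

from __future__ import annotations

import pandas as pd

from ._util import round_half_up

#: default tissue contrasts, (reference, comparison)
DEFAULT_PAIRS = (
    ("leaves", "buds"),
    ("leaves", "seed13"),
    ("leaves", "seed19"),
    ("seed13", "seed19"),
)
MIN_REPORT_COUNT = 50
MIN_REPORT_FC = 2.0


def aggregate_families(counts: pd.DataFrame, families: pd.Series | dict) -> pd.DataFrame:
    """Sum per-miRNA count rows into family rows.

    ``families`` maps each row label of ``counts`` to its family; every
    called miRNA must carry a label.  Family totals are exact integer sums.
    """
    fam = pd.Series(families)
    missing = counts.index.difference(fam.index)
    if len(missing):
        raise ValueError(f"rows without family label: {list(missing)[:5]}")
    out = counts.groupby(fam.reindex(counts.index)).sum()
    out.index.name = "family"
    return out.sort_index(key=lambda ix: _family_sort_key(ix))


def _family_sort_key(index: pd.Index) -> pd.Index:
    def key(name: str):
        digits = "".join(c for c in str(name) if c.isdigit())
        return (0, int(digits)) if digits else (1, str(name))

    return pd.Index([key(n) for n in index])


def signed_fold_change(count_a: float, count_b: float) -> float | None:
    """Signed ratio of B over A at one decimal; None when undefined.

    r = B/A; reported as round(r, 1) when r >= 1 and -round(1/r, 1)
    otherwise, so a decrease appears as a negative fold >= 2 in magnitude.
    Zero on either side is a presence/absence case, not a fold change.
    """
    if count_a < 0 or count_b < 0:
        raise ValueError("counts must be non-negative")
    if count_a == 0 or count_b == 0:
        return None
    ratio = count_b / count_a
    if ratio >= 1.0:
        return round_half_up(ratio, 1)
    return -round_half_up(1.0 / ratio, 1)


def is_reported(fc: float | None, min_fc: float = MIN_REPORT_FC) -> bool:
    """Printed-table rule: only |fold| >= min_fc values are shown."""
    return fc is not None and abs(fc) >= min_fc


def normalize_cpm(counts: pd.DataFrame, totals: pd.Series | None = None) -> pd.DataFrame:
    """Counts per million of miRNA-assigned reads per library.

    ``totals`` defaults to the column sums of ``counts``; a zero total is an
    error (no miRNA reads to normalize against).
    """
    if totals is None:
        totals = counts.sum(axis=0)
    totals = pd.Series(totals).reindex(counts.columns)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"zero miRNA read total in libraries: {bad}")
    return counts / totals * 1e6


def library_share_pct(counts: pd.DataFrame) -> pd.DataFrame:
    """Each row's share of its library total, in integer-rounded percent."""
    share = counts / counts.sum(axis=0) * 100.0
    return share.map(lambda v: round_half_up(v, 0))


def build_table2(
    family_counts: pd.DataFrame,
    pairs: tuple[tuple[str, str], ...] = DEFAULT_PAIRS,
    min_report_count: int = MIN_REPORT_COUNT,
    min_fc: float = MIN_REPORT_FC,
    fc_on: str = "raw",
) -> pd.DataFrame:
    """Per-family report of counts and signed fold changes per tissue pair.

    Rows: families reaching ``min_report_count`` reads in at least one
    library.  Fold-change cells below ``min_fc`` in magnitude (or undefined)
    are left as NA, mirroring the printed-table convention.  ``fc_on``
    chooses the ratio basis: "raw" counts (default; reproduces published
    ratios exactly) or "normalized" (CPM).
    """
    if fc_on not in ("raw", "normalized"):
        raise ValueError("fc_on must be 'raw' or 'normalized'")
    basis = family_counts if fc_on == "raw" else normalize_cpm(family_counts)
    keep = family_counts.max(axis=1) >= min_report_count
    rows = []
    for family in family_counts.index[keep]:
        row: dict = {"family": family}
        for lib in family_counts.columns:
            row[lib] = int(family_counts.loc[family, lib])
        for ref, cmp_ in pairs:
            fc = signed_fold_change(basis.loc[family, ref], basis.loc[family, cmp_])
            row[f"{cmp_}/{ref}"] = fc if is_reported(fc, min_fc) else pd.NA
        rows.append(row)
    return pd.DataFrame(rows).set_index("family") if rows else pd.DataFrame(
        columns=["family", *family_counts.columns,
                 *[f"{c}/{r}" for r, c in pairs]]
    ).set_index("family")
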