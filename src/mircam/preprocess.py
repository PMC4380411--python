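"""Read preprocessing: adapter clipping, quality/length filtering, collapsing.

Raw 50-cycle reads carry only a 3' adapter, so the insert is everything left
of the first adapter occurrence.  Reads are then filtered on mean base
quality (phred >= 26 by default) and insert length (15-27 nt), and collapsed
into unique sequence tags carrying per-library counts, with a summary table
of raw/filtered counts and length histograms per library.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from ._util import round_half_up
from .io import RawRead

MIN_LEN = 15
MAX_LEN = 27


def find_adapter(
    sequence: str, adapter3: str, min_overlap: int = 6, max_mismatches: int = 1
) -> int:
    """Leftmost start of a 3' adapter match, or -1 if none.

    A match is a prefix of the adapter of length >= ``min_overlap`` (shorter
    only when truncated by the read end) aligned at the position with at most
    ``max_mismatches`` mismatches.
    """
    n, m = len(sequence), len(adapter3)
    if m < min_overlap:
        raise ValueError("adapter shorter than min_overlap")
    for start in range(0, n - min_overlap + 1):
        overlap = min(m, n - start)
        if sequence[start : start + overlap] == adapter3[:overlap]:
            return start
        mismatches = 0
        for a, b in zip(sequence[start : start + overlap], adapter3):
            if a != b:
                mismatches += 1
                if mismatches > max_mismatches:
                    break
        if mismatches <= max_mismatches:
            return start
    return -1


def clip_adapter(
    read: RawRead, adapter3: str, min_overlap: int = 6, max_mismatches: int = 1
) -> RawRead | None:
    """Clip the 3' adapter; None means the adapter was not found (discard:
    on a 50-cycle run a read without adapter has unknown insert length)."""
    if len(adapter3) < min_overlap:
        raise ValueError("adapter3 must be at least min_overlap long")
    if not read.sequence:
        return None
    pos = find_adapter(read.sequence, adapter3, min_overlap, max_mismatches)
    if pos < 0:
        return None
    return RawRead(read.id, read.sequence[:pos], read.quality[:pos])


def quality_filter(read: RawRead, min_phred: int = 26, mode: str = "mean") -> bool:
    """Keep iff aggregate phred >= min_phred (inclusive boundary).

    ``mode='mean'`` (default) uses the mean base quality; ``mode='min'``
    requires every base to clear the threshold.
    """
    if not read.quality:
        return False
    if mode == "mean":
        return sum(read.quality) / len(read.quality) >= min_phred
    if mode == "min":
        return min(read.quality) >= min_phred
    raise ValueError(f"unknown quality mode {mode!r}")


def length_filter(sequence: str, min_len: int = MIN_LEN, max_len: int = MAX_LEN) -> bool:
    """Keep iff min_len <= length <= max_len (both inclusive)."""
    return min_len <= len(sequence) <= max_len


@dataclass
class FilterSummary:
    """Per-library filtering bookkeeping (Table-1-style)."""

    library: str
    unfiltered_reads: int = 0
    filtered_reads: int = 0
    discarded_adapter: int = 0
    discarded_quality: int = 0
    discarded_length: int = 0
    discarded_n: int = 0
    unique_tags: int = 0
    length_hist_redundant: dict[int, int] = field(default_factory=dict)
    length_hist_unique: dict[int, int] = field(default_factory=dict)

    @property
    def percent_kept(self) -> float:
        if self.unfiltered_reads == 0:
            return 0.0
        return round_half_up(100.0 * self.filtered_reads / self.unfiltered_reads, 1)

    def check_conservation(self) -> None:
        total = (
            self.filtered_reads
            + self.discarded_adapter
            + self.discarded_quality
            + self.discarded_length
            + self.discarded_n
        )
        if total != self.unfiltered_reads:
            raise AssertionError(
                f"{self.library}: {total} accounted for of {self.unfiltered_reads}"
            )


def filter_library(
    reads: Iterable[RawRead],
    adapter3: str,
    min_phred: int = 26,
    min_len: int = MIN_LEN,
    max_len: int = MAX_LEN,
    min_overlap: int = 6,
    quality_mode: str = "mean",
    library: str = "library",
) -> tuple[list[str], FilterSummary]:
    """Clip + filter one library; returns surviving insert sequences and the
    summary.  Inserts containing N are excluded from tags but counted."""
    summary = FilterSummary(library)
    kept: list[str] = []
    for read in reads:
        summary.unfiltered_reads += 1
        clipped = clip_adapter(read, adapter3, min_overlap)
        if clipped is None:
            summary.discarded_adapter += 1
            continue
        if not quality_filter(clipped, min_phred, quality_mode):
            summary.discarded_quality += 1
            continue
        if not length_filter(clipped.sequence, min_len, max_len):
            summary.discarded_length += 1
            continue
        if "N" in clipped.sequence:
            summary.discarded_n += 1
            continue
        summary.filtered_reads += 1
        length = len(clipped.sequence)
        summary.length_hist_redundant[length] = (
            summary.length_hist_redundant.get(length, 0) + 1
        )
        kept.append(clipped.sequence)
    return kept, summary


def collapse(
    sequences_by_library: dict[str, list[str]],
    summaries: dict[str, FilterSummary] | None = None,
) -> pd.DataFrame:
    """Collapse filtered inserts into unique tags with per-library counts.

    Returns a DataFrame indexed by tag sequence with one integer column per
    library, ordered by total count (desc) then sequence.  Column sums equal
    the filtered read counts exactly.
    """
    libraries = list(sequences_by_library)
    counts = {
        lib: pd.Series(seqs, dtype="object").value_counts()
        for lib, seqs in sequences_by_library.items()
    }
    table = pd.DataFrame(counts).fillna(0).astype(int)
    table.columns = libraries
    table.index.name = "tag"
    order = table.sum(axis=1)
    table = table.loc[
        sorted(table.index, key=lambda t: (-order[t], t))
    ]
    if summaries is not None:
        for lib in libraries:
            s = summaries[lib]
            lib_tags = table[table[lib] > 0]
            s.unique_tags = int(len(lib_tags))
            s.length_hist_unique = (
                lib_tags.index.str.len().value_counts().sort_index().to_dict()
            )
    return table


def summary_table(summaries: dict[str, FilterSummary]) -> pd.DataFrame:
    """Raw/filtered read-count report with a Total row (percent at 1 decimal)."""
    rows = []
    for lib, s in summaries.items():
        rows.append(
            {"Sample": lib, "Unfiltered reads": s.unfiltered_reads,
             "Filtered reads": s.filtered_reads, "%": s.percent_kept}
        )
    total_u = sum(s.unfiltered_reads for s in summaries.values())
    total_f = sum(s.filtered_reads for s in summaries.values())
    pct = round_half_up(100.0 * total_f / total_u, 1) if total_u else 0.0
    rows.append(
        {"Sample": "Total", "Unfiltered reads": total_u, "Filtered reads": total_f, "%": pct}
    )
    return pd.DataFrame(rows)


def percent_unique(unique: int, filtered: int, ndigits: int = 2) -> float:
    """Share of unique tags among filtered reads, as a printed percentage."""
    if filtered == 0:
        return 0.0
    return round_half_up(100.0 * unique / filtered, ndigits)
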