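#!/usr/bin/env python
"""Clip adapters, filter on quality (mean phred >= 26) and length (15-27 nt),
collapse to unique tags; write the per-library retention summary.

Reads results/data/, writes results/preprocess/.
"""

from pathlib import Path

from mircam.io import read_fastq
from mircam.preprocess import collapse, filter_library, percent_unique, summary_table
from mircam.synthdata import DEFAULT_ADAPTER3, DEFAULT_LIBRARIES

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    outdir = BASE / "preprocess"
    outdir.mkdir(parents=True, exist_ok=True)
    sequences, summaries = {}, {}
    for lib in DEFAULT_LIBRARIES:
        kept, summary = filter_library(
            read_fastq(BASE / "data" / f"{lib}.fastq"), DEFAULT_ADAPTER3, library=lib
        )
        summary.check_conservation()
        sequences[lib], summaries[lib] = kept, summary
    tags = collapse(sequences, summaries)
    tags.to_csv(outdir / "tags.tsv", sep="\t")
    table = summary_table(summaries)
    table.to_csv(outdir / "filter_summary.tsv", sep="\t", index=False)
    print(table.to_string(index=False))
    filtered = int(table.loc[table["Sample"] == "Total", "Filtered reads"].iloc[0])
    print(f"{len(tags)} unique tags "
          f"({percent_unique(len(tags), filtered)}% of filtered reads)")


if __name__ == "__main__":
    main()
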