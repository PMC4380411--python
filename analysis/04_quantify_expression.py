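#!/usr/bin/env python
"""Aggregate called miRNAs into families, normalize to counts-per-million,
and build the tissue fold-change report (raw-count ratios, >= 2-fold shown,
families with >= 50 reads).

Reads results/discovery/, writes results/quantify/.
"""

from pathlib import Path

import pandas as pd

from mircam.pipeline import _contrast_pairs
from mircam.quantify import build_table2, normalize_cpm

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    outdir = BASE / "quantify"
    outdir.mkdir(parents=True, exist_ok=True)
    fam = pd.read_csv(BASE / "discovery" / "family_counts.tsv", sep="\t", index_col=0)
    counts = pd.read_csv(BASE / "discovery" / "mirna_counts.tsv", sep="\t", index_col=0)
    normalize_cpm(counts).to_csv(outdir / "mirna_cpm.tsv", sep="\t", float_format="%.2f")
    table = build_table2(fam, _contrast_pairs(list(fam.columns)))
    table.to_csv(outdir / "fold_changes.tsv", sep="\t", na_rep="")
    print(table.to_string())
    reported = table[[c for c in table.columns if "/" in c]].notna().sum().sum()
    print(f"{len(table)} families over the 50-read gate; "
          f"{int(reported)} fold changes at >= 2-fold")


if __name__ == "__main__":
    main()
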