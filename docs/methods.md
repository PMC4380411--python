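# Methods

## Scope and model

The package treats plant miRNA discovery as a chain of explicit, testable
decisions over small-RNA sequencing libraries: adapter clipping → quality
and length filters → tag collapsing → genome anchoring → reference
classification → abundance gating → hairpin-structure criteria → decoy
exclusion → quantification → target prediction. Every stage is a pure
function over in-memory containers (pandas DataFrames, dataclasses), and
the pipeline orchestrator only sequences them, so each threshold can be
probed at its boundary in isolation.

## RNA secondary structure model

`mircam.fold` implements a Zuker-style minimum-free-energy dynamic program
over a compact nearest-neighbor model (parameters in `mircam._energy`,
integers in 0.1 kcal/mol at 37 °C):

- Watson–Crick and G:U pairs; Turner-2004-style stacking free energies,
  symmetrized so a duplex scores identically from either strand.
- Affine hairpin/bulge/internal-loop initiation tables with
  Jacobson–Stockmayer logarithmic extrapolation (1.75·RT·ln n) beyond the
  tabulated sizes; minimum hairpin loop 3 nt; interior loops capped at
  30 unpaired nt (the standard nearest-neighbor cap — unreachable for the
  ≤ 20-nt oracle sequences, so DP-vs-enumeration equality is exact).
- Linear multiloop penalty 3.4 + 0.4·branches kcal/mol, no per-unpaired
  charge; no dangles, coaxial stacking, terminal-AU penalties or special
  tetraloops.

The simplifications are deliberate: the pipeline uses folding only as a
stability *gate* (MFE < −20 kcal/mol), not as a quantitative
thermodynamic prediction, so the model needs to rank hairpins correctly
rather than match a reference folder decimal-for-decimal. An exhaustive
structure enumerator in the test suite scores structures by independent
loop decomposition over the same parameter table and must agree with the
DP exactly on random panels. Traceback ties prefer pairing the leftmost 5′
base, making structures deterministic. The fill and traceback are
numba-compiled (pure-Python fallback); a 150-nt fold takes ~4 ms.

## Hairpin criteria and precursor refinement

A candidate passes when (i) MFE is strictly below −20 kcal/mol, (ii) the
stem-loop is at most 210 nt, and (iii) at least 75% of the mature's bases
pair into the star span. The star is located from the fold: the partners
of the mature's outermost paired bases, shifted +2 nt for the 2-nt 3′
overhangs a Dicer duplex leaves, clamped at the precursor ends. A star is
absent when fewer than half the mature bases pair, when the implied span
overlaps the mature, or when its length deviates from the mature length by
more than 8 nt — a span assembled from scattered helices is not a duplex,
and this sanity bound is what keeps random windows from passing criterion
(iii).

The 210-nt cap is kept configurable because the underlying catalogue
itself reports one 213-nt precursor while stating the sub-210 criterion;
the discrepancy is documented rather than resolved, and the default
follows the stated criterion.

Because the anchored window (±200 nt) is far longer than a real precursor,
`refine_precursor` scans sub-windows containing the mature (lengths
52–240 nt on a 10-nt grid, then 1-nt end polishing) and returns the
*smallest* passing sub-window, breaking length ties by MFE density
(mfe/length). Minimal length is the primary key on purpose: a passing
hairpin plus random flank can accidentally improve raw energy density, and
a real precursor does not grow by absorbing flank. With this rule the
refined span recovers implanted precursor ends to within ±10 nt.

## Thresholds (defaults)

| parameter | default | meaning |
|---|---|---|
| min_phred | 26 | mean base quality to keep a read (mean, not per-base: a per-base rule at 26 would discard nearly everything on typical data; `quality_mode="min"` is available) |
| min/max insert | 15 / 27 nt | small-RNA size window, inclusive |
| adapter overlap | 6 nt, ≤ 1 mismatch | leftmost prefix match of the 3′ adapter; reads without adapter are discarded (insert length unknown) |
| multimap cap | 20 | anchors reported per tag, ordered (contig, coordinate) |
| homology | ≤ 3 mismatches | equal-length Hamming vs matures, windowed vs precursors; ties → smallest reference id |
| abundance gate | > 80 reads (≥ 81) | raw counts in at least one library, no normalization at this gate |
| flank | 200 nt | window extracted each side of the anchor |
| MFE gate | < −20 kcal/mol | strict inequality |
| precursor cap | ≤ 210 nt | inclusive |
| complementarity | ≥ 75% | inclusive, half-up rounded to 1 decimal |
| decoy block | 18 nt | exact shared block with decoy ncRNA disqualifies (either orientation) |
| report gates | ≥ 50 reads, \|fc\| ≥ 2 | family fold-change table |
| target gates | 25 / 20 | strict / relaxed alignment-score thresholds |

Fold changes are computed on **raw counts** by default: the published
per-family ratios (e.g. 3988/69 = 57.8) are exact raw-count ratios, even
though the accompanying prose describes normalization to per-library miRNA
totals. Both modes are shipped (`fc_on="raw" | "normalized"`); the default
reproduces the printed table. Rounding everywhere is half-up (decimal),
not banker's, matching printed-table conventions.

Target-alignment scoring (+2/−3, gap open −5 first base, −2 extension,
G:U not rewarded, miRNA reverse complement vs transcript sense strand) is
a design choice: the original score gates came from an unspecified BLAST
configuration, so the constants were fixed once such that a perfect
~21-nt site scores ~42 and the 25/20 gates separate light from heavy
mismatch loads; they are config-exposed. Alignment is delegated to
biopython's PairwiseAligner and validated against an independent textbook
Gotoh DP; the reported alignment is the first co-optimal one in
deterministic DP order.

## Synthetic data generator

`mircam.synthdata` emulates the statistical structure the analysis
assumes, with a truth table for every implanted locus:

- **Libraries:** four tissues (leaves, buds, seed13, seed19), 10,000
  50-cycle reads each by default, inserts + TruSeq small-RNA 3′ adapter,
  random pad beyond the adapter, Sanger phred+33.
- **Loci:** 12 known + 6 novel hairpin loci implanted on both strands of a
  random 100-kb genome. Precursors are mature + {A,C}-only loop (12–40 nt,
  unpairable with itself) + complementary arm with 0–1 point bulges; star
  arms carry 2-nt 3′ overhangs. Matures are drawn with a rejection gate on
  designed-duplex stacking energy (≤ −38 kcal/mol; ≤ −33 for novel) so
  every implanted locus genuinely clears the −20 kcal/mol criterion —
  verified by folding 100 generator draws in the suite. Novel matures are
  2-substitution variants of known references, so homology-mode discovery
  can find them.
- **Abundances:** Zipf law (α = 0.7) over loci with a per-library cyclic
  rank rotation, giving every locus > 80 expected reads in every library
  (recovery is testable) while producing strong tissue contrast for the
  fold-change report; per-(locus, arm) counts are multinomial draws. Star
  reads are 6% of miRNA reads. Expected counts recorded in the truth table
  sum exactly to the miRNA-derived read number per library.
- **Background (50% of reads):** 40% random genome fragments (15–30 nt,
  exercising the length filter), 30% 24-nt genome fragments mimicking the
  24-nt siRNA peak of seed libraries (they anchor but have no hairpin and
  must never be called), 30% fragments of 8 implanted tRNA-like decoy
  ncRNAs concentrated in hotspots (abundant enough to reach candidacy in
  de-novo mode, removed by the decoy filter).
- **Noise:** 0.1% per-base substitution rate (the source protocol states
  none; exposed as a parameter), and a 5% low-quality read fraction
  (mean phred 20 vs 35) giving the phred-26 filter a known reject class.
- Everything derives from one seeded numpy Generator; outputs are
  byte-identical under a fixed seed.

What the generator does **not** emulate: an allohexaploid repeat
structure, realistic base composition or transcriptome context, ligation
bias, PCR duplicates, or miRBase-scale reference sets. Passing recovery
tests therefore demonstrates correctness of the pipeline's logic and
thresholds on clean heavy-tailed data, not performance on real camelina
libraries.

## Problem sizes used in validation

The suite validates at sizes chosen for thorough-but-fast coverage:
folding oracle equivalence on 200 random sequences ≤ 20 nt (exhaustive
enumeration), alignment oracle on 60 short transcripts plus a 400-trial
spurious-hit calibration, Hamming oracle on 200 tags × 50 references,
end-to-end recovery on the default 4 × 10,000-read dataset (seed 42), and
25 random-window refinements for the false-positive rate of the hairpin
search (≤ 1/25 passing). Determinism is checked by re-running a reduced
pipeline and comparing output checksums.

## Known limitations

- The energy parameters are a compact subset of a full nearest-neighbor
  table; absolute MFEs differ from reference folders by a few kcal/mol on
  long sequences (an optional external cross-check hook exists but is
  never required).
- Exact-only genome matching (no mismatched or gapped anchoring); tags
  containing N are never anchored.
- Known-miRNA counts sum only exactly-matching tags; no fractional
  assignment of multi-family tags (ties go to the lexicographically first
  family and are flagged).
- No statistical differential-expression testing — the fold-change table
  is thresholded arithmetic, as in the source analysis; no replicates are
  modelled.
- The published headline catalogue counts (hundreds of known miRNAs,
  thousands of targets) depend on full-scale libraries, the real genome
  and database versions, and are out of scope; the package asserts the
  arithmetic and the method, not the catalogue.
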