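"""End-to-end orchestration: reads -> miRNA calls -> tables -> targets.

Stage order: preprocess -> genome anchoring -> known/homolog matching ->
abundance gate -> precursor window folding and criteria -> decoy exclusion
-> quantification -> target prediction.  Known miRNAs (exact reference
matches) are always retained; those whose locus fails the structural
criteria are flagged "no-structure" rather than dropped.  Novel calls must
pass every gate.

Execution is single-process and deterministic: identical inputs and
parameters reproduce byte-identical non-log outputs, recorded as sha256
checksums in a run manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import hairpin as hp
from . import preprocess as pp
from . import quantify as qt
from . import seqmatch as sm
from . import targets as tg
from .io import (
    read_fasta,
    read_fastq,
    read_flat_config,
    revcomp,
    write_bed,
    write_dot_bracket,
    write_fasta,
    write_gff3,
)


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """All stage inputs and thresholds (defaults are the analysis defaults)."""

    fastq: dict[str, Path] = field(default_factory=dict)  # library -> path
    genome: Path | None = None
    mature_ref: Path | None = None
    precursor_ref: Path | None = None
    decoys: Path | None = None
    cds: Path | None = None
    annotation: Path | None = None
    lipid_list: Path | None = None
    outdir: Path = Path("results/run")

    adapter3: str = "TGGAATTCTCGGGTGCCAAGG"
    min_phred: int = 26
    quality_mode: str = "mean"
    min_len: int = 15
    max_len: int = 27
    flank: int = 200
    min_mfe: float = -20.0
    max_precursor_len: int = 210
    min_complementarity: float = 75.0
    #: novel candidacy needs a raw count of at least this in some library
    #: (i.e. strictly more than 80 reads).
    min_novel_count: int = 81
    min_report_count: int = 50
    min_fc: float = 2.0
    fc_on: str = "raw"
    min_score: float = 25.0
    lipid_min_score: float = 20.0
    novel_mode: str = "homology"  # or "denovo"
    multimap_cap: int = 20
    seed: int = 0

    def validate(self) -> None:
        if not self.fastq:
            raise PipelineError("no FASTQ libraries configured")
        for name, path in [("genome", self.genome), ("mature_ref", self.mature_ref)]:
            if path is None:
                raise PipelineError(f"missing required input: {name}")
        paths = list(self.fastq.values()) + [
            p
            for p in (self.genome, self.mature_ref, self.precursor_ref,
                      self.decoys, self.cds, self.annotation, self.lipid_list)
            if p is not None
        ]
        for path in paths:
            if not Path(path).exists():
                raise PipelineError(f"input file not found: {path}")
        if self.novel_mode not in ("homology", "denovo"):
            raise PipelineError(f"novel_mode must be homology|denovo, got {self.novel_mode}")
        if len(self.adapter3) < 6:
            raise PipelineError("adapter3 must be at least 6 nt")
        if not (0 < self.min_len <= self.max_len):
            raise PipelineError("bad length window")
        if self.min_mfe >= 0:
            raise PipelineError("min_mfe must be negative (kcal/mol)")
        if not 0 <= self.min_complementarity <= 100:
            raise PipelineError("min_complementarity must be a percentage")

    @classmethod
    def from_file(cls, path: str | Path, overrides: dict[str, str] | None = None):
        """Flat key=value config; ``fastq.<library> = path`` declares inputs.
        CLI overrides take precedence."""
        values = read_flat_config(path)
        if overrides:
            values.update(overrides)
        cfg = cls()
        base = Path(path).parent
        for key, raw in values.items():
            if key.startswith("fastq."):
                cfg.fastq[key.split(".", 1)[1]] = base / raw
                continue
            if not hasattr(cfg, key):
                raise PipelineError(f"unknown config key {key!r}")
            current = getattr(cfg, key)
            if key in ("genome", "mature_ref", "precursor_ref", "decoys", "cds",
                       "annotation", "lipid_list", "outdir"):
                setattr(cfg, key, base / raw)
            elif isinstance(current, bool):
                setattr(cfg, key, raw.lower() in ("1", "true", "yes"))
            elif isinstance(current, int):
                setattr(cfg, key, int(raw))
            elif isinstance(current, float):
                setattr(cfg, key, float(raw))
            else:
                setattr(cfg, key, raw)
        return cfg


@dataclass
class MiRNARecord:
    """One called miRNA (known or novel)."""

    mirna_id: str
    sequence: str  # DNA
    family: str
    known: bool
    status: str  # "ok" | "no-structure"
    counts: dict[str, int]
    anchors: list[sm.GenomeAnchor]
    precursor: hp.HairpinCandidate | None
    ref_id: str = ""
    mismatches: int = 0

    @property
    def max_count(self) -> int:
        return max(self.counts.values()) if self.counts else 0


@dataclass
class PipelineResult:
    config: PipelineConfig
    summaries: dict[str, pp.FilterSummary]
    tags: pd.DataFrame
    records: list[MiRNARecord]
    counts: pd.DataFrame
    family_counts: pd.DataFrame
    cpm: pd.DataFrame
    table2: pd.DataFrame
    target_hits: list[tg.TargetHit]
    lipid_hits: list[tg.TargetHit]
    manifest: dict
    #: per-candidate structural measurements before gating (for threshold
    #: re-application without re-folding).
    candidate_metrics: pd.DataFrame = field(default_factory=pd.DataFrame)


def _log(msg: str) -> None:
    print(f"[mircam] {msg}", file=sys.stderr)


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    digest.update(path.read_bytes())
    return digest.hexdigest()


def discover_candidates(
    tags_df: pd.DataFrame,
    genome: dict[str, str],
    mature_ref: dict[str, str],
    precursor_ref: dict[str, str] | None,
    decoys: dict[str, str] | None,
    config: PipelineConfig,
) -> tuple[list[MiRNARecord], pd.DataFrame]:
    """Anchor tags, classify known/homolog, gate, fold, decoy-filter.

    Returns the called records plus a metrics table of every folded novel
    candidate (tag, counts, mfe, length, complementarity, decoy flag) so
    thresholds can be re-applied cheaply.
    """
    libraries = list(tags_df.columns)
    index = sm.GenomeIndex(genome)
    all_tags = list(tags_df.index)
    anchors, anchored = sm.anchor_to_genome(all_tags, index, config.multimap_cap)
    _log(f"anchored {len(anchored)}/{len(all_tags)} tags")

    known_hits = sm.match_known(anchored, mature_ref)
    remaining = [t for t in anchored if t not in known_hits]

    if config.novel_mode == "homology":
        homolog_hits = sm.match_homolog(remaining, mature_ref, precursor_ref)
        candidates = list(homolog_hits)
    else:
        homolog_hits = {}
        candidates = remaining
    # abundance gate: > 80 reads in at least one library
    candidates = [
        t for t in candidates if int(tags_df.loc[t].max()) >= config.min_novel_count
    ]
    _log(f"known tags: {len(known_hits)}; novel candidates after gate: {len(candidates)}")

    records: list[MiRNARecord] = []
    # known miRNAs: group exactly-matching tags by reference id
    by_ref: dict[str, list[str]] = {}
    for tag, hit in known_hits.items():
        by_ref.setdefault(hit.ref_id, []).append(tag)
    for ref_id in sorted(by_ref):
        ref_tags = by_ref[ref_id]
        counts = {
            lib: int(sum(tags_df.loc[t, lib] for t in ref_tags)) for lib in libraries
        }
        tag = max(ref_tags, key=lambda t: int(tags_df.loc[t].sum()))
        tag_anchors = anchors[tag]
        cand = None
        if tag_anchors:
            window = hp.extract_window(tag_anchors[0], genome, config.flank)
            cand = hp.refine_precursor(
                window, config.min_mfe, config.max_precursor_len,
                config.min_complementarity,
            )
        records.append(
            MiRNARecord(
                mirna_id=ref_id,
                sequence=tag,
                family=sm.parse_family(ref_id),
                known=True,
                status="ok" if cand is not None else "no-structure",
                counts=counts,
                anchors=tag_anchors,
                precursor=cand,
                ref_id=ref_id,
            )
        )

    # novel candidates: fold every anchor, keep the best passing precursor
    metric_rows = []
    novel_calls: list[MiRNARecord] = []
    for tag in sorted(candidates, key=lambda t: (-int(tags_df.loc[t].sum()), t)):
        best = None
        for anchor in anchors[tag]:
            window = hp.extract_window(anchor, genome, config.flank)
            cand = hp.refine_precursor(
                window, config.min_mfe, config.max_precursor_len,
                config.min_complementarity,
            )
            if cand is not None and (best is None or cand.mfe < best.mfe):
                best = cand
        hit = homolog_hits.get(tag)
        decoy_flagged = False
        if best is not None and decoys:
            decoy_flagged = bool(sm.match_decoys({"c": best.sequence}, decoys))
        metric_rows.append(
            {
                "tag": tag,
                "max_count": int(tags_df.loc[tag].max()),
                "passed_structure": best is not None,
                "mfe": best.mfe if best is not None else float("nan"),
                "precursor_len": best.stem_loop_len if best is not None else 0,
                "complementarity": (
                    best.complementarity if best is not None else float("nan")
                ),
                "decoy_flagged": decoy_flagged,
                "homolog_ref": hit.ref_id if hit else "",
                "homolog_mismatches": hit.mismatches if hit else -1,
            }
        )
        if best is None or decoy_flagged:
            continue
        novel_calls.append(
            MiRNARecord(
                mirna_id="",  # assigned after deduplication
                sequence=tag,
                family=hit.family if hit else "",
                known=False,
                status="ok",
                counts={lib: int(tags_df.loc[tag, lib]) for lib in libraries},
                anchors=anchors[tag],
                precursor=best,
                ref_id=hit.ref_id if hit else "",
                mismatches=hit.mismatches if hit else -1,
            )
        )

    # deduplicate novel calls whose precursors overlap (same locus seen via
    # several tags); the most abundant tag represents the locus.
    novel_calls.sort(key=lambda r: (-sum(r.counts.values()), r.sequence))
    kept: list[MiRNARecord] = []
    for rec in novel_calls:
        pre = rec.precursor
        duplicate = any(
            k.precursor.contig == pre.contig
            and k.precursor.strand == pre.strand
            and k.precursor.start <= pre.end
            and k.precursor.end >= pre.start
            for k in kept
        )
        if not duplicate:
            kept.append(rec)
    kept.sort(key=lambda r: (r.precursor.contig, r.precursor.start))
    for i, rec in enumerate(kept, start=1):
        rec.mirna_id = f"Csa-miR{i:03d}"
        if not rec.family:
            rec.family = rec.mirna_id
    records.extend(kept)
    metrics = pd.DataFrame(
        metric_rows,
        columns=["tag", "max_count", "passed_structure", "mfe", "precursor_len",
                 "complementarity", "decoy_flagged", "homolog_ref",
                 "homolog_mismatches"],
    )
    return records, metrics


def quantify_records(
    records: list[MiRNARecord], libraries: list[str]
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Counts / family / CPM tables from the called records."""
    counts = pd.DataFrame(
        {lib: {r.mirna_id: r.counts.get(lib, 0) for r in records} for lib in libraries}
    ).fillna(0).astype(int)
    counts.index.name = "mirna"
    families = {r.mirna_id: r.family for r in records}
    if records:
        fam = qt.aggregate_families(counts, families)
        cpm = qt.normalize_cpm(counts) if counts.values.sum() else counts.astype(float)
    else:
        fam = pd.DataFrame(columns=libraries)
        cpm = pd.DataFrame(columns=libraries)
    return counts, fam, cpm


def run_all(config: PipelineConfig) -> PipelineResult:
    """Execute every stage and write the output tree + manifest."""
    config.validate()
    t_start = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"parameters": _jsonable_config(config), "stages": {}, "files": {}}

    # --- preprocess ---------------------------------------------------------
    sequences: dict[str, list[str]] = {}
    summaries: dict[str, pp.FilterSummary] = {}
    for lib, path in config.fastq.items():
        kept, summary = pp.filter_library(
            read_fastq(path), config.adapter3, config.min_phred,
            config.min_len, config.max_len, quality_mode=config.quality_mode,
            library=lib,
        )
        summary.check_conservation()
        sequences[lib] = kept
        summaries[lib] = summary
        _log(f"{lib}: {summary.filtered_reads}/{summary.unfiltered_reads} reads kept "
             f"({summary.percent_kept}%)")
    tags_df = pp.collapse(sequences, summaries)
    manifest["stages"]["preprocess"] = {
        lib: dataclasses.asdict(s) for lib, s in summaries.items()
    }

    genome = read_fasta(config.genome)
    mature_ref = read_fasta(config.mature_ref)
    precursor_ref = read_fasta(config.precursor_ref) if config.precursor_ref else None
    decoys = read_fasta(config.decoys) if config.decoys else None

    records, metrics = discover_candidates(
        tags_df, genome, mature_ref, precursor_ref, decoys, config
    )
    n_known = sum(r.known for r in records)
    n_novel = len(records) - n_known
    _log(f"called {n_known} known + {n_novel} novel miRNAs")
    manifest["stages"]["discover"] = {
        "tags_in": int(len(tags_df)), "known_called": n_known, "novel_called": n_novel,
    }

    libraries = list(tags_df.columns)
    counts, fam, cpm = quantify_records(records, libraries)
    pairs = _contrast_pairs(libraries)
    table2 = (
        qt.build_table2(fam, pairs, config.min_report_count, config.min_fc, config.fc_on)
        if len(fam)
        else pd.DataFrame()
    )

    target_hits: list[tg.TargetHit] = []
    lipid_hits: list[tg.TargetHit] = []
    if config.cds is not None:
        cds = read_fasta(config.cds)
        mirnas = {r.mirna_id: r.sequence for r in records}
        target_hits = tg.scan_targets(mirnas, cds, config.min_score)
        annotation = None
        if config.annotation is not None:
            annotation = pd.read_csv(config.annotation, sep="\t", dtype=str).fillna("")
        target_hits = tg.annotate_hits(target_hits, annotation)
        if config.lipid_list is not None:
            lipid_ids = {
                line.strip()
                for line in Path(config.lipid_list).read_text().splitlines()
                if line.strip()
            }
            lipid_hits = tg.scan_targets(mirnas, cds, config.lipid_min_score, lipid_ids)
            lipid_hits = tg.annotate_hits(lipid_hits, annotation)
        manifest["stages"]["targets"] = {
            "mirnas": len(mirnas), "hits": len(target_hits), "lipid_hits": len(lipid_hits),
        }

    result = PipelineResult(
        config=config, summaries=summaries, tags=tags_df, records=records,
        counts=counts, family_counts=fam, cpm=cpm, table2=table2,
        target_hits=target_hits, lipid_hits=lipid_hits, manifest=manifest,
        candidate_metrics=metrics,
    )
    render_reports(result, outdir)
    for path in sorted(outdir.iterdir()):
        if path.name != "manifest.json" and path.is_file():
            manifest["files"][path.name] = _sha256(path)
    manifest["elapsed_seconds"] = round(time.time() - t_start, 2)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return result


def _jsonable_config(config: PipelineConfig) -> dict:
    out = {}
    for key, value in dataclasses.asdict(config).items():
        if isinstance(value, dict):
            out[key] = {k: str(v) for k, v in value.items()}
        elif isinstance(value, Path):
            out[key] = str(value)
        else:
            out[key] = value
    return out


def _contrast_pairs(libraries: list[str]) -> tuple[tuple[str, str], ...]:
    if set(qt.DEFAULT_PAIRS[0]) <= set(libraries):
        return tuple(p for p in qt.DEFAULT_PAIRS if p[0] in libraries and p[1] in libraries)
    ref = libraries[0]
    return tuple((ref, lib) for lib in libraries[1:])


def render_reports(result: PipelineResult, outdir: Path) -> None:
    """Write every report table and sequence/feature export."""
    outdir.mkdir(parents=True, exist_ok=True)
    pp.summary_table(result.summaries).to_csv(
        outdir / "filter_summary.tsv", sep="\t", index=False
    )
    result.tags.to_csv(outdir / "tags.tsv", sep="\t")
    result.counts.to_csv(outdir / "mirna_counts.tsv", sep="\t")
    if len(result.cpm):
        result.cpm.to_csv(outdir / "mirna_cpm.tsv", sep="\t", float_format="%.2f")
    result.family_counts.to_csv(outdir / "family_counts.tsv", sep="\t")
    table2 = result.table2.copy()
    table2.to_csv(outdir / "table2.tsv", sep="\t", na_rep="")

    rows = []
    bed_rows = []
    gff_rows = []
    fasta_records = []
    dot_records = []
    for rec in result.records:
        pre = rec.precursor
        rows.append(
            {
                "mirna": rec.mirna_id, "sequence": rec.sequence,
                "family": rec.family, "known": rec.known, "status": rec.status,
                "ref_id": rec.ref_id, "mismatches": rec.mismatches,
                "n_loci": len(rec.anchors),
                "precursor_len": pre.stem_loop_len if pre else 0,
                "mfe": pre.mfe if pre else "",
                "complementarity": pre.complementarity if pre else "",
                **{f"count_{lib}": c for lib, c in rec.counts.items()},
            }
        )
        for anchor in rec.anchors:
            bed_rows.append(
                (anchor.contig, anchor.start, anchor.end, rec.mirna_id,
                 rec.max_count, anchor.strand)
            )
        if pre is not None:
            fasta_records.append((f"{rec.mirna_id}_precursor", pre.sequence))
            dot_records.append(
                (rec.mirna_id, pre.fold.sequence, pre.fold.structure, pre.mfe)
            )
            gff_rows.append(
                (pre.contig, "miRNA_primary_transcript", pre.start, pre.end,
                 pre.strand, f"ID={rec.mirna_id}_pre")
            )
            m_lo, m_hi = _feature_span(pre, pre.mature_offset, pre.mature_len)
            gff_rows.append(
                (pre.contig, "miRNA", m_lo, m_hi, pre.strand,
                 f"ID={rec.mirna_id};Parent={rec.mirna_id}_pre")
            )
            if pre.star_offset is not None:
                s_lo, s_hi = _feature_span(pre, pre.star_offset, pre.star_len)
                gff_rows.append(
                    (pre.contig, "miRNA_star", s_lo, s_hi, pre.strand,
                     f"ID={rec.mirna_id}_star;Parent={rec.mirna_id}_pre")
                )
    known = [r for r in rows if r["known"]]
    novel = [r for r in rows if not r["known"]]
    cols = list(rows[0].keys()) if rows else []
    pd.DataFrame(known, columns=cols).to_csv(outdir / "known_mirnas.tsv", sep="\t", index=False)
    pd.DataFrame(novel, columns=cols).to_csv(outdir / "novel_mirnas.tsv", sep="\t", index=False)
    write_bed(outdir / "anchors.bed", bed_rows)
    write_gff3(outdir / "precursors.gff3", gff_rows)
    write_fasta(outdir / "precursors.fa", fasta_records)
    write_dot_bracket(outdir / "precursors.dot", dot_records)
    if result.target_hits:
        tg.hits_table(result.target_hits).to_csv(outdir / "targets.tsv", sep="\t", index=False)
        tally = tg.tally_go(result.target_hits)
        tally.rename_axis("go_term").rename("hits").to_csv(outdir / "go_tally.tsv", sep="\t")
    if result.lipid_hits:
        tg.hits_table(result.lipid_hits).to_csv(outdir / "lipid_targets.tsv", sep="\t", index=False)


def _feature_span(pre: hp.HairpinCandidate, offset: int, length: int) -> tuple[int, int]:
    """Genomic 1-based span of a sub-feature of an (oriented) precursor."""
    if pre.strand == "+":
        return pre.start + offset, pre.start + offset + length - 1
    return pre.end - (offset + length - 1), pre.end - offset


def reapply_gates(
    metrics: pd.DataFrame,
    min_mfe: float = -20.0,
    max_len: int = 210,
    min_complementarity: float = 75.0,
    min_novel_count: int = 81,
) -> pd.DataFrame:
    """Re-apply the novel-call gates to a candidate-metrics table (no
    re-folding).  Used to study gate monotonicity."""
    ok = (
        (metrics["max_count"] >= min_novel_count)
        & metrics["passed_structure"]
        & (metrics["mfe"] < min_mfe)
        & (metrics["precursor_len"] <= max_len)
        & (metrics["complementarity"] >= min_complementarity)
        & ~metrics["decoy_flagged"]
    )
    return metrics[ok]


def evaluate_against_truth(result: PipelineResult, truth: pd.DataFrame,
                           decoy_spans: pd.DataFrame | None = None) -> dict:
    """Recovery metrics against a simulated truth table."""
    known_truth = truth[truth["known"]]
    novel_truth = truth[~truth["known"]]
    called_known_refs = {r.ref_id for r in result.records if r.known}
    called_sequences = {r.sequence for r in result.records}
    known_recalled = sum(
        1 for _, row in known_truth.iterrows() if row["ref_id"] in called_known_refs
    )
    lib_cols = [c for c in truth.columns if c.startswith("expected_mature_")]
    novel_gated = novel_truth[novel_truth[lib_cols].max(axis=1) > 80]
    novel_records = [r for r in result.records if not r.known]

    def novel_hit(row) -> bool:
        if row["mature_seq"] in called_sequences:
            return True
        for rec in novel_records:
            pre = rec.precursor
            if (
                pre is not None
                and pre.contig == row["contig"]
                and pre.start <= row["end"]
                and pre.end >= row["start"]
            ):
                return True
        return False

    novel_recalled = sum(1 for _, row in novel_gated.iterrows() if novel_hit(row))
    decoy_calls = 0
    if decoy_spans is not None and len(decoy_spans):
        for rec in novel_records:
            pre = rec.precursor
            if pre is None:
                continue
            overlap = (
                (decoy_spans["contig"] == pre.contig)
                & (decoy_spans["start"] <= pre.end)
                & (decoy_spans["end"] >= pre.start)
            )
            if overlap.any():
                decoy_calls += 1
    return {
        "known_total": int(len(known_truth)),
        "known_recalled": int(known_recalled),
        "known_recall": known_recalled / len(known_truth) if len(known_truth) else 1.0,
        "novel_total": int(len(novel_gated)),
        "novel_recalled": int(novel_recalled),
        "novel_recall": novel_recalled / len(novel_gated) if len(novel_gated) else 1.0,
        "decoy_calls": int(decoy_calls),
        "novel_called": len(novel_records),
    }
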