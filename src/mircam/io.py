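"""File-format helpers shared across the pipeline.

FASTA/FASTQ parsing goes through Bio.SeqIO; the small tabular/interval
writers (TSV, BED, GFF3, dot-bracket) are thin and deterministic so that a
re-run with the same seed reproduces byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

_COMPLEMENT = str.maketrans("ACGTUN", "TGCAAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (U treated as T)."""
    return seq.translate(_COMPLEMENT)[::-1]


def dna_to_rna(seq: str) -> str:
    return seq.replace("T", "U")


def rna_to_dna(seq: str) -> str:
    return seq.replace("U", "T")


@dataclass
class RawRead:
    """One sequencing read: id, bases and per-base phred scores."""

    id: str
    sequence: str
    quality: list[int]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise ValueError(f"read {self.id}: sequence/quality length mismatch")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA file as {id: uppercase sequence}; duplicate ids are an error."""
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        records[rec.id] = str(rec.seq).upper()
    return records


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for k in range(0, len(seq), width):
                fh.write(seq[k : k + width] + "\n")


def read_fastq(path: str | Path) -> Iterator[RawRead]:
    """Stream a Sanger (phred+33) FASTQ file."""
    for rec in SeqIO.parse(str(path), "fastq"):
        yield RawRead(
            rec.description or rec.id,
            str(rec.seq).upper(),
            rec.letter_annotations["phred_quality"],
        )


def write_fastq(path: str | Path, reads: Iterable[RawRead]) -> None:
    with open(path, "w") as fh:
        for read in reads:
            qual = "".join(chr(q + 33) for q in read.quality)
            fh.write(f"@{read.id}\n{read.sequence}\n+\n{qual}\n")


def write_bed(path: str | Path, rows: Iterable[tuple]) -> None:
    """Write (contig, start1, end1, name, score, strand) rows as 6-column BED
    (0-based half-open)."""
    with open(path, "w") as fh:
        for contig, start1, end1, name, score, strand in rows:
            fh.write(f"{contig}\t{start1 - 1}\t{end1}\t{name}\t{score}\t{strand}\n")


def write_gff3(path: str | Path, rows: Iterable[tuple]) -> None:
    """Write (contig, type, start1, end1, strand, attributes) rows as GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for contig, ftype, start1, end1, strand, attrs in rows:
            fh.write(
                f"{contig}\tmircam\t{ftype}\t{start1}\t{end1}\t.\t{strand}\t.\t{attrs}\n"
            )


def write_dot_bracket(path: str | Path, entries: Iterable[tuple[str, str, str, float]]) -> None:
    """Write (name, sequence, structure, mfe) in ViennaRNA-style text."""
    with open(path, "w") as fh:
        for name, seq, struct, mfe in entries:
            fh.write(f">{name}\n{seq}\n{struct} ({mfe:.1f})\n")


def read_flat_config(path: str | Path) -> dict[str, str]:
    """Parse a flat ``key = value`` text file ('#' starts a comment)."""
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"malformed config line: {line!r}")
        key, value = line.split("=", 1)
        out[key.strip()] = value.strip()
    return out


def write_flat_config(path: str | Path, values: dict) -> None:
    with open(path, "w") as fh:
        for key, value in values.items():
            fh.write(f"{key} = {value}\n")
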