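"""Synthetic small-RNA sequencing libraries with known ground truth.

The generator emulates the statistical structure a plant small-RNA miRNA
discovery analysis assumes: four tissue libraries (leaves, buds, seed-13,
seed-19) of 50-cycle single-end reads carrying only a 3' adapter; a bimodal
21/24-nt insert length structure (miRNA-sized inserts plus a 24-nt
siRNA-like background class); heavy-tailed (Zipf) locus abundances with
per-library rank rotation so that tissues show strong fold-change contrast;
hairpin precursor loci implanted in a random genome with mature and star
arms and 2-nt 3' duplex overhangs; and a tRNA/rRNA-like decoy class whose
reads are abundant but must never survive miRNA discovery.

Everything is driven by one numpy Generator, so a seed fixes every output
byte-for-byte.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._energy import ENCODE, PAIR_TABLE, STACK
from .io import RawRead, revcomp, write_fasta, write_fastq, write_flat_config

_BASES = np.array(list("ACGT"))
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

DEFAULT_LIBRARIES = ("leaves", "buds", "seed13", "seed19")
#: Illumina TruSeq small-RNA 3' adapter.
DEFAULT_ADAPTER3 = "TGGAATTCTCGGGTGCCAAGG"


class ConfigError(ValueError):
    """Invalid simulation configuration."""


class GeometryError(ValueError):
    """Invalid hairpin geometry request."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition knobs for the synthetic dataset.

    Defaults are the package's standing description of the emulated study:
    four tissue libraries, half the reads miRNA-derived, Zipf-distributed
    locus abundances, and a small star-read fraction.
    """

    seed: int = 42
    genome_length: int = 100_000
    n_known_loci: int = 12
    n_novel_loci: int = 6
    n_decoy_ncrna: int = 8
    libraries: tuple[str, ...] = DEFAULT_LIBRARIES
    reads_per_library: int = 10_000
    mature_length_range: tuple[int, int] = (20, 22)
    star_fraction: float = 0.06
    background_fraction: float = 0.5
    adapter3: str = DEFAULT_ADAPTER3
    abundance_alpha: float = 0.7
    #: fraction of reads drawn from the low-quality mixture component
    #: (mean phred 20), which the phred-26 mean filter rejects.
    low_quality_fraction: float = 0.05
    #: per-base substitution sequencing-error rate.
    error_rate: float = 0.001
    read_length: int = 50

    def __post_init__(self) -> None:
        for name in ("star_fraction", "background_fraction", "low_quality_fraction", "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if len(self.adapter3) < 6:
            raise ConfigError("adapter3 must be at least 6 nt")
        if self.reads_per_library < 0 or self.genome_length <= 0:
            raise ConfigError("sizes must be positive")
        lo, hi = self.mature_length_range
        if not (19 <= lo <= hi <= 24):
            raise ConfigError("mature_length_range must lie within 19-24 nt")
        # rough capacity check; implantation re-checks exactly.
        need = (self.n_known_loci + self.n_novel_loci) * 300 + self.n_decoy_ncrna * 200
        if self.genome_length < need:
            raise ConfigError(
                f"genome_length {self.genome_length} too small for "
                f"{self.n_known_loci + self.n_novel_loci} loci + {self.n_decoy_ncrna} decoys"
            )


@dataclass(frozen=True)
class HairpinLocus:
    """A designed precursor with its mature/star arms (0-based offsets)."""

    precursor: str
    mature: str
    star: str
    mature_offset: int
    star_offset: int
    arm: str  # "5p" or "3p": which arm carries the mature


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _duplex_stack_energy(mature: str) -> int:
    """Stacking energy (0.1 kcal/mol) of the perfect designed duplex.

    Used as a rejection gate when drawing matures: implanted precursors must
    be solid hairpins, i.e. clear the -20 kcal/mol stability criterion with
    margin even after bulges and the hairpin-loop penalty.
    """
    rna = mature.replace("T", "U")
    ptypes = [PAIR_TABLE[ENCODE[b], ENCODE[{"A": "U", "U": "A", "G": "C", "C": "G"}[b]]] for b in rna]
    return int(sum(STACK[ptypes[i], ptypes[i + 1]] for i in range(len(ptypes) - 1)))


#: designed-duplex stacking gates (0.1 kcal/mol): strong enough that the
#: folded precursor stays below -20 kcal/mol after loop penalties and (for
#: known loci) one bulge.
_STACK_GATE_KNOWN = -380
_STACK_GATE_NOVEL = -330


def _draw_mature(rng: np.random.Generator, lo: int, hi: int, gate: int = _STACK_GATE_KNOWN) -> str:
    while True:
        mature = _random_seq(rng, int(rng.integers(lo, hi + 1)))
        if _duplex_stack_energy(mature) <= gate:
            return mature


def build_hairpin_locus(
    mature: str,
    loop_len: int,
    n_bulges: int,
    rng: np.random.Generator,
    arm: str = "5p",
) -> HairpinLocus:
    """Assemble a stem-loop precursor around a mature sequence.

    The precursor is ``5'arm + loop + 3'arm`` where one arm is the mature and
    the other its reverse complement carrying ``n_bulges`` point changes at
    interior positions.  The loop is drawn from {A, C} only, so it cannot
    pair with itself and the designed duplex is the unique optimal helix.
    The star is the complementary arm shifted so the duplex has 2-nt 3'
    overhangs (clamped at the precursor ends).
    """
    if loop_len < 3:
        raise GeometryError(f"loop_len must be >= 3, got {loop_len}")
    if not 19 <= len(mature) <= 24:
        raise GeometryError(f"mature length must be 19-24 nt, got {len(mature)}")
    if arm not in ("5p", "3p"):
        raise GeometryError(f"arm must be '5p' or '3p', got {arm!r}")
    ml = len(mature)
    other = list(revcomp(mature))
    if n_bulges:
        positions = rng.choice(np.arange(2, ml - 2), size=n_bulges, replace=False)
        for pos in positions:
            current = other[pos]
            choices = [b for b in "ACGT" if b != current and b != _COMP[current]]
            other[pos] = str(rng.choice(np.array(choices)))
    other_arm = "".join(other)
    loop = "".join(rng.choice(np.array(["A", "C"]), size=loop_len))
    if arm == "5p":
        precursor = mature + loop + other_arm
        L = len(precursor)
        # designed pairing p(i) = L-1-i; star span = [p(me)+2, p(ms)+2] clamped
        star_lo = (L - ml) + 2
        star_hi = min(L - 1 + 2, L - 1)
        mature_offset = 0
    else:
        precursor = other_arm + loop + mature
        L = len(precursor)
        star_lo = 2
        star_hi = ml + 1
        mature_offset = L - ml
    star = precursor[star_lo : star_hi + 1]
    return HairpinLocus(precursor, mature, star, mature_offset, star_lo, arm)


def random_locus(
    rng: np.random.Generator, mature_length_range: tuple[int, int] = (20, 22)
) -> HairpinLocus:
    """One default-recipe hairpin locus (the same draw the simulator uses
    for known loci): stability-gated mature, {A,C} loop of 12-40 nt, 0-1
    bulges, random arm."""
    lo, hi = mature_length_range
    mature = _draw_mature(rng, lo, hi)
    return build_hairpin_locus(
        mature,
        int(rng.integers(12, 41)),
        int(rng.integers(0, 2)),
        rng,
        arm=str(rng.choice(np.array(["5p", "3p"]))),
    )


@dataclass
class SimulatedDataset:
    """In-memory result of :func:`simulate_libraries` (plus paths if written)."""

    config: SimulationConfig
    genome: dict[str, str]
    mature_ref: dict[str, str]  # RNA (U) sequences, miRBase-style ids
    precursor_ref: dict[str, str]
    decoys: dict[str, str]
    truth: pd.DataFrame
    reads: dict[str, list[RawRead]]
    decoy_spans: pd.DataFrame = field(default_factory=pd.DataFrame)
    paths: dict[str, Path] = field(default_factory=dict)


def _zipf_probs(n: int, alpha: float) -> np.ndarray:
    w = np.arange(1, n + 1, dtype=float) ** -alpha
    return w / w.sum()


def _phred_string(rng: np.random.Generator, length: int, mean: float) -> list[int]:
    q = np.clip(np.rint(rng.normal(mean, 3.0, size=length)), 2, 41).astype(int)
    return list(q)


def _sequencing_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0.0:
        return seq
    arr = np.array(list(seq))
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for pos in hits:
        alternatives = [b for b in "ACGT" if b != arr[pos]]
        arr[pos] = rng.choice(np.array(alternatives))
    return "".join(arr)


def simulate_libraries(
    config: SimulationConfig, outdir: str | Path | None = None
) -> SimulatedDataset:
    """Generate genome, references, decoys, truth table and per-library reads.

    Read counts per (locus, arm) cell are multinomial draws from the
    configured Zipf abundance law; the truth table records the exact expected
    counts, which sum per library to the number of miRNA-derived reads.
    """
    rng = np.random.default_rng(config.seed)
    n_loci = config.n_known_loci + config.n_novel_loci
    lo, hi = config.mature_length_range

    # --- reference matures and implanted loci ------------------------------
    loci: list[dict] = []
    mature_ref: dict[str, str] = {}
    for i in range(config.n_known_loci):
        mature = _draw_mature(rng, lo, hi)
        family = f"miR{101 + i}"
        name = f"csa-{family}a"
        hp = build_hairpin_locus(
            mature,
            int(rng.integers(12, 41)),
            int(rng.integers(0, 2)),
            rng,
            arm=str(rng.choice(np.array(["5p", "3p"]))),
        )
        mature_ref[name] = mature.replace("T", "U")
        loci.append(
            {"locus_id": f"locus_known_{i:02d}", "ref_id": name, "family": family,
             "known": True, "hairpin": hp}
        )
    known_names = [l["ref_id"] for l in loci]
    for i in range(config.n_novel_loci):
        parent = known_names[i % len(known_names)]
        parent_seq = mature_ref[parent].replace("U", "T")
        while True:
            mutated = list(parent_seq)
            for pos in rng.choice(np.arange(2, len(mutated) - 2), size=2, replace=False):
                alternatives = [b for b in "ACGT" if b != mutated[pos]]
                mutated[pos] = str(rng.choice(np.array(alternatives)))
            novel_mature = "".join(mutated)
            if (
                novel_mature.replace("T", "U") not in mature_ref.values()
                and _duplex_stack_energy(novel_mature) <= _STACK_GATE_NOVEL
            ):
                break
        family = parent.split("-", 1)[1].rstrip("abcdefgh")
        hp = build_hairpin_locus(
            novel_mature,
            int(rng.integers(12, 41)),
            0,
            rng,
            arm=str(rng.choice(np.array(["5p", "3p"]))),
        )
        loci.append(
            {"locus_id": f"locus_novel_{i:02d}", "ref_id": f"novel_{i:02d}",
             "family": family, "known": False, "hairpin": hp}
        )
    # reference matures with no implanted locus (database entries only)
    for i in range(4):
        mature_ref[f"ath-miR{201 + i}a"] = _random_seq(
            rng, int(rng.integers(lo, hi + 1))
        ).replace("T", "U")

    # --- decoy ncRNAs -------------------------------------------------------
    decoys = {
        f"decoy_trna_{i:02d}": _random_seq(rng, int(rng.integers(70, 91)))
        for i in range(config.n_decoy_ncrna)
    }

    # --- genome with implants ----------------------------------------------
    contig = "chr1"
    genome_arr = rng.choice(_BASES, size=config.genome_length)
    implants = [(l["locus_id"], l["hairpin"].precursor, True) for l in loci]
    implants += [(name, seq, False) for name, seq in decoys.items()]
    n_impl = len(implants)
    slot = config.genome_length // n_impl
    spans: dict[str, tuple[int, int, str]] = {}
    for k, (name, seq, is_locus) in enumerate(implants):
        max_off = slot - len(seq) - 2
        if max_off <= 0:
            raise ConfigError("genome_length too small to hold implanted loci")
        start0 = k * slot + int(rng.integers(0, max_off))
        strand = str(rng.choice(np.array(["+", "-"]))) if is_locus else "+"
        placed = seq if strand == "+" else revcomp(seq)
        genome_arr[start0 : start0 + len(seq)] = list(placed)
        spans[name] = (start0 + 1, start0 + len(seq), strand)  # 1-based inclusive
    genome = {contig: "".join(genome_arr)}

    # --- abundance law ------------------------------------------------------
    n_libs = len(config.libraries)
    n_mirna = round(config.reads_per_library * (1.0 - config.background_fraction))
    base_probs = _zipf_probs(n_loci, config.abundance_alpha)
    lib_probs = np.empty((n_libs, n_loci))
    for l in range(n_libs):
        shift = l * n_loci // n_libs
        ranks = (np.arange(n_loci) + shift) % n_loci
        lib_probs[l] = base_probs[ranks]

    truth_rows = []
    for i, locus in enumerate(loci):
        hp: HairpinLocus = locus["hairpin"]
        start1, end1, strand = spans[locus["locus_id"]]
        row = {
            "locus_id": locus["locus_id"],
            "contig": contig,
            "start": start1,
            "end": end1,
            "strand": strand,
            "arm": hp.arm,
            "mature_seq": hp.mature,
            "star_seq": hp.star,
            "family": locus["family"],
            "known": locus["known"],
            "ref_id": locus["ref_id"],
        }
        for l, lib in enumerate(config.libraries):
            total = n_mirna * lib_probs[l, i]
            row[f"expected_mature_{lib}"] = total * (1.0 - config.star_fraction)
            row[f"expected_star_{lib}"] = total * config.star_fraction
        truth_rows.append(row)
    truth = pd.DataFrame(truth_rows)

    # --- reads --------------------------------------------------------------
    reads: dict[str, list[RawRead]] = {}
    genome_seq = genome[contig]
    for l, lib in enumerate(config.libraries):
        lib_reads: list[RawRead] = []
        serial = 0

        def emit(insert: str, cls: str) -> None:
            nonlocal serial
            seq = insert + config.adapter3
            if len(seq) < config.read_length:
                seq += _random_seq(rng, config.read_length - len(seq))
            seq = seq[: config.read_length]
            seq = _sequencing_errors(rng, seq, config.error_rate)
            mean = 20.0 if rng.random() < config.low_quality_fraction else 35.0
            qual = _phred_string(rng, len(seq), mean)
            lib_reads.append(
                RawRead(f"{lib}_{serial:06d} insert={len(insert)} class={cls}", seq, qual)
            )
            serial += 1

        # miRNA-derived reads: multinomial over (locus, arm) cells
        cell_probs = np.concatenate(
            [lib_probs[l] * (1.0 - config.star_fraction), lib_probs[l] * config.star_fraction]
        )
        counts = rng.multinomial(n_mirna, cell_probs)
        for i, locus in enumerate(loci):
            for _ in range(counts[i]):
                emit(locus["hairpin"].mature, "mature")
        for i, locus in enumerate(loci):
            for _ in range(counts[n_loci + i]):
                emit(locus["hairpin"].star, "star")

        # background reads
        n_bg = config.reads_per_library - n_mirna
        if config.n_decoy_ncrna > 0:
            n_decoy_reads = round(0.3 * n_bg)
        else:
            n_decoy_reads = 0
        n_sirna = round(0.3 * n_bg)
        n_rand = n_bg - n_decoy_reads - n_sirna
        for _ in range(n_rand):
            length = int(rng.integers(15, 31))
            pos = int(rng.integers(0, config.genome_length - length))
            emit(genome_seq[pos : pos + length], "bg_random")
        for _ in range(n_sirna):
            pos = int(rng.integers(0, config.genome_length - 24))
            emit(genome_seq[pos : pos + 24], "bg_sirna24")
        if n_decoy_reads:
            hotspots = []
            for name, seq in decoys.items():
                for _ in range(3):
                    flen = int(rng.integers(20, 25))
                    off = int(rng.integers(0, len(seq) - flen))
                    hotspots.append(seq[off : off + flen])
            hs_counts = rng.multinomial(
                n_decoy_reads, _zipf_probs(len(hotspots), config.abundance_alpha)
            )
            for frag, cnt in zip(hotspots, hs_counts):
                for _ in range(cnt):
                    emit(frag, "bg_decoy")
        reads[lib] = lib_reads

    dataset = SimulatedDataset(
        config=config,
        genome=genome,
        mature_ref=mature_ref,
        precursor_ref={
            l["ref_id"]: l["hairpin"].precursor.replace("T", "U")
            for l in loci
            if l["known"]
        },
        decoys=decoys,
        truth=truth,
        reads=reads,
        decoy_spans=pd.DataFrame(
            [
                {"name": name, "contig": contig, "start": spans[name][0],
                 "end": spans[name][1]}
                for name in decoys
            ],
            columns=["name", "contig", "start", "end"],
        ),
    )
    if outdir is not None:
        dataset.paths = write_dataset(dataset, Path(outdir))
    return dataset


def write_dataset(dataset: SimulatedDataset, outdir: Path) -> dict[str, Path]:
    """Write all generator outputs as plain-text files; returns the path map."""
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for lib, lib_reads in dataset.reads.items():
        path = outdir / f"{lib}.fastq"
        write_fastq(path, lib_reads)
        paths[f"fastq_{lib}"] = path
    paths["genome"] = outdir / "genome.fa"
    write_fasta(paths["genome"], dataset.genome.items())
    paths["mature_ref"] = outdir / "matures.fa"
    write_fasta(paths["mature_ref"], dataset.mature_ref.items())
    paths["precursor_ref"] = outdir / "precursors.fa"
    write_fasta(paths["precursor_ref"], dataset.precursor_ref.items())
    paths["decoys"] = outdir / "decoys.fa"
    write_fasta(paths["decoys"], dataset.decoys.items())
    paths["truth"] = outdir / "truth.tsv"
    dataset.truth.to_csv(paths["truth"], sep="\t", index=False, float_format="%.4f")
    paths["decoy_spans"] = outdir / "decoy_spans.tsv"
    dataset.decoy_spans.to_csv(paths["decoy_spans"], sep="\t", index=False)
    paths["config"] = outdir / "config.txt"
    write_flat_config(paths["config"], dataclasses.asdict(dataset.config))
    return paths


def make_target_transcriptome(
    mirnas: dict[str, str],
    rng: np.random.Generator,
    n_transcripts: int = 40,
    transcript_length: int = 600,
    site_fraction: float = 0.5,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Random CDS set with perfect complementarity sites implanted.

    A fraction of transcripts carries the exact reverse complement of one
    miRNA (DNA alphabet) at a random interior position; the returned table
    records transcript, miRNA and 1-based site span.
    """
    cds: dict[str, str] = {}
    rows = []
    names = sorted(mirnas)
    for t in range(n_transcripts):
        tid = f"Csa_CDS_{t:04d}"
        seq = _random_seq(rng, transcript_length)
        if names and rng.random() < site_fraction:
            mid = names[int(rng.integers(0, len(names)))]
            site = revcomp(mirnas[mid].replace("U", "T"))
            pos = int(rng.integers(50, transcript_length - 50 - len(site)))
            seq = seq[:pos] + site + seq[pos + len(site):]
            rows.append(
                {"transcript_id": tid, "mirna_id": mid,
                 "site_start": pos + 1, "site_end": pos + len(site)}
            )
        cds[tid] = seq
    return cds, pd.DataFrame(rows, columns=["transcript_id", "mirna_id", "site_start", "site_end"])
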