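"""Genome anchoring, known/homolog classification, decoy exclusion."""

import numpy as np
import pytest

from mircam.io import revcomp, write_fasta, read_fasta
from mircam.seqmatch import (
    GenomeIndex,
    anchor_to_genome,
    match_decoys,
    match_homolog,
    match_known,
    parse_family,
)

from _oracles import all_pairs_best_hit, naive_genome_scan


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


class TestAnchoring:
    def test_plus_strand_anchor(self, rng):
        genome = {"c1": random_dna(rng, 400)}
        tag = genome["c1"][100:121]  # 1-based 101..121
        anchors, anchored = anchor_to_genome([tag], genome)
        assert anchored == [tag]
        a = anchors[tag][0]
        assert (a.contig, a.start, a.end, a.strand) == ("c1", 101, 121, "+")
        assert genome["c1"][a.start - 1 : a.end] == tag

    def test_minus_strand_anchor(self, rng):
        genome = {"c1": random_dna(rng, 400)}
        tag = revcomp(genome["c1"][200:221])
        anchors, _ = anchor_to_genome([tag], genome)
        a = anchors[tag][0]
        assert (a.start, a.end, a.strand) == (201, 221, "-")
        assert revcomp(genome["c1"][a.start - 1 : a.end]) == tag

    def test_n_containing_tag_has_no_anchor(self, rng):
        genome = {"c1": random_dna(rng, 100)}
        tag = genome["c1"][10:31]
        broken = "N" + tag[1:]
        anchors, anchored = anchor_to_genome([broken], genome)
        assert anchored == []

    def test_agrees_with_naive_scan(self, rng):
        genome_seq = random_dna(rng, 5000)
        # make some repeats so multi-mapping happens
        genome_seq = genome_seq[:1000] + genome_seq[500:540] * 3 + genome_seq[1000:]
        genome = {"c1": genome_seq}
        index = GenomeIndex(genome)
        tags = [genome_seq[i : i + 20] for i in range(0, 4000, 37)]
        tags += [revcomp(t) for t in tags[:20]]
        tags += [random_dna(rng, 20) for _ in range(30)]
        for tag in tags:
            expected = {(p + 1, "+") for p in naive_genome_scan(genome_seq, tag)}
            expected |= {
                (p + 1, "-") for p in naive_genome_scan(genome_seq, revcomp(tag))
            }
            got = {(a.start, a.strand) for a in index.anchor(tag, cap=10**9)}
            assert got == expected

    def test_multimap_cap(self, rng):
        unit = random_dna(rng, 30)
        genome = {"c1": ("T" * 10).join([unit] * 25)}
        tag = unit[:20]
        anchors, _ = anchor_to_genome([tag], genome, cap=20)
        assert len(anchors[tag]) == 20

    def test_strand_swap_symmetry(self, rng):
        genome = {"c1": random_dna(rng, 500)}
        tag = genome["c1"][50:72]
        index = GenomeIndex(genome)
        fwd = index.anchor(tag)
        rev = index.anchor(revcomp(tag))
        assert [(a.start, a.end) for a in fwd] == [(a.start, a.end) for a in rev]
        assert {a.strand for a in fwd} == {"+"} and {a.strand for a in rev} == {"-"}

    def test_implanted_matures_anchor_at_truth_spans(self, small_dataset):
        genome = small_dataset.genome
        index = GenomeIndex(genome)
        for _, row in small_dataset.truth.iterrows():
            anchors = index.anchor(row["mature_seq"])
            assert any(
                a.start >= row["start"] and a.end <= row["end"]
                and a.strand == row["strand"]
                for a in anchors
            ), row["locus_id"]


class TestKnownMatching:
    REF = {"ath-miR166b": "UCGGACCAGGCUUCAUUCCCC"}

    def test_exact_match_is_known(self):
        hits = match_known(["TCGGACCAGGCTTCATTCCCC"], self.REF)
        hit = hits["TCGGACCAGGCTTCATTCCCC"]
        assert hit.ref_id == "ath-miR166b"
        assert hit.mismatches == 0
        assert hit.family == "miR166"

    def test_single_substitution_is_not_known(self):
        assert match_known(["ACGGACCAGGCTTCATTCCCC"], self.REF) == {}

    def test_size_must_match_exactly(self):
        truncated = "TCGGACCAGGCTTCATTCCC"  # one nt short
        assert match_known([truncated], self.REF) == {}

    def test_duplicate_reference_ids_error(self, tmp_path):
        path = tmp_path / "dup.fa"
        path.write_text(">a\nACGT\n>a\nACGG\n")
        with pytest.raises(ValueError, match="a"):
            read_fasta(path)


class TestHomologMatching:
    def test_two_mismatch_hit(self):
        ref = {"csa-miR101a": "ACGTACGTACGTACGTACGTA"}
        tag = "ACGAACGTACGTACGTACGTT"  # Hamming 2
        hits = match_homolog([tag], ref)
        assert hits[tag].mismatches == 2
        assert hits[tag].family == "miR101"

    def test_distance_four_is_no_hit(self):
        ref = {"csa-miR101a": "ACGTACGTACGTACGTACGTA"}
        tag = "TTTA" + "ACGTACGTACGTACGTA"  # Hamming 4 from the reference
        assert match_homolog([tag], ref) == {}

    def test_precursor_window_match(self):
        pre = {"pre1": "AAAACCCCGGGGTTTTACGTACGTACGTAAAA"}
        tag = "CCCCGGGGTTTTACGTACGT"
        hits = match_homolog([tag], {}, pre)
        assert hits[tag].ref_id == "pre1"
        assert hits[tag].mismatches == 0

    def test_matches_exhaustive_all_pairs_scan(self, rng):
        refs = {f"ref{i:02d}": random_dna(rng, 21) for i in range(50)}
        tags = [random_dna(rng, 21) for _ in range(100)]
        # plant near-misses so some hits exist
        ref_seqs = list(refs.values())
        for k in range(50):
            base = list(ref_seqs[k % 50])
            for pos in rng.choice(21, size=int(rng.integers(0, 4)), replace=False):
                base[pos] = str(rng.choice([b for b in "ACGT" if b != base[pos]]))
            tags.append("".join(base))
        hits = match_homolog(tags, refs)
        for tag in tags:
            expected = all_pairs_best_hit(tag, refs, max_mm=3)
            got = hits.get(tag)
            if expected is None:
                assert got is None
            else:
                assert (got.ref_id, got.mismatches) == expected

    def test_known_and_homolog_are_disjoint(self, rng):
        refs = {f"r{i}": random_dna(rng, 21) for i in range(10)}
        tags = list(refs.values()) + [random_dna(rng, 21) for _ in range(20)]
        known = match_known(tags, refs)
        homolog = match_homolog([t for t in tags if t not in known], refs)
        assert set(known) & set(homolog) == set()


class TestFamilyParsing:
    @pytest.mark.parametrize(
        "rid,family",
        [
            ("ath-miR166a-5p", "miR166"),
            ("csa-miR101a", "miR101"),
            ("miR6300", "miR6300"),
            ("osa-MIR396c", "miR396"),
            ("miRf10010-akr", "miRf10010"),
        ],
    )
    def test_examples(self, rid, family):
        assert parse_family(rid) == family


class TestDecoyMatching:
    def test_shared_block_flagged(self, rng):
        decoy = {"trna1": random_dna(rng, 80)}
        pre = random_dna(rng, 60) + decoy["trna1"][10:30] + random_dna(rng, 40)
        assert match_decoys({"cand": pre}, decoy) == {"cand"}

    def test_empty_decoy_set(self, rng):
        assert match_decoys({"cand": random_dna(rng, 100)}, {}) == set()

    def test_simulated_decoy_candidates_all_flagged(self):
        """Windows around decoy loci are flagged; true precursors are not
        (seed-9 dataset)."""
        from mircam.synthdata import SimulationConfig, simulate_libraries

        dataset = simulate_libraries(
            SimulationConfig(
                seed=9, genome_length=20_000, n_known_loci=4, n_novel_loci=2,
                n_decoy_ncrna=3, reads_per_library=0,
            )
        )
        genome = dataset.genome["chr1"]
        decoy_windows = {
            row["name"]: genome[max(0, row["start"] - 40) : row["end"] + 40]
            for _, row in dataset.decoy_spans.iterrows()
        }
        true_precursors = {
            row["locus_id"]: genome[row["start"] - 1 : row["end"]]
            for _, row in dataset.truth.iterrows()
        }
        assert match_decoys(decoy_windows, dataset.decoys) == set(decoy_windows)
        assert match_decoys(true_precursors, dataset.decoys) == set()
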