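"""Complementarity target prediction: scoring, gates, annotation."""

import numpy as np
import pandas as pd
import pytest

from mircam.io import revcomp
from mircam.synthdata import make_target_transcriptome
from mircam.targets import (
    TargetHit,
    annotate_hits,
    scan_targets,
    score_target,
    tally_go,
)

from _oracles import best_gapless_score, gotoh_local


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


def transcript_with_site(rng, mirna, n_subs=0, length=300):
    """Random transcript carrying the miRNA's reverse-complement site with
    ``n_subs`` spread substitutions."""
    site = list(revcomp(mirna))
    positions = np.linspace(3, len(site) - 4, max(n_subs, 1)).astype(int)
    for pos in positions[:n_subs]:
        site[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[site[pos]]
    seq = random_dna(rng, length)
    mid = length // 2
    return seq[:mid] + "".join(site) + seq[mid:]


class TestScoreTarget:
    def test_perfect_site_scores_two_per_base(self, rng):
        mirna = random_dna(rng, 21)
        transcript = transcript_with_site(rng, mirna)
        score, details = score_target(mirna, transcript)
        assert score == 42.0  # 21 x 2
        assert details["matches"] == 21 and details["mismatches"] == 0
        assert (
            transcript[details["start"] - 1 : details["end"]] == revcomp(mirna)
        )

    def test_mutated_site_straddles_the_two_gates(self, rng):
        """A site with several spread substitutions drops below the strict
        gate (25) but stays above the relaxed lipid-scan gate (20)."""
        mirna = random_dna(rng, 21)
        transcript = transcript_with_site(rng, mirna, n_subs=4)
        score, _ = score_target(mirna, transcript)
        assert 20 <= score < 25
        hits25 = scan_targets({"m": mirna}, {"t": transcript}, min_score=25)
        hits20 = scan_targets({"m": mirna}, {"t": transcript}, min_score=20)
        assert hits25 == [] and len(hits20) == 1

    def test_empty_transcript_is_error(self, rng):
        with pytest.raises(ValueError):
            score_target(random_dna(rng, 21), "")

    def test_mirna_length_bounds(self, rng):
        with pytest.raises(ValueError):
            score_target("ACGT", random_dna(rng, 100))

    def test_agrees_with_independent_gotoh_dp(self, rng):
        for _ in range(40):
            mirna = random_dna(rng, int(rng.integers(18, 25)))
            transcript = random_dna(rng, int(rng.integers(30, 61)))
            score, _ = score_target(mirna, transcript)
            query = revcomp(mirna)
            assert score == gotoh_local(query, transcript)
            assert score >= best_gapless_score(query, transcript)

    def test_random_sites_rarely_reach_gate_25(self, rng):
        """Spurious-hit calibration: a random 21-mer against a random 10-kb
        transcript clears the score-25 gate in under 1% of trials."""
        hits = 0
        trials = 400
        for _ in range(trials):
            score, _ = score_target(random_dna(rng, 21), random_dna(rng, 10_000))
            hits += score >= 25
        assert hits / trials < 0.01 + 2.5 * np.sqrt(0.01 / trials)  # <=1% + noise


class TestScanTargets:
    def test_single_perfect_site_single_hit(self, rng):
        mirna = random_dna(rng, 21)
        cds = {"t1": transcript_with_site(rng, mirna), "t2": random_dna(rng, 300)}
        hits = scan_targets({"m1": mirna}, cds, min_score=25)
        assert [h.transcript_id for h in hits] == ["t1"]

    def test_lower_gate_gives_superset(self, rng):
        mirnas = {f"m{i}": random_dna(rng, 21) for i in range(5)}
        cds = {f"t{i}": random_dna(rng, 2000) for i in range(10)}
        strict = {(h.mirna_id, h.transcript_id) for h in scan_targets(mirnas, cds, 25)}
        relaxed = {(h.mirna_id, h.transcript_id) for h in scan_targets(mirnas, cds, 20)}
        assert strict <= relaxed

    def test_implanted_sites_fully_recovered(self):
        """Every implanted site in the synthetic CDS set is found at the
        relaxed gate (seed 11)."""
        rng = np.random.default_rng(11)
        mirnas = {f"mir{i}": random_dna(rng, 21) for i in range(8)}
        cds, sites = make_target_transcriptome(mirnas, rng, n_transcripts=30)
        hits = scan_targets(mirnas, cds, min_score=20)
        found = {(h.mirna_id, h.transcript_id) for h in hits}
        for _, row in sites.iterrows():
            assert (row["mirna_id"], row["transcript_id"]) in found

    def test_restriction_list(self, rng):
        mirna = random_dna(rng, 21)
        cds = {
            "lipid1": transcript_with_site(rng, mirna),
            "other1": transcript_with_site(rng, mirna),
        }
        hits = scan_targets({"m": mirna}, cds, 20, restrict_to={"lipid1"})
        assert [h.transcript_id for h in hits] == ["lipid1"]

    def test_no_self_targeting_in_synthetic_set(self, small_dataset):
        """A miRNA should not score as its own target unless it is a
        near-palindrome; none of the synthetic matures do."""
        for mirna in small_dataset.truth["mature_seq"]:
            score, _ = score_target(mirna, mirna)
            assert score < 25


class TestAnnotation:
    def _hits(self):
        return [
            TargetHit("m1", "t1", 1, 21, 42.0, 21, 0, 0),
            TargetHit("m1", "t2", 1, 21, 42.0, 21, 0, 0),
            TargetHit("m2", "t1", 1, 21, 30.0, 18, 3, 0),
        ]

    def test_left_join_attaches_description(self):
        ann = pd.DataFrame(
            [{"transcript_id": "t1", "ortholog_id": "AT1G01010",
              "description": "acyl-CoA oxidase", "go_terms": "lipid metabolism|DNA binding"}]
        )
        hits = annotate_hits(self._hits(), ann)
        assert hits[0].annotation == "acyl-CoA oxidase"
        assert hits[1].annotation == ""  # missing annotation retained

    def test_empty_annotation_is_harmless(self):
        hits = annotate_hits(self._hits(), pd.DataFrame())
        assert all(h.annotation == "" for h in hits)

    def test_go_tally_counts_shared_terms(self):
        hits = self._hits()
        for h in hits:
            h.go_terms = ("DNA binding",)
        hits[0].go_terms = ("DNA binding", "signaling")
        tally = tally_go(hits)
        assert tally["DNA binding"] == 3
        assert tally["signaling"] == 1
        assert tally.index[0] == "DNA binding"
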