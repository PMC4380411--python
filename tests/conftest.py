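"""Shared fixtures: simulated datasets and pipeline runs (session-scoped,
because discovery folds hundreds of windows)."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pytest

from mircam.io import write_fasta
from mircam.pipeline import PipelineConfig, run_all
from mircam.synthdata import (
    SimulationConfig,
    make_target_transcriptome,
    simulate_libraries,
)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


SMALL_CONFIG = SimulationConfig(
    seed=7,
    genome_length=20_000,
    n_known_loci=4,
    n_novel_loci=2,
    n_decoy_ncrna=2,
    reads_per_library=3_000,
)


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("sim_small")
    return simulate_libraries(SMALL_CONFIG, outdir)


@pytest.fixture(scope="session")
def small_run(small_dataset, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("run_small")
    config = _pipeline_config(small_dataset, outdir)
    result = run_all(config)
    return result, small_dataset


@pytest.fixture(scope="session")
def dataset42(tmp_path_factory):
    """The default-scale synthetic study: 4 libraries x 10,000 reads."""
    outdir = tmp_path_factory.mktemp("sim42")
    return simulate_libraries(SimulationConfig(seed=42), outdir)


@pytest.fixture(scope="session")
def run42(dataset42, tmp_path_factory):
    """Full default pipeline run on the seed-42 dataset, incl. targets."""
    outdir = tmp_path_factory.mktemp("run42")
    rng = np.random.default_rng(11)
    mirnas = {
        row["ref_id"]: row["mature_seq"]
        for _, row in dataset42.truth.iterrows()
    }
    cds, sites = make_target_transcriptome(mirnas, rng)
    cds_path = outdir / "cds.fa"
    write_fasta(cds_path, cds.items())
    lipid_path = outdir / "lipid_genes.txt"
    lipid_path.write_text("\n".join(sorted(cds)[:10]) + "\n")
    config = _pipeline_config(dataset42, outdir / "out")
    config.cds = cds_path
    config.lipid_list = lipid_path
    result = run_all(config)
    return result, dataset42, sites


def _pipeline_config(dataset, outdir: Path) -> PipelineConfig:
    libs = dataset.config.libraries
    return PipelineConfig(
        fastq={lib: dataset.paths[f"fastq_{lib}"] for lib in libs},
        genome=dataset.paths["genome"],
        mature_ref=dataset.paths["mature_ref"],
        precursor_ref=dataset.paths["precursor_ref"],
        decoys=dataset.paths["decoys"],
        outdir=outdir,
        adapter3=dataset.config.adapter3,
    )
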