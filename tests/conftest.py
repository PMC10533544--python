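"""Shared fixtures: a small simulated community, parsed once per session."""
from pathlib import Path

import pytest

from lysoscape import io as lio
from lysoscape.simulate import (
    SimulationConfig,
    Stratum,
    simulate_community,
    simulate_hit_tables,
)


@pytest.fixture(scope="session")
def small_truth(tmp_path_factory):
    """A compact two-stratum community: enough proviruses to exercise
    every stage, small enough to regenerate in seconds."""
    cfg = SimulationConfig(
        seed=11,
        strata=[
            Stratum("seawater", "epipelagic", 10, 0.6),
            Stratum("sediment", "deep_sea", 10, 0.5),
        ],
        genome_length_bp=(28_000, 38_000),
        provirus_length_bp=(3_000, 6_000),
        n_genera=5,
    )
    outdir = tmp_path_factory.mktemp("community")
    return simulate_community(cfg, outdir)


@pytest.fixture(scope="session")
def small_parsed(small_truth):
    genomes = lio.parse_genomes(
        sorted(Path(small_truth.paths["fasta_dir"]).glob("*.fasta")),
        small_truth.paths["gff"],
        small_truth.paths["metadata"],
    )
    proviruses = lio.parse_proviruses(
        small_truth.paths["proviruses"], small_truth.paths["viral_genes"]
    )
    return genomes, proviruses


@pytest.fixture(scope="session")
def hit_tables(tmp_path_factory):
    cfg = SimulationConfig(seed=23)
    return simulate_hit_tables(cfg, tmp_path_factory.mktemp("hits"))
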