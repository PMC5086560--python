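import numpy as np
import pytest

from tnessential.essentiality import analyze
from tnessential.genome_index import assign_informative_sites, build_flank_index
from tnessential.synthgen import (
    SimulationConfig,
    simulate_genome,
    simulate_library,
    site_to_flank_counts,
)


@pytest.fixture(scope="session")
def default_scenario():
    """The default synthetic experiment: 0.5 Mb genome, ~400 genes, 10%
    essential, N=5,600 unique mutants over ~20k TA sites, 3 libraries."""
    cfg = SimulationConfig(seed=1)
    genome, genes = simulate_genome(cfg)
    fidx = build_flank_index(genome, k=16)
    site_matrix, truth = simulate_library(genome, genes, cfg, flank_index=fidx)
    flank_matrix = site_to_flank_counts(site_matrix, fidx, seed=cfg.seed)
    genes = assign_informative_sites(genes, genome, fidx, trim_3prime=0.1)
    return {
        "cfg": cfg,
        "genome": genome,
        "genes": genes,
        "fidx": fidx,
        "site_matrix": site_matrix,
        "flank_matrix": flank_matrix,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def default_analysis(default_scenario):
    s = default_scenario
    records, diag = analyze(s["flank_matrix"], s["genes"], s["fidx"])
    return {"records": records, "diag": diag, **s}


@pytest.fixture(scope="session")
def small_scenario():
    """A fast, noise-free scenario used for FASTQ round trips."""
    cfg = SimulationConfig(
        genome_length=60_000,
        n_genes=50,
        n_unique_mutants=600,
        reads_mean=25.0,
        noise_site_fraction=0.0,
        seed=7,
    )
    genome, genes = simulate_genome(cfg)
    fidx = build_flank_index(genome, k=16)
    site_matrix, truth = simulate_library(genome, genes, cfg, flank_index=fidx)
    return {
        "cfg": cfg,
        "genome": genome,
        "genes": genes,
        "fidx": fidx,
        "site_matrix": site_matrix,
        "truth": truth,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
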