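import numpy as np
import pytest

from gemmapgc.pipeline import run_scan
from gemmapgc.references import load_references
from gemmapgc.synthetic_data import (SimulationSpec, fixture_path,
                                     simulate_genome)


@pytest.fixture(scope="session")
def references():
    return load_references()


@pytest.fixture(scope="session")
def template_genome():
    """One simulated genome carrying the Gemmatimonadetes-type cluster."""
    return simulate_genome(SimulationSpec(seed=11, target_protein_identity=0.75))


@pytest.fixture(scope="session")
def template_scan(template_genome):
    genome, _ = template_genome
    return run_scan(genome)


@pytest.fixture(scope="session")
def table3_path():
    return fixture_path("table3_key_genes.tsv")


@pytest.fixture(scope="session")
def table3_stats_path():
    return fixture_path("table3_genome_stats.tsv")


@pytest.fixture(scope="session")
def table2_path():
    return fixture_path("table2_gene_presence.tsv")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
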