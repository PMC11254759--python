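import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from temap import (
    SimConfig,
    make_references,
    simulate_free_transposition,
    simulate_targeted_insertions,
)
from temap.junction_amplicon import analyze_junctions


@pytest.fixture(scope="session")
def small_cfg():
    return SimConfig(seed=11, n_reads=400, genome_len=60_000, error_rate=0.001)


@pytest.fixture(scope="session")
def refs(small_cfg):
    return make_references(small_cfg)


@pytest.fixture(scope="session")
def targeted_sim(small_cfg, refs):
    return simulate_targeted_insertions(small_cfg, refs)


@pytest.fixture(scope="session")
def insertion_sim(small_cfg, refs):
    return simulate_free_transposition(small_cfg, refs)


@pytest.fixture(scope="session")
def junction_analysis(targeted_sim, refs):
    _, reads = targeted_sim
    return analyze_junctions(reads, refs.locus, refs.te)


@pytest.fixture(scope="session")
def clean_cfg():
    """Error-free, all-perfect-junction configuration."""
    return SimConfig(
        seed=7,
        n_reads=200,
        genome_len=60_000,
        error_rate=0.0,
        f_intact=1.0,
        junction_edit_spectrum={"perfect": 1.0},
    )


@pytest.fixture(scope="session")
def clean_refs(clean_cfg):
    return make_references(clean_cfg)


@pytest.fixture(scope="session")
def clean_targeted_sim(clean_cfg, clean_refs):
    return simulate_targeted_insertions(clean_cfg, clean_refs)
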