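import numpy as np
import pytest

from srnablocks import preprocess, synthgen
from srnablocks.aligner import hierarchical_filter
from srnablocks.synthgen import Library, SimConfig


def tiny_config(seed: int = 7, depth: int = 4000, **overrides) -> SimConfig:
    kwargs = dict(
        seed=seed,
        genome_length=50_000,
        n_mirna_loci=3,
        n_te_loci=2,
        n_gene_sirna_loci=2,
        n_decoy_trna=4,
        n_decoy_rdna=2,
        n_plastid_contigs=1,
        n_repeat_features=1,
        library_design=[
            Library("lib_a", "tissue", "dark", depth),
            Library("lib_b", "tissue", "fr", depth),
        ],
        de_plan=[("te_0000", "lib_a_vs_lib_b", 4.0)],
        error_rate=0.005,
    )
    kwargs.update(overrides)
    return SimConfig(**kwargs)


@pytest.fixture(scope="session")
def sim():
    cfg = tiny_config()
    refs, features, truth = synthgen.generate_genome(cfg)
    return cfg, refs, features, truth


@pytest.fixture(scope="session")
def libraries(sim):
    cfg, refs, _features, truth = sim
    return synthgen.simulate_libraries(truth, refs, cfg)


@pytest.fixture(scope="session")
def tags(libraries):
    return {
        lib_id: preprocess.preprocess_library(reads)
        for lib_id, reads in libraries.items()
    }


@pytest.fixture(scope="session")
def triage(sim, tags):
    _cfg, refs, _features, _truth = sim
    return hierarchical_filter(tags, refs)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
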