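import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from feomics import ddge, synthio

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def libs_95k():
    """The study's two cDNA libraries of 95,000 reads each."""
    return [
        ddge.LibrarySpec("count_fe_minus", 95_000),
        ddge.LibrarySpec("count_fe_plus", 95_000),
    ]


@pytest.fixture(scope="session")
def small_genome():
    """A 30-gene synthetic genome with three planted promoter motifs."""
    spec = synthio.SynthGenomeSpec(
        n_genes=30,
        planted_gene_ids=frozenset({"g00002", "g00007", "g00019"}),
        seed=42,
    )
    return spec, synthio.gen_genome(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
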