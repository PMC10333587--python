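import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from rrsim.founder_synth import desk_synthesis_config, synthesize_study
from rrsim.genome_core import FULL, OBSERVED, Population, TraitArchitecture

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_arch():
    """Two observed markers plus one hidden locus, hand-set effects.

    alpha = (1, 2), beta = (0.5, -0.5); hidden locus (full-genome column
    1) has alpha' = 0 and beta' = 3.
    """
    return TraitArchitecture(
        additive_obs=np.array([1.0, 2.0]),
        dominance_obs=np.array([0.5, -0.5]),
        additive_hidden=np.array([0.0]),
        dominance_hidden=np.array([3.0]),
        observed_index_map=np.array([0, 2]),
    )


@pytest.fixture
def toy_individual():
    """Observed-scope individual: het at locus 1, homozygous major at locus 2."""
    return Population(
        genotypes=np.array([[[1, 0], [1, 1]]], dtype=np.int8), scope=OBSERVED
    )


@pytest.fixture
def toy_individual_full():
    """Same individual in full scope, heterozygous at the hidden locus."""
    return Population(
        genotypes=np.array([[[1, 0], [1, 0], [1, 1]]], dtype=np.int8), scope=FULL
    )


@pytest.fixture(scope="session")
def desk_study():
    """Session-wide scaled-down synthetic study (60 founders, 200/2000 loci)."""
    return synthesize_study(desk_synthesis_config(seed=5))
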