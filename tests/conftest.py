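import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from rhpmap.chemistry import (Monomer, MonomerRegistry, build_monomer_registry,
                              default_reactivity_matrix, validate_reactivity_matrix)
from rhpmap.simulate import (Chain, DeadChainSpec, Ensemble, FeedState,
                             SimulationConfig, simulate_batch)

settings.register_profile(
    "ci", derandomize=True, max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def registry():
    return build_monomer_registry()


@pytest.fixture(scope="session")
def ratios(registry):
    return default_reactivity_matrix(registry)


@pytest.fixture(scope="session")
def binary_registry():
    return MonomerRegistry((
        Monomer("monoA", "A", 100.0, 10.0),
        Monomer("monoB", "B", 100.0, 10.0),
    ))


def make_binary_matrix(binary_registry, r12, r21):
    return validate_reactivity_matrix([[1.0, r12], [r21, 1.0]], binary_registry)


@pytest.fixture(scope="session")
def small_ensemble(registry, ratios):
    """A modest quaternary simulation reused by several test modules."""
    feed = FeedState(np.array([0.25, 0.25, 0.25, 0.25]))
    cfg = SimulationConfig(n_chains=400, target_conversion=0.7,
                           mean_dp_target=40, seed=11,
                           dead_chain=DeadChainSpec(fraction=0.1))
    return simulate_batch(feed, ratios, cfg, registry=registry)


def hand_built_ensemble(registry, specs):
    """Ensemble assembled directly from (sequence_string, living) pairs."""
    chains = [Chain(sequence=registry.encode(s), living=liv) for s, liv in specs]
    m = len(registry)
    consumed = np.zeros(m, dtype=np.int64)
    for ch in chains:
        if len(ch.sequence):
            consumed += np.bincount(ch.sequence, minlength=m)
    pool0 = np.maximum(consumed, 1)
    return Ensemble(chains=chains, feed0=FeedState(fractions=pool0 / pool0.sum()),
                    pool0=pool0, consumed=consumed, registry=registry, seed=0)
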