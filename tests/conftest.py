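import numpy as np
import pytest

from mitoshift import PedigreeSimConfig, simulate_pedigree


@pytest.fixture(scope="session")
def neutral_pairs():
    """One deterministic neutral pedigree (200 pairs) reused across tests."""
    return simulate_pedigree(
        PedigreeSimConfig(n_mothers=20, pups_per_mother=10, seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def wright_fisher_pmf(n_copies: int, generations: int, k0: int) -> np.ndarray:
    """Exact end-state pmf of a haploid Wright-Fisher chain.

    Independent oracle used against the Kimura machinery: iterates the
    binomial transition matrix, no diffusion approximation anywhere.
    """
    from scipy.stats import binom

    states = np.arange(n_copies + 1)
    transition = binom.pmf(states[None, :], n_copies,
                           (states / n_copies)[:, None])
    v = np.zeros(n_copies + 1)
    v[k0] = 1.0
    for _ in range(generations):
        v = v @ transition
    return v
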