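import numpy as np
import pytest

from qtlpath.motifs import build_motif
from qtlpath.simulate import SimulationConfig, simulate_population


@pytest.fixture(scope="session")
def motif_dataset():
    """Factory with a session cache: motif_dataset(name, seed, **cfg)."""
    cache = {}

    def factory(name, seed=0, **cfg_kwargs):
        key = (name, seed, tuple(sorted(cfg_kwargs.items())))
        if key not in cache:
            cfg = SimulationConfig(seed=seed, **cfg_kwargs)
            cache[key] = simulate_population(build_motif(name), config=cfg)
        return cache[key]

    return factory


def exact_sign_flip_p(stats):
    """One-sided exact sign-flip permutation p-value for mean(stats) > 0."""
    stats = np.asarray(stats, dtype=float)
    n = len(stats)
    observed = stats.mean()
    count = 0
    for mask in range(2 ** n):
        signs = np.array([1 if mask & (1 << i) else -1 for i in range(n)])
        if (signs * stats).mean() >= observed - 1e-12:
            count += 1
    return count / 2 ** n


@pytest.fixture(scope="session")
def sign_flip_p():
    return exact_sign_flip_p
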