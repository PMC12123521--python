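import numpy as np
import pytest

from molfuse import data_io, fixtures
from molfuse import meta_trainer as mt


@pytest.fixture(scope="session")
def suite():
    """The five-task synthetic benchmark (tasks + merged multitask pool)."""
    return fixtures.make_benchmark_suite(seed=0)


@pytest.fixture(scope="session")
def tasks(suite):
    task_recs, _ = suite
    return {name: mt.make_task(name, recs) for name, recs in task_recs.items()}


@pytest.fixture(scope="session")
def cache_plain():
    """Feature cache without an image encoder (zero image embeddings);
    isolates graph-branch behaviour and keeps unit tests fast."""
    return mt.FeatureCache(encoder=None)


@pytest.fixture(scope="session")
def molecules_300():
    return fixtures.generate_molecules(300, seed=42)


@pytest.fixture(scope="session")
def depictions_20(molecules_300):
    return [data_io.render_depiction(s) for s in molecules_300[:20]]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


def numeric_gradient(f, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central finite differences of a scalar function of the array ``x``
    (mutates and restores x in place)."""
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        x[i] += eps
        fp = f()
        x[i] -= 2 * eps
        fm = f()
        x[i] += eps
        g[i] = (fp - fm) / (2 * eps)
    return g
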