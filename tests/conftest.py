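import dataclasses

import numpy as np
import pytest

from permamicro import datagen
from permamicro.core_io import CountTable


@pytest.fixture(scope="session")
def default_experiment():
    """Generated paired experiment at study-condition defaults."""
    cfg = datagen.GeneratorConfig(seed=7)
    return datagen.generate_experiment(cfg)


@pytest.fixture(scope="session")
def noiseless_experiment():
    """Same design with cv_noise = 0: forward pipeline must recover truths exactly."""
    cfg = datagen.GeneratorConfig(seed=7, cv_noise=0.0)
    return datagen.generate_experiment(cfg)


@pytest.fixture()
def small_table():
    counts = np.array([[10, 0], [5, 20], [1, 4]])
    return CountTable(
        ["f1", "f2", "f3"],
        ["s1", "s2"],
        counts,
        {"f1": {"taxonomy": "A;x"}, "f2": {"taxonomy": "B;y"}, "f3": {"taxonomy": "B;z"}},
    )


def make_random_table(rng: np.random.Generator, n_features=50, n_samples=6, depth=1000):
    p = rng.dirichlet(np.ones(n_features))
    counts = np.column_stack([rng.multinomial(depth, p) for _ in range(n_samples)])
    return CountTable(
        [f"f{i}" for i in range(n_features)], [f"s{j}" for j in range(n_samples)], counts
    )
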