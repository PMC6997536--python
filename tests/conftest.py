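import numpy as np
import pandas as pd
import pytest

from miragg import SimConfig, SourceList, simulate_sources


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_source(name, genes, scores, direction="better-is-lower", mirna="hsa-miR-1"):
    return SourceList(
        name=name,
        entries=pd.DataFrame({"mirna": [mirna] * len(genes), "gene": list(genes), "score": scores}),
        direction=direction,
    )


@pytest.fixture
def toy_sources():
    """Three small overlapping sources over a shared gene universe."""
    return [
        make_source("a", ["g1", "g2", "g3", "g4"], [0.1, 0.2, 0.3, 0.4]),
        make_source("b", ["g2", "g3", "g5"], [5.0, 1.0, 3.0], direction="better-is-higher"),
        make_source("c", ["g1", "g5"], [0.01, 0.9]),
    ]


@pytest.fixture(scope="session")
def small_sim():
    """A modest simulated benchmark shared by read-only tests."""
    config = SimConfig(n_interactions=3000, n_sources=4, prevalence=0.05, signal=1.0, seed=11)
    sources, truth = simulate_sources(config)
    return config, sources, truth
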