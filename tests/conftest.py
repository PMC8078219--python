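import numpy as np
import pandas as pd
import pytest

import histocyto as hc


def make_table(rng: np.random.Generator, n: int, columns=("A", "B", "C")) -> hc.CoiTable:
    """Random numeric table with ids 1..n, for gating/filter oracle tests."""
    data = {"ID": np.arange(1, n + 1, dtype=np.int64)}
    for c in columns:
        data[c] = rng.uniform(0, 255, size=n)
    return hc.CoiTable(pd.DataFrame(data), {"id": "ID"}, {})


@pytest.fixture(scope="session")
def tiny_spec() -> hc.SceneSpec:
    """Noise-free 18-cell scene: two well-separated membrane populations,
    planted contacts, no planted cluster."""
    return hc.SceneSpec(
        size=(384, 384), n_slices=8,
        populations=[
            hc.PopulationSpec("T", 10, {"LT": (180.0, 0.0), "LB": (30.0, 0.0)}),
            hc.PopulationSpec("B", 8, {"LT": (30.0, 0.0), "LB": (180.0, 0.0)}),
        ],
        cluster=None, contact_fraction=0.3, noise_sd=0.0, seed=11)


@pytest.fixture(scope="session")
def tiny_bundle(tiny_spec, tmp_path_factory):
    out = tmp_path_factory.mktemp("tiny_bundle")
    paths, truth = hc.generate(tiny_spec, out)
    return paths, truth


@pytest.fixture(scope="session")
def usecase_bundle(tmp_path_factory):
    """The default study-scale preset: 176 cells, 6 channels, 12 slices,
    planted T/B mixture, dense region and contacts."""
    out = tmp_path_factory.mktemp("usecase_bundle")
    spec = hc.usecase_spec(seed=7)
    paths, truth = hc.generate(spec, out)
    return paths, truth
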