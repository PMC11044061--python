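from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from msnpipe.atlas import synthetic_atlas
from msnpipe.msn import FEATURES

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def atlas():
    return synthetic_atlas()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240416)


def random_weighted_graph(rng: np.random.Generator, n: int, p_edge: float = 0.5) -> np.ndarray:
    """Random symmetric weight matrix in [0, 1] with zero diagonal."""
    w = rng.uniform(0.05, 1.0, size=(n, n))
    mask = rng.random(size=(n, n)) < p_edge
    w = np.triu(w * mask, k=1)
    return w + w.T


def make_morphometry(rng: np.random.Generator, n_regions: int = 8) -> pd.DataFrame:
    """Small random per-subject morphometric table."""
    table = pd.DataFrame(
        rng.normal(size=(n_regions, len(FEATURES))), columns=list(FEATURES)
    )
    table.insert(0, "region_id", [f"R{i:03d}" for i in range(n_regions)])
    return table
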