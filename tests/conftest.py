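"""Shared fixtures: tiny graphs, chain models and simulated samples."""

import numpy as np
import pandas as pd
import pytest

from pathsem.graph import PathwayGraph
from pathsem.model import PathModel


def chain_model(p: int, names: list | None = None) -> PathModel:
    """A causal chain y0 -> y1 -> ... -> y(p-1)."""
    names = names or [f"y{i}" for i in range(p)]
    m = PathModel(names)
    for k in range(p - 1):
        m.add_beta(names[k + 1], names[k], provenance="kegg:activation")
    return m


def chain_beta(p: int, coef: float = 0.5) -> np.ndarray:
    B = np.zeros((p, p))
    for k in range(p - 1):
        B[k + 1, k] = coef
    return B


def draw(B: np.ndarray, n: int, rng, psi: np.ndarray | None = None) -> np.ndarray:
    """Exact linear-system sampler used as the independent simulation oracle."""
    p = B.shape[0]
    L = np.eye(p) if psi is None else np.linalg.cholesky(psi)
    U = rng.standard_normal((n, p)) @ L.T
    return np.linalg.solve(np.eye(p) - B, U.T).T


@pytest.fixture
def tiny_graph() -> PathwayGraph:
    """a -> b -> c -> d plus a shortcut a -> c."""
    g = PathwayGraph()
    for s, t, k in [
        ("a", "b", "activation"),
        ("b", "c", "inhibition"),
        ("c", "d", "activation"),
        ("a", "c", "binding"),
    ]:
        g.add_edge(s, t, k)
    return g


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240501)


@pytest.fixture
def chain5_data(rng) -> tuple:
    """n=400 samples from a 5-node chain with coefficient 0.5."""
    B = chain_beta(5)
    X = draw(B, 400, rng)
    return chain_model(5), pd.DataFrame(X, columns=[f"y{i}" for i in range(5)]), B
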