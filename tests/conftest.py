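"""Shared fixtures: tiny node tables, exhaustive DAG enumeration, toy data."""

from __future__ import annotations

import networkx as nx
import numpy as np
import pytest

from omicsbn.omics_io import NODE_GE, Node, NodeTable


def make_ge_table(n: int) -> NodeTable:
    return NodeTable([Node(f"G{i + 1}", NODE_GE, f"G{i + 1}")
                      for i in range(n)])


def all_dags(n: int) -> list[list[frozenset[int]]]:
    """Every labelled DAG on n nodes, as parent-set lists (brute force)."""
    pairs = [(i, j) for i in range(n) for j in range(n) if i != j]
    out = []
    for bits in range(2 ** len(pairs)):
        ps = [frozenset() for _ in range(n)]
        g = nx.DiGraph()
        g.add_nodes_from(range(n))
        for k, (i, j) in enumerate(pairs):
            if bits >> k & 1:
                g.add_edge(i, j)
                ps[j] = ps[j] | {i}
        if nx.is_directed_acyclic_graph(g):
            out.append(ps)
    return out


@pytest.fixture(scope="session")
def dags3() -> list[list[frozenset[int]]]:
    return all_dags(3)


@pytest.fixture(scope="session")
def dags4() -> list[list[frozenset[int]]]:
    return all_dags(4)


@pytest.fixture(scope="session")
def chain_data3() -> np.ndarray:
    """Standardised data simulated from the chain G1 -> G2 -> G3."""
    rng = np.random.default_rng(5)
    m = 30
    x1 = rng.standard_normal(m)
    x2 = 0.8 * x1 + rng.standard_normal(m)
    x3 = 0.7 * x2 + rng.standard_normal(m)
    X = np.column_stack([x1, x2, x3])
    return (X - X.mean(0)) / X.std(0, ddof=1)


def standardise(X: np.ndarray) -> np.ndarray:
    return (X - X.mean(0)) / X.std(0, ddof=1)
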