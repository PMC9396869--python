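"""Posterior summarisation: CPDAGs, edge weights, thresholding, export.

DAGs sampled by the chain are converted to the completed partially
directed acyclic graph (CPDAG) of their Markov equivalence class —
compelled edges directed, reversible edges undirected — deduplicated per
chain, pooled across the two independent chains, and summarised as
empirical edge frequencies ("edge weights").  Reported edges are those
whose weight reaches a quantile (default 0.75) of all positive weights.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .omics_io import NodeTable


@dataclass(frozen=True)
class CPDAG:
    """Equivalence-class representation of a DAG.

    ``directed`` holds compelled edges as ordered pairs; ``undirected``
    holds reversible edges as unordered pairs stored with i < j.
    """

    directed: frozenset[tuple[int, int]]
    undirected: frozenset[tuple[int, int]]

    def __post_init__(self):
        und_touch = {frozenset(e) for e in self.undirected}
        dir_touch = {frozenset(e) for e in self.directed}
        if und_touch & dir_touch:
            raise ValueError("an edge cannot be both compelled and reversible")


def _as_parent_sets(G) -> list[frozenset[int]]:
    if hasattr(G, "parent_sets"):
        return list(G.parent_sets)
    return [frozenset(p) for p in G]


def dag_to_cpdag(G) -> CPDAG:
    """Convert a DAG to its CPDAG.

    Unshielded colliders are oriented first, then Meek's rules R1-R3 are
    applied to a fixpoint; edges they orient are exactly the compelled
    edges of the equivalence class (no background knowledge, so R4 never
    fires).  Accepts a NetworkStructure or a list of parent sets.
    """
    parent_sets = _as_parent_sets(G)
    n = len(parent_sets)
    adj = np.zeros((n, n), dtype=bool)  # symmetric skeleton
    for j, pa in enumerate(parent_sets):
        for i in pa:
            adj[i, j] = adj[j, i] = True
    dirm = np.zeros((n, n), dtype=bool)  # oriented (compelled) edges

    # v-structures: a -> j <- b with a, b non-adjacent are compelled
    for j, pa in enumerate(parent_sets):
        pa = sorted(pa)
        for x in range(len(pa)):
            for y in range(x + 1, len(pa)):
                a, b = pa[x], pa[y]
                if not adj[a, b]:
                    dirm[a, j] = True
                    dirm[b, j] = True

    idx = np.arange(n)

    def oriented(i, j):
        return dirm[i, j] or dirm[j, i]

    changed = True
    while changed:
        changed = False
        for i, j in zip(*np.nonzero(adj)):
            if oriented(i, j):
                continue
            # Meek R1: a -> i, i - j, a and j non-adjacent  =>  i -> j
            if np.any(dirm[:, i] & ~adj[:, j] & (idx != j)):
                dirm[i, j] = True
                changed = True
                continue
            # Meek R2: i -> k -> j with i - j  =>  i -> j
            if np.any(dirm[i, :] & dirm[:, j]):
                dirm[i, j] = True
                changed = True
                continue
            # Meek R3: i - c -> j, i - d -> j, c and d non-adjacent => i -> j
            cands = np.flatnonzero(adj[i, :] & ~dirm[i, :] & ~dirm[:, i]
                                   & dirm[:, j])
            done = False
            for x in range(len(cands)):
                for y in range(x + 1, len(cands)):
                    if not adj[cands[x], cands[y]]:
                        dirm[i, j] = True
                        changed = True
                        done = True
                        break
                if done:
                    break

    directed = set()
    undirected = set()
    for j, pa in enumerate(parent_sets):
        for i in pa:
            if dirm[i, j] or dirm[j, i]:
                # orientations produced from a DAG agree with the DAG
                directed.add((int(i), int(j)))
            else:
                undirected.add((min(int(i), int(j)), max(int(i), int(j))))
    return CPDAG(directed=frozenset(directed), undirected=frozenset(undirected))


def dedup_cpdags(cpdags: list[CPDAG]) -> list[CPDAG]:
    """Exact-equality dedup, preserving order of first appearance."""
    seen = set()
    out = []
    for c in cpdags:
        key = (c.directed, c.undirected)
        if key not in seen:
            seen.add(key)
            out.append(c)
    return out


@dataclass
class EdgeWeightMatrix:
    """Empirical edge frequencies over the pooled CPDAG sample.

    An undirected (reversible) edge contributes to both ordered pairs,
    so reversible evidence is never discarded.
    """

    values: np.ndarray  # N x N, w_ij = frequency of edge i -> j
    n_samples: int


def cpdag_indicator(c: CPDAG, n: int) -> np.ndarray:
    """N x N 0/1 matrix of edge presence, undirected edges on both pairs."""
    M = np.zeros((n, n))
    for i, j in c.directed:
        M[i, j] = 1.0
    for i, j in c.undirected:
        M[i, j] = 1.0
        M[j, i] = 1.0
    return M


def edge_weights(cpdags: list[CPDAG], n_nodes: int) -> EdgeWeightMatrix:
    """Empirical frequency of each ordered edge over the pooled sample."""
    if not cpdags:
        raise ValueError("empty CPDAG sample")
    total = np.zeros((n_nodes, n_nodes))
    for c in cpdags:
        total += cpdag_indicator(c, n_nodes)
    return EdgeWeightMatrix(values=total / len(cpdags), n_samples=len(cpdags))


def threshold_edges(weights: EdgeWeightMatrix,
                    q: float = 0.75) -> set[tuple[int, int]]:
    """Edges whose weight reaches the q-quantile of all positive weights.

    The quantile uses linear interpolation (R type 7, the numpy default).
    """
    if not 0.0 <= q <= 1.0:
        raise ValueError("q must lie in [0, 1]")
    w = weights.values
    positive = w[w > 0]
    if positive.size == 0:
        return set()
    thr = float(np.quantile(positive, q))
    return {(int(i), int(j)) for i, j in zip(*np.nonzero(w >= thr)) if w[i, j] > 0}


def export_network(weights: EdgeWeightMatrix, kept: set[tuple[int, int]],
                   table: NodeTable, out_dir: str | Path,
                   prefix: str = "network") -> dict[str, Path]:
    """Write the weighted network as TSV edge list, SIF and GraphML."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    nodes = table.nodes
    rows = []
    for i, j in zip(*np.nonzero(weights.values)):
        rows.append({
            "source": nodes[i].id, "target": nodes[j].id,
            "weight": float(weights.values[i, j]),
            "kept": bool((int(i), int(j)) in kept),
        })
    rows.sort(key=lambda r: (-r["weight"], r["source"], r["target"]))
    edge_df = pd.DataFrame(rows, columns=["source", "target", "weight", "kept"])
    tsv_path = out_dir / "edge_weights.tsv"
    edge_df.to_csv(tsv_path, sep="\t", index=False)

    sif_path = out_dir / f"{prefix}.sif"
    with open(sif_path, "w") as fh:
        for i, j in sorted(kept):
            fh.write(f"{nodes[i].id}\t{nodes[i].type}-{nodes[j].type}\t"
                     f"{nodes[j].id}\n")

    g = nx.DiGraph()
    for node in nodes:
        g.add_node(node.id, nodeType=node.type, gene=node.gene)
    for i, j in sorted(kept):
        g.add_edge(nodes[i].id, nodes[j].id,
                   weight=float(weights.values[i, j]))
    graphml_path = out_dir / f"{prefix}.graphml"
    nx.write_graphml(g, graphml_path)
    return {"edges": tsv_path, "sif": sif_path, "graphml": graphml_path}
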