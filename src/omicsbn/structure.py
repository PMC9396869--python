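"""DAG state over typed nodes, with admissibility and parent-count caps."""

from __future__ import annotations

import numpy as np

from .omics_io import NODE_CNV, NODE_GE, NODE_METH, NodeTable
from .prior import ConstraintSet, admissible_matrix


def transitive_closure(A: np.ndarray) -> np.ndarray:
    """Boolean matrix of directed paths of length >= 1 (strict closure)."""
    n = A.shape[0]
    M = A | np.eye(n, dtype=bool)
    while True:
        M2 = M @ M
        if (M2 == M).all():
            break
        M = M2
    return A @ M  # first step an edge, then any walk: paths of length >= 1


class NetworkStructure:
    """A DAG over the typed node set.

    Parent sets are the primary representation; a boolean adjacency
    matrix ``A`` (``A[i, j]`` means edge i -> j) and the strict
    transitive closure ``R`` are kept in sync for fast cycle checks.
    """

    def __init__(self, table: NodeTable,
                 constraints: ConstraintSet | None = None,
                 parent_sets: list[frozenset[int]] | None = None):
        self.table = table
        self.constraints = constraints if constraints is not None else ConstraintSet()
        N = len(table)
        self.types = table.types
        self.is_ge = self.types == NODE_GE
        self.admissible = admissible_matrix(table)
        if parent_sets is None:
            parent_sets = [frozenset() for _ in range(N)]
        self.parent_sets: list[frozenset[int]] = list(parent_sets)
        self.A = np.zeros((N, N), dtype=bool)
        for j, pa in enumerate(self.parent_sets):
            for i in pa:
                self.A[i, j] = True
        self.R = transitive_closure(self.A)
        self.validate()

    @property
    def n_nodes(self) -> int:
        return len(self.table)

    @property
    def n_edges(self) -> int:
        return int(self.A.sum())

    def edges(self) -> list[tuple[int, int]]:
        return [(int(i), int(j)) for i, j in zip(*np.nonzero(self.A))]

    def copy(self) -> "NetworkStructure":
        new = object.__new__(NetworkStructure)
        new.table = self.table
        new.constraints = self.constraints
        new.types = self.types
        new.is_ge = self.is_ge
        new.admissible = self.admissible
        new.parent_sets = list(self.parent_sets)
        new.A = self.A.copy()
        new.R = self.R.copy()
        return new

    # -- parent-count bookkeeping ------------------------------------
    def parent_type_count(self, j: int, node_type: str) -> int:
        return sum(1 for p in self.parent_sets[j] if self.types[p] == node_type)

    def cap_allows(self, i: int, j: int) -> bool:
        """Would adding parent i to node j respect the per-type caps?"""
        c = self.constraints
        t = self.types[i]
        if t == NODE_GE:
            return self.parent_type_count(j, NODE_GE) < c.max_ge_parents
        if t == NODE_CNV:
            return self.parent_type_count(j, NODE_CNV) < c.max_cnv_parents
        cap = c.max_meth_parents
        return cap is None or self.parent_type_count(j, NODE_METH) < cap

    # -- mutation ----------------------------------------------------
    def _refresh_closure(self) -> None:
        self.R = transitive_closure(self.A)

    def add_edge(self, i: int, j: int) -> None:
        self.A[i, j] = True
        self.parent_sets[j] = self.parent_sets[j] | {i}
        # closure gains paths u ~> i -> j ~> v
        src = self.R[:, i].copy()
        src[i] = True
        dst = self.R[j, :].copy()
        dst[j] = True
        self.R |= np.outer(src, dst)

    def delete_edge(self, i: int, j: int) -> None:
        self.A[i, j] = False
        self.parent_sets[j] = self.parent_sets[j] - {i}
        self._refresh_closure()

    def set_parents(self, j: int, parents: frozenset[int]) -> None:
        self.A[:, j] = False
        for i in parents:
            self.A[i, j] = True
        self.parent_sets[j] = frozenset(parents)
        self._refresh_closure()

    def apply_move(self, move) -> None:
        kind, i, j = move
        if kind == "add":
            self.add_edge(i, j)
        elif kind == "delete":
            self.delete_edge(i, j)
        elif kind == "reverse":
            self.delete_edge(i, j)
            self.add_edge(j, i)
        else:
            raise ValueError(f"unknown move kind {kind!r}")

    # -- validation --------------------------------------------------
    def validate(self) -> None:
        if np.any(self.R.diagonal()):
            raise ValueError("structure contains a cycle")
        c = self.constraints
        for j, pa in enumerate(self.parent_sets):
            for i in pa:
                if not self.admissible[i, j]:
                    raise ValueError(f"edge {i}->{j} is not admissible")
            if self.parent_type_count(j, NODE_GE) > c.max_ge_parents and self.is_ge[j]:
                raise ValueError(f"node {j} exceeds the GE-parent cap")
            if self.parent_type_count(j, NODE_CNV) > c.max_cnv_parents:
                raise ValueError(f"node {j} exceeds the CNV-parent cap")
            if (c.max_meth_parents is not None
                    and self.parent_type_count(j, NODE_METH) > c.max_meth_parents):
                raise ValueError(f"node {j} exceeds the METH-parent cap")

    def __eq__(self, other) -> bool:
        return (isinstance(other, NetworkStructure)
                and self.parent_sets == other.parent_sets)

    def __hash__(self) -> int:
        return hash(tuple(self.parent_sets))
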