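"""Energy-based structure prior over regulatory networks.

The biological prior knowledge is a matrix ``B`` over admissible ordered
node pairs with entries in [0, 1]: 1 for a curated directed interaction,
0.75 for a transcription-factor/target association, 0.5 for "no
knowledge", 0 for a known non-edge.  A structure G is scored by its
energy — the total disagreement between B and G's parent sets —

    eps(j, pa) = sum_{i in pa} (1 - B_ij) + sum_{i in C_j \\ pa} B_ij,
    E(G) = sum_j eps(j, pa_j),

and the prior is the Gibbs distribution P(G | beta) = exp(-beta E(G)) / Z(beta)
with inverse-temperature-like strength beta (>= 0.5).  Z is replaced by
its node-factorised upper bound, obtained by summing over admissible
parent sets per node while ignoring global acyclicity.

Type rules: only GE nodes may have parents; a CNV or METH node may only
parent the GE node of its own gene.  Pairs forbidden by type carry no B
entry at all (hard exclusion), whereas B = 0 on an admissible pair is a
soft penalty.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .omics_io import NODE_CNV, NODE_GE, NODE_METH, NodeTable

PROV_DATABASE = "database_edge"   # B = 1
PROV_TF = "tf_target"             # B = 0.75
PROV_UNKNOWN = "unknown"          # B = 0.5
PROV_FORBIDDEN = "forbidden"      # B = 0
PROV_EMPIRICAL = "empirical"      # estimated from chain acceptance statistics


@dataclass
class ConstraintSet:
    """Per-type parent-count caps for GE nodes.

    Defaults reflect the sparsity of transcriptional control: at most
    three GE parents, at most one CNV parent (the gene's own copy
    number), and no cap on (own-gene) METH parents.  CNV and METH nodes
    never have parents.
    """

    max_ge_parents: int = 3
    max_cnv_parents: int = 1
    max_meth_parents: int | None = None

    def __post_init__(self) -> None:
        if self.max_ge_parents < 0 or self.max_cnv_parents < 0:
            raise ValueError("parent caps must be non-negative")
        if self.max_meth_parents is not None and self.max_meth_parents < 0:
            raise ValueError("parent caps must be non-negative")


@dataclass
class BetaState:
    """Prior-strength parameter and its Gaussian proposal scale."""

    beta: float
    sigma: float = 5.0
    beta_min: float = 0.5

    def __post_init__(self) -> None:
        if self.beta < self.beta_min:
            raise ValueError(f"beta must be >= {self.beta_min}")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


def admissible_matrix(table: NodeTable) -> np.ndarray:
    """Boolean N x N matrix of admissible ordered pairs (parent, child)."""
    types = table.types
    genes = table.genes
    N = len(table)
    adm = np.zeros((N, N), dtype=bool)
    is_ge = types == NODE_GE
    # GE -> GE (all ordered pairs, no self loops)
    adm[np.ix_(is_ge, is_ge)] = True
    np.fill_diagonal(adm, False)
    # CNV/METH -> own-gene GE only
    for i in np.flatnonzero(~is_ge):
        for j in np.flatnonzero(is_ge):
            if genes[i] == genes[j]:
                adm[i, j] = True
    return adm


class PriorKnowledgeMatrix:
    """B entries over every admissible ordered pair, with provenance.

    ``values`` is a dense N x N float array that is only meaningful where
    ``admissible`` is True; ``provenance`` tracks where each entry came
    from so that empirical estimates never overwrite curated knowledge.
    """

    def __init__(self, table: NodeTable, values: np.ndarray | None = None,
                 provenance: np.ndarray | None = None):
        self.table = table
        self.admissible = admissible_matrix(table)
        N = len(table)
        if values is None:
            values = np.where(self.admissible, 0.5, 0.0)
            provenance = np.where(self.admissible, PROV_UNKNOWN, "").astype(object)
        self.values = np.asarray(values, dtype=float)
        if provenance is None:
            provenance = np.where(self.admissible, PROV_UNKNOWN, "").astype(object)
        self.provenance = np.asarray(provenance, dtype=object)
        self.validate()

    def validate(self) -> None:
        vals = self.values[self.admissible]
        if ((vals < 0) | (vals > 1)).any():
            raise ValueError("B entries must lie in [0, 1]")

    def copy(self) -> "PriorKnowledgeMatrix":
        return PriorKnowledgeMatrix(self.table, self.values.copy(),
                                    self.provenance.copy())

    def set_entry(self, i: int, j: int, value: float, provenance: str) -> None:
        if not self.admissible[i, j]:
            raise ValueError(f"pair ({i}, {j}) is not admissible")
        if not 0.0 <= value <= 1.0:
            raise ValueError("B entries must lie in [0, 1]")
        self.values[i, j] = value
        self.provenance[i, j] = provenance

    def candidates(self, j: int) -> np.ndarray:
        """Admissible candidate parents of node j (index array)."""
        return np.flatnonzero(self.admissible[:, j])


_PROV_FOR_VALUE = {1.0: PROV_DATABASE, 0.75: PROV_TF,
                   0.5: PROV_UNKNOWN, 0.0: PROV_FORBIDDEN}


def load_prior(path: str | Path, table: NodeTable) -> PriorKnowledgeMatrix:
    """Read prior knowledge from a TSV edge list (source, target, value)
    or a square matrix; unlisted admissible pairs default to 0.5."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") >= header.count(",") else ","
    df = pd.read_csv(path, sep=sep, index_col=None)
    B = PriorKnowledgeMatrix(table)
    cols = [c.lower() for c in df.columns]
    if {"source", "target", "value"}.issubset(cols):
        df.columns = cols
        for _, row in df.iterrows():
            i = table.index.get(str(row["source"]))
            j = table.index.get(str(row["target"]))
            if i is None or j is None:
                continue
            v = float(row["value"])
            B.set_entry(i, j, v, _PROV_FOR_VALUE.get(v, PROV_DATABASE))
    else:
        mat = pd.read_csv(path, sep=sep, index_col=0)
        for src in mat.index:
            for tgt in mat.columns:
                i, j = table.index.get(str(src)), table.index.get(str(tgt))
                if i is None or j is None or not B.admissible[i, j]:
                    continue
                v = float(mat.loc[src, tgt])
                B.set_entry(i, j, v, _PROV_FOR_VALUE.get(v, PROV_DATABASE))
    return B


def local_energy(j: int, parents, B: PriorKnowledgeMatrix) -> float:
    """Disagreement between node j's parent set and the prior knowledge."""
    cand = B.candidates(j)
    parents = set(int(p) for p in parents)
    if not parents <= set(cand.tolist()):
        raise ValueError(f"parents of node {j} include an inadmissible pair")
    b = B.values[cand, j]
    in_pa = np.array([c in parents for c in cand])
    return float(np.sum(np.where(in_pa, 1.0 - b, b)))


def graph_energy(parent_sets, B: PriorKnowledgeMatrix) -> float:
    """E(G): sum of local energies over all nodes."""
    if isinstance(parent_sets, dict):
        items = parent_sets.items()
    else:
        items = enumerate(parent_sets)
    return float(sum(local_energy(j, pa, B) for j, pa in items))


def energy_edge_delta(i: int, j: int, B: PriorKnowledgeMatrix) -> float:
    """Change in E(G) when edge i -> j is added: (1 - B_ij) - B_ij."""
    return float(1.0 - 2.0 * B.values[i, j])


def _elementary_symmetric(w: np.ndarray, k: int) -> np.ndarray:
    """e_0..e_k of the weights w via the standard DP recurrence."""
    e = np.zeros(k + 1)
    e[0] = 1.0
    for idx, wi in enumerate(w):
        for r in range(min(k, idx + 1), 0, -1):
            e[r] += wi * e[r - 1]
    return e


def log_partition_upper(beta: float, B: PriorKnowledgeMatrix,
                        constraints: ConstraintSet | None = None) -> float:
    """Node-factorised upper bound on log Z(beta).

    Per node, sum exp(-beta * eps) over admissible parent sets under the
    per-type cardinality caps, ignoring global acyclicity.  With
    ``w_i = exp(-beta (1 - 2 B_ij))`` the sum over size-capped GE subsets
    is a sum of elementary symmetric polynomials; the (single) CNV
    candidate contributes a factor (1 + w) and uncapped METH candidates a
    product of (1 + w) factors.
    """
    if beta < 0:
        raise ValueError("beta must be non-negative")
    if constraints is None:
        constraints = ConstraintSet()
    types = B.table.types
    total = 0.0
    for j in range(len(B.table)):
        cand = B.candidates(j)
        if cand.size == 0:
            continue  # node can have no parents: single empty set, eps = 0
        b = B.values[cand, j]
        colsum = float(np.sum(b))
        logw = -beta * (1.0 - 2.0 * b)
        factor = 0.0  # log scale
        ctypes = types[cand]
        for t, cap in ((NODE_GE, constraints.max_ge_parents),
                       (NODE_CNV, constraints.max_cnv_parents),
                       (NODE_METH, constraints.max_meth_parents)):
            lw = logw[ctypes == t]
            if lw.size == 0:
                continue
            if cap is None or cap >= lw.size:
                # unconstrained: product of (1 + w), stable in log space
                factor += float(np.sum(np.logaddexp(0.0, lw)))
            else:
                shift = float(lw.max())
                e = _elementary_symmetric(np.exp(lw - shift), cap)
                scale = shift * np.arange(cap + 1)
                m = float(scale.max())
                factor += m + float(np.log(np.sum(e * np.exp(scale - m))))
        total += -beta * colsum + factor
    return total


def log_prior(parent_sets, beta: float, B: PriorKnowledgeMatrix,
              constraints: ConstraintSet | None = None) -> float:
    """log P(G | beta) = -beta E(G) - log Z_upper(beta)."""
    return (-beta * graph_energy(parent_sets, B)
            - log_partition_upper(beta, B, constraints))


def log_beta_ratio(parent_sets, beta_candidate: float, beta_current: float,
                   B: PriorKnowledgeMatrix,
                   constraints: ConstraintSet | None = None,
                   energy: float | None = None) -> float:
    """log [P(G | beta_c) / P(G | beta_s)] for a fixed structure G."""
    if energy is None:
        energy = graph_energy(parent_sets, B)
    return (-(beta_candidate - beta_current) * energy
            - (log_partition_upper(beta_candidate, B, constraints)
               - log_partition_upper(beta_current, B, constraints)))
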