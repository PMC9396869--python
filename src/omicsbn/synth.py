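"""Synthetic multi-omics generator with known ground truth.

Emulates the mechanisms the inference targets: a random typed DAG whose
GE-GE skeleton respects the three-parent cap, positive copy-number
gene-dosage effects on the own gene's expression, methylation effects on
the own gene's expression (negative by default, promoter-style), linear
Gaussian structural equations, and a corrupted prior that retains a
stated fraction of the true edges.  Every other module can therefore be
exercised end to end without any external download.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .omics_io import (NODE_CNV, NODE_GE, NODE_METH, Node, NodeTable,
                       OmicsDataset)
from .prior import ConstraintSet, PriorKnowledgeMatrix, PROV_DATABASE


@dataclass
class GroundTruthModel:
    """True DAG over typed nodes plus structural-equation parameters."""

    table: NodeTable
    coefficients: dict[tuple[int, int], float]  # (parent, child) -> coef
    noise_sd: dict[int, float] = field(default_factory=dict)

    def parents_of(self, j: int) -> list[int]:
        return [i for (i, jj) in self.coefficients if jj == j]

    def edges(self) -> set[tuple[int, int]]:
        return set(self.coefficients)

    def ge_edges(self) -> set[tuple[int, int]]:
        types = self.table.types
        return {(i, j) for i, j in self.coefficients
                if types[i] == NODE_GE and types[j] == NODE_GE}

    def validate(self, constraints: ConstraintSet | None = None) -> None:
        from .structure import NetworkStructure
        n = len(self.table)
        parent_sets = [frozenset() for _ in range(n)]
        for (i, j) in self.coefficients:
            parent_sets[j] = parent_sets[j] | {i}
        NetworkStructure(self.table, constraints, parent_sets)  # raises
        types = self.table.types
        for (i, j), c in self.coefficients.items():
            if abs(c) < 1e-12:
                raise ValueError("zero structural coefficient")
            if types[i] == NODE_CNV and c <= 0:
                raise ValueError("CNV dosage effects must be positive")


@dataclass
class GoldStandard:
    """Reference edge set and the universe of evaluable ordered pairs."""

    reference: set[tuple[str, str]]
    universe: list[tuple[str, str]]

    def __post_init__(self):
        if not self.reference <= set(self.universe):
            raise ValueError("reference edges must lie in the universe")


def random_typed_dag(n_genes: int, edge_density: float = 0.2,
                     cnv_fraction: float = 0.4, meth_per_gene: float = 0.6,
                     rng: np.random.Generator | None = None,
                     constraints: ConstraintSet | None = None,
                     meth_effect_sign: int = -1,
                     coef_min: float = 0.3, coef_max: float = 1.0,
                     n_cnv: int | None = None,
                     n_meth: int | None = None) -> GroundTruthModel:
    """Sample a ground-truth model over typed nodes.

    The GE-GE skeleton is drawn under a random topological order with at
    most three GE parents per gene; a fraction of genes carries a CNV
    parent (positive dosage coefficient) and methylation probes are
    attached per gene (``meth_per_gene`` on average, or exactly
    ``n_meth`` probes if given).  Coefficients are +-U[coef_min,
    coef_max], CNV coefficients positive, METH coefficients with the
    configured sign.
    """
    if rng is None:
        rng = np.random.default_rng()
    if not 0.0 <= edge_density < 1.0:
        raise ValueError("edge_density must lie in [0, 1)")
    if constraints is None:
        constraints = ConstraintSet()
    if meth_effect_sign not in (-1, 1):
        raise ValueError("meth_effect_sign must be -1 or +1")
    genes = [f"G{k + 1}" for k in range(n_genes)]
    order = rng.permutation(n_genes)

    def coef(sign: int | None = None) -> float:
        mag = float(rng.uniform(coef_min, coef_max))
        if sign is None:
            sign = -1 if rng.random() < 0.5 else 1
        return sign * mag

    nodes = [Node(id=g, type=NODE_GE, gene=g) for g in genes]
    coefficients: dict[tuple[int, int], float] = {}
    for pos in range(1, n_genes):
        j = int(order[pos])
        preds = [int(order[p]) for p in range(pos)]
        k = min(int(rng.binomial(len(preds), edge_density)),
                constraints.max_ge_parents)
        for i in rng.choice(preds, size=k, replace=False) if k else []:
            coefficients[(int(i), j)] = coef()

    # CNV parents (own gene, positive dosage coefficient)
    if n_cnv is not None:
        cnv_genes = sorted(rng.choice(n_genes, size=n_cnv, replace=False))
    else:
        cnv_genes = [g for g in range(n_genes) if rng.random() < cnv_fraction]
    cnv_edges = []
    for g in cnv_genes:
        idx = len(nodes)
        nodes.append(Node(id=f"cnv_{genes[g]}", type=NODE_CNV, gene=genes[g]))
        cnv_edges.append((idx, g))

    # METH parents (own gene, configured sign)
    if n_meth is not None:
        probe_genes = [int(g) for g in rng.choice(n_genes, size=n_meth,
                                                  replace=n_meth > n_genes)]
    else:
        probe_genes = []
        for g in range(n_genes):
            count = int(np.floor(meth_per_gene))
            if rng.random() < meth_per_gene - count:
                count += 1
            probe_genes.extend([g] * count)
    meth_edges = []
    probe_counter: dict[int, int] = {}
    for g in probe_genes:
        probe_counter[g] = probe_counter.get(g, 0) + 1
        idx = len(nodes)
        nodes.append(Node(id=f"meth_{genes[g]}_{probe_counter[g]}",
                          type=NODE_METH, gene=genes[g]))
        meth_edges.append((idx, g))

    for i, j in cnv_edges:
        coefficients[(i, j)] = coef(sign=1)
    for i, j in meth_edges:
        coefficients[(i, j)] = coef(sign=meth_effect_sign)

    model = GroundTruthModel(table=NodeTable(nodes=nodes),
                             coefficients=coefficients,
                             noise_sd={k: 1.0 for k in range(len(nodes))})
    model.validate(constraints)
    return model


def simulate_multiomics(model: GroundTruthModel, m: int,
                        rng: np.random.Generator | None = None
                        ) -> OmicsDataset:
    """Ancestral sampling of the linear-Gaussian structural equations.

    CNV and latent METH root values are N(0, 1); methylation beta-values
    are the logistic transform of the latent values (so they lie in
    (0, 1)); each GE value is the coefficient-weighted sum of its
    parents' structural values plus Gaussian noise.
    """
    if rng is None:
        rng = np.random.default_rng()
    if m < 2:
        raise ValueError("need at least 2 samples")
    table = model.table
    n = len(table)
    types = table.types
    values = np.zeros((m, n))
    parents: dict[int, list[tuple[int, float]]] = {j: [] for j in range(n)}
    for (i, j), c in model.coefficients.items():
        parents[j].append((i, c))

    order = _topological_order(n, model.coefficients)
    for j in order:
        sd = model.noise_sd.get(j, 1.0)
        col = sd * rng.standard_normal(m)
        for i, c in parents[j]:
            col = col + c * values[:, i]
        values[:, j] = col

    samples = [f"S{k + 1}" for k in range(m)]
    is_ge = types == NODE_GE
    is_cnv = types == NODE_CNV
    is_meth = types == NODE_METH
    ge = pd.DataFrame(values[:, is_ge], index=samples,
                      columns=[nd.id for nd in table if nd.type == NODE_GE])
    cnv = pd.DataFrame(values[:, is_cnv], index=samples,
                       columns=[nd.id for nd in table if nd.type == NODE_CNV])
    meth_latent = values[:, is_meth]
    meth = pd.DataFrame(1.0 / (1.0 + np.exp(-meth_latent)), index=samples,
                        columns=[nd.id for nd in table if nd.type == NODE_METH])
    cnv_map = {nd.id: nd.gene for nd in table if nd.type == NODE_CNV}
    meth_map = {nd.id: nd.gene for nd in table if nd.type == NODE_METH}
    ds = OmicsDataset(ge=ge, cnv=cnv, meth=meth, cnv_gene_map=cnv_map,
                      meth_gene_map=meth_map)
    ds.validate()
    return ds


def _topological_order(n: int, coefficients) -> list[int]:
    children: dict[int, list[int]] = {i: [] for i in range(n)}
    indeg = [0] * n
    for (i, j) in coefficients:
        children[i].append(j)
        indeg[j] += 1
    ready = [v for v in range(n) if indeg[v] == 0]
    out = []
    while ready:
        v = ready.pop()
        out.append(v)
        for c in children[v]:
            indeg[c] -= 1
            if indeg[c] == 0:
                ready.append(c)
    if len(out) != n:
        raise ValueError("coefficient graph contains a cycle")
    return out


def corrupt_prior(model: GroundTruthModel, keep_fraction: float,
                  rng: np.random.Generator | None = None
                  ) -> PriorKnowledgeMatrix:
    """Prior retaining a random fraction of the true GE-GE edges as B = 1.

    The number kept is floor(keep_fraction * n_edges); all other
    admissible pairs stay at 0.5 ("no knowledge").
    """
    if rng is None:
        rng = np.random.default_rng()
    if not 0.0 <= keep_fraction <= 1.0:
        raise ValueError("keep_fraction must lie in [0, 1]")
    B = PriorKnowledgeMatrix(model.table)
    true_edges = sorted(model.ge_edges())
    n_keep = int(np.floor(keep_fraction * len(true_edges) + 1e-9))
    if n_keep and true_edges:
        chosen = rng.choice(len(true_edges), size=n_keep, replace=False)
        for k in chosen:
            i, j = true_edges[int(k)]
            B.set_entry(i, j, 1.0, PROV_DATABASE)
    return B


def gold_standard(model: GroundTruthModel, ge_only: bool = False
                  ) -> GoldStandard:
    """Gold standard from the true edges; the universe is the admissible
    ordered pairs (optionally GE-GE only), excluding self-pairs."""
    from .prior import admissible_matrix
    table = model.table
    adm = admissible_matrix(table)
    types = table.types
    ids = [nd.id for nd in table]
    universe = []
    for i, j in zip(*np.nonzero(adm)):
        if ge_only and not (types[i] == NODE_GE and types[j] == NODE_GE):
            continue
        universe.append((ids[i], ids[j]))
    edges = model.edges() if not ge_only else model.ge_edges()
    reference = {(ids[i], ids[j]) for i, j in edges}
    return GoldStandard(reference=reference, universe=universe)
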