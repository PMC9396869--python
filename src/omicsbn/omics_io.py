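"""Input, validation and preprocessing of the three omics matrices.

The framework operates on three sample-aligned matrices: gene expression
(GE, real values), copy-number variation (CNV, segment means, one feature
per gene) and DNA methylation (METH, beta-values in [0, 1], usually several
probes per gene).  This module reads them from delimited text, aligns the
samples, screens methylation probes for association with their gene's
expression, and assembles the typed node set over which networks are
learned.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

NODE_GE = "GE"
NODE_CNV = "CNV"
NODE_METH = "METH"


class OmicsIOError(ValueError):
    """Raised for malformed or inconsistent omics input."""


@dataclass
class OmicsDataset:
    """Sample-aligned GE/CNV/METH matrices plus feature-to-gene maps.

    All three data frames are indexed by the same ordered sample
    identifiers (GE order is canonical).  ``cnv_gene_map`` and
    ``meth_gene_map`` send feature identifiers to gene symbols that must
    exist among the GE columns.
    """

    ge: pd.DataFrame
    cnv: pd.DataFrame
    meth: pd.DataFrame
    cnv_gene_map: dict[str, str] = field(default_factory=dict)
    meth_gene_map: dict[str, str] = field(default_factory=dict)

    @property
    def samples(self) -> list[str]:
        return list(self.ge.index)

    @property
    def n_samples(self) -> int:
        return len(self.ge.index)

    @property
    def genes(self) -> list[str]:
        return list(self.ge.columns)

    def validate(self) -> None:
        m = self.n_samples
        if m < 2:
            raise OmicsIOError(f"need at least 2 shared samples, got {m}")
        for name, df in (("cnv", self.cnv), ("meth", self.meth)):
            if list(df.index) != self.samples:
                raise OmicsIOError(f"{name} matrix is not sample-aligned with GE")
        for df, name in ((self.ge, "GE"), (self.cnv, "CNV"), (self.meth, "METH")):
            if df.columns.duplicated().any():
                dupes = df.columns[df.columns.duplicated()].tolist()
                raise OmicsIOError(f"duplicate feature identifiers in {name}: {dupes}")
        bad = self.meth.columns[((self.meth < 0) | (self.meth > 1)).any(axis=0)]
        if len(bad):
            raise OmicsIOError(
                f"beta-values outside [0, 1] for probe(s): {list(bad)}"
            )
        genes = set(self.ge.columns)
        for fid, gene in {**self.cnv_gene_map, **self.meth_gene_map}.items():
            if gene not in genes:
                raise OmicsIOError(
                    f"feature {fid!r} maps to gene {gene!r} absent from the GE matrix"
                )


@dataclass(frozen=True)
class Node:
    """A typed network node: expression level, copy number or methylation."""

    id: str
    type: str  # one of NODE_GE / NODE_CNV / NODE_METH
    gene: str


@dataclass
class NodeTable:
    """Node list and id -> column position in the concatenated data matrix."""

    nodes: list[Node]

    def __post_init__(self) -> None:
        ids = [n.id for n in self.nodes]
        if len(set(ids)) != len(ids):
            raise OmicsIOError("duplicate node identifiers")
        ge_genes = [n.gene for n in self.nodes if n.type == NODE_GE]
        if len(set(ge_genes)) != len(ge_genes):
            raise OmicsIOError("more than one GE node per gene")
        self.index: dict[str, int] = {n.id: k for k, n in enumerate(self.nodes)}

    def __len__(self) -> int:
        return len(self.nodes)

    def __iter__(self):
        return iter(self.nodes)

    @property
    def types(self) -> np.ndarray:
        return np.array([n.type for n in self.nodes])

    @property
    def genes(self) -> np.ndarray:
        return np.array([n.gene for n in self.nodes])

    def ge_positions(self) -> np.ndarray:
        return np.flatnonzero(self.types == NODE_GE)


@dataclass
class ProbeScreenResult:
    """Outcome of regressing a gene's expression on one methylation probe."""

    probe: str
    gene: str
    p_value: float
    r2: float
    selected: bool


def _read_matrix(path: str | Path, kind: str) -> pd.DataFrame:
    """Read a delimited matrix: first column sample id, header of feature ids.

    Tab is the default separator; comma is accepted.
    """
    path = Path(path)
    if not path.exists():
        raise OmicsIOError(f"{kind} file not found: {path}")
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") >= header.count(",") else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad_rows = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            raise OmicsIOError(
                f"non-numeric value in {kind} file {path.name}, "
                f"column {col!r}, row(s) {list(bad_rows)[:5]}"
            )
    if df.isna().any().any():
        raise OmicsIOError(f"missing values in {kind} file {path.name}")
    return df


def _read_mapping(path: str | Path) -> tuple[dict[str, str], dict[str, str]]:
    path = Path(path)
    if not path.exists():
        raise OmicsIOError(f"mapping file not found: {path}")
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") >= header.count(",") else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    required = {"feature_id", "feature_type", "gene_symbol"}
    if not required.issubset(df.columns):
        raise OmicsIOError(
            f"mapping file must have columns {sorted(required)}, got {list(df.columns)}"
        )
    cnv_map, meth_map = {}, {}
    for _, row in df.iterrows():
        ftype = row["feature_type"].upper()
        if ftype == NODE_CNV:
            cnv_map[row["feature_id"]] = row["gene_symbol"]
        elif ftype == NODE_METH:
            meth_map[row["feature_id"]] = row["gene_symbol"]
        else:
            raise OmicsIOError(f"unknown feature_type {row['feature_type']!r}")
    return cnv_map, meth_map


def _drop_zero_variance(df: pd.DataFrame, kind: str) -> pd.DataFrame:
    var = df.var(axis=0, ddof=0)
    dead = var[var == 0.0].index
    if len(dead):
        logger.warning("dropping %d zero-variance %s feature(s): %s",
                       len(dead), kind, list(dead)[:10])
        df = df.drop(columns=dead)
    return df


def load_omics(ge_path, cnv_path, meth_path, mapping_path) -> OmicsDataset:
    """Load, align and validate the three omics matrices.

    Samples are restricted to the intersection across the three files, in
    GE order (the CNV/METH samples must be a superset of the GE samples).
    Zero-variance features are dropped with a warning.
    """
    ge = _read_matrix(ge_path, "GE")
    cnv = _read_matrix(cnv_path, "CNV")
    meth = _read_matrix(meth_path, "METH")
    cnv_map, meth_map = _read_mapping(mapping_path)

    shared = [s for s in ge.index if s in set(cnv.index) and s in set(meth.index)]
    if len(shared) < 2:
        raise OmicsIOError("fewer than 2 samples shared across GE/CNV/METH")
    if len(shared) < len(ge.index):
        logger.warning("restricting to %d shared samples (GE had %d)",
                       len(shared), len(ge.index))
    ge, cnv, meth = ge.loc[shared], cnv.loc[shared], meth.loc[shared]

    bad = meth.columns[((meth < 0) | (meth > 1)).any(axis=0)]
    if len(bad):
        raise OmicsIOError(f"beta-values outside [0, 1] for probe(s): {list(bad)}")

    ge = _drop_zero_variance(ge, "GE")
    cnv = _drop_zero_variance(cnv, "CNV")
    meth = _drop_zero_variance(meth, "METH")

    cnv_map = {f: g for f, g in cnv_map.items() if f in cnv.columns}
    meth_map = {f: g for f, g in meth_map.items() if f in meth.columns}
    # features whose gene was dropped (zero variance) are orphans
    genes = set(ge.columns)
    orphans = [f for f, g in {**cnv_map, **meth_map}.items() if g not in genes]
    if orphans:
        logger.warning("dropping %d feature(s) mapped to removed genes: %s",
                       len(orphans), orphans[:10])
        cnv = cnv.drop(columns=[f for f in orphans if f in cnv.columns])
        meth = meth.drop(columns=[f for f in orphans if f in meth.columns])
        cnv_map = {f: g for f, g in cnv_map.items() if f not in orphans}
        meth_map = {f: g for f, g in meth_map.items() if f not in orphans}
    ds = OmicsDataset(ge=ge, cnv=cnv, meth=meth,
                      cnv_gene_map=cnv_map, meth_gene_map=meth_map)
    ds.validate()
    return ds


def write_omics(dataset: OmicsDataset, ge_path, cnv_path, meth_path,
                mapping_path, sep: str = "\t") -> None:
    """Write a dataset back to the delimited-text dialect read by load_omics."""
    dataset.ge.to_csv(ge_path, sep=sep)
    dataset.cnv.to_csv(cnv_path, sep=sep)
    dataset.meth.to_csv(meth_path, sep=sep)
    rows = [{"feature_id": f, "feature_type": NODE_CNV, "gene_symbol": g}
            for f, g in dataset.cnv_gene_map.items()]
    rows += [{"feature_id": f, "feature_type": NODE_METH, "gene_symbol": g}
             for f, g in dataset.meth_gene_map.items()]
    pd.DataFrame(rows, columns=["feature_id", "feature_type", "gene_symbol"]
                 ).to_csv(mapping_path, sep=sep, index=False)


def orq_transform(values: np.ndarray) -> np.ndarray:
    """Ordered-quantile (rank-based inverse normal) transform.

    ``x_i -> Phi^{-1}((r_i - 0.5) / n)`` with average ranks on ties.  The
    output is a monotone function of the input with empirical mean ~ 0;
    methylation beta-values are mapped to an approximately Gaussian scale
    before they enter regression or network scoring.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size < 2:
        raise ValueError("orq_transform expects a 1-D vector of length >= 2")
    if not np.all(np.isfinite(values)):
        raise ValueError("orq_transform requires finite values")
    if np.ptp(values) == 0.0:
        raise ValueError("orq_transform undefined for a constant vector")
    r = stats.rankdata(values, method="average")
    return stats.norm.ppf((r - 0.5) / values.size)


def screen_meth_probes(dataset: OmicsDataset, p_threshold: float = 0.05,
                       r2_threshold: float = 0.3,
                       transform: bool = True) -> list[ProbeScreenResult]:
    """Select methylation probes associated with their gene's expression.

    Each probe is regressed (simple OLS, ORQ-transformed probe values by
    default) against its mapped gene's expression; probes pass when the
    slope p-value is below ``p_threshold`` and R^2 exceeds
    ``r2_threshold``.  Only selected probes become METH nodes.
    """
    if dataset.n_samples < 3:
        raise OmicsIOError("probe screening needs at least 3 samples")
    results: list[ProbeScreenResult] = []
    genes = set(dataset.ge.columns)
    for probe, gene in dataset.meth_gene_map.items():
        if gene not in genes:
            warnings.warn(f"probe {probe!r} maps to absent gene {gene!r}; skipped")
            continue
        x = dataset.meth[probe].to_numpy(dtype=float)
        y = dataset.ge[gene].to_numpy(dtype=float)
        if transform:
            try:
                x = orq_transform(x)
            except ValueError:
                warnings.warn(f"probe {probe!r} is constant; skipped")
                continue
        fit = stats.linregress(x, y)
        r2 = float(fit.rvalue ** 2)
        p = float(fit.pvalue)
        selected = bool(p < p_threshold and r2 > r2_threshold)
        results.append(ProbeScreenResult(probe=probe, gene=gene, p_value=p,
                                         r2=r2, selected=selected))
    return results


def dm_probe_filter(meth_case: pd.DataFrame, meth_control: pd.DataFrame,
                    delta_quantile: float = 0.75,
                    p_threshold: float = 0.05) -> list[str]:
    """Differential-methylation probe filter between two sample groups.

    Keeps probes whose Welch t-test p-value on mean beta is below
    ``p_threshold`` and whose |delta beta| (case mean minus control mean)
    reaches the ``delta_quantile`` quantile of all |delta beta| values.
    """
    if meth_case.shape[0] < 2 or meth_control.shape[0] < 2:
        raise OmicsIOError("each group needs at least 2 samples")
    if list(meth_case.columns) != list(meth_control.columns):
        raise OmicsIOError("case and control groups must share the same probes")
    case = meth_case.to_numpy(dtype=float)
    control = meth_control.to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(case, control, axis=0, equal_var=False)
    delta = case.mean(axis=0) - control.mean(axis=0)
    thr = float(np.quantile(np.abs(delta), delta_quantile))
    keep = (np.nan_to_num(p, nan=1.0) < p_threshold) & (np.abs(delta) >= thr)
    # >= so delta_quantile = 0 is a vacuous bound; ties at the quantile pass
    return [probe for probe, k in zip(meth_case.columns, keep) if k]


def build_node_table(dataset: OmicsDataset,
                     selected_probes: list[str] | None = None) -> NodeTable:
    """Assemble the typed node set: one GE node per gene, CNV nodes for
    mapped copy-number features, METH nodes for (selected) probes."""
    nodes = [Node(id=g, type=NODE_GE, gene=g) for g in dataset.ge.columns]
    for fid, gene in dataset.cnv_gene_map.items():
        nodes.append(Node(id=fid, type=NODE_CNV, gene=gene))
    probes = (set(selected_probes) if selected_probes is not None
              else set(dataset.meth_gene_map))
    for fid, gene in dataset.meth_gene_map.items():
        if fid in probes:
            nodes.append(Node(id=fid, type=NODE_METH, gene=gene))
    return NodeTable(nodes=nodes)


def assemble_data_matrix(dataset: OmicsDataset, table: NodeTable,
                         standardise: bool = True) -> np.ndarray:
    """Concatenate node columns into an m x N matrix in NodeTable order.

    METH columns are ORQ-transformed; all columns are then standardised to
    zero mean and unit variance (the scale on which the Gaussian network
    score and its zero prior mean are calibrated).
    """
    cols = []
    for node in table:
        if node.type == NODE_GE:
            col = dataset.ge[node.id].to_numpy(dtype=float)
        elif node.type == NODE_CNV:
            col = dataset.cnv[node.id].to_numpy(dtype=float)
        else:
            col = orq_transform(dataset.meth[node.id].to_numpy(dtype=float))
        cols.append(col)
    X = np.column_stack(cols)
    if standardise:
        X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    return X
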