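"""BGe marginal-likelihood score for Gaussian Bayesian networks.

The score of a DAG factorises into per-node terms
``S(X_j, X_pa(j) | D)``, each the marginal likelihood of the node given
its parents under a normal-Wishart prior.  Every DAG in a Markov
equivalence class receives the same total score (score equivalence),
which is what licenses summarising posterior samples as CPDAGs.

The node score is computed as a difference of set marginals,
``log p(d_{pa ∪ {j}}) - log p(d_{pa})``, using the corrected,
score-equivalent normalisation in which the Wishart degrees of freedom
are adjusted by the subset size.  The prior parametric matrix is
``T = t·I`` with ``t = alpha_mu (alpha_w - N - 1) / (alpha_mu + 1)`` by
default, which keeps the implied prior marginals consistent across
subset sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln


class DegenerateDataError(ValueError):
    """Posterior scatter matrix is singular (e.g. collinear parents).

    Add a small ridge to the data, remove duplicated columns, or check
    that the number of samples exceeds the parent-set size.
    """


@dataclass
class BgeHyperparams:
    """Normal-Wishart hyperparameters of the BGe score.

    alpha_mu
        Prior precision on the mean (equivalent sample size); default 1.
    alpha_w
        Wishart degrees of freedom; must exceed N + 1, default N + 2.
    t_scale
        Scale of the prior parametric matrix ``T = t·I``.  ``None``
        selects ``alpha_mu (alpha_w - N - 1) / (alpha_mu + 1)``.
    mu0
        Prior mean; default zero (data columns are standardised at load).
    """

    n_nodes: int
    alpha_mu: float = 1.0
    alpha_w: float | None = None
    t_scale: float | None = None
    mu0: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.alpha_w is None:
            self.alpha_w = self.n_nodes + 2.0
        if self.alpha_w <= self.n_nodes + 1:
            raise ValueError("alpha_w must exceed N + 1")
        if self.alpha_mu <= 0:
            raise ValueError("alpha_mu must be positive")
        if self.t_scale is None:
            self.t_scale = (self.alpha_mu * (self.alpha_w - self.n_nodes - 1)
                            / (self.alpha_mu + 1.0))
        if self.t_scale <= 0:
            raise ValueError("t_scale must be positive")
        if self.mu0 is None:
            self.mu0 = np.zeros(self.n_nodes)


@dataclass
class ScoreCache:
    """Memoises node scores and set marginals keyed by index tuples."""

    node_scores: dict[tuple[int, tuple[int, ...]], float] = field(default_factory=dict)
    set_marginals: dict[tuple[int, ...], float] = field(default_factory=dict)
    hits: int = 0
    misses: int = 0


class BgeScorer:
    """Precomputes sufficient statistics for repeated node-score queries."""

    def __init__(self, data: np.ndarray, hyper: BgeHyperparams | None = None,
                 cache: ScoreCache | None = None):
        data = np.asarray(data, dtype=float)
        if data.ndim != 2:
            raise ValueError("data must be an m x N matrix")
        self.n, self.N = data.shape
        self.hyper = hyper if hyper is not None else BgeHyperparams(n_nodes=self.N)
        if self.hyper.n_nodes != self.N:
            raise ValueError("hyperparameter dimension does not match data")
        self.cache = cache if cache is not None else ScoreCache()

        h = self.hyper
        xbar = data.mean(axis=0)
        centred = data - xbar
        S = centred.T @ centred
        d = xbar - h.mu0
        # posterior parametric matrix R = T + S + n*am/(n+am) (x̄-μ0)(x̄-μ0)'
        self.R = (h.t_scale * np.eye(self.N) + S
                  + (self.n * h.alpha_mu / (self.n + h.alpha_mu)) * np.outer(d, d))
        self._log_am_ratio = np.log(h.alpha_mu / (self.n + h.alpha_mu))

    def _set_marginal(self, subset: tuple[int, ...]) -> float:
        """log marginal likelihood of the data restricted to ``subset``.

        For |A| = l the Wishart degrees of freedom are shifted to
        ``alpha_w - N + l`` so that the node score, a difference of two
        of these terms, is score equivalent.
        """
        if not subset:
            return 0.0
        cached = self.cache.set_marginals.get(subset)
        if cached is not None:
            return cached
        h = self.hyper
        idx = np.asarray(subset)
        l = idx.size
        n = self.n
        aw_l = h.alpha_w - self.N + l
        sign, logdet_R = np.linalg.slogdet(self.R[np.ix_(idx, idx)])
        if sign <= 0:
            raise DegenerateDataError(
                f"singular posterior scatter for columns {subset}")
        i = np.arange(1, l + 1)
        log_gamma_ratio = float(
            np.sum(gammaln((aw_l + n + 1 - i) / 2.0)
                   - gammaln((aw_l + 1 - i) / 2.0)))
        out = (0.5 * l * self._log_am_ratio
               - 0.5 * n * l * np.log(np.pi)
               + log_gamma_ratio
               + 0.5 * aw_l * l * np.log(h.t_scale)
               - 0.5 * (aw_l + n) * logdet_R)
        self.cache.set_marginals[subset] = out
        return out

    def node_score(self, node: int, parents) -> float:
        """log S(X_node, X_parents | D): local BGe score of one family."""
        pa = tuple(sorted(int(p) for p in parents))
        key = (int(node), pa)
        cached = self.cache.node_scores.get(key)
        if cached is not None:
            self.cache.hits += 1
            return cached
        self.cache.misses += 1
        fam = tuple(sorted(pa + (int(node),)))
        out = self._set_marginal(fam) - self._set_marginal(pa)
        self.cache.node_scores[key] = out
        return out

    def graph_score(self, parent_sets: dict[int, frozenset[int]] | list) -> float:
        """Total log score: sum of node scores over all nodes."""
        if isinstance(parent_sets, dict):
            items = parent_sets.items()
        else:
            items = enumerate(parent_sets)
        return float(sum(self.node_score(j, pa) for j, pa in items))


def bge_node_score(node: int, parents, data: np.ndarray,
                   hyper: BgeHyperparams | None = None,
                   cache: ScoreCache | None = None) -> float:
    """Functional wrapper around :meth:`BgeScorer.node_score`."""
    return BgeScorer(data, hyper, cache).node_score(node, parents)


def bge_graph_score(parent_sets, data: np.ndarray,
                    hyper: BgeHyperparams | None = None,
                    cache: ScoreCache | None = None) -> float:
    """Functional wrapper around :meth:`BgeScorer.graph_score`."""
    return BgeScorer(data, hyper, cache).graph_score(parent_sets)


def bge_delta(scorer: BgeScorer, parent_sets: dict[int, frozenset[int]],
              move) -> float:
    """log score(G') - log score(G) for a single-edge move.

    Only the affected families are rescored: the child for add/delete,
    both endpoints for reverse.  ``move`` is ``(kind, i, j)`` with kind in
    {"add", "delete", "reverse"} acting on edge i -> j.
    """
    kind, i, j = move
    pa_j = parent_sets[j]
    if kind == "add":
        if i in pa_j:
            raise ValueError(f"edge {i}->{j} already present")
        return scorer.node_score(j, pa_j | {i}) - scorer.node_score(j, pa_j)
    if kind == "delete":
        if i not in pa_j:
            raise ValueError(f"edge {i}->{j} not present")
        return scorer.node_score(j, pa_j - {i}) - scorer.node_score(j, pa_j)
    if kind == "reverse":
        if i not in pa_j:
            raise ValueError(f"edge {i}->{j} not present")
        pa_i = parent_sets[i]
        return (scorer.node_score(j, pa_j - {i}) - scorer.node_score(j, pa_j)
                + scorer.node_score(i, pa_i | {j}) - scorer.node_score(i, pa_i))
    raise ValueError(f"unknown move kind {kind!r}")
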