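"""Structure-proposal kernels and the Metropolis-Hastings acceptance step.

Two proposal families drive the sampler: uniform single-edge moves
(add / delete / reverse) over the valid neighbourhood with the exact
neighbourhood-size Hastings correction, and the Markov-blanket
resampling (MBR) move, which re-draws a node's parent set and its
children's parent sets from the BGe-score-proportional distribution for
faster mixing.  MBR is attempted with a fixed probability (1/15 per
iteration by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.special import logsumexp

from .bge import BgeScorer
from .omics_io import NODE_CNV, NODE_GE, NODE_METH
from .prior import ConstraintSet
from .structure import NetworkStructure

P_MBR_DEFAULT = 1.0 / 15.0


@dataclass
class ProposalResult:
    """Candidate structure, its Hastings log-ratio and the move record."""

    candidate: NetworkStructure
    log_proposal_ratio: float
    move: object  # ("add"|"delete"|"reverse", i, j) or ("mbr", node) / ("mbr", None)


def enumerate_neighborhood(G: NetworkStructure,
                           constraints: ConstraintSet | None = None
                           ) -> list[tuple[str, int, int]]:
    """All valid single-edge moves from G.

    Adds keep acyclicity, admissibility and caps; every existing edge can
    be deleted; reverses require the reversed pair to be admissible
    itself (hence only GE-GE edges) and must not close a cycle.
    """
    A, R, adm = G.A, G.R, G.admissible
    c = G.constraints
    N = G.n_nodes
    types = G.types
    # cap_ok[i, j]: node j may gain one more parent of node i's type
    cap_ok = np.zeros((N, N), dtype=bool)
    is_ge = G.is_ge
    cap_ok[is_ge, :] = A[is_ge].sum(axis=0)[None, :] < c.max_ge_parents
    is_cnv = types == NODE_CNV
    if is_cnv.any():
        cap_ok[is_cnv, :] = A[is_cnv].sum(axis=0)[None, :] < c.max_cnv_parents
    is_meth = types == NODE_METH
    if is_meth.any():
        if c.max_meth_parents is None:
            cap_ok[is_meth, :] = True
        else:
            cap_ok[is_meth, :] = (A[is_meth].sum(axis=0)[None, :]
                                  < c.max_meth_parents)
    add_mask = adm & ~A & ~R.T & cap_ok
    moves: list[tuple[str, int, int]] = [
        ("add", int(i), int(j)) for i, j in zip(*np.nonzero(add_mask))]
    idx = np.arange(N)
    for i, j in zip(*np.nonzero(A)):
        moves.append(("delete", int(i), int(j)))
        if adm[j, i] and cap_ok[j, i]:
            # a path i ~> j other than the edge itself would become a cycle
            if not np.any(A[i] & R[:, j] & (idx != j)):
                moves.append(("reverse", int(i), int(j)))
    return moves


def propose_single_edge(G: NetworkStructure, rng: np.random.Generator,
                        constraints: ConstraintSet | None = None
                        ) -> ProposalResult:
    """Uniform draw over the neighbourhood, with the |N| Hastings ratio."""
    moves = enumerate_neighborhood(G, constraints)
    if not moves:
        raise RuntimeError("empty move neighbourhood")
    move = moves[rng.integers(len(moves))]
    candidate = G.copy()
    candidate.apply_move(move)
    n_back = len(enumerate_neighborhood(candidate, constraints))
    log_ratio = float(np.log(len(moves)) - np.log(n_back))
    return ProposalResult(candidate=candidate, log_proposal_ratio=log_ratio,
                          move=move)


def accept_structure(log_score_delta: float, log_prior_delta: float,
                     log_proposal_ratio: float,
                     rng: np.random.Generator) -> bool:
    """Metropolis-Hastings acceptance for a structure move."""
    log_a = log_score_delta + log_prior_delta + log_proposal_ratio
    if not np.isfinite(log_a):
        if np.isnan(log_a):
            raise ValueError("non-finite acceptance ratio")
        return log_a > 0
    if log_a >= 0:
        return True
    return bool(rng.random() < np.exp(log_a))


class ParentSetSpace:
    """Enumeration of all admissible, cap-respecting parent sets of a node.

    Sets are stored as candidate index tuples plus bitmasks over node
    ids for fast acyclicity filtering; BGe scores are filled lazily on
    first use and reused for the lifetime of the sampler.
    """

    def __init__(self, j: int, G: NetworkStructure,
                 max_sets: int = 50_000):
        c = G.constraints
        cand = np.flatnonzero(G.admissible[:, j])
        ge = [int(i) for i in cand if G.types[i] == NODE_GE]
        cnv = [int(i) for i in cand if G.types[i] == NODE_CNV]
        meth = [int(i) for i in cand if G.types[i] == NODE_METH]
        ge_cap = min(c.max_ge_parents, len(ge))
        cnv_cap = min(c.max_cnv_parents, len(cnv))
        meth_cap = len(meth) if c.max_meth_parents is None else min(
            c.max_meth_parents, len(meth))

        def subsets(pool, cap):
            out = [()]
            for r in range(1, cap + 1):
                out.extend(combinations(pool, r))
            return out

        ge_subs = subsets(ge, ge_cap)
        cnv_subs = subsets(cnv, cnv_cap)
        meth_subs = subsets(meth, meth_cap)
        total = len(ge_subs) * len(cnv_subs) * len(meth_subs)
        self.too_large = total > max_sets
        self.node = j
        if self.too_large:
            self.sets = []
            return
        sets: list[tuple[int, ...]] = []
        for g in ge_subs:
            for cv in cnv_subs:
                for mt in meth_subs:
                    sets.append(tuple(sorted(g + cv + mt)))
        self.sets = sets
        raw_masks = [sum(1 << i for i in s) for s in sets]
        # uint64 bitmasks vectorise the acyclicity filter for <= 64 nodes;
        # larger problems fall back to Python integers
        self._np_masks = G.n_nodes <= 64
        if self._np_masks:
            self.masks = np.array(raw_masks, dtype=np.uint64)
        else:
            self.masks = raw_masks
        self.index = {s: k for k, s in enumerate(sets)}
        self.scores: np.ndarray | None = None

    def ensure_scores(self, scorer: BgeScorer) -> np.ndarray:
        if self.scores is None:
            self.scores = np.array(
                [scorer.node_score(self.node, s) for s in self.sets])
        return self.scores

    def allowed_mask(self, forbidden_mask: int, require: int | None = None
                     ) -> np.ndarray:
        """Boolean mask of sets disjoint from ``forbidden_mask`` (nodes
        that would close a cycle), optionally containing ``require``."""
        if self._np_masks:
            forb = np.uint64(forbidden_mask)
            ok = (self.masks & forb) == 0
            if require is not None:
                bit = np.uint64(1 << require)
                ok &= (self.masks & bit) != 0
        else:
            ok = np.array([(m & forbidden_mask) == 0 for m in self.masks])
            if require is not None:
                bit = 1 << require
                ok &= np.array([(m & bit) != 0 for m in self.masks])
        return ok


def _descendant_mask(G: NetworkStructure, v: int) -> int:
    """Bitmask of v and its descendants (nodes that may not parent v)."""
    mask = 1 << v
    for d in np.flatnonzero(G.R[v]):
        mask |= 1 << int(d)
    return mask


def mbr_propose(G: NetworkStructure, scorer: BgeScorer,
                rng: np.random.Generator,
                spaces: dict[int, ParentSetSpace] | None = None
                ) -> ProposalResult:
    """Markov-blanket resampling move.

    A GE node X is chosen uniformly; the parent sets of X and of each of
    X's children are detached, then resampled sequentially (X first,
    children in index order) from the BGe-score-proportional distribution
    over admissible, acyclicity-preserving, cap-respecting parent sets —
    children constrained to retain X as a parent so the blanket is
    reassembled around the same node.  The returned Hastings ratio is the
    exact reverse-path construction probability over the same sequence.
    """
    if spaces is None:
        spaces = {}
    ge_nodes = np.flatnonzero(G.is_ge)
    X = int(ge_nodes[rng.integers(len(ge_nodes))])
    children = sorted(int(c) for c in np.flatnonzero(G.A[X]))
    affected = [X] + children

    for v in affected:
        if v not in spaces:
            spaces[v] = ParentSetSpace(v, G)
        if spaces[v].too_large:
            return ProposalResult(candidate=G.copy(), log_proposal_ratio=0.0,
                                  move=("mbr", None))

    stripped = G.copy()
    for v in affected:
        stripped.set_parents(v, frozenset())

    # forward construction
    fwd = stripped.copy()
    log_q_fwd = 0.0
    for v in affected:
        space = spaces[v]
        scores = space.ensure_scores(scorer)
        ok = space.allowed_mask(_descendant_mask(fwd, v),
                                require=None if v == X else X)
        allowed = np.flatnonzero(ok)
        if allowed.size == 0:
            return ProposalResult(candidate=G.copy(), log_proposal_ratio=0.0,
                                  move=("mbr", None))
        logp = scores[allowed]
        pick = int(allowed[np.argmax(logp + rng.gumbel(size=allowed.size))])
        log_q_fwd += float(scores[pick] - logsumexp(logp))
        fwd.set_parents(v, frozenset(space.sets[pick]))

    # reverse construction probability (same sequence, original sets)
    rev = stripped.copy()
    log_q_rev = 0.0
    for v in affected:
        space = spaces[v]
        scores = space.ensure_scores(scorer)
        ok = space.allowed_mask(_descendant_mask(rev, v),
                                require=None if v == X else X)
        orig = tuple(sorted(G.parent_sets[v]))
        k = space.index.get(orig)
        if k is None or not ok[k]:
            # the reverse path cannot reconstruct G: treat as a rejected
            # (identity) proposal rather than an invalid ratio
            return ProposalResult(candidate=G.copy(), log_proposal_ratio=0.0,
                                  move=("mbr", None))
        log_q_rev += float(scores[k] - logsumexp(scores[np.flatnonzero(ok)]))
        rev.set_parents(v, frozenset(orig))

    return ProposalResult(candidate=fwd,
                          log_proposal_ratio=log_q_rev - log_q_fwd,
                          move=("mbr", X))
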