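"""Evaluation metrics: ROC over edge weights, AUC with 83% CIs, kappa.

Edge weights are graded against a gold-standard edge set over a declared
universe of ordered pairs.  The AUC uses the rank (Mann-Whitney)
formulation; its confidence interval is the Hanley-McNeil normal
approximation, at the 83% level whose *overlap* between two methods
approximates a 5%-level test of AUC difference.  Cohen's kappa measures
agreement between two reported edge sets over the same universe.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve


@dataclass
class RocResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    n_pos: int
    n_neg: int


def _scores_labels(weights, gold, universe):
    gold = set(gold)
    scores = np.array([float(weights.get(pair, 0.0)) for pair in universe])
    labels = np.array([pair in gold for pair in universe], dtype=bool)
    return scores, labels


def roc_auc(weights: dict, gold, universe) -> RocResult:
    """ROC curve and rank-formulation AUC of edge weights vs a gold set.

    ``weights`` maps ordered pairs to confidence values (missing pairs
    score 0); ``universe`` fixes the evaluable pairs, and must contain
    every gold edge.
    """
    universe = list(universe)
    if not universe:
        raise ValueError("empty evaluation universe")
    if not set(gold) <= set(universe):
        raise ValueError("gold edges outside the evaluation universe")
    scores, labels = _scores_labels(weights, gold, universe)
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one positive and one negative pair")
    ranks = stats.rankdata(scores)
    auc = (ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    fpr, tpr, thr = roc_curve(labels.astype(int), scores)
    return RocResult(fpr=fpr, tpr=tpr, thresholds=thr, auc=float(auc),
                     n_pos=n_pos, n_neg=n_neg)


def auc_ci83(auc: float, n_pos: int, n_neg: int,
             level: float = 0.83) -> tuple[float, float]:
    """Hanley-McNeil normal-approximation CI for an AUC, truncated to [0, 1].

    At the default 83% level the z multiplier is Phi^{-1}(0.915) = 1.372;
    two AUCs are declared different when their 83% CIs are disjoint.
    """
    if n_pos < 1 or n_neg < 1:
        raise ValueError("need at least one positive and one negative")
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc * auc / (1.0 + auc)
    var = (auc * (1.0 - auc) + (n_pos - 1) * (q1 - auc * auc)
           + (n_neg - 1) * (q2 - auc * auc)) / (n_pos * n_neg)
    se = float(np.sqrt(max(var, 0.0)))
    z = float(stats.norm.ppf(0.5 + level / 2.0))
    return (max(0.0, auc - z * se), min(1.0, auc + z * se))


def auc_ci_bootstrap(weights: dict, gold, universe, n_boot: int = 2000,
                     level: float = 0.83,
                     rng: np.random.Generator | None = None
                     ) -> tuple[float, float]:
    """Percentile-bootstrap alternative to the normal-approximation CI."""
    if rng is None:
        rng = np.random.default_rng()
    universe = list(universe)
    scores, labels = _scores_labels(weights, gold, universe)
    n = scores.size
    aucs = []
    for _ in range(n_boot):
        idx = rng.integers(n, size=n)
        s, l = scores[idx], labels[idx]
        if l.all() or not l.any():
            continue
        ranks = stats.rankdata(s)
        n_pos = int(l.sum())
        aucs.append((ranks[l].sum() - n_pos * (n_pos + 1) / 2.0)
                    / (n_pos * (n - n_pos)))
    lo = (1.0 - level) / 2.0
    return (float(np.quantile(aucs, lo)), float(np.quantile(aucs, 1.0 - lo)))


def cis_overlap(ci_a: tuple[float, float], ci_b: tuple[float, float]) -> bool:
    """True when two confidence intervals overlap (no detected difference)."""
    return not (ci_a[1] < ci_b[0] or ci_b[1] < ci_a[0])


def cohens_kappa(edges_a, edges_b, universe) -> float:
    """Chance-corrected agreement of two edge sets over a universe."""
    universe = list(universe)
    if not universe:
        raise ValueError("empty universe")
    a = set(edges_a)
    b = set(edges_b)
    if not (a <= set(universe) and b <= set(universe)):
        raise ValueError("edge sets must lie within the universe")
    n = len(universe)
    in_a = np.array([p in a for p in universe])
    in_b = np.array([p in b for p in universe])
    p_o = float(np.mean(in_a == in_b))
    p_yes = in_a.mean() * in_b.mean()
    p_no = (1 - in_a.mean()) * (1 - in_b.mean())
    p_e = float(p_yes + p_no)
    if p_e == 1.0:
        return 1.0 if p_o == 1.0 else 0.0
    return (p_o - p_e) / (1.0 - p_e)


def edge_weight_dict(ewm, table) -> dict[tuple[str, str], float]:
    """EdgeWeightMatrix -> {(source id, target id): weight} over nonzeros."""
    ids = [nd.id for nd in table]
    out = {}
    for i, j in zip(*np.nonzero(ewm.values)):
        out[(ids[i], ids[j])] = float(ewm.values[i, j])
    return out
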