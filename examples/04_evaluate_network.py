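"""Grading an inferred network: ROC/AUC, 83% CIs and Cohen's kappa.

Compares two edge-weight tables against a gold standard over a declared
universe of ordered pairs, computes the AUC of each with its 83%
confidence interval (two methods differ when their 83% CIs are
disjoint), and measures the agreement of their thresholded edge sets.
"""

import numpy as np

from omicsbn import (auc_ci83, cis_overlap, cohens_kappa, gold_standard,
                     random_typed_dag, roc_auc)

rng = np.random.default_rng(5)
model = random_typed_dag(8, edge_density=0.3, rng=rng, n_cnv=0, n_meth=0)
gs = gold_standard(model, ge_only=True)
print(f"gold standard: {len(gs.reference)} edges out of "
      f"{len(gs.universe)} ordered pairs")

# a sharp and a noisy scorer of the same truth
sharp = {p: (0.7 + 0.3 * rng.random() if p in gs.reference
             else 0.5 * rng.random()) for p in gs.universe}
noisy = {p: np.clip((0.55 if p in gs.reference else 0.45)
                    + 0.4 * rng.standard_normal(), 0, 1)
         for p in gs.universe}

for name, weights in (("sharp", sharp), ("noisy", noisy)):
    res = roc_auc(weights, gs.reference, gs.universe)
    lo, hi = auc_ci83(res.auc, res.n_pos, res.n_neg)
    print(f"{name:>6}: AUC = {res.auc:.3f}, 83% CI = ({lo:.3f}, {hi:.3f})")

res_a = roc_auc(sharp, gs.reference, gs.universe)
res_b = roc_auc(noisy, gs.reference, gs.universe)
ci_a = auc_ci83(res_a.auc, res_a.n_pos, res_a.n_neg)
ci_b = auc_ci83(res_b.auc, res_b.n_pos, res_b.n_neg)
verdict = "overlap (no detected difference)" if cis_overlap(ci_a, ci_b) \
    else "are disjoint (significant difference)"
print(f"the 83% CIs {verdict}")

top_a = {p for p, w in sharp.items() if w > np.quantile(list(sharp.values()),
                                                        0.75)}
top_b = {p for p, w in noisy.items() if w > np.quantile(list(noisy.values()),
                                                        0.75)}
print(f"kappa between the two top-quartile edge sets: "
      f"{cohens_kappa(top_a, top_b, gs.universe):.2f}")
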