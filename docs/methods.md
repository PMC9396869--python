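# Methods

## Model

A regulatory network is a DAG over typed nodes.  For `n1` genes with
expression columns, `n2` copy-number features and `n3` selected
methylation probes, the node set has one GE node per gene and one
CNV/METH node per mapped feature.  Admissibility is structural: GE→GE
edges between any two distinct genes; a CNV or METH node may only
parent the GE node of its own gene; CNV and METH nodes have no
parents.  Parent caps encode the sparsity of transcriptional control:
at most three GE parents and one CNV parent per GE node, METH parents
uncapped.  Pairs forbidden by type carry no prior entry at all (they
are outside the move space); `B = 0` on an admissible pair is a soft
penalty instead.

### Likelihood: the BGe score

`P(D|G)` is the score-equivalent Gaussian-network marginal likelihood
under a normal–Wishart prior with precision-on-the-mean `α_μ` (default
1), Wishart degrees of freedom `α_w` (default `N + 2`, `N` = node
count) and parametric matrix `T = t·I` with
`t = α_μ (α_w − N − 1)/(α_μ + 1)`, the choice that keeps the implied
marginals consistent across subset sizes.  A family score is computed
as the difference of two subset marginals whose degrees of freedom are
shifted by the subset size (the corrected, score-equivalent
normalisation); the parentless case reduces to a 1-D normal–gamma
marginal, which the test suite verifies against direct numerical
integration.  Data columns are standardised once at load (METH
beta-values are first mapped through the ordered-quantile transform),
making the zero prior mean appropriate.  All arithmetic is in the log
domain; the `T = t·I` ridge keeps scores finite under collinear
parents, and a genuinely singular posterior scatter raises an error
advising a data check.

### Prior: energy over structures

Knowledge enters as `B_ij ∈ [0,1]` over admissible ordered pairs: 1
curated edge, 0.75 TF–target association, 0.5 unknown, 0 curated
non-edge.  Structure energy and prior are

    ε(j, pa) = Σ_{i∈pa}(1−B_ij) + Σ_{i∈C_j \ pa} B_ij,
    E(G) = Σ_j ε(j, pa_j),     P(G|β) = exp(−β E(G)) / Z(β).

`Z(β)` uses the node-factorised upper bound (sum over per-node
admissible parent sets, ignoring global acyclicity).  Under the
cardinality caps the per-node sum is computed exactly with elementary
symmetric polynomials of `w_i = exp(−β(1−2B_ij))` per candidate type —
a dynamic programme, not enumeration — so it is cheap even for large
candidate sets.  The caps are applied inside `Z` because the move
space respects them (configurable off).

### The strength parameter β

β is sampled at fixed structure with a Gaussian proposal
`β_c ~ N(β_s, σ_s²)`, `σ_s` initialised at 5, and the ratio
`P(G|β_c)/P(G|β_s)`.  The support is the interval
`[β_min, β_max] = [0.5, 10]`; proposals outside are rejected outright.
The initial value is drawn from U[0, 10] and clamped up to 0.5.  The
upper bound is a deliberate design choice: the acceptance ratio treats
the hyperprior on β as flat, and a flat hyperprior on an unbounded
support is improper — once the chain's structure realises every high-B
entry the ratio saturates at 1 and β performs a free upward random
walk (observed empirically before the bound was added).  Bounding the
support at the top of the initialisation range makes the hyperprior
proper and leaves the documented behaviours intact: β climbs toward
the bound when the prior matches the data and stays low when it does
not (this contrast is asserted in the tests).

## Sampling scheme

Structure moves mix single-edge proposals (uniform over the valid
add/delete/reverse neighbourhood, with the exact neighbourhood-size
Hastings correction) and, with probability 1/15 per iteration, a
Markov-blanket resampling (MBR) move: a uniformly chosen GE node has
its parent set and its children's parent sets detached and resampled
sequentially from the BGe-score-proportional distribution over
admissible, cap-respecting, acyclicity-preserving parent sets,
children constrained to retain the resampled node; the Hastings ratio
is the exact reverse-path construction probability over the same node
sequence (fixed increasing order, so the reverse path is
well-defined).  Parent-set spaces are enumerated once per node and
their scores cached; if a node's space would exceed 50,000 sets the
move degrades to an identity proposal for that draw.  Reverse moves
exist only where the opposite pair is itself admissible (GE–GE).

The four phases:

1. **Rough adaptation** (default 2,000 iterations): batches of 100
   interleaved structure/β moves; after each batch `σ_s` is scaled by
   `exp(±0.4)` until the β acceptance rate enters [0.28, 0.60].
2. **Transient**: windows of 500 iterations until a Geweke-style
   two-window z-test on the log-posterior trace falls below 1.96 (cap
   20 windows, then proceed with a warning).
3. **Second adaptation** (default 10,000 iterations): σ fine-tuning
   with step 0.1; every *single-edge* proposal updates the counts
   `f_ij` (proposed) and `a_ij` (evidence for the edge): an accepted
   add or a rejected delete increments `a_ij`; a reverse increments
   `f_ij` and `f_ji`, crediting `a_ji` on acceptance and `a_ij` on
   rejection.  MBR moves are not counted.  On exit `B̂_ij = a_ij/f_ij`
   replaces every original 0.5 entry with `f_ij > 0` (curated entries
   are kept verbatim; unproposed pairs stay at 0.5), and β is fixed at
   the phase mean.  Counts do not feed back into the energy during the
   phase itself — the target stays Markovian; `B̂` applies only from
   the phase boundary.
4. **Sampling**: two independent chains (independent seed streams from
   the one master seed), no β moves.  Each 500-iteration horizon runs
   three independent segments from the current state and keeps the
   endpoint with the highest log posterior, recording the winner's
   trajectory.  Defaults per chain: 200,000 iterations, burn-in
   100,000, thinning 500.  Convergence uses the cumulative
   between-chain `c_rms`: at thinned index k, the RMS over admissible
   ordered pairs of the difference in running CPDAG edge frequencies.
   The stopping threshold is the third quartile of successive
   |differences|; the run stops when the last 100 thinned values lie
   below it, otherwise both chains extend in 50,000-iteration blocks
   (default cap: 2 extensions).  `c_rms` uses the un-deduplicated
   thinned snapshots; burn-in labels are by absolute iteration, so
   extensions only add post-burn-in samples.

"Fixed BGe score except the MBR step" is realised through the score
cache: horizon segments reuse frozen family scores, while MBR
recomputes (cached) parent-set scores as its construction requires;
the target posterior is unchanged either way.

## Posterior summary

Sampled DAGs are converted to CPDAGs by orienting unshielded colliders
and closing under Meek's rules R1–R3 (no background knowledge, so R4
never fires); the conversion is verified against a brute-force
equivalence-class oracle on all 543 four-node DAGs.  Within each
chain, post-burn-in thinned CPDAGs are deduplicated exactly (first
appearance order); the two deduplicated sets are pooled, and the edge
weight `w_ij` is the fraction of pooled CPDAGs containing `i→j`
compelled or `i–j` reversible.  A reversible edge credits both ordered
pairs — the only convention that never discards reversible evidence;
consequently a fully supported but uncompelled pair shows
`w_ij = w_ji = 1`.  Reported edges are those with weight at or above
the 0.75 quantile (linear interpolation, R type 7) of all positive
weights.

## Preprocessing

Matrices are delimited text (tab default, comma accepted), first
column sample id.  Samples are intersected across the three matrices
with GE order canonical; zero-variance features are dropped (and
CNV/METH features orphaned by a dropped gene with them).  Methylation
probes are screened per gene by simple OLS of the gene's expression on
the ORQ-transformed probe values; a probe becomes a node when the
slope p-value is below `meth.p_threshold` and `R² > meth.r2_threshold`
(defaults 0.05 and 0.3).  The 0.05 default departs from the 0.5
sometimes quoted for this screen, which is a near-vacuous significance
level; 0.5 remains reachable through configuration.  The transform is
applied before the regression.  The ordered-quantile transform uses
average ranks and the offset `(r−0.5)/n`, so ties are handled and
quantiles stay finite; a constant vector is an error.  A separate
differential-methylation filter (Welch t-test on beta means plus a
|Δβ| quantile gate, default 0.75) supports case/control designs; the
Δβ comparison is `≥` the quantile so that a zero quantile is vacuous.

## The synthetic generator

The generator emulates the mechanisms the method targets: a GE–GE
skeleton drawn under a random topological order with the three-parent
cap; per-gene CNV parents with strictly positive dosage coefficients;
per-gene METH parents with negative coefficients by default
(promoter-style down-regulation; sign configurable, as gene-body
methylation can act positively); linear-Gaussian structural equations
with unit noise and coefficient magnitudes in [0.3, 1] (bounded away
from zero so every edge is in principle detectable at the default
sample sizes).  METH root values are sampled in a latent Gaussian
space, act linearly through that latent value, and are recorded as
logistic-transformed beta-values in (0, 1) — so the recorded data are
bounded and skewed like real beta-values while the generating model
stays linear-Gaussian.  The corrupted prior reveals
`floor(keep_fraction · #edges)` uniformly chosen true GE–GE edges at
`B = 1` and leaves everything else at 0.5.

What passing synthetic tests do **not** show: robustness to nonlinear
regulation, measurement batch effects, probe cross-hybridisation,
discrete copy-number states, or prior knowledge that is *wrong* rather
than merely incomplete (the corrupted prior omits edges but never
fabricates them).

## Evaluation

AUC uses the rank (Mann–Whitney) formulation over a declared universe
of ordered pairs (admissible pairs, optionally GE–GE only — the
negative set matters and is always explicit).  Its confidence interval
is the Hanley–McNeil normal approximation at the 83% level
(z = Φ⁻¹(0.915) = 1.372), truncated to [0, 1]; two AUCs are declared
different when their 83% CIs are disjoint.  A percentile bootstrap is
available behind a flag.  Cohen's κ compares two binary edge sets over
the same universe.  Copy-number-link recovery is summarised as the
median own-gene CNV weight reaching the median of all positive weights
(`≥` rather than `>`, because both saturate at 1 on concentrated
posteriors) and being positive.

## Problem sizes and numerical choices

The bundled checks run at desk scale by design: exhaustive posterior
comparisons on 3–4 nodes (60,000 / 150,000 iterations, comfortably
inside ±0.03 of enumeration), recovery studies with 10 genes + 4 CNV +
6 METH nodes, 100 samples and 20,000-iteration chains, and phase-2
directionality runs with n = 200.  Default chain lengths (200,000 /
100,000 / 500) remain those of a full analysis.  Ties in the uniform
single-edge proposal are broken by the rng; cache keys are exact
parent-set tuples; score drift is guarded by an optional consistency
check that recomputes cached quantities.  The convergence rule
degenerates on an exactly constant `c_rms` series (threshold 0, strict
inequality fails) — by construction it then keeps sampling, which is
the conservative direction.

## Known limitations

* MBR enumerates per-node parent-set spaces; with very many
  candidates (large gene panels and many probes per gene) a node's
  space can exceed the 50,000-set guard and MBR degrades to an
  identity move there, losing its mixing benefit but not correctness.
* The β hyperprior bound at 10 is a modelling choice; analyses that
  want a harder prior can raise `mcmc.beta_max`.
* Edge weights are frequencies over *deduplicated* CPDAG sets, so they
  are support indicators rather than exact posterior probabilities;
  the exhaustive-oracle checks therefore compare un-deduplicated DAG
  frequencies.
* CNV and METH features must be pre-mapped to genes; no genomic
  annotation is performed.
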