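# omicsbn

Bayesian-network inference of gene regulatory networks from matched
multi-omics data: gene expression (GE), copy-number variation (CNV) and
DNA methylation (METH) matrices measured on the same samples.

## Who it is for

Computational biologists who want directed regulatory structure — which
gene drives which, and whether a gene's expression is controlled by its
copy number or promoter methylation — rather than co-expression
clusters, and who have partial prior knowledge (pathway databases,
TF-target lists) they want to weigh against the data instead of
imposing outright.

## The model

A network is a DAG `G` over typed nodes: one GE node per gene, one CNV
node per measured copy-number feature and one METH node per selected
methylation probe.  CNV and METH nodes can only parent the GE node of
their own gene; each GE node takes at most three GE parents and one CNV
parent.  The posterior over structures is

    P(G | D) ∝ P(D | G) · P(G | β)

with two ingredients:

* **BGe score** — `P(D | G)` is the Gaussian-network marginal
  likelihood under a normal–Wishart prior (`T = t·I`), decomposing into
  per-family terms `S(X_j, X_pa(j) | D)`.  It is score-equivalent:
  every DAG in a Markov equivalence class scores identically, so
  posterior samples are summarised as CPDAGs.
* **Energy-based prior** — prior knowledge is a matrix `B` with
  `B_ij ∈ [0,1]` (1 known edge, 0.75 TF–target, 0.5 no knowledge,
  0 known non-edge).  A structure's energy
  `E(G) = Σ_j [ Σ_{i∈pa(j)} (1−B_ij) + Σ_{i∉pa(j)} B_ij ]`
  measures disagreement with `B`, and
  `P(G | β) = exp(−β·E(G)) / Z(β)` with a node-factorised upper bound
  for `Z` and the strength `β` itself sampled by Metropolis–Hastings on
  `[0.5, 10]`.

Sampling runs in four phases: rough tuning of the β proposal spread, a
transient (stationarity) phase, a second adaptive phase that estimates
β and — the key trick — fills every "no knowledge" entry of `B` with
*empirical* knowledge `B̂_ij = a_ij / f_ij`, the acceptance/proposal
ratio of edge `i→j` accumulated from the chain's own single-edge moves,
and finally two independent sampling chains at fixed β with a greedy
horizon (best of three 500-iteration segments), Markov-blanket
resampling (p = 1/15) for mixing, thinning, burn-in and a between-chain
`c_rms` stopping rule.  Edge weights are empirical CPDAG frequencies
pooled over both chains; edges above the 0.75 quantile of positive
weights are reported.

## Worked example

```bash
python examples/01_simulate_and_infer.py
```

simulates a 6-gene study (2 CNV features, 2 methylation probes, 80
samples), reveals half the true gene–gene edges in the prior and runs
the full pipeline.  Output from the run committed here:

```
estimated prior strength beta = 5.58
7 edges above the 0.75-quantile weight threshold

                  edge  weight  in truth?
        G1 -> G2         1.00  yes
    cnv_G5 -> G5         1.00  yes
        G3 -> G5         1.00  yes
        G1 -> G5         1.00  yes
        G1 -> G4         1.00  yes
        G3 -> G4         1.00  yes
        G2 -> G1         1.00  no
```

A weight is the fraction of sampled equivalence classes containing the
edge.  `G1 -> G2` and `G2 -> G1` both at 1.00 show the reversible-edge
convention: the pair is linked in every posterior draw but its
direction is not compelled, so both orientations are credited.  The
estimated β ≈ 5.6 says the data supported the supplied prior strongly.

The same pipeline is available as a shell tool:

```bash
omicsbn simulate --genes 10 --samples 100 --seed 7 --out study/
omicsbn run --ge study/GE.tsv --cnv study/CNV.tsv --meth study/METH.tsv \
            --map study/MAP.tsv --prior study/PRIOR.tsv --seed 42 --out net/
omicsbn evaluate --weights net/edge_weights.tsv --gold study/GOLD.tsv --ge-only
```

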