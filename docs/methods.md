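# Methods

This note documents the statistical model implemented by `wapscore`, the
choices made where the design was genuinely open, the defaults and what
they mean, and what the synthetic-data tests do and do not demonstrate.

## The attachment model

The score treats the protein-interaction network as fixed and asks, for
each gene product j, whether its interaction partners are unusually
concentrated among the top-i most differentially expressed genes — for
every top-set size i at once.  The null model is a random graph that
preserves degrees *on average*: each possible interaction (u, v) is an
independent Bernoulli variable with probability k_u k_v / 2M (the
Chung–Lu relaxation of the configuration model).  For sparse networks
the count X of interactions between j and a fixed gene set is then
approximately Poisson with mean

    lambda_{j,i} = (k_j / 2M) · Σ_{h ≤ i, h ≠ j} k_h .

Gene j is excluded from its own top-set sum (no self-interactions
exist), both in lambda and in the observed count.

Because a set of size i can absorb at most i interactions from j, the
p-value is the *conditional* tail of the Poisson distribution,

    P_{j,i} = Pr(X ≥ x_{j,i} | X ≤ i) ,

normalized so that P = 1 exactly when x = 0.  This truncation is what
makes p-values at different i comparable and removes the need for any
differential-expression cutoff: the score of gene j is min_i P_{j,i}.

**Numerical evaluation.**  When i > lambda + 10·sqrt(lambda) + 50 the
truncation mass above i is far below double-precision resolution and
the untruncated survival function is used, evaluated as the regularized
lower incomplete gamma function `gammainc(x, lambda)` (exact to machine
precision; verified against the independent Poisson survival function to
10+ significant digits).  Otherwise the truncated ratio is evaluated by
a max-shifted exponential sum over the support 0..i; the e^(-lambda)
factors cancel between numerator and denominator.  The same scalar
routine backs both the fast scan and the brute-force oracle, so the two
agree bitwise.

**The O(M) scan.**  For fixed x the tail is non-decreasing in lambda
(and in i at fixed lambda), so within any rank interval in which j's
attachment count x is constant the p-value is minimized at the left
endpoint — the rank of the neighbor whose arrival incremented x.
Evaluating P only at the ranks of j's neighbors therefore finds the
exact minimum; summed over genes this is Σ k_j = 2M evaluations.  The
monotonicity that justifies the shortcut is property-tested, and the
scan is tested for exact (same-float) agreement with an exhaustive
O(n)-per-gene scan on dozens of random instances.  Ties in min P across
several i resolve to the smallest i.

## Degree correction

Taking a minimum over more candidates biases min P downward for
high-degree genes: on uniformly random rankings the median min P falls
roughly as a power law in k.  Scores are made comparable across degrees
by multiplying with k^alpha; the package default alpha = 0.1799 (with a
companion constant beta = 1.056 that cancels in the correction ratio
and is kept for completeness).

The *direction* of the correction was an open design point: a literal
reading of the published correction ratio applies k^(-alpha), which
rewards high degree and strengthens the bias it is meant to remove.  We
resolved this empirically, as the package's own calibration operation:
on a 2000-vertex configuration-model network, null scores show
Spearman(min P, k) ≈ −0.13; multiplying by k^(+alpha) flattens this to
|rho| < 0.05, while k^(-alpha) worsens it to ≈ −0.24.  The default
orientation is therefore `"inverted"` (k^(+alpha)); the literal variant
remains available as `orientation="as_printed"`.

`calibrate_degree_correction` refits alpha on any network by regressing
log median null min P on log k across distinct degrees (weighted by
gene count, ≥ 100 random rankings required, ≥ 3 distinct degrees), and
selects the orientation minimizing the residual |Spearman| with degree.
Degree-0 genes have min P = 1 by construction and pass through the
correction unchanged; they are retained so the DEG and WAP rankings
always cover the same gene universe.

## Proportion of false positives

Significance of the sorted corrected scores is assessed by permuting
sample labels (preserving group sizes and, crucially, gene
co-expression), re-ranking, and re-scoring.  For the observed score of
rank j, a permutation yielding k null scores ≤ the observed value
contributes min(k/j, 1); the PFP at rank j is the average contribution
over permutations.  Ties count as "at least as significant"
(conservative), the observed profile is not included as a
pseudo-permutation, and each permutation derives its seed independently
from the master seed, so results do not depend on execution order.
1000 permutations is the practical default; 10⁴ for publication-grade
profiles; the per-profile cost is O(M) p-value evaluations plus one
t-test pass.

## Reproducibility metrics

For rankings A and B over the same n genes, with top-i sets A_i, B_i:
I_i = |A_i ∩ B_i|, U_i = 2i − I_i, R_i = I_i/U_i.  Both summaries are
implemented exactly as published, including their asymmetries:

* `maxR = max {R_i : a ≤ U_i ≤ b}` windows on the **union size**
  (defaults a = 50, b = 1000).  The lower bound avoids spuriously large
  R at small i; the upper bound avoids the trivial R_n = 1.
* `AUC = w_1 R'_1 + w_b R'_b/2 + Σ_{i=2}^{b−1} w_i R'_i` with
  w_i = U'_{i+1} − U'_i truncates on the **index** i and uses
  tie-collapsed series: within a run of equal U, R' is the run's mean R.
  The published endpoint weighting (first term unhalved, last halved) is
  kept rather than symmetrized.  The terminal weight needs U'_{b+1};
  when b = n or i = b falls inside a tie run this is undefined, and the
  last positive increment before b is substituted — flagged through a
  dedicated warning category and a summary flag, because ties at i = b
  are routine (U increments by 0, 1 or 2 per step).

Dataset machinery: `split_dataset` halves a study into
⌊n/2⌋+⌊m/2⌋ and ⌈n/2⌉+⌈m/2⌉ samples stratified by group (the number of
distinct balanced partitions is bounded below by n!²/(n/2)!⁴/2, already
31752 at n = 10, so resampling splits is informative);
`perturb_labels` pairs disease with control samples by a uniformly
random matching and swaps each pair's labels independently with
probability rho — rho = 0 is the identity, rho = 1 swaps every formed
pair, and group sizes are always preserved.  The Bernoulli-pair-swap
reading is the package's interpretation of a mixing parameter whose
original mechanics are not fully specified.

## MVT

Pearson dissimilarity between samples is d = (1 − r)/2, mapping
correlation into [0, 1] (the 1 − r convention is available by flag).
With disease group D and control group C,

    mvt = d(D, C) / (s(D) + s(C)) ,

the ratio of the mean cross-group dissimilarity to the summed mean
within-group dissimilarities.  The permutation p-value shuffles the
group mask only — the dissimilarity matrix is label-independent and is
computed once — and uses the add-one convention
p = (1 + #{MVT ≥ mvt}) / (1 + B), which never returns 0 and keeps the
estimator a valid (sub-uniform) Monte-Carlo p-value.  Calibration is
verified by a Kolmogorov–Smirnov check against uniformity over hundreds
of exchangeable-null datasets.

## Synthetic data

The generator emulates the minimal structure the pipeline's claims rely
on; its defaults are the package's study conditions:

| parameter | default | meaning |
|---|---|---|
| n_genes | 2000 | gene/vertex universe |
| degree_exponent, min_degree | 2.5, 2 | Zipf-tailed degrees, mean ≈ 3 |
| n_disease, n_control | 20, 20 | samples per group |
| n_de_genes | 100 | planted DE genes |
| de_placement | network_module | BFS-grown connected module (vs `random`) |
| effect_size | 1.5 | mean shift in disease, units of noise SD |
| correlation_block_size, block_correlation | 10, 0.3 | shared latent factor per gene block |
| noise_sd | 1.0 | noise scale |

Networks are configuration-model draws (rejection sampling for a simple
graph, erased fallback); expression is block-correlated Gaussian noise,
with the planted genes shifted in the disease group.  The block
correlation exists so that label permutation preserves non-trivial
co-expression, the property the PFP scheme depends on.

**What this does not emulate:** microarray/RNA-seq count distributions,
batch effects, co-expression aligned with network topology, and hub
genes being biologically coherent modules.  Passing tests demonstrate
internal correctness and the direction of the claimed effects under
these idealized conditions, not effect sizes on real data.

**A known behavior of the rewired-network control:** rewiring preserves
degrees, so a very high-degree hub inside the planted module keeps a
large, stable neighborhood after rewiring and can keep WAP rankings
reproducible on the rewired network (the analogue of the
ubiquitously-connected-protein exception seen on real networks).  How
far the rewired control falls below the true-network result therefore
depends on the degree composition of the planted module and varies
across generator seeds; the benchmark retains per-split paired values
so this can be inspected directly.

## Problem sizes and determinism

Tests and the acceptance script use 2000-gene networks, 200
permutations for PFP, 200 random splits for the benchmark, and
200 × 500 permutations for MVT calibration — sizes chosen so the full
pipeline exercises every code path in about a minute on one CPU while
keeping the stochastic assertions comfortably away from their
thresholds.  Every stochastic operation takes an explicit seed;
per-permutation and per-split seeds fan out from the master seed by
counter (`SeedSequence(master, spawn_key=(index,))`), so results are
independent of execution order and adding splits never changes earlier
rows.  Ties anywhere (rankings, WAP tables) break by ascending gene
identifier.

## Limitations

* The Poisson attachment null assumes a sparse network
  (k_u k_v ≪ 2M); for genes whose degree approaches the network size
  the Bernoulli-sum approximation degrades.
* The degree-correction power law is fitted to the *median* null score;
  residual degree dependence in the tails is not corrected.
* Mapping between expression identifiers and network identifiers is the
  caller's responsibility (a 2-column mapping file is accepted by the
  CLI); no probe summarization or normalization is performed.
* PFP values are reported raw by default (an optional step-up pass
  makes the profile monotone), and Benjamini–Hochberg FDR is
  deliberately not applied to WAP scores.
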