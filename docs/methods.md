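# Methods

This note documents the models, numerical choices and known limitations
of `cyanodelim`, in the spirit of the methods documentation shipped by
simulation and statistics packages.

## GMYC model and likelihood

An ultrametric gene tree is decomposed, for a candidate threshold time
*T* (or a map of clade-local thresholds), into inter-node intervals
ordered root → tips. During interval *i* the combined event hazard is

    b_i = λ_div · k_i^p_div + λ_coal · Σ_j [n_ij (n_ij − 1)]^p_coal

with *k&#8321;* lineages in the between-entity (diversification) class and
*n&#8321;&#11388;* lineages inside entity *j*. The log-likelihood is
`Σ_i [e_i ln b_i − b_i x_i]`, where *x&#8321;* is the waiting time and *e&#8321;*
the number of nodes terminating the interval. Two details are worth
stating explicitly:

* **Class-specific exponents.** The scaling exponents `p_div` and
  `p_coal` are estimated separately for the two classes. Variants with
  a shared exponent exist; this implementation fixes the class-specific
  parameterization and counts parameters accordingly (null 2, single
  threshold 5, multiple 4 + number of thresholds).
* **Censored threshold slabs.** Candidate thresholds sit at midpoints
  between consecutive distinct node heights, so a threshold always
  falls strictly inside an internode slab. The slab is split at the
  threshold; the tips-side piece carries exposure (`−b·x`) but no event
  term, because no node terminates it. With this convention the waiting
  times of every tree sum exactly to the root height.
* **Null model.** One coalescent-form class containing every lineage
  (`b = λ·[n(n−1)]^p`). An event interval whose hazard is zero yields
  an explicit −∞ log-likelihood, never a silent NaN.

**Optimization.** For each candidate threshold the four parameters are
maximized by bounded L-BFGS-B over (log λ_div, log λ_coal, p_div,
p_coal) with log-rates in [−10, 10], exponents in [0, 3], tolerance
1e-8 and five deterministic starts: moment-matched rates at exponents
1.0 and 0.5, two skewed-rate variants, and a warm start from the
previous candidate. The likelihood surface over *T* is multimodal;
profiling over all candidates handles that dimension exactly.

**Confidence set.** All candidate entity counts whose profile
log-likelihood lies within 2 units of the maximum — the conventional
rule of single-threshold GMYC software, stated here because published
tables usually print such intervals without defining them.

**Multiple thresholds.** Greedy forward search from the best single
threshold: each step considers, for every diversification-side node, a
clade-local threshold at subtree-height midpoints, and applies the best
likelihood improvement; it stops below an improvement of 1e-6 or at
`max_thresholds`. This is a hill-climbing reconstruction — the search
is not guaranteed to visit the global optimum of the multiple-threshold
model.

**Likelihood-ratio test.** LR = 2(L_model − L_null) against χ² with
df = 3 (single) or 2 + #thresholds (multiple); stars at 0.05/0.01/0.001.
A negative LR (optimizer failure) is clamped to zero and flagged.
Simulations with this package show the test is **anticonservative** on
single-coalescent trees (≈20–30% rejections at α = 0.05 over 100
replicates of 30-tip coalescents): the threshold is maximized over ~29
candidates while the χ² reference ignores that selection. This matches
the behavior reported for the method in the delimitation literature and
should be kept in mind when interpreting a significant LRT on real
data; the multitree consensus below is the more robust summary.

## Multitree sampling and consensus

Per tree, a Metropolis–Hastings chain explores (log λ_div, log λ_coal,
p_div, p_coal, threshold index) under the single-threshold likelihood
with weakly informative priors: uniform threshold index, log-rates
uniform on [−10, 10], exponents uniform on [0, 3]. Proposals are
random-scan single-component updates — Gaussian (sd 0.3) on one
continuous parameter, or a ±1 step on the threshold index mixed with an
occasional (p = 0.2) uniform jump. The jump component is symmetric and
lets chains cross likelihood valleys between threshold modes, which
pure ±1 walks demonstrably fail to do. The original multitree method's
priors and proposal scheme are not published in detail; this scheme is
a documented reconstruction. Only the single-threshold model is
sampled, matching the threshold-based nature of the multitree
co-assignment approach.

Defaults mirror the source workflow (1000 trees, chain 50 000, burn-in
40 000, thinning 100 → 100 partitions per tree). The scaled-down runs
used by the test suite and the acceptance script keep the same
proportions — 20 trees, chain 3000, burn-in 2400 (80%), thinning 6,
again 100 partitions per tree — which removes the convergence failures
shorter ad-hoc chains showed while keeping runs desk-sized.

**Consensus.** The co-assignment matrix *P* is converted to *D = 1 − P*
and clustered by PAM (BUILD + SWAP, deterministic, ties to the lowest
index; the SWAP objective is asserted non-increasing). For k = 2 ..
min(k_max, n−1) the average silhouette width selects k, ties toward the
smaller k (parsimony of clusters). Singleton clusters take s(i) = 0 by
convention. Whether k = 1 should ever be entertained is an open design
point; the implementation reports a degenerate one-cluster flag when
every pairwise co-assignment probability is ≥ 0.5, rather than letting
k = 1 compete in a silhouette that cannot be computed for it. In the
exactness checks the heuristic (PAM) consensus is compared against
exhaustive k-medoids enumeration followed by the same silhouette rule.

## Diversity statistics

* Haplotype identity is byte identity over the full aligned sequence,
  gaps included; the ambiguity-aware mode merges a sequence into a
  haplotype when every site is IUPAC-compatible and at least one member
  is unambiguous.
* `Hd = n/(n−1)(1 − Σp²)`; its variance uses the standard estimator
  `V = 2/(n(n−1)) · {2(n−2)[Σp³ − (Σp²)²] + Σp² − (Σp²)²}`. The ±
  figure is the SD of the estimator (published tables are ambiguous
  between SD and SE; SD is implemented).
* Site-deletion policy for S and π defaults to complete deletion (drop
  any column containing a gap or ambiguity), the default of the classic
  diversity software; pairwise deletion is available.
* Group-wise tables skip groups with fewer than 10 sequences by default
  (the "more than 9 sequences" evaluation rule), overridable.

## Statistical-parsimony networks

Mutational steps are column-wise mismatches over a five-state alphabet
when gaps are read as an informative character (each gap column is one
character; indel blocks are not coalesced — the literal reading of the
five-state convention). Construction is agglomerative: pairs in
increasing step order join components when at or below the connection
limit, inserting step−1 inferred intermediates; within a distance tier
every pair bridging components that were distinct at the tier start is
recorded, so equal-length alternative connections are retained as loops
flagged ambiguous rather than resolved by the original tool's
unpublished tie-break cascade.

**Connection limit.** The classic limit is the largest step count *j*
whose probability of parsimony is at least the requested level
(typically 0.95). The numerical recursion of the original tool is not
reproduced in the source literature, so the default estimator here is a
model-based reconstruction: per-site substitution counts are Poisson(θ)
with θ moment-matched from the observed differences via the
Jukes–Cantor correction, and

    P_j = [P(K=1)/P(site differs)]^j · [P(K=0)/P(site same)]^(m−j)

is the probability that every observed difference arose from exactly
one substitution and no hidden changes occurred elsewhere. It is
decreasing in *j*, and the implied limit grows with sequence length
(m = 582 at 95% gives 7 steps). Because exact numerical parity with the
legacy tool is not guaranteed, the estimator is pluggable and
`fixed:N` gives bit-reproducible runs.

## Community–environment statistics

* **Normalization**: per-variable z-scores (sample SD), after expanding
  a categorical substrate column into 0/1 indicators; constant columns
  are rejected by name.
* **ANOSIM**: R = (mean between-group rank − mean within-group rank) /
  (M/2) over all M pairwise dissimilarities, mean ranks on ties;
  p = (exceedances + 1)/(n_perm + 1) over seeded label permutations
  (never exactly zero). Pairwise tables mark pairs containing a
  singleton group as not computable. The statistic is rank-based and
  therefore invariant to monotone transforms of the dissimilarities.
* **SIMPER**: the Bray–Curtis decomposition
  `δ_k(i,j) = |x_ik − x_jk| / Σ_s (x_is + x_js)` averaged over
  between-group pairs; percents normalize to 100.
* **BIO-ENV/BVSTEP**: per restart, a random starting subset is improved
  by the best single addition or drop of a variable, maximizing the
  Spearman correlation between the Euclidean distances of the
  environmental subset and the biotic dissimilarities; stopping at
  rho > 0.95 or improvement < 0.001 (both configurable). Model
  frequencies are tallied across restarts; significance permutes the
  biotic matrix labels and re-searches. An exhaustive all-subsets
  search provides the upper bound the greedy search can never exceed.
  The published collinearity pre-filter reads "exclude one of a pair of
  variables if the Euclidean distance between them exceeds 0.80", which
  on z-scored columns of realistic length excludes nearly every pair;
  it is implemented literally (`collin_mode="distance"`), with an
  absolute-correlation alternative and an off switch, and the intent is
  deliberately not second-guessed. The planted-signal analyses in this
  repository run with the filter off because their variables are
  generated with known, moderate cross-correlation.
* **Matrix correlation (RELATE)**: Spearman over off-diagonal entries,
  one-sided permutation p by relabeling one matrix.
* The number of search restarts versus significance permutations is
  exposed as two separate parameters because "10 000 permutations" in
  the source workflow is ambiguous between the two roles.

## Synthetic data generator

The generator emulates the statistical structure the analyses assume,
not the biology of any particular marker:

* **Trees.** A pure-birth species tree; within each species a Kingman
  coalescent grafted onto the terminal branch. With `separation_ratio`
  set, all coalescents share one scale chosen so the expected
  within-species depth equals the *shallowest* species divergence
  divided by the ratio — a single global threshold then separates the
  two processes, which is the regime the delimitation model posits
  (a per-species scale would let deep species' coalescents overlap
  shallow speciations). Coalescents deeper than the available branch
  are rejection-resampled. Posterior-like samples re-draw the
  coalescents and multiply branch lengths by lognormal noise
  (log-sd `jitter_sd`, default 0.05); re-ultrametrization assigns each
  internal node its mean jittered path length to descendant tips, which
  preserves the depth scale of shallow clades (absorbing the defect
  into terminal branches instead provably distorts them).
* **Alignments.** A single-rate symmetric (Jukes–Cantor-style) process;
  per-branch substitution probability `3/4·(1 − e^(−4/3·μ·ℓ))`.
  Optional single-column deletion events on random branches exercise
  the gap policies. At the study-like scale (582 sites, 30 sequences,
  μ = 0.15 per unit length) a typical draw yields ~15 haplotypes and a
  few hundred variable sites — the qualitative regime, not a calibrated
  imitation, of the empirical marker.
* **Communities.** Equi-correlated Gaussian environmental variables
  (pairwise correlation 0.25 by default); OTU occurrence probability is
  a logistic function of the designated driver variables with
  OTU-specific signed effects scaled by `effect_size` (default 2.0,
  chosen so composition is strongly but not deterministically
  structured) plus Gaussian noise (sd 0.5). Degenerate all-absent or
  all-present OTU columns are resampled.

What passing tests on these data do **not** show: robustness to
substitution-model misspecification, rate heterogeneity, recombination,
sampling biases across localities, or phylogenetic error beyond the
branch-length jitter used here. The generators are deliberately the
favourable regime for each method; the recovery rates reported by the
acceptance script quantify method behavior under the stated conditions
only.

## Problem sizes used in checks

The repository's own end-to-end checks use 5 species × 6 tips
(separation ratio 20), 100 trees for recovery/type-I, 20-tree posterior
samples over 50 replicates for the consensus pipeline, 8-haplotype
instances for network/consensus oracles, and 30-locality, 10-variable
communities with 2 planted drivers for BVSTEP — sizes chosen to make
every stochastic property measurable on a single desktop CPU while
keeping the Monte Carlo margins interpretable.

## Known limitations

* The GMYC LRT's anticonservativeness (above) is reported, not
  corrected; a simulation-calibrated reference distribution would be
  the principled fix and is out of scope.
* `fit_multiple` is a greedy search; its entity count is a lower bound
  on the attainable multiple-threshold likelihood optimum.
* The connection-limit estimator is a reconstruction; limits from the
  legacy network tool may differ by a few steps at a given length.
* The MH sampler treats each tree independently; no across-tree
  adaptation or parallel tempering is attempted.
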