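# cyanodelim

Species delimitation and ecological-gradient analysis for symbiont
populations, built around the workflow used to study cyanobacterial
photobionts (*Rivularia*) of the maritime lichen genus *Lichina*: delimit
operational taxonomic units (OTUs) on ultrametric gene trees, summarize
delimitation uncertainty across a posterior sample of trees, describe
haplotype diversity and relatedness, and ask which environmental
variables structure OTU composition across localities.

The package is aimed at researchers with single-locus population
alignments (e.g. the phycocyanin operon spacer, PC-IGS) and posterior
tree samples from a Bayesian dating analysis, who want a scripted,
reproducible version of the classic GMYC + TCS + PRIMER tool chain.

## What it computes

**GMYC delimitation** (`cyanodelim.gmyc`). The generalized mixed
Yule–coalescent model assumes branching before a threshold time *T*
reflects diversification between entities and branching after it
reflects coalescence within entities. On each inter-node interval *i*
with waiting time *x&#8321;*, *k&#8321;* between-entity lineages and *n&#8321;&#11388;* lineages
within entity *j*, the hazard is

```
b_i = λ_div · k_i^p_div  +  λ_coal · Σ_j [n_ij (n_ij − 1)]^p_coal
```

and the log-likelihood is `Σ_i [e_i·ln b_i − b_i·x_i]` (*e&#8321;* = nodes
terminating the interval). `fit_single` profiles *T* over midpoints
between node heights; `fit_multiple` adds clade-local thresholds
greedily; `likelihood_ratio_test` compares against a one-process null
via χ² (df 3 for the single threshold).

**Multitree consensus** (`cyanodelim.bgmyc`). A Metropolis–Hastings
sampler draws GMYC delimitations over many posterior trees; the
fraction of sampled partitions placing tips *i, j* together forms a
co-assignment matrix *P*. The consensus partition applies k-medoids
(PAM) to *D = 1 − P* and picks the cluster count with the optimum
average silhouette width.

**Diversity statistics** (`cyanodelim.popgen`). Haplotype collapsing,
segregating sites *S*, haplotype diversity `Hd = n/(n−1)·(1 − Σp²)`
with its sampling SD, and per-site nucleotide diversity π, with
complete or pairwise site deletion.

**Statistical-parsimony networks** (`cyanodelim.network`). Haplotype
networks with gaps readable as a fifth character state, a pluggable
probability-of-parsimony connection limit, and inferred intermediate
nodes; outputs GraphML + TSV.

**Community ecology** (`cyanodelim.ecology`). Sørensen / Bray–Curtis /
Euclidean dissimilarities, ANOSIM with seeded permutation tests and
pairwise tables, SIMPER contributions, BIO-ENV/BVSTEP stepwise search
for the environmental-variable subset whose Euclidean distances best
rank-correlate (Spearman) with the biotic matrix, and RELATE-style
matrix correlation.

**Synthetic data** (`cyanodelim.simulate`). Seeded generators for
species trees with grafted within-species coalescents, posterior-like
jittered tree samples, alignments under a symmetric substitution model
(with optional indel columns), and locality × OTU tables driven by
known environmental variables — every analysis is testable end to end
without any download.

## Worked example

```python
from cyanodelim import simulate, gmyc, bgmyc, popgen

# 1. a study-like dataset: 5 photobiont species, 6 sequences each,
#    species divergences 20x deeper than within-species coalescences
tree, sample, truth = simulate.simulate_species_tree_sample(
    n_species=5, tips_per_species=6, separation_ratio=20,
    n_posterior=20, jitter_sd=0.05, seed=42)

# 2. single-threshold GMYC on the tree, tested against the null
null = gmyc.fit_null(tree)
fit = gmyc.fit_single(tree)
lrt = gmyc.likelihood_ratio_test(null, fit)
print(f"GMYC single threshold: {fit.n_entities} entities "
      f"(confidence set {fit.conf_set}), "
      f"LR = {lrt.statistic:.3f}, p = {lrt.p_value:.2e} {lrt.stars}")

# 3. multitree sampling -> co-assignment -> consensus partition
parts = bgmyc.sample_partitions(sample, n_trees=20, chain_length=3000,
                                burnin=2400, thin=6, seed=1)
P = bgmyc.coassignment_matrix(parts)
res = bgmyc.consensus_partition(P, k_max=29)
print(f"consensus partition: k = {res.k} "
      f"(average silhouette {res.average_silhouette:.3f})")

# 4. sequence diversity on a simulated 582-bp alignment
aln = simulate.simulate_alignment(tree, n_sites=582, mut_rate=0.15, seed=42)
haps = popgen.collapse_haplotypes(aln)
hd, sd = popgen.haplotype_diversity(haps.counts())
print(f"{haps.n_haplotypes} haplotypes, S = {popgen.segregating_sites(aln)}, "
      f"Hd = {hd:.3f} +/- {sd:.3f}, pi = {popgen.nucleotide_diversity(aln):.4f}")
```

Output:

```
GMYC single threshold: 5 entities (confidence set [5]), LR = 14.163, p = 2.69e-03 **
consensus partition: k = 5 (average silhouette 0.936)
15 haplotypes, S = 284, Hd = 0.929 +/- 0.026, pi = 0.1737
```

The delimitation recovers the five simulated species exactly (both the
point estimate and the multitree consensus), the likelihood-ratio test
rejects the one-process null, and the diversity block mirrors the
layout of a classic per-region summary table (counts, *S*, Hd ± SD, π).

A command-line interface exposes the same steps
(`cyanodelim gmyc|bgmyc|consensus|haplo|diversity|network|anosim|simper|bioenv|relate|simulate`);
run `cyanodelim --help` for the full surface.

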