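# mifilter

Mutual-information network filtering of contaminant taxa in microbiome
count tables.

## The problem

16S rRNA amplicon and metagenomic sequencing produce a samples × taxa count
table in which many columns are not community members at all: reagent and
cross-sample contamination and sequencing errors introduce spurious
ASVs/OTUs, especially in low-biomass samples. Classic remedies filter on
abundance or prevalence with arbitrary cutoffs, which discards genuine
low-abundance taxa and keeps prevalent contaminants.

`mifilter` instead exploits the fact that real community members co-vary:
it builds a taxon co-occurrence network weighted by normalised mutual
information, and treats taxa that share no information with the rest of the
community as putative contaminants. It is aimed at microbiome researchers
cleaning ASV/OTU tables before downstream analysis, and requires no blanks
or negative controls.

## The method

For taxa $X_j, X_{j'}$ (abundances discretized by per-taxon histograms,
equal-width Sturges bins by default):

1. **Adjusted MI adjacency.**
   $\tilde{\mathcal I}_{jj'} = I(X_j;X_{j'}) / H(X_j,X_{j'})$ with
   $I = H(X_j)+H(X_{j'})-H(X_j,X_{j'})$. This lies in $[0,1]$, is
   symmetric, has unit diagonal, and is independent of the logarithm base.
2. **Hard threshold by scale-free fit.** The binary network at threshold
   $\tau$ has an edge iff $\tilde{\mathcal I}_{jj'} \ge \tau$. For each
   $\tau$ in a grid (0.05–0.95), the degree distribution $P(k)$ is fitted
   by OLS of $\log P(k)$ on $\log k$ (a power law $P(k)\sim k^{-\gamma}$ is
   linear there); the $\tau$ with the highest $R^2$ wins, ties going to
   higher mean connectivity $\bar k$. Taxa isolated at the selected $\tau$
   (degree 0) are removed.
3. **Information loss.** Taxa are ranked by weighted degree
   $d_j=\sum_{j'\ne j}\tilde{\mathcal I}_{jj'}$ and removed below degree
   quantiles $q_k$; the loss is
   $\Lambda_k = 1-\lVert\tilde{\mathcal I}'_k\rVert_F^2 /
   \lVert\tilde{\mathcal I}\rVert_F^2$.
4. **Step tests.** Whether stepping $q_k\to q_{k+1}$ loses significant
   information is tested one-sidedly by (a) a permutation test whose null
   shuffles each taxon's counts across samples and recomputes the step
   loss, and (b) a bootstrap test of the studentised increment under
   column resampling of the pooled retained sets. p-values use the
   $(\text{count}+1)/(M+1)$ convention, so with $M=500$ the floor is
   $1/501 < 0.002$.
5. **Evaluation.** With ground-truth labels: four traditional
   abundance/prevalence filters for comparison and an ROC curve of the
   non-isolation rule over $\tau$.

A seeded mock-community simulator (`generate_community`) provides labelled
tables patterned on a published vaginal-microbiome mock community
(240 samples, 7 true strains, 39 contaminants, ~99.9% of reads from true
strains).

## Worked example

```python
from mifilter import (adjusted_mi_matrix, brooks_like_spec, generate_community,
                      hard_threshold, isolated_taxa, scan_thresholds)

table, labels = generate_community(brooks_like_spec(seed=1))
adj  = adjusted_mi_matrix(table)
scan = scan_thresholds(adj)
net  = hard_threshold(adj, scan.selected_tau)
kept, removed = isolated_taxa(net)
print(scan.selected_tau, len(kept), len(removed))
```

prints

```
0.3 7 39
```

the scale-free scan selects the hard threshold 0.3; at that threshold the
7 genuinely present strains stay connected and all 39 contaminants are
isolated and removed (84.8% of taxa filtered, 0% contamination kept).
Running the step tests on the same table
(`scan_steps(table, n_permutations=500, n_bootstrap=500, seed=11)`) yields
permutation p-values of 1.000 on every contaminant-only step and
p < 0.002 on the two steps that start consuming true taxa, so the
recommended removal level is the 0.86 degree quantile — right at the
simulated contaminant fraction 39/46 ≈ 0.85.

The `examples/` directory contains five short narrative scripts (simulate,
network + threshold, information loss, step tests, filter comparison), and
the same pipeline is scriptable from a shell:

```bash
mifilter simulate --seed 1 -o run/
mifilter filter run/counts.tsv -o run/
mifilter report run/counts.tsv --labels run/labels.tsv -o run/
```

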