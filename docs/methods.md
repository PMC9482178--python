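# Methods

This note documents the statistical model behind `mifilter`, the choices
made where the design was genuinely open, what the synthetic data do and do
not emulate, and known limitations.

## Information-theoretic adjacency

Taxon abundances are discretized per taxon with histogram partitions.
Default: equal-width bins with Sturges' rule on the sample count
(`ceil(log2 n) + 1`; n = 240 gives 9 bins). Equal-frequency binning and
fixed bin counts are available (`DiscretizationScheme`). A constant column
collapses to a single bin rather than failing.

All quantities are plug-in estimates from empirical bin frequencies,
computed in nats. Mutual information is evaluated through the joint-entropy
identity `I = H(X) + H(Y) − H(X,Y)`, which guarantees symmetry and (up to
round-off) non-negativity; values in `(−1e−12, 0)` are clamped to zero and
anything more negative raises, since the plug-in estimate is analytically
non-negative. The network weight is the *adjusted* MI, `I / H(X,Y)`,
which satisfies the three adjacency conditions (range `[0,1]`, symmetry,
unit diagonal) and is invariant to the logarithm base because the base
cancels in the ratio. Degenerate pairs with zero joint entropy (two
constant taxa) get weight 0; a zero-variance taxon therefore shares no
information with anything and will always be isolated.

The all-pairs estimator one-hot encodes every taxon's bin labels and gets
all pairwise joint histograms from a single sparse product, so resampling
procedures can re-estimate the full adjacency thousands of times; tests
verify it against a per-pair contingency-table oracle at 1e−10.

No bias correction (e.g. Miller–Madow) is applied: the filter compares
*normalised* MI values against a common threshold, and the plug-in bias is
part of the empirical noise floor the threshold scan absorbs.

## Threshold selection

The binary network at threshold τ keeps an edge where the adjusted MI is
≥ τ (inclusive). Node degrees never count the diagonal — mean
connectivities below 1 are meaningful and indicate mostly-isolated
networks. For each τ in the default grid 0.05–0.95 (step 0.05), the
empirical degree distribution over the distinct observed degrees is fitted
by ordinary least squares of log P(k) on log k; k = 0 nodes cannot enter a
log fit and are excluded from it, but still count toward mean
connectivity. The reported R² is the coefficient of determination of that
regression; the slope and its magnitude (γ̂) are reported separately and no
sign convention is forced on γ̂.

Selected τ: the highest R² among *supported* fits, ties broken by larger
mean connectivity, with two qualifications made deliberately:

* a fit on exactly two support points is perfect by construction and
  carries no evidence of scale-freeness; such fits are flagged
  `low_support` and excluded from selection whenever any fit with three or
  more points exists (they are still reported, and they remain eligible
  when nothing better is defined, so singleton grids work);
* fits with fewer than two positive-degree points are undefined and never
  selectable; if every τ is undefined the scan raises and suggests a
  denser grid or different binning.

Taxa isolated at the selected τ are reported as putative contaminants; if
*everything* is isolated the partition is still returned with a warning.

## Information loss and removal quantiles

Weighted degree: off-diagonal row sums of the adjusted MI matrix
(excluding the diagonal's constant +1, which would distort quantile ranks).
Removal at quantile q discards taxa whose degree is *strictly below* the
type-7 (linear interpolation) empirical q-quantile; degrees are rounded at
1e−12 first so degrees equal up to summation round-off behave as exact
ties — in particular, with all-equal degrees nothing is ever removed.
Pairwise MI does not change when other columns are dropped, so the reduced
matrix is the exact principal submatrix of the full one and is never
re-estimated. The loss `Λ = 1 − ‖reduced‖²_F / ‖full‖²_F` is
non-decreasing as the retained set shrinks, 0 for no removal, 1 for total
removal, and depends only on the retained set, not the removal order. A
one-at-a-time trajectory (increasing degree, ties by taxon id) is provided
for per-taxon inspection.

## Hypothesis tests on removal steps

Both tests address H0: stepping the removal quantile from q_k to q_{k+1}
does not change the information loss, one-sided against loss increase, with
the `(count+1)/(resamples+1)` p-value convention (floor 1/(M+1), ceiling
exactly 1). A step that removes no additional taxa is degenerate and
reported with p = 1.

**Permutation test.** The null model destroys cross-taxon association
while preserving every marginal: each taxon's counts are independently
shuffled across samples, the adjacency, degrees and the same quantile step
are recomputed, and the resampled increments Δ* collected. Because columns
are shuffled wholesale, the procedure is a valid exchangeability test —
under i.i.d. taxa the observed table is one permutation among many, which
is what gives the measured type-I control (3% at nominal 5% in the
package's null simulation). On association-free resamples a step costs
only the near-diagonal Frobenius mass, so steps that discard genuinely
connected taxa land far in the upper tail and bottom out at the p-value
floor. The alternative null considered — removing a random same-size
subset of retained taxa instead of the lowest-degree ones — was rejected
during design: the lowest-degree taxa lose *less* mass than random taxa by
construction, so that test can never reject and cannot reproduce the
contrast between early and crossing steps that motivates the method. In a
grid scan one set of permutations serves all steps, which keeps the null
consistent across steps and the cost at one adjacency estimate per
resample.

**Bootstrap test.** The studentised increment
`t_k = (Λ_{k+1} − Λ_k) / sqrt(‖Σ_{k+1}‖²/m_{k+1} + ‖Σ_k‖²/m_k)` uses
squared Frobenius norms of the covariance matrices of the retained count
columns (matching the loss's norm; a spectral-norm variant is available).
Covariances are computed on raw counts by default, with a
relative-abundance option. Each resample draws `m_k + m_{k+1}` columns
with replacement from the pooled retained sets, splits them into Z*/Y*,
and evaluates the recentred statistic. Pairwise MI and covariance depend
only on the pair of original columns, so the resampled matrices are exact
index selections of the full ones — the bootstrap loop is pure index
arithmetic and needs no re-estimation. Resamples containing constant
columns are retained (their MI rows are zero by the degenerate rule);
a resample whose covariance norms both vanish is counted conservatively
toward the p-value.

The two tests probe different alternatives and need not agree. On the
synthetic preset the bootstrap is conservative at adjacent crossing steps:
its null pools the retained columns, which at the crossing are themselves
true taxa, so the resampled spread is comparable to the observed increment
(measured rejection 0/30 there, versus 30/30 for the permutation test);
it does reject reliably (15/15) for wide steps whose retained sets differ
drastically. The scan's removal recommendation therefore defaults to the
permutation test; the recommended level is the largest grid quantile
reached before the first rejecting step (the top of the grid, with a
warning, if every step is degenerate). No multiple-testing correction is
applied across steps.

## Synthetic mock community

`generate_community` emulates a mock-community validation design:
prescribed mixtures of a few true strains plus sparse contamination, with
multinomial reads at a nominal per-sample depth (compositional closure
included; realised yields vary with the sampled mixture's total prescribed
mass). Key structure:

* Each sample realises one of `n_states` (default 8) community states;
  each *leader* taxon's prescribed relative abundance across states is a
  scaled permutation of `0..n_states−1` (level 0 = absent from that
  mixture), so abundances vary over well-separated linear levels that
  survive equal-width binning. Leaders follow the sample's state with
  probability ≈ ρ (graded mildly across leaders); the remaining true taxa
  each track a designated leader with probability ρ^(1/3), modelling
  co-prescribed partner strains and guaranteeing every true taxon one
  strong network edge. At ρ = 0 all coupling vanishes and true taxa are
  exchangeable with uncoupled contaminants of the same scale.
* Contaminants are independent level taxa scaled by `10^(−abundance_gap)`
  (default 4 log10 — about 10⁻⁴ relative abundance, a read or two when
  present), with batch-structured presence: each contaminant belongs to one
  of `n_batches` sample batches and appears more often inside it, as
  reagent and cross-sample contamination does in practice. This weak
  contaminant co-occurrence reproduces the gradually thinning low-τ
  network real tables show; fully independent contaminants instead yield
  sparsely-populated, spuriously clean low-τ degree distributions that can
  capture the threshold scan. Contaminants are always independent of the
  true community, and labels are exact.
* Defaults (240 samples, 7 true, 39 contaminants, depth 15000,
  gap 4, sparsity 0.2, ρ = 0.9) mirror the published mock community used
  to validate this method class: ~99.9% of reads from true strains and a
  most-frequent-contaminant relative abundance near 10⁻⁴.

A separate i.i.d. negative-binomial generator (`generate_null_table`)
provides exchangeable-taxon nulls for type-I-error experiments.

What passing tests on these data do **not** show: robustness to ecological
gradients without discrete state structure (smoothly log-normal
co-variation discretizes to much weaker adjusted MI), to compositional
artefacts in unbalanced real communities, to taxonomic misassignment, or
to contaminants correlated with the true community (cross-contamination
from the samples themselves).

## Numerical choices

* MI clamp tolerance 1e−12 nats; adjusted MI clipped to [0, 1]; joint
  entropies symmetrised to remove reduceat ordering jitter.
* Degree rounding at 1e−12 before quantile thresholds (exact-tie
  behaviour).
* OLS fits use `np.polyfit`; R² = 1 when the residual sum is < 1e−14
  (perfect fits), 0 when the fit explains nothing of a degenerate spread.
* Resampling streams derive from a single `SeedSequence`; scans spawn
  independent child streams for the permutation and bootstrap stages, so
  results are exactly reproducible from (seed, grid, M, B).

## Problem sizes used in the checks

The bundled experiments run at the preset's own scale: recovery over 50
simulated communities (240 × 46), type-I control over 200 null tables
(200 × 40) at 200 resamples per test, and 500-resample step tests for the
reference analysis. The acceptance script repeats recovery over 20
simulations. These sizes make the full suite run in a few minutes on one
CPU while keeping binomial error on the reported rates small.

## Known limitations

* With few taxa the degree distribution has very few support points, so
  R² across thresholds is noisy; the low-support exclusion mitigates but
  does not remove this. Community-detection-based selection would be a
  natural extension.
* Isolated-node filtering cannot catch contaminants that correlate with
  each other above the selected threshold; the quantile-removal stage
  (step tests) partially addresses this.
* Plug-in MI is biased upward at small n; the bias is part of the noise
  floor rather than corrected, so very small studies (n ≲ 50) will see
  inflated adjacency weights throughout.
* The bootstrap step test has little power for adjacent quantile steps
  (see above); treat it as corroboration for coarse removal decisions.
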