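# Methods

## Model and procedure

### Switch triplets and liquid association

The object of inference is a *switch triplet*: a gene pair (X₁, X₂) whose
Pearson correlation depends on the expression level of a modulator X₃. The
screen operationalises this by ranking samples on X₃, taking the top and
bottom tertiles as the "high" and "low" strata, and computing the pair
correlation in each: ρ_high, ρ_low, and ρ_diff = |ρ_high − ρ_low|. The
tertile rule is the default because on standardized profiles the upper-third
cut of a standard normal sits at ≈ +0.43, matching the high-stratum range
observed in cross-shaped scatter plots of real screens; median splits and
custom quantiles are options (`ScreenConfig.stratum_rule`).

Before screening, every gene profile is passed through a rank-based normal
quantile transform — rank r of n maps to Φ⁻¹((r − 0.5)/n), average ranks for
ties — and then standardized to mean 0, SD 1 (n − 1 denominator). The
(r − 0.5)/n offset avoids ±∞ at the extreme ranks. The classical liquid
association score LA = (1/n)Σᵢ x₁ᵢx₂ᵢx₃ᵢ is computed on these transformed
profiles and reported descriptively alongside each triplet.

Significance defaults to the Fisher-z two-sample statistic for a difference
of correlations estimated on disjoint strata,
z = (atanh ρ_high − atanh ρ_low)/√(1/(n_high−3) + 1/(n_low−3)), two-sided
against the standard normal. On pure-noise matrices the resulting p-values
are uniform (checked by Kolmogorov–Smirnov at 10 000 triplets in the test
suite). A permutation alternative (shuffling X₃ across samples and
recomputing ρ_diff) is provided for settings where the bivariate-normal
approximation is doubtful; it is exact but ~10³× slower.

Multiplicity control is Bonferroni. **m defaults to the number of enumerated
triplets**, G·C(G−1, 2) — the number of tests actually performed — not the
number of triplets passing the ρ_diff reporting floor: the floor preselects
small p-values, so using the post-floor count as m would inflate the
family-wise error rate by the ratio of total to retained triplets (~40× at
the default floor). An explicit integer override and a Benjamini–Hochberg
option exist. The significance threshold on adjusted p is 0.01. Note this
literature sometimes labels the Bonferroni-adjusted quantity "FDR"; what is
controlled is the family-wise error rate.

The ρ_diff reporting floor defaults to 0.5, below the smallest difference
(0.56) seen among headline triplets in published screens of this kind; it
only trims the output table and never affects p or m. ρ_diff is reported as
an absolute value, with the signed difference retained in a separate column.

### Differential expression

The moderated two-sample t shrinks per-gene pooled variances s²_g (d_g =
n₁ + n₂ − 2 df) toward a prior: s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g), with
t̃_g = (x̄₁ − x̄₂)/(s̃_g√(1/n₁ + 1/n₂)) referred to t with d₀ + d_g df. The
hyperparameters are estimated by method of moments on e_g = log s²_g −
ψ(d_g/2) + log(d_g/2): the excess of Var(e) over ψ′(d_g/2) identifies d₀
through the trigamma inverse (Newton iteration), and the mean identifies
s₀². When the excess is non-positive, d₀ = ∞ and all genes share s₀²
(normal reference). `prior_df=0` recovers the classical pooled t exactly.
Genes with zero pooled variance are excluded from moment estimation and
shrunk fully to the prior. Empirical type-I error on 10⁴ null genes is
0.049 at α = 0.05 (asserted in [0.03, 0.07] by the suite). DEG testing runs
per disease (case vs control within each disease label).

### Mutual-information network

Edges are scored by MI. The default estimator is a plug-in estimate on a
k × k equal-frequency contingency table with k = ⌈√(n/5)⌉ — a documented
approximation to adaptive-partitioning estimators — **with the Miller–Madow
first-order bias correction** (subtract (k−1)²/(2n), floor at 0). Without
the correction the plug-in bias at n = 2000, k = 20 is ≈ 0.09 nats, as
large as the signal of interest; with it, the estimate of MI at ρ = 0.6 is
within ±0.08 of the closed form. The Gaussian estimator −½ln(1 − ρ²) is
available and is the closed-form oracle in tests; it is capped at 50 nats
as |ρ| → 1.

Edge significance: the (1 − α) quantile of MI over `n_perm` sample-permuted
random gene pairs (α = 0.05, n_perm = 1000 by default); each retained edge
also gets an empirical p from that null sample. DPI pruning then removes
edge (i, j) iff some common neighbour k has min(MI(i,k), MI(j,k)) − ε >
MI(i,j), with all removals evaluated against the pre-pruning network, so
the operation is order-independent and idempotent. ε defaults to 0 (strict
minimum of each triangle, the canonical description).

### Enrichment and integration

Over-representation is the upper hypergeometric tail P(X ≥ k) against the
universe of genes present in the analysed matrix (pathway sizes K are
counted in that restricted universe — the only self-consistent choice when
the matrix was pre-filtered to an annotation subset). A "two-sided" variant
(doubling the smaller tail, capped at 1) is available but off by default:
over-representation is what the downstream gates consume. Adjustment is
Holm's step-down; passing requires adjusted p < 0.05 and ≥ 3 query hits.
Passing pathways with pairwise Cohen's kappa ≥ 0.4 (on membership
indicator vectors over the universe) are merged by single linkage into
groups labelled by their lowest-p member; published tools use richer
iterative merging rules that are not fully public, so single linkage is the
documented stand-in.

A significant triplet is *pathway-coherent* when X₁ and X₂ co-occur in at
least one pathway passing in at least one disease, and *network-supported*
(default rule) when both X₃–X₁ and X₃–X₂ edges exist — the switch gene
framed as the regulator. `any_edge` and `connected` rules are provided
because real screens show mixed connectivity patterns; the default is a
design choice, not an assertion about how detectability must be defined.
The headline set is the intersection of both gates, and is a subset of each
gate's set, which are subsets of the significant set (asserted as an
invariant). When screening is run per disease, a triplet's
`diseases_involved` lists the diseases whose runs call it significant;
pooled runs leave it empty.

Validation statistics mirror the screen's plausibility checks: the per-gene
X₃ "event rate" among significant triplets at a grid of p thresholds (mean
over genes appearing at least once as X₃) against the uniform baseline 1/G,
and the DEG fraction among all genes versus among X₃ positions of
significant triplets (computed as exact rational counts).

## Synthetic data: what it emulates and what it does not

`generate_study` emulates the statistical structure the analysis assumes:
i.i.d. standard-normal background (one substream per gene row, so adding
genes never perturbs existing rows), a minority of genes with a case-group
mean shift in SD units, and planted cross-shaped triplets. Strata for
planting are defined on X₃'s sample *ranks*, so planting commutes with any
monotone transform — in particular with the screen's normal quantile
transform. Within the upper/lower stratum the pair is bivariate normal with
the requested ρ_high/ρ_low; the middle third is left uncorrelated, since
the cross-shaped model constrains only the extremes. Defaults in the
packaged demonstrations use ρ_high ∈ [0.6, 0.8] and ρ_low ∈ [−0.8, −0.6],
the magnitudes typical of published switch triplets, at 120 samples (40 per
tertile) and a 2-SD DEG effect — sizes at which a screen of this design has
near-complete power, which is the point of a demonstration fixture.

`TripletSpec.driver_strength` (default 0) adds a linear X₃ component to
both pair genes. A pure cross-shaped triplet has *zero marginal* X₃–X₁ and
X₃–X₂ dependence by construction and is therefore invisible to any
marginal-dependence network; a planted triplet can only be expected to pass
the network gate if the modulator is also a marginal driver. The toy
pipeline config plants one such driver triplet (strength 1.0, i.e. the
driver component as large as the independent one).

Not emulated: bead-array noise models, probe effects, batch structure,
heavy-tailed or discrete expression marginals, correlated background genes.
A green planted-recovery test therefore establishes correctness of the
statistics and plumbing under the stated generative model, not performance
on real microarray data.

## Numerical choices and degenerate inputs

- Ties in ranks: average ranks (deterministic, symmetric).
- Constant vectors are rejected by the quantile transform and standardizer;
  zero within-stratum variance is rejected by the conditional-correlation
  computation.
- |ρ| = 1 in the Fisher-z test underflows; the smallest positive float is
  returned with a warning. In the vectorized screen, correlations are
  clipped to 1 − 10⁻¹⁵ before atanh.
- Bonferroni adjustment caps at 1; Holm enforces monotonicity by a running
  maximum; BH by a reverse running minimum.
- The toy pipeline runs the GRN with DPI tolerance ε = 0.15 (the value
  conventional for ARACNE runs on dense graphs) rather than the strict
  default: the planted driver triplet's true dependency graph is a
  *triangle* — X₃ drives both pair genes *and* the pair is directly coupled
  through the switch mechanism — and in that geometry zero-tolerance DPI is
  guaranteed to prune one true edge.
- Determinism: every stochastic step derives from one integer seed through
  fixed `SeedSequence` spawn keys; reruns of `run_pipeline` with the same
  config write byte-identical TSVs (asserted in the suite).

## Known limitations

- The Fisher-z p-value is asymptotic and assumes approximate bivariate
  normality within strata (guaranteed here by the quantile transform only
  marginally, not jointly); the permutation option is the remedy when that
  matters.
- Exhaustive enumeration is O(G³) triplets; at 50 genes (58 800 triplets) a
  screen takes well under a second, but genome-scale runs require the gene
  pre-filtering step that the pipeline's design presumes.
- The binned MI estimator with k = ⌈√(n/5)⌉ is a fixed-partition
  approximation; rankings among near-tied edges at small n are noisy, which
  is why the DPI tolerance matters for dense true subgraphs.
- A triplet detected by the screen in one orientation is usually detectable
  in others (three-way dependence has no privileged factorisation), so
  per-gene X₃ event rates on strongly planted data count some re-oriented
  duplicates; the validation statistics treat this as signal concentration,
  which is what they measure in real screens too.
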