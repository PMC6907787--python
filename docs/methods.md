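# Methods

This note documents the models, algorithms and design choices behind
`vaxbiome`, the parameters that matter, and what the synthetic-data tests do
and do not demonstrate about real data.

## Study template and synthetic data

The package is organized around a longitudinal mouse vaccine design: six
treatment groups — negative control (NG), wild-type probiotic vector (WT),
an epitope-expressing vaccine strain (MPER), the same strain with a secreted
IL-1β or surface-FliC adjuvant (IL1b, FliC), and the vaccine with a rice-
bran prebiotic diet (RB) — with six mice per group (five for RB), fecal
sampling at weeks 0, 2, 4, 6, 8 and 10 (RB additionally at −1 and 12), one
cecal sample per mouse at necropsy, and a target sequencing depth of 4×10⁴
reads per sample.

`simulate.simulate_study` emulates this template post-OTU-calling:

- **Counts.** Each sample's latent log-composition is a per-OTU baseline
  (Normal(0, 1.2)) plus a per-treatment polynomial trend in scaled week
  acting on a ±1 "responder" loading vector (20% of OTUs respond per
  treatment), plus a per-mouse scalar intercept (SD 0.4) acting on a fixed
  direction.  The softmax of the latent field gives the expected
  composition; counts are Dirichlet-multinomial with concentration 150
  (configurable; ∞ degenerates to multinomial) at a log-normal depth around
  the 4×10⁴ target (log-SD 0.25).  A plain multinomial would understate the
  between-sample dispersion of real 16S data and make the diversity
  analyses trivially easy; the concentration value is a round number giving
  visible but not overwhelming overdispersion at this depth.
- **Richness.** Group differences in richness are induced by presence
  masks: per treatment and week, a polynomial fraction of OTUs (in a fixed
  treatment-specific random order) is removed from the composition before
  renormalization.  Masks act on presence rather than abundance so observed
  richness and Chao1 respond directly.  Effect sizes are chosen to make
  group separation detectable at desk scale, not to match any particular
  empirical magnitude.
- **IgA.** Total IgA (ng/mL) follows a per-treatment cubic in scaled week
  plus a per-mouse intercept (SD 120) and Gaussian noise (SD 80), floored
  at zero; antigen-specific IgA is identically zero for NG/WT, and
  zero-inflated log-normal for the epitope-bearing groups with a
  week-increasing positivity probability.  The RB group and cecal samples
  carry no IgA values, matching the study template.
- **Mock community.** Five mock samples with ten expected members at high
  counts; a random 15% of the remaining OTUs receive spurious counts
  uniform on [1, 25] per sample.  The ceiling 25 makes the derived cutoff
  consequential (it removes real singletons/doubletons downstream) without
  dominating the table.
- **ELISA plate.** Standards are 1:10 serial dilutions from 1000 ng/mL in
  duplicate with OD linear in log10 concentration between 0.05 and 2.0 over
  0.1–1000 ng/mL (clamped outside), negatives have a small background above
  the curve floor (mean 0.06, SD 0.008), and OD noise is 0.02.  Titer
  samples are constructed so their true endpoint sits midway (in log2)
  between the passing and failing dilution.

All randomness flows from one master seed through named CRC-32-keyed
substreams (counts, mock, IgA, ELISA, Gibbs, forest, NMDS), so changing one
component's configuration never perturbs another's draws, and identical
seeds give byte-identical outputs.

What the generator does **not** emulate: sequence-level error, chimeras,
cage/coprophagy effects, compositional covariance beyond the single
mouse-effect direction, taxonomic realism beyond a Firmicutes/Bacteroidetes-
dominated vocabulary, or plate-layout artifacts.  Passing tests therefore
demonstrate correctness of the estimators and calibration under this
generative model, not performance guarantees on real sequencing data.

## Count filtering and normalization

The mock-derived cutoff is the maximum count over all mock samples of any
OTU *not* in the expected member set; thresholding zeroes every entry ≤ the
cutoff (the cutoff count itself is treated as noise).  Taking the maximum
over all OTUs including members would annihilate the table, so the member
set is an explicit argument.  All-zero OTU columns are retained (and
flagged) to keep identifier alignment with the taxonomy.

Cumulative sum scaling divides each sample by the sum of its counts at or
below the chosen quantile (default 0.5) of its nonzero counts, times 1000.
The original method's data-adaptive quantile selection is replaced by a
fixed configurable quantile for determinism and desk-scale testability; the
1000 rescaling constant is applied uniformly so it cancels in Bray–Curtis.
The >1% prevalence rule is implemented as *strictly greater than the
threshold in at least one sample* — the natural reading when the quantity
feeds per-sample bar plots; a taxon at exactly the threshold everywhere is
excluded.

## Diversity and ordination

Chao1 uses the bias-corrected form S_obs + F1(F1−1)/(2(F2+1)) so
doubleton-free samples are defined; Shannon uses natural logarithms.  The
Hill-number ordering (inverse Simpson ≤ exp(Shannon) ≤ richness) is enforced
as a property test, and Chao1/Shannon are cross-checked against an
independent implementation.

NMDS minimizes Kruskal stress-1,
sqrt(Σ(d̂ − f(d))² / Σ d̂²), by gradient descent on the coordinates with
step halving; each candidate step refits the disparities f by weighted
pool-adjacent-violators isotonic regression of the configuration distances
on the rank order of the observed dissimilarities, with tied observed values
pooled into a common block.  The default start is the classical
metric-scaling configuration (eigendecomposition of the doubly centered
squared-distance matrix); remaining starts are random, and the best final
stress wins.  Steps are only accepted when they lower the stress, so stress
is non-increasing within a run; convergence is declared at relative stress
decrease < 1e-6 (configurable) or 500 iterations.  Aggregate ordinations
default to k = 3 and per-treatment temporal ordinations to k = 2.  Group
summaries report centroids and covariance ellipsoids scaled by the
chi-square quantile at the requested level with k degrees of freedom;
groups smaller than k + 1 are flagged degenerate.

## Hierarchical trend models

The model family for a Gaussian response y (an alpha index, total IgA, or
log-transformed antigen-specific IgA with zeros replaced by 1) is a
polynomial in scaled week x = (week − mid-range)/half-range of degree
d ∈ {0, 1, 2, 3}:

    y = α + Σ_{p=1..d} β_p x^p + ε,   ε ~ N(0, σ²)

where α and each β_p carry one of three structures: global, per-treatment,
or per-treatment with exchangeable per-mouse deviations
(u ~ N(0, σ²_mouse), mice nested in treatments).  Degree 0 has no trend
structure, giving 3 + 3×3×3 = 30 candidate models.  Time is centered and
scaled to [−1, 1] before polynomial expansion to stabilize the cubic fits.

Priors are conjugate and weakly informative: coefficients N(0, 10⁴·var(y)),
variances inverse-gamma(10⁻³, 10⁻³).  The Gibbs sampler draws all
coefficients jointly from their Gaussian full conditional (Cholesky of the
posterior precision), then the residual and mouse-level variances from
inverse-gamma full conditionals, in a fixed scan order; chains start from
overdispersed residual-variance initializations.  The default schedule is 3
chains × 500,000 iterations with 200,000 burn-in and thinning at 500 (600
retained per chain, 1,800 total); a test profile (3 × 20,000/8,000/thin 20,
also 600 per chain) and a smoke profile (2 × 2,000/800/thin 4) are provided
for suites and pipeline runs.  Convergence requires Gelman–Rubin R̂ ≤ 1.1
for every parameter; unconverged fits are excluded from selection.  DIC is
D̄ + pD with pD = D̄ − D(posterior mean), deviance −2 log L under the
Gaussian likelihood; the minimum-DIC converged model wins, ties to the
smaller model.  Credibility bands for the expected response marginalize
mouse effects at their mean of zero rather than conditioning on a reference
mouse.  The sampler's full conditionals are validated against a brute-force
grid posterior on the intercept-only model (total-variation distance
< 0.05), and the 95% bands cover the generating treatment-level curves in
≥ 85% of (treatment, week) cells over 50 synthetic replicates.

## Random forest

CART trees with Gini impurity: at each node, mtry features sampled without
replacement; numeric splits at midpoints of consecutive sorted unique
values; growth to purity (min node size 1, no depth limit); a node whose
sampled features are all constant becomes a leaf.  Forests grow each tree
on an independent bootstrap; out-of-bag votes give per-sample predictions
(plurality, ties broken by a seeded class shuffle), the OOB error and the
true × predicted confusion matrix.  Importance is mean decrease in Gini:
node size × impurity decrease summed over a feature's splits, averaged over
trees.  Feature-count tuning fits `reps` forests per candidate
m = 1..M with mtry = m and picks the minimum median OOB error (ties to
smaller m), with means reported alongside — the median is the selection
criterion, the mean is informational.  The tuned count is interpreted as
mtry (features sampled per split); this is one of two readings of
"number of features" in this workflow and is recorded as an assumption.
Class imbalance is handled by unweighted bootstrap.  The inner loops are
numba-compiled; a scaled-down tuning workflow (M = 30, reps = 20, 200
trees on a 200 × 150 matrix) runs in well under five minutes on one CPU.

## ELISA and association screening

The positivity cutoff is mean(negatives) + 3.365 × sample SD; 3.365 is the
one-sided 99% Student-t quantile at 5 degrees of freedom (n = 6 negatives),
rounded to three decimals.  A prediction-interval construction would carry
an extra sqrt(1 + 1/n) factor (≈ 3.634 at n = 6); the plain 3.365 multiplier
is the assay convention followed here, and the discrepancy is documented
rather than resolved.  Endpoint titers use the monotone-prefix
rule — the largest dilution in the unbroken above-cutoff prefix — which
pins down behavior for non-monotone series.  The standard curve is a
monotone piecewise-linear interpolant of duplicate-averaged OD against
log10 concentration: deterministic, exactly invertible within the
standards' OD span, and flagged outside it; a four-parameter logistic would
be a possible extension, not required for calibrated quantification here.
Quantification averages dilution-corrected inverse-curve estimates over
in-range dilutions.

Spearman screening ranks with average ties and uses the two-sided
t-approximation p-value on n − 2 df (|ρ| = 1 ⇒ p = 0).  Screens run per
treatment, separately for total and antigen-specific IgA so missingness in
one variable does not drop samples from the other, with no multiple-testing
correction and flags at p < 0.1; treatments with fewer than three complete
pairs are skipped with a warning.  At the null, the flag rate calibrates to
0.10 within binomial tolerance.

## Pipeline

`run_all` chains the stages — simulate/load, mock filter, RB-timepoint
harmonization (weeks −1 and 12 dropped for the trend analyses only), alpha
+ 30-model selection per index, CSS → Bray–Curtis → NMDS (aggregate and
per-treatment), phylum bars with the >1% rule, random-forest tuning/fit/
importance for fecal and cecal subsets separately, ELISA quantification and
IgA trend selection, and the Spearman screen over the top-30 important
features plus alpha indices.  Every output carries a header with stage,
seed and parameters; the manifest records SHA-256 checksums, so seeded
reruns can be verified bit-for-bit.  Pipeline defaults use the smoke chain
profile and reduced forest sizes so a full synthetic run takes about a
minute; the full-scale MCMC schedule is a configuration switch away
(`chain_profile="full"`).

## Numerical notes and limitations

- Thresholding, aggregation and prevalence are exact integer/rational
  operations; CSS scale invariance holds to 1e-9.
- The Gibbs sampler's SSR is computed from precomputed cross-products;
  with noiseless data the residual variance posterior collapses toward the
  inverse-gamma rate and coefficient posteriors concentrate at the
  least-squares solution.
- NMDS is a local optimizer: rank-degenerate or tiny configurations can
  stall at nonzero stress; multiple starts mitigate but do not guarantee
  the global optimum.  Stress comparisons across monotone-transformed
  inputs agree to ~1e-3, not exactly.
- The forest's split tie-breaking (first candidate encountered in the
  seeded feature order) and vote tie-breaking (seeded class shuffle) are
  deterministic under the run seed but not canonical; importance scales
  match the node-size-weighted convention, so absolute values are not
  comparable across implementations, only rankings.
- CLI exit codes: 0 success, 2 configuration error, 3 data error.
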