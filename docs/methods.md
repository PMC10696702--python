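# Methods

This note documents the statistical procedures `metabrisk` implements, the
synthetic study generator that exercises them, the defaults and numerical
choices, and what the test suite does and does not establish.

## The analysis chain

### Scaling and QC

Feature retention uses the QC-injection detection fraction: a feature is
kept iff it was detected in at least 80% of QC injections (`min_detect`,
configurable).  Assay precision is the percent relative standard deviation,
100·sd/mean with the n−1 sample SD, over replicate QC injections; 15% is
the conventional LC-MS acceptability bound.  Multivariate analyses run on
log + Pareto-scaled data: missing abundances are imputed as half the
per-feature observed minimum (a common metabolomics convention; the
imputation policy is a documented default, not an inference), natural logs
are taken, and each column is centered and divided by the square root of
its SD.  Pareto scaling leaves column variance equal to the pre-scaling SD
— a compromise between no scaling (intensity-dominated) and unit-variance
scaling (noise-inflating).  The order impute → log → scale is the only
numerically coherent one.  Scaling parameters are fit per study set, since
the sets are modelled separately throughout.  Zero-variance columns are an
error by design: they must be filtered before modelling.

### OPLS-DA, Q², VIP, permutations

The discriminant engine is the classic single-response OPLS sequence.  With
class labels coded ±1 and centered (cases are always the positive class),
each orthogonal component is extracted by computing the predictive weight
w ∝ X'y, splitting the loading of the current score into its w-parallel
and w-orthogonal parts, and deflating the orthogonal part from X; the final
predictive component comes from the deflated matrix.  With one response the
weights are closed-form, so fitting is fully deterministic — no NIPALS
iteration or random initialisation is involved.  `n_orth = 0` degenerates
exactly to one-component PLS-DA (verified against an independent PLS1
oracle).  Two-class discrimination uses one predictive component, the
standard choice; the orthogonal count is a parameter (default 1), with
`choose_n_orth` available to pick it by maximising Q² up to a cap of 5.

Model quality: R²X is the cumulative fraction of X sum-of-squares captured
by all extracted components (deflation conserves variance exactly, which
the tests assert to 1e-8); R²Y is the fraction of class variance explained
by the predictive component; Q² = 1 − PRESS/SS over stratified
cross-validation folds (default 7, deterministic round-robin assignment
within class), refitting the model from scratch per training fold.  X is
assumed scaled once upfront; fold-wise rescaling is deliberately omitted
because the scaling is part of the fixed preprocessing contract, not of the
model.

VIP over the predictive component is √p·|w| with unit-norm weights, so the
squared VIPs always sum to the number of features; VIP > 1 ("above average
influence") is the selection threshold.  Significance uses label
permutations: the statistic (R²Y by default in the pipeline; Q² available)
is recomputed under uniformly permuted labels and the exceedance count k of
n is reported both as the raw ratio "k/n" — the convention in which a fully
separated model reads "0/100 (p < 0.01)" — and as the add-one estimate
(k+1)/(n+1), which is the value used for inference because the raw ratio is
biased at zero.

### Replicated selection and enrichment

A metabolite is selected when VIP > 1.0 in both independent sets; fold
change is the case/control ratio of mean raw abundance per set.  The
replication filter is intentionally *not* multiplicity-corrected — it
mirrors the practice of intersecting per-set VIP exceedances — so at large
feature counts a handful of chance double-exceedances accompany the true
positives (see "what the tests show" below).  Super-class enrichment is
one-sided hypergeometric over-representation of each chemical super-class
within the selection, against the background of all identified metabolites
(not all detected features), BH-adjusted across classes.  Over-representation
analysis was chosen over quantitative set enrichment because the input is a
hard-thresholded list; this is an interpretation and is flagged as such.

### Gaussian graphical model

Partial correlations come from the precision matrix: pcor_ij =
−Ω_ij/√(Ω_ii·Ω_jj) with Ω the inverse of the sample covariance.  With
p/n > 0.2 the covariance is first regularised by Ledoit-Wolf analytic
shrinkage toward the scaled identity ("auto" mode); an explicit shrinkage
intensity in [0,1) may be given instead, and shrinkage 0 demands a
well-conditioned covariance and raises otherwise.  Edge inference uses the
Fisher z-transform with variance 1/(n − (p−2) − 3) — the conditioning set
has p−2 variables — two-sided normal p-values and BH adjustment over all
pairs; edges are kept at q < 0.05.

Node importance is unnormalised betweenness centrality (shortest-path
counts) on the significant-edge graph, computed via networkx and verified
against exhaustive path enumeration.  The "0.5 cutoff" on centrality is
interpreted as a *display* threshold — nodes below it are flagged, never
removed — because a cutoff applied to edges would change the topology; the
edge-filtering reading is still available through `edge_cutoff`.  Per-node
group effects are z-scores: the Welch t statistic of log abundance mapped
through its t distribution to a standard-normal quantile (so magnitudes are
comparable across unequal-variance metabolites), BH-adjusted across nodes,
significant at q < 0.05.  A standardized-mean-difference definition would
be a reasonable alternative; Welch-z was chosen because it propagates
sample size into the score, which the downstream FDR thresholding needs.

### Genetics

SNP QC runs in a fixed, documented order — SNP missingness > 5%, sample
missingness > 5%, MAF < 0.05, exact Hardy-Weinberg p < 1e-6 — because the
result can depend on the order; per-filter removal counts are logged.  The
HWE test is the exact conditional-on-allele-counts test (PLINK convention),
summing the probabilities of all heterozygote configurations no more likely
than the observed one; it is verified against direct enumeration.  GWAS is
a per-SNP additive logistic regression of case status on allele count and
age, fitted by IRLS, with Wald p-values; separation is flagged and the
p-value withheld.  Risk SNPs are those below the selection threshold
(5×10⁻⁵ default; the threshold is the operative rule).  The GRS weight is
the GWAS log-odds, the risk allele is the allele with positive log-odds
(so weights are positive), and missing genotypes contribute their expected
count 2·f_risk.  GRS grouping is a median split with ties to "low".  Both
the weight definition and the split point are documented defaults for
underdetermined conventions.

### Prediction

Prediction models are maximum-likelihood logistic fits on the significant
network metabolites (log abundances), optionally plus the GRS.  The
reported AUC is the apparent (in-sample) AUC, reproducing the conventional
biomarker-study procedure; an optional stratified k-fold cross-validated
AUC is provided (off by default) because apparent AUC is optimistic.  The
ROC is built over all score thresholds with tied scores collapsed into
single steps, and the trapezoid AUC is algebraically identical to the
Mann-Whitney concordance probability (asserted to 1e-12).  The 95% CI is
DeLong's structural-components normal interval, truncated to [0,1]; when
the DeLong variance degenerates (perfect separation), a seeded stratified
bootstrap percentile interval (2000 resamples) is used — note that with a
clear margin the bootstrap interval is itself degenerate at 1.  The
smoking screen is a single multivariable logistic model of the binary
covariate on all network metabolites jointly, reporting per-feature odds
ratios and Wald p-values.

## The synthetic study generator

The generator emulates a two-set nested case-control serum metabolomics
study with a cohort-trained genetic risk score.  Defaults are the study
conditions: sets of 35+35 and 31+31; 2610 detected features of which 250
are "identified" (annotated with an identifier, formula and one of eight
chemical super-classes); a 23-metabolite network block among the identified
features; 5 biomarkers inside the block; 92 risk SNPs among 500 genotyped;
and a genotyped pool of 2000 additional subjects.

* **Abundances are log-normal.**  The latent scale is Gaussian, so the
  pipeline's log transform restores exactly the distributional assumption
  of the graphical model.  The network block's latent covariance is the
  inverse of a planted sparse precision matrix (edge probability
  `precision_matrix_density` = 0.08, implied |partial correlation|
  `pcor_strength` = 0.4, unit diagonal inflated only if positive
  definiteness requires it); all other features are independent noise.
* **Cases are shifted by `effect_size` (default 1.5) latent SDs on the
  biomarker features, in both sets.**  The shift applies to biomarkers
  only: correlated network neighbours share fluctuations, not the group
  difference.
* **Disease is genetic.**  Case status is Bernoulli under a logistic model
  whose linear predictor is the risk-allele count weighted by a common
  per-SNP log-odds (default 0.25), centered so the sampling frame is
  case-enriched; study subjects are then drawn to hit the exact group
  sizes, and the remainder forms the GWAS pool — mirroring a risk score
  trained on a full cohort and applied to the nested sets.  This makes GRS
  recovery testable: the GRS computed from the planted weights correlates
  > 0.99 with the generative linear predictor.
* **QC structure.**  Identified features are detected in QC injections
  with probability 0.995, noise features with 0.5 (over 14 injections), so
  the 80% filter removes roughly half the noise floor and essentially no
  identified metabolites.  Seven replicate QC injections with σ_log = 0.1
  give a median %RSD near 10%.
* Ages are N(52, 8) clipped to 35–69 with cases ~2 years older (so
  matching and age adjustment have something to do); blood-draw dates are
  uniform over eight years.  A single seed expands into per-stage
  substreams; identical config + seed reproduces identical tables byte for
  byte.

What the generator does *not* emulate: raw spectra, retention-time drift,
batch effects, correlated noise among unidentified features, linkage
disequilibrium between SNPs, population structure, or any real biochemical
pathway structure.  Passing recovery tests therefore demonstrates the
statistical machinery is correct and calibrated under its stated model —
not that the pipeline is robust to the full messiness of real LC-MS or
genotyping data.

## Numerical choices and edge cases

* Label encoding: "case" is always the positive class; otherwise the
  lexicographically larger label is positive.
* Mann-Whitney: exact enumeration-equivalent p for tie-free samples with
  min(n₁,n₂) ≤ 8, normal approximation with tie correction otherwise.
  Shapiro-Wilk at α = 0.05 triggers the skewness handling (t → t-on-log →
  Mann-Whitney).
* Propensity matching is greedy nearest-neighbour without replacement in
  descending case-propensity order, no caliper by default (a caliper is an
  option); greedy was chosen over optimal matching as the documented
  default for an underdetermined convention.
* Degenerate inputs raise informative errors rather than propagating NaN:
  constant features in scaling/OPLS-DA, single-class labels, empty QC
  survivors, all-SNPs-removed QC, singular covariance at shrinkage 0,
  insufficient Fisher-z degrees of freedom.
* Permutation p-values use (k+1)/(n+1) for any decision; the raw k/n is
  reporting only.

## Known limitations and honest caveats

* **Apparent AUC is optimistic.**  The default reproduces the common
  in-sample procedure; at the default planted effect (1.5 SD on five
  biomarkers) the panel models saturate at AUC ≈ 1.0 and the
  panel ≥ reduced-panel ≥ ordering holds as ties.  Cross-validated AUC is
  one flag away.
* **The replication filter is not FDR-controlled.**  At the full
  2610-feature scale, a few to ~a dozen noise features pass VIP > 1 in
  both sets by chance alongside the five planted biomarkers; at a few
  hundred features the chance count is ≤ 2.  This is the documented
  behavior of the intersect-the-exceedances rule, not a defect.
* **Node-flag recovery is FDR-bounded, not exact.**  With 17 true effects
  among 23 nodes, the BH step-up threshold admits one of the six null
  nodes in roughly a fifth of replicates; tests therefore assert full
  recovery of the planted nodes with at most one false flag, which is the
  guarantee BH actually makes.
* **Marginal GWAS betas attenuate under dense genetic architectures.**
  Logistic regression is non-collapsible: with ~92 simultaneous risk SNPs
  the omitted-variable variance shrinks each marginal per-SNP estimate by
  roughly half, so generative log-odds are only recovered (±0.25 at
  n ≈ 500) under sparse architectures; recovery tests use 3 risk SNPs.
  The GRS itself is insensitive to this (weights are applied to the same
  marginal scale they were estimated on).
* **DeLong intervals undercover slightly** (long-run coverage ≈ 0.94 at
  n = 100 + 100), a known property of Wald-type intervals on the AUC; the
  coverage test allows for it.
* Test and acceptance simulations use reduced replicate counts and, where
  the property does not depend on dimensionality, reduced feature counts
  (e.g. 300 features instead of 2610); the problem sizes are stated in
  each test.
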