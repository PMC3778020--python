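# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the design decisions behind `envqtl`.

## 1. Mixed-model association scans

Growth rates (and, where requested, expression levels) are tested for
association with each biallelic marker under the two-variance-component
model y = Xβ + u + e with u ~ N(0, σ²_g K) and e ~ N(0, σ²_e I). The kinship
K is identity-by-state allele sharing — entry (i, j) is the fraction of
markers at which segregants i and j carry the same parental allele — which
is the natural relatedness measure for a biparental haploid cross (an
`identity` option turns the correction off). K receives a ridge of 1e-8
before its eigendecomposition; a negative eigenvalue beyond tolerance raises
a diagnostic error.

Variance components are estimated by REML on the variance ratio
δ = σ²_e/σ²_g: after rotating by the eigenvectors of K the likelihood is a
one-dimensional function of δ, maximized by Brent's bounded search on
log δ ∈ [−10, 10] (xatol 1e-6). Solutions within 0.1 of a bound are flagged
as boundary fits — with an identity kinship the split σ²_g vs σ²_e is
unidentifiable and only their sum is meaningful, which the flag records.
A zero-variance trait short-circuits to σ²_g = σ²_e = 0 and p = 1 for all
markers.

Marker tests reuse the null-model δ̂ for every marker (the standard
two-stage approximation; `exact_emma=True` re-optimizes δ per marker).
Covariates are partialled out of trait and genotype under the GLS weights,
and the per-marker noise scale is re-estimated from the marker's own
residuals, so the statistic is exactly t-distributed with
n − rank(design) df under normality; with identity kinship the scan
reproduces OLS p-values to machine precision. Monomorphic markers return
β = 0, p = 1, and a flag. Tests are two-sided throughout. Missing trait
entries (the checkered design) are dropped per trait with the kinship
subset accordingly.

## 2. False-discovery control

`storey_qvalues` estimates π₀ on the λ-grid {0, 0.05, …, 0.95} with a
least-squares cubic fit evaluated at the grid maximum (a deterministic
cubic smoother), clipped to (1/m, 1], then applies the step-up transform
q(p₍ᵢ₎) = min₍ⱼ≥ᵢ₎ π₀ m p₍ⱼ₎/j. Forcing π₀ = 1 reproduces
Benjamini–Hochberg adjusted p-values exactly, operation for operation.

## 3. QTL regions and the growth genetic model

Markers with q below the FDR threshold (default 0.05) are grouped greedily
around their best peaks within a 50 kb window; ties break to the smaller p,
then the leftmost position. Per-environment regions are merged across
environments by peak proximity to form the candidate-locus pool.

The multi-environment growth genetic model stacks growth over
(segregant, environment) pairs and selects, by forward–backward search,
terms from {marker main effect, marker × environment interaction} over the
candidate peaks, minimizing BIC (AIC available); environment intercepts are
always included, and an interaction may enter without its main effect —
required for loci whose allele helps growth in one environment and hurts it
in another. BIC uses the Gaussian profile likelihood with the noise
variance counted as a parameter. The candidate ordering (chromosome,
position, environment) fixes tie-breaking, making selection independent of
input order. BIC's false-inclusion probability per candidate is roughly
P(χ²₁ > log n) (≈1.5% at n ≈ 400), which sets the expected null-selection
behaviour tested in the suite.

## 4. Persistent vs environment-dependent decomposition

A gene's expression at a locus is decomposed across environments with three
available interaction codings:

- `sum` (joint fit, sum-to-zero contrasts): β_shared is the across-
  environment mean effect and each γ_e a deviation; the β_shared test is
  exactly calibrated (uniform p under the global null).
- `reference`: deviations relative to the first environment.
- `single` (one deviating environment at a time): E separate fits
  t ~ env intercepts + β_shared·s + γ_e·(s × 1{env = e}); the persistent
  evidence is the *least favourable* shared test over the E fits.

Classification uses `single`. The reason is structural: under `sum` (or any
single joint fit), an effect confined to one of E environments contributes
1/E of itself to the shared component, so strong environment-dependent
genes would be labelled "both". Under `single`, the fit that lets the
gene's active environment deviate drives the shared estimate to zero, and
the max-p rule makes "persistent" mean "a common effect remains no matter
which single environment is allowed to deviate". The calibrated `sum`
coding remains the default for effect-size reporting and for the
persistent/dependent candidate rankings.

Labels come from two family-pooled q-value sets at FDR 0.05: the shared
p-values pooled across genes, and one dependent p-value per gene — the
Bonferroni-corrected minimum over its environment interactions. Pooling
every gene × environment p-value into a single family was rejected: genes
with several true interactions multiply the discovery count, drag the
effective threshold up, and mislabel a sizeable fraction of purely
persistent genes. Both families use the conservative π₀ = 1 variant; at
family sizes of a few hundred with ≥50% signal the π₀ smoother is too
unstable for reproducible labels (estimates as low as 0.17 when the truth
is 0.5 were observed), while BH keeps the same step-up machinery.

An optional kinship correction for the stacked checkered samples expands
the segregant kinship block-diagonally per environment (separate cultures
are conditionally independent given genotype); its eigendecomposition is
shared across genes, with only δ re-fitted per gene.

`downsample_for_power` draws ⌈mean per-environment sample count⌉ rows from
the stack, for comparing persistent vs dependent detection at matched
sample size.

## 5. Bayesian-network mediation scoring

See the README for the two models. Numerical specifics: both sub-models are
ordinary least squares; the joint log-likelihood is the sum of the two
Gaussian profile log-likelihoods −(n/2)(log(2π·RSS/n) + 1); parameter
counts include every regression coefficient plus the two noise variances,
so Model 1 exceeds Model 0 by exactly one parameter under the default
coding. n is the number of stacked profiled samples for the gene, shared by
both models. The posterior is computed as expit((BIC₀ − BIC₁)/2), which is
overflow-safe for any BIC difference. Expression is standardized to zero
mean and unit variance within each environment before fitting (config
switch), making γ comparable across genes; the posterior itself is
invariant to affine changes of growth or expression. The direction sign is
the expression–growth correlation within the tested environment. A
constant-expression gene cannot support Model 1 and is flagged with
posterior 0. `partial=True` keeps the tested term's direct genotype effect
in Model 1's growth sub-model (partial instead of full mediation);
full mediation is the default. Expression enters the growth sub-model only
through the tested environment's interaction, not as a main effect in
other environments.

The single-environment variant restricts both models to the tested
environment's samples, collapsing the persistent sub-model to a
single-environment genotype effect; with one environment in the data it
coincides with the multi-environment score exactly.

Ranking is by descending posterior with gene-id tie-breaks; the per-QTL
evaluation uses the top 100 candidates, and the cross-strategy comparison
pools (gene, term) pairs over all growth-model interaction terms by
confidence before reading the curve at 100 predictions, mirroring an
evaluation across all growth QTLs.

## 6. Deletion-assay fitness and validation

The selection coefficient ŝ of a deletion strain is the least-squares slope
of log2 barcode abundance on generation count (replicates as independent
observations; assayed generations 0 and 5, triplicate). Significance uses
the empirical-Bayes moderated t: the prior (d₀, s₀²) is fitted by matching
the mean and spread of log sample variances to the scaled-F/log-chi-square
moments (trigamma inversion by Newton), the posterior variance is
(d₀s₀² + d_g s²_g)/(d₀ + d_g), and the moderated t is referred to a t with
d₀ + d_g df. d₀ = 0 recovers the ordinary t; d₀ = ∞ pools the variance
completely. Calls at |ŝ| > 0.05 and q < 0.05 are labelled beneficial or
detrimental.

A ranked candidate validates when its deletion call is significant *and*
directionally consistent: positive expression–growth correlation predicts
a detrimental deletion, and vice versa (an `ignore_direction` switch
disables the direction requirement). The random-background rate is
(number of significant calls)/(2 × assayed genes) per environment — the
factor 2 because a random candidate carries a random direction — so random
rankings give fold enrichment ≈ 1 by construction. Jackknife errors over
growth QTLs use sd = √((m−1)/m · Σ(θ̂₍ᵢ₎ − θ̄₍·₎)²) on leave-one-out means.

## 7. The synthetic cross

The generator emulates a haploid two-parent cross: each chromosome is an
independent Markov chain of parental origins with a constant per-interval
flip probability (default 0.02; a linkage structure stand-in, not a genetic
map), 0/1 alleles at Mendelian 50/50 frequency, and evenly spaced 1-based
marker positions. Expression is generated directly on a log-like additive
scale (no array-intensity model). Causal order is enforced by construction:
genotype-driven expression first, then growth, then consequence-gene
expression, so permuting consequence noise can never alter growth.

The default benchmark (`benchmark_scenario`) uses 200 segregants,
500 markers on 5 chromosomes, 500 genes, 5 environments with 35 strains
profiled per environment, and 6 growth QTLs whose growth effects flow
entirely through their mediators; one QTL is active with opposite signs in
two environments, the others in one environment each. Per QTL: 5 mediators
(persistent genotype→expression effect 0.8, expression→growth effect 0.3
per mediator in the active environments), 20 side-effect genes (persistent
effect 0.8, no growth link), 20 environment-dependent genes (effect 1.2 in
one environment), plus 20 consequence genes per QTL responding to realized
growth (coefficient 0.5 in every environment); expression noise sd 0.6,
growth residual sd 0.5. These scales correspond to a strong trans-acting
hotspot — roughly 30% of a target gene's per-environment expression
variance explained by the locus — and keep the full pipeline at well under
a minute per seed. Deletion truth gives each mediator |s| = 0.15 in its
active environments, signed opposite to its expression→growth effect, and
sprinkles background fitness effects (|s| = 0.15, random sign) over 25% of
all gene × environment pairs, matching the observation that a fifth to a
third of non-essential deletions are consequential in a given condition;
assay noise sd is 0.05 per replicate observation. Ground-truth role labels
are written to a JSON sidecar that the analysis pipeline never reads — only
evaluation harnesses do.

What the generator does **not** emulate: array probe-level noise and
normalization artefacts, local (cis) eQTL structure, correlated expression
modules, polygenic growth background, diploid genetics, and growth-curve
(OD) measurement error. Passing tests therefore demonstrate correctness and
calibration of the statistical machinery and the qualitative superiority of
the multi-environment network under the modelled causal structure — not
performance on real tiling-array data.

## 8. Reproducibility and scale choices

Every stochastic routine takes an explicit seed; pipeline stages derive
sub-seeds deterministically from the master seed, and a fixed seed yields
byte-identical reports. The test-bench sizes (10 seeds for the benchmark
suite, 3 for the acceptance script; 10,000 tests for scan calibration;
4,000 genes for selection-coefficient recovery) were chosen so the whole
verification runs in a few minutes on one CPU while keeping Monte-Carlo
error comfortably inside the asserted margins.

## 9. Known limitations

- The constant-recombination chromosome model produces uniform linkage;
  recombination hotspots or map expansion would change region-calling
  granularity.
- The stepwise growth model restricts candidates to region peak markers;
  fine-mapping within regions and epistasis are out of scope.
- The mediation network scores one gene at a time; multi-gene causal paths
  and partial-mediation mixtures are not searched.
- The moderated-t prior assumes exchangeable variances across genes; strong
  mean–variance trends would call for a trended prior.
- No kinship random effect inside the Bayesian network itself; the growth
  covariates absorb the major loci but not a polygenic background.
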