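# Methods

This note records the models metgxe implements, the numerical choices behind
them, what the synthetic-data generator does and does not emulate, and the
design decisions that were genuinely open.

## Data model

A *trial environment* is a year-location (YL): one testing site in one
season. Plot records carry hybrid, year, location, region (north/south),
replicate, calendar dates, yield (ton/ha at 15.5% grain moisture),
days-to-anthesis, days-to-silking, and the anthesis–silking interval
ASI = silking − anthesis. Environmental covariates (ECs) are defined at the
YL level: 21 daily covariate types from a crop-model-style simulation,
averaged within 9 phenological stages → 189 ECs.

## Curation rules

Phenotypes are filtered in a fixed order — (1) any missing
planting/harvesting/anthesis/silking date; (2) ASI strictly greater than
15 days; (3) within each YL, yield outside
[Q25 − 2.5·IQR, Q75 + 2.5·IQR] — so that outlier quantiles are computed on
date-complete, ASI-sane records. Quantiles use the linear-interpolation
definition (numpy's default); this matters because the quantile dialect
moves the fences. YLs with fewer than 4 records skip the outlier rule
(logged). Each dropped record logs exactly the first rule that fired.

SNPs keep minor allele frequency strictly above 3% and missing rate
strictly below 10%, then are mean-imputed. LD pruning links SNPs with
squared dosage correlation above 0.85 within 1 Mbp on the same chromosome;
connected components form LD sets and the retained representative is the
member with the highest mean R² to the other members (ties to the lowest bp
position). "Most representative" is named but not defined in the
literature this follows; mean-R² centrality is the natural reading and is
pinned here for reproducibility. GDD accumulates
max(0, (min(tmax, cap) + max(tmin, base))/2 − base) with base 10 °C and cap
30 °C — the maize convention, configurable because sources rarely state it.

## Kernels

G = XX′/tr(XX′) from internally centered dosages; Ω = WW′/tr(WW′) from
internally centered ECs scaled by the population (n) standard deviation —
the scaling dialect is pinned because it changes Ω. Zero-variance EC
columns are dropped, not imputed. Both kernels have trace exactly 1, so
variance components multiply kernels with mean diagonal 1/n; the model code
rescales kernels to record-level mean diagonal 1 so that variance
components read directly as phenotypic shares.

The interaction kernel K = (Z₁GZ₁′)∘(Z₂ΩZ₂′) is held in factored form.
Writing G = Σᵢ λᵢuᵢuᵢ′ and Ω = Σⱼ δⱼvⱼvⱼ′, the vectors
(Z₁uᵢ√λᵢ)∘(Z₂vⱼ√δⱼ) over retained eigenpairs (relative eigenvalue
> 1e−10) satisfy K = CC′ exactly (a Hadamard product of Gram matrices is
the Gram of the column-wise Khatri–Rao product), so an SVD of C yields
orthonormal B and weights D with K = B·diag(D)·B′ without ever
materializing K. The oracle suite checks the factorization against the
explicitly formed K to < 1e−8 relative Frobenius error on random instances.

EC principal components are rotated toward geography by scanning clockwise
angles on a 0.5° grid over [0°, 360°) and maximizing
corr(rot₁, longitude) + corr(rot₂, latitude); the grid is used rather than
a closed form because the objective is a sum of two correlations with no
simple stationary-point structure, and the printed convention is whole
degrees clockwise.

## Environmental indices

Soil-layer covariates aggregate across the 10 × 200 mm layers with
crop-accessibility weights (weighted mean; all-zero-weight days yield 0 and
are flagged). Stage intervals are half-open [start, next start), the last
stage closing at harvest, avoiding double counting of boundary days.

Daily water demand = Eo × green-cover fraction × crop factor 2; daily
SDR = supply/demand clipped at 4; zero-demand days (pre-emergence cover 0)
map to the clip value rather than NaN so they cannot poison the window
mean — the cap is the index's own saturation value. SDR is the mean daily
value over the reproductive window (flag-leaf appearance through end of
grain fill; stages 6–8 in the generator). HI30 counts window days with
tmax strictly above 30 °C. Stress flags: drought SDR ≤ 0.54 (inclusive),
heat HI30 > 36 (strict). Whether supply should be accessibility-weighted
before or after layer aggregation is ambiguous in the sources; this
implementation aggregates first and takes the ratio of aggregates.

The per-EC ANOVA uses sequential sums of squares — region, then location
within region, residual = year-location — as proportions of total SS
(summing to 1 within 1e−10); the stratified variant partitions into
location + year-location within each region. With real coordinates the
north/south split is the 37°N latitude proxy for the hardiness-zone
boundary.

## ML fits and tests

Models with crossed iid random effects are fitted by maximum likelihood
(not REML) so that full-vs-null LRTs are valid. The fixed effects and the
error variance are profiled analytically; the optimizer works on the log
variance ratios λₜ = σ²ₜ/σ²ε (L-BFGS-B, bounds e⁻¹⁸–e⁸). All linear
algebra runs on cached cross-products through the Woodbury identity, and
the largest random term (hybrid×location) — whose own Gram block is
diagonal — is eliminated by a Schur complement, so one likelihood
evaluation costs O(q₀³ + q₀²q₁) with q₀ the levels of the remaining terms.
A dense-covariance likelihood evaluation serves as the test oracle.
Variance-component SEs come from a finite-difference observed information
in log parameters (delta method); fixed-effect SEs from σ̂²(X′V⁻¹X)⁻¹.

The association LRT is the upper tail of χ²₁ at Λ = 2(ℓ_full − ℓ_null) with
no boundary ½-mixture correction — a deliberate fidelity choice to the
stated test (the tested EC coefficient is not on a boundary, so the plain
χ²₁ reference is also the asymptotically correct one). Negative numerical
Λ is clipped to 0 with a warning. Because the EC is a YL-level covariate,
the χ²₁ asymptotics are governed by the number of YLs, not records: at 12
YLs the measured type-I rate is ~0.11, at 50 YLs 0.056. The calibration
suite therefore uses a 50-YL layout (15 hybrids × 10 years × 5 locations
× 2 replicates).

An identically-zero EC column is treated as absent (Λ = 0, p = 1); a
non-zero constant column is collinear with the intercept and raises.

M_eff, the effective number of independent tests, defaults to the Li & Ji
eigenvalue estimator, with Gao's 99.5%-cumulative-variance rule as an
alternative (`method="gao"`); Gao's rule is exactly invariant to
duplicating columns, Li & Ji only approximately. The Bonferroni threshold
is α/M_eff. Group enrichment is the one-sided hypergeometric upper tail,
computed only for groups with at least two covariates.

## The reaction-norm Gibbs sampler

Each random term is reparameterized on kernel eigen-features: for a term
with record-level covariance σ²·Q, Q = Φ Φ′, the effect is Φα with
α ~ N(0, σ²I), turning the model into grouped ridge regression. Records
are collapsed to (hybrid, YL) cells with √m-weighted sufficient statistics
(cell means plus within-cell error SS), which is exact for this model.

Two computational paths give the same posterior (tested to |Δ| < 0.01 per
component at a shared seed):

* **Crossed fast path** — when every hybrid appears in every YL with a
  constant replicate count, the cell matrix is a Kronecker design and all
  block projections are U′RV-type products of H×r and L×r matrices; an
  iteration costs milliseconds even at 300 hybrids × 30 YLs.
* **General path** — arbitrary designs build per-term feature matrices from
  the full-design kernels, orthogonalize each by SVD, and update
  coefficients element-wise; the interaction basis may be truncated to the
  top eigenvalue products (`max_interaction_rank`) to bound cost; the
  truncation threshold is reported and only used in cross-validation
  (rank 400 by default there).

Priors are scaled-inverse-χ² with 5 df and scales set so each prior mode
equals an equal share of the phenotypic variance; defaults 15,000
iterations / 5,000 burn-in / thin 5 (tests and CV use shorter chains —
2,000–6,000 iterations — which this conjugate, fast-mixing sampler does not
need more of for posterior means). Chains are seeded; diagnostics (saved
samples, posterior SDs) ride along in the fit result.

Prediction for levels absent from training uses the kernel extension
E[u_test | u_train] = K[test,train] K[train,train]⁺ u_train, which the
feature representation realizes implicitly in the general path and which is
applied explicitly after crossed-path fits.

The two-trait variant places an unstructured 2×2 covariance on the SNP
term, the EC term, and the error (inverse-Wishart updates; weakly
informative scale 0.1× an equal variance share, because a strong prior
scale visibly pulls correlations toward zero). The SNP×EC term is omitted
by default — at desk scale its bivariate covariance is weakly identified —
and can be enabled with a flag.

## Phenotypic correlations

Across-YL: pooled Pearson. Within-YL: per-YL Pearson correlations combined
with inverse-squared-SE weights, SE(rᵢ) = √((1−rᵢ²)/(nᵢ−2)); YLs with fewer
than 3 records are excluded and listed. A record-count weighting is
available behind a flag (the weighted-average dialect is ambiguous in the
sources). Between-YL: Pearson correlation of model-estimated YL means
(μ̂ + Ŷ + L̂ + ŶL from the baseline fit) of the two traits.

## Cross-validation

10F-CV assigns whole hybrids to 10 near-equal folds (deterministic under a
seed; assignment serializable); LYO-CV holds out one year at a time.
Within each training split, EC standardization for Ω and any PC scores are
recomputed from training rows only (a full-data Ω option exists behind a
flag and is marked in the audit log); genotypes of test hybrids are inputs,
so G may use all hybrids. An audit log records the rows every
preprocessing step touched, making leakage a testable property. Random
effects of unseen levels predict at their prior mean 0. Accuracy is the
within-YL Pearson correlation of predictions and observations, aggregated
with inverse-squared-SE weights.

A structural note on hybrid-holdout CV with a no-marker model: pooled
predictions differ across folds only through the noise each left-out fold
removes from the training means, which drives the within-YL correlation to
approximately −1/√(test hybrids per YL per fold) — near zero but slightly
negative, and closer to zero the more hybrids the network tests. The CV
benchmark uses 600 hybrids × 12 YLs so this desk-scale artifact sits in the
band observed at network scale.

## The synthetic-data generator

The generator emulates the statistical structure the analyses assume:
tester-group population structure via Balding–Nichols group allele
frequencies (configurable differentiation, default F = 0.25, 3 groups —
enough for k-means on the top-2 genomic PCs to recover groups at ≥90%);
north/south location networks split at the latitude boundary; 150-day
seasons with 9 jittered contiguous stages; EC columns built from
region + location-within-region + YL effects whose realized sequential-SS
shares equal the configured partition (default 0.2/0.2/0.6, i.e. ~60% of
EC variability in year and year-location terms); and daily EC-type series
whose stage means reproduce the EC matrix exactly. Missing genotypes are
missing completely at random, matching the mean-imputation downstream.

Phenotypes follow the reaction-norm model with the variance *parameters*
pinned: each component's coefficient vector in the (mean-diagonal-1) kernel
eigenbasis is rescaled so its mean square equals the configured fraction.
This makes the generator's truth the same estimand the fitter reports, so
recovery tests measure estimator error, not draw noise; the realized
phenotypic variance then equals the fraction sum only in expectation
(fluctuating with the few effective degrees of freedom of the EC kernel).
Default fractions follow a published grain-yield partition (EC 0.485,
SNP 0.067, SNP×EC 0.091, error 0.380; their printed sum is 1.023 and the
config validator allows that rounding slack). Flowering traits are
generated with hybrid and environment components and ASI ≡ silking −
anthesis by construction.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: weather physics and crop-model state
dynamics (daily series are statistical stand-ins), linkage-disequilibrium
decay beyond block-correlated SNPs, within-trial spatial field trends and
block effects (the analysis models omit them too), genotype-missingness
informativeness, and selection structure among tested hybrids.

## Problem sizes

Tests and the acceptance script run at desk scale, chosen as the package's
defaults: kernel oracles on ≤100-record instances; reaction-norm recovery
at 300 hybrids × 30 YLs × 2 replicates (18,000 records, fast path); LRT
calibration over 500 null simulations at 50 YLs; CV benchmarking at 600
hybrids × 12 YLs with 10 folds and 4 leave-year-out splits. All random
number streams are seeded.

## Known limitations

* ML variance components at very few levels (e.g. 3–4 locations) carry the
  usual small-sample downward bias and large spread; the recovery suites
  quantify this by averaging over replicates.
* The general-path sampler scales as O(cells × features) per iteration;
  designs with many thousands of partially crossed cells should truncate
  the interaction basis or use the crossed path on a crossed core.
* The two-trait model reports correlations for SNP, EC, and error terms
  only (no bivariate SNP×EC by default).
* VCF input is a minimal bi-allelic dosage reader (phasing ignored, `./.`
  missing), not a full VCF-spec implementation.
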