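# Methods

This note documents the statistical models behind covarkit, the defaults
and why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical edge-case policies.

## Size standardization

Each trait is fit by ordinary least squares against the natural log of
standard length (SL) and replaced by its residuals. The log base is fixed at
e: changing the base rescales the slope but leaves residuals — and hence
every covariance — unchanged. The default scope is *pooled* (one allometric
model per trait across all individuals entering an analysis), because a
common baseline is required when group means are later compared; a
*per-group* scope is available when groups are known to differ in allometry.
Rows with a missing trait are excluded from that trait's fit and from any P
matrix that uses the trait (complete-case per matrix); missing values are
never imputed, since imputation would manufacture covariance.

## P matrices and the bootstrap engine

The covariance denominator defaults to n − 1 (`ddof=1`). Because the
standardization already removed one slope and intercept per trait, a
stricter n − 2 convention is available; the two differ by a scalar factor
that cancels in every correlation-based statistic, so the choice only
matters for respondability-type magnitudes.

Confidence intervals are percentile bootstrap over individuals resampled
with replacement *within* a group (populations pooled into groups are not
treated as strata by default; stratified resampling is a straightforward
extension but was not needed for any test here). Between-group comparisons
resample each group independently and form the replicate-paired difference;
a difference is significant iff its percentile CI excludes zero. The
default is 1000 replicates — 100-replicate runs (a common choice in the
literature) give visibly coarse 95% interval endpoints (the 2.5th percentile
of 100 values interpolates between the 2nd and 3rd order statistic). BCa
intervals are not implemented.

Replicates whose resampled matrix breaks a statistic's preconditions (e.g.
a singular matrix under autonomy) are dropped and counted; more than 20%
failures aborts the run, since the percentile interval is then meaningless.

All resampling is driven by `numpy.random.Generator` seeded from
`SeedSequence` substreams: the skewer ensemble, each group's resampling
stream, and each pipeline stage get separate spawned children of the root
seed, so runs are bit-reproducible and adding a stage never perturbs the
draws of another.

## Random-skewers statistics

Skewers are drawn as standard Gaussian vectors normalized to unit length
(uniform on the sphere — this construction is what makes the
identity-matrix values exactly 1). The default ensemble is 10 000 skewers:
point estimates quoted to two significant figures need the Monte Carlo
error of each statistic below ~1%, which 10 000 achieves for 18-trait
matrices (verified by a doubling test). One fixed ensemble is shared across
bootstrap replicates so that replicate spread reflects sampling error only.

Definitions, for unit β and response r = Pβ:

- respondability: mean ‖r‖ (scales linearly in P);
- flexibility: mean βᵀr/‖r‖; skewers with numerically zero response
  (β in the null space of a rank-deficient P) are skipped and counted, with
  a warning above 10% skipped;
- autonomy: mean of (βᵀP⁻¹β)⁻¹ / (βᵀPβ). Requires invertibility: if the
  condition number exceeds 1e12 the call fails, unless an explicit ridge is
  passed, in which case ε·mean(diag P) is added to the diagonal ("bending")
  and should be reported alongside the estimate;
- constraints: mean |cos(r, v₁)| with v₁ the leading eigenvector. The
  absolute value is deliberate: an eigenvector's sign is arbitrary, so a
  signed mean would be 0 in expectation and meaningless. Tied leading
  eigenvalues (λ₁ − λ₂ ≤ 1e-12, relative) are an error since PC1 is then
  undefined.

Respondability, flexibility, autonomy and constraints operate on the
covariance matrix; mean squared correlation and V_rel operate on the derived
correlation matrix, matching each statistic's standard definition.

## Integration and matrix similarity

V_rel = Var(λ)/(d−1) with Var(λ) = Σ(λᵢ−1)²/d over correlation-matrix
eigenvalues. The identity tr(C²) − d = 2Σᵢ<ⱼ rᵢⱼ² makes V_rel *exactly* the
mean squared off-diagonal correlation in every dimension; both routes are
implemented and cross-checked in the tests. An optional small-sample
correction rescales out the null expectation 1/(n−1) (the V_rel a finite
sample of independent traits shows on average); it is off by default and
both values can be reported.

`compare_vrel` maps each V_rel to z = atanh(√V_rel) with sampling variance
1/(n−2) and refers the standardized difference to the normal distribution,
two-sided.

PCA similarity is Σᵢⱼ λᵢᴬλⱼᴮ(vᵢᴬ·vⱼᴮ)² normalized by Σᵢ λᵢᴬλᵢᴮ (eigenvalues
descending, clipped at zero). The normalizer is pinned by two requirements —
self-similarity exactly 1 and disjoint-eigenspace pairs exactly 0 — and is
stated here prominently because alternative normalizations exist in the
literature and change absolute values (not orderings).

Covariance-space PCA vectorizes each matrix to its d(d+1)/2 unique entries,
with covariances counted **once**; duplicating the off-diagonal entries
would double their weight and change loadings. The PCA is covariance-based
(centered, unscaled), and group contributions per axis are squared-score
shares.

## F2 additive null

Under two alleles per locus, Mendelian segregation, linkage equilibrium and
purely additive effects, the F2 of a cross between lines fixed for
alternative alleles centers on MP = (P₁+P₂)/2. Collapsing a trait's genetic
basis to one effective locus gives the 1:2:1 phenotype distribution over
{P₁, MP, P₂} and variance (P₁−P₂)²/8 — the maximal segregation variance;
with L equal-effect loci the expectation is (P₁−P₂)²/(8L). The
single-locus form is the default null (most conservative against claims of
*excess* variance), with L as an explicit option.

Mean deviations are judged by a percentile-bootstrap interval on each F2
trait mean (a Student-t interval is available); a trait deviates iff the
interval excludes MP. This preserves the decision rule of
posterior-interval approaches while requiring no probabilistic-programming
machinery. No multiple-testing correction is applied by default (each trait
is read on its own interval, as is conventional for this design);
Benjamini–Hochberg can be layered on by the user.

Variance deviations are tested at the cross level by Welch's two-sample t
between the set of observed per-trait variances and the set of expected
variances (hence non-integer df), plus per-trait two-sided chi-square flags
((n−1)s²/σ₀² against chi-square with n−1 df).

**A caveat worth stating:** when the F0 parents are single measured
individuals, measurement/environmental error on the parents propagates into
MP with standard deviation σ_e/√2 — often larger than the standard error of
the F2 mean itself. Deviation flags then test "F2 mean equals the measured
mid-parent", not "equals the genetic mid-parent", and their false-positive
rate relative to the genetic null exceeds α. The calibration tests
therefore use noise-free simulated parents; analyses of real single-parent
crosses should read marginal flags with this in mind.

## Diagnostics

Minimum sample size uses the one-way fixed-effects ANOVA power function
with noncentrality λ = n·η²/(1−η²) (statsmodels' noncentral-F solver seeds
the search; the returned n is then verified to bracket the target exactly:
power(n) ≥ target > power(n−1)). The variance-stabilization curve simulates
the SD of the sample-variance estimator across a grid of n; for normal data
this has the closed form σ²√(2/(n−1)), which the tests verify to 5%. The
stabilization criterion (relative spread below a tolerance) is a parameter,
never a constant — with tolerance 0.33 the curve stabilizes at n = 20.

## Synthetic-data generators

`covariance_from_vrel` uses the equicorrelation family: for
C = (1−r)I + r·11ᵀ the eigenvalues are 1+(d−1)r and 1−r (×(d−1)), so
V_rel = r² exactly in every dimension and the target is hit by r = √target
with no root-finding. Randomization must preserve the correlation-matrix
eigenvalues or the target would drift: the generator therefore uses random
sign flips (conjugation by a ±1 diagonal matrix) and log-normal per-trait
variances, both of which leave V_rel untouched, rather than a dense random
rotation, which would not. The cost of this choice is that the generated
correlation structure is always single-factor-like; tests that need
varied eigenstructure use generic Wishart-style matrices instead.

`simulate_group` composes trait values as mean + slope·ln(SL) + MVN(0, Σ)
with SL log-normal (defaults: ~35 mm median, 15% CV — typical of adult
pupfish-sized specimens; residual trait variances of ~0.01 mm² and group
sizes of 42–85 match a wild morphometric study of this design).

`simulate_f2_cross` codes genotypes −1/0/+1 at unlinked biallelic loci,
parents fixed for alternative alleles, F1 all heterozygous, and each F2
locus an independent sum of two Bernoulli(½) draws (exact 1:2:1). Trait
values add per-locus additive effects (an arbitrary pleiotropy matrix),
dominance on the standard a/d scale (heterozygote value k·a, |k| ≤ 1.5 so
over/underdominance is expressible), optional pairwise additive-by-additive
epistasis terms g_i·g_j·w, and Gaussian environmental noise. Each of the
additive model's assumptions can thus be violated one at a time.

What the generators do **not** emulate: linkage and recombination-distance
structure (loci are unlinked by construction), selection or mortality
during rearing, measurement error with trait-specific magnitudes,
non-Gaussian residual variation, and allometry that differs between groups
unless configured. Passing tests on synthetic data therefore demonstrate
correctness of the estimators and calibration of the inference under the
stated model, not robustness to these real-data complications.

## Problem sizes and defaults used in the shipped checks

Calibration and power simulations run at 6 traits, groups of 200, 200
simulations, and 100 bootstrap replicates per test; parameter-recovery
checks use 10 000 individuals; skewer oracles use 10 000 skewers against
independent brute-force loops. The study-scale demonstration in
`scripts/acceptance.py` uses three groups of 61/85/42 individuals and 18
traits with 1000 bootstrap replicates and 10 000 skewers. These sizes were
chosen so each check is decisively informative (Monte Carlo error well
below the tolerance it asserts) while the whole suite stays desk-scale.

## Known limitations

- Percentile bootstrap CIs on near-boundary statistics (e.g. V_rel near 0)
  are not range-preserving transformations and can be slightly
  anticonservative at small n.
- `compare_vrel`'s 1/(n−2) variance is an approximation; at very small n
  (≤ 10) its z-test should be read qualitatively.
- Autonomy requires a full-rank matrix; for d approaching n, bootstrap
  replicates can degenerate and the ridge ("bending") option trades a small
  bias for computability — always report the ridge used.
- The additive-null variance expectation collapses each trait to L
  effective equal-effect loci; real architectures with unequal effects lie
  between the L = 1 and large-L expectations.
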