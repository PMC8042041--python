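# Methods

## Model and assumptions

The package estimates the causal effect θ of an exposure on a binary outcome
from two GWAS summary-statistic sets, under the standard two-sample MR data
model: for instrument *i*, the standardized outcome effect decomposes as

    Γᵢ = θ·γᵢ + αᵢ

where γᵢ is the standardized exposure effect and αᵢ a direct (horizontally
pleiotropic) effect, zero for valid instruments. Observed effects carry
sampling noise with known standard errors; exposure and outcome noise may be
correlated (correlation ρ) when the two GWAS share participants. Effects
enter the estimators on the standardized scale:

* exposure: γ̂ = β̂_E/(se_E·√n_E), se(γ̂) = n_E^(−1/2) — i.e. z-score/√n;
* outcome: Γ̂ = β̂_Y·√(2·MAF·(1−MAF)), se rescaled by the same factor.

The two transforms are deliberately asymmetric (the exposure is rescaled by
its z-score, the outcome by the allele-frequency variance factor). Both
preserve each variant's z-score exactly, so statistical significance is
untouched; only the effect scale changes. With a binary outcome on the
log-odds scale, θ exponentiates to an odds ratio; all estimators report
OR with 95% CI using the normal multiplier 1.959964.

## Estimators

**IVW** — weighted least squares of Γ̂ on γ̂ through the origin, weights
1/se_Γ² (first-order/fixed-effect weighting; a multiplicative random-effects
option inflates the SE by max(1, √(Q/(m−1)))). Unbiased only when no
horizontal pleiotropy is present; under directional pleiotropy of mean c its
asymptotic bias is c·E[γ]/E[γ²], which the acceptance checks verify against
simulation.

**MR-Egger** — the same regression with a free intercept. Under InSIDE
(instrument strength independent of direct effects), the slope is a
consistent estimate of θ and the intercept estimates the mean direct effect;
the intercept's p-value is the pleiotropy test. Instruments are
sign-oriented so γ̂ ≥ 0 before fitting (the standard Egger convention,
configurable off). Standard errors use the weighted residual dispersion
floored at 1 and t(m−2) reference for the intercept test.

**IMRP** — iterative pleiotropy pruning. Given a current θ, each instrument
is tested with

    tᵢ = (Γ̂ᵢ − θγ̂ᵢ) / √(se_Γᵢ² + θ²·se_γᵢ² − 2θρ·se_Γᵢ·se_γᵢ)

against a two-sided normal; instruments with p below `alpha_pleio`
(default 0.05) are excluded, θ is re-estimated on the retained set, and the
loop repeats until the excluded set is stable (max 50 iterations; the result
carries a convergence flag). θ is estimated by weighted origin regression
using the same overlap-corrected residual variance as weights, iterated to
its fixed point — an estimating-equation form, so the weights and the test
are mutually consistent. With `alpha_pleio = 0` nothing is excluded and the
estimate equals IVW computed with those corrected weights (numerically close
to, but not exactly, the 1/se_Γ²-weighted IVW; the difference is O(θ²se_γ²)
and negligible when the exposure GWAS is much larger than the outcome GWAS).
ρ defaults to 0 and is exposed because the overlap between exposure and
outcome samples is rarely known precisely.

**Normal-mixture profile (MRMix-style)** — for each θ on a grid (default
[−2, 2] step 0.01) the residuals dᵢ = Γ̂ᵢ − θγ̂ᵢ with known null variance
sᵢ²(θ) = se_Γᵢ² + θ²se_γᵢ² are fitted by EM to

    π₀·N(0, sᵢ²) + (1 − π₀)·N(0, sᵢ² + σ²),

profiling the fitted null proportion π₀; the estimate is the grid argmax
(exact ties resolved toward smaller |θ|). This matches the intuition that at
the true θ the largest share of instruments looks like pure sampling noise;
it requires a majority of valid instruments. The SE is a nonparametric
bootstrap over instruments (default 200 resamples, seeded). A profile whose
objective varies by less than 10⁻³ across the grid is flagged unstable —
the wide-confidence-interval regime seen with weak instruments.

EM details: π₀ starts at 0.9; σ² starts at the excess of residual scatter
over the mean noise variance and is updated by a 3-step fixed-point on the
M-step stationarity condition, floored at 10⁻¹² to prevent component
collapse. Convergence tolerance 10⁻⁴ on both parameters with a 100-iteration
cap: the objective only needs ~10⁻³ resolution to order grid points, and
tightening to 10⁻⁶ changes no reported digit in our checks while tripling
runtime. The EM is vectorized across grid points and bootstrap resamples;
bootstrap profiles use a coarse (5-step) scan refined around every
near-maximal coarse point, which reproduces the full-grid argmax for
unimodal profiles. The observed-data profile always uses the full grid.

## Data preparation

**Meta-analysis** — fixed-effect inverse-variance combination per variant;
cohort records are sign-aligned to the first cohort's allele pair (swap or
strand complement; unreconcilable records excluded and counted). Cochran's Q
on k−1 df screens between-study heterogeneity at a Bonferroni-adjusted
threshold across all variants tested in >1 cohort; flagged variants are
retained but reported. Combined n is the sum, combined eaf the n-weighted
mean.

**Harmonization** — inner join on variant id, then outcome records are
rewritten to the exposure's effect allele: label swap negates β and mirrors
eaf; strand complement relabels without sign change. Palindromic variants
(A/T, C/G) are strand-ambiguous; the default `infer` policy keeps them when
both minor-allele frequencies are below 0.4, flipping when the frequencies
sit on opposite sides of 0.5, and drops them otherwise (`drop` and `keep`
policies available). Indel alleles are matched by label only. Multi-allelic
reconciliation is out of scope; unreconcilable records are dropped with
counts.

**Clumping** — greedy index-SNP selection among variants with p < p1
(default 5e-8): repeatedly promote the smallest-p remaining variant
(ties broken lexicographically by id, making the selection order-invariant
and bit-reproducible) and remove remaining variants within 500 kb on the
same chromosome with r² ≥ 0.1 (sensitivity setting 0.05). The LD source is
a user-supplied matrix or long-format pair table; absent pairs count as
r² = 0 with a logged warning, matching reference-panel behaviour. The
"LD coefficient" is interpreted as r², the semantics of the conventional
clumping tools. A secondary threshold p2 is accepted in configurations for
interface parity but does not alter index selection when p1 = p2.

**Frequency filter** — min(eaf, 1−eaf) > threshold; records with missing
eaf pass only a zero threshold, because the outcome standardization needs
MAF downstream.

## Power

Approximate two-sided power of the IVW-style test for a binary outcome:
noncentrality |θ|·√(n·r²·φ(1−φ)) with case fraction φ and instrument r², so
power = Φ(−z_{1−α/2}+ncp) + Φ(−z_{1−α/2}−ncp). This equals α exactly at
θ = 0 and ignores weak-instrument bias, pleiotropy and winner's curse; it is
a planning approximation, not a guarantee.

## Synthetic-data generator

The generator emulates the statistical structure the estimators assume:
standardized effects γᵢ ~ N(0, σ_γ²) with σ_γ = 0.01 by default (the order
of per-instrument effect-size SD seen in large cardiometabolic GWAS),
αᵢ ~ N(pleio_mean, pleio_sd²) for a configurable invalid fraction (balanced
or directional), per-cohort sampling noise at n^(−1/2) with optional
exposure/outcome correlation ρ, and exact back-transformation to per-allele
(β, se) so the standardization code path is exercised end to end. Defaults
(m = 129 instruments, exposure n ≈ 659k, outcome n ≈ 11k) mirror the scale
of a diabetes-exposure / infectious-disease-hospitalization study. Optional
block LD, palindromic-allele injection and swapped-allele records stress the
clumping and harmonization paths.

Two generator options exist purely to make specific properties testable:
`noise_scale = 0` gives the noiseless limit (exact recovery checks), and
`gamma_positive` draws half-normal instrument effects so that the Egger
sign-orientation step cannot scramble planted directional pleiotropy —
with symmetric γ, orientation flips the sign of α on flipped instruments
and E[γ] = 0 degenerates the IVW bias formula. Exact-recovery checks for
the mixture estimator use strong instruments (σ_γ large relative to
grid-step × noise SE); with weak instruments the π₀ profile is flat near the
truth at grid resolution and the argmax is only set-identified.

What the generator does **not** emulate: realistic genome-wide LD,
winner's-curse selection of instruments, ancestry structure, liability-scale
binary traits, or allele-frequency-dependent effect sizes. Passing tests
therefore demonstrate correctness of the estimators under their stated
model, not robustness to every real-data pathology.

The back-transform inverse is exact for the outcome; for the exposure the
per-allele (β, se) pair is underdetermined by γ (any se reproduces the same
γ), so the canonical GWAS standard error 1/√(2·MAF·(1−MAF)·n) of a
unit-variance trait is used unless an explicit se is supplied.

## Numerical choices and degenerate inputs

* CI multiplier fixed at 1.959964; p-values two-sided normal (t(m−2) for the
  Egger intercept).
* Wald ratio undefined at γ̂ = 0 (error); IVW requires ≥1 instrument with
  γ̂ ≠ 0; Egger and IMRP require ≥3, the mixture ≥10.
* IMRP raises if every instrument is excluded; reaching max_iter returns the
  current estimate flagged unconverged.
* Mixture EM fits that go non-finite are marked invalid and skipped by the
  argmax; σ² floored at 10⁻¹².
* Clumping with an empty candidate set returns an empty selection; an empty
  harmonization intersection is a fatal error with an id-format diagnostic.
* Record validation drops (and counts by reason) rows with se ≤ 0, p ∉ (0,1],
  eaf ∉ [0,1], n < 1, identical alleles, or duplicate ids; a file whose
  numeric columns fail to parse in >50% of rows is rejected outright.
* Per-SNP sample size n is required input; sources that omit it must be
  annotated before ingestion (documented requirement rather than silent
  imputation).

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` run entirely on synthetic data:
oracle-equivalence on 100 random instrument sets (m ≤ 50), calibration on
10,000 null SNPs, pruning on 100 instruments with 10 planted outliers,
directional-pleiotropy coverage over 200 replicates (m = 100), mixture
recovery over 50 replicates (m = 200, 40% invalid, 200 bootstrap resamples),
clumping against a brute-force oracle on 200 instances (≤ 20 SNPs), and
meta-analysis calibration on 5,000 three-cohort variants. These sizes give
Monte-Carlo error small enough for 3-SE assertions while keeping a full run
in a few minutes on one CPU.

## Known limitations

* Fixed-effect meta-analysis only; no random-effects model.
* No liability-scale conversion for binary exposures: the same exposure
  standardization is applied to binary and quantitative traits.
* The Table-1-style correlation SE uses the large-sample approximation
  √((1−ρ²)/(m−2)).
* LD is consumed, never computed: no reference-panel management or proxy
  SNPs.
* The mixture estimator's SE is bootstrap-based; no asymptotic variance.
* MR-PRESSO/MR-TRYX-style outlier methods, weighted-median/mode estimators
  and multivariable MR are out of scope.
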