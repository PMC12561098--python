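# Methods

This note documents the statistical models implemented in `mrmediate`, the
defaults and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical choices that matter for reproducing a
run.

## Data model and harmonization

The unit of data is a per-variant GWAS association table (`SummaryStats`):
rsid, chromosome, 1-based position, effect/other allele (A/C/G/T), effect-
allele frequency, beta, standard error, two-sided p, sample size.  Binary
traits carry log-odds effects throughout; odds ratios are converted only at
I/O boundaries (`effect_is_or`).  Rows violating the container invariants
(se ≤ 0, p outside (0,1], identical alleles, frequency outside (0,1),
duplicate rsid) are dropped with a logged count, never silently.

Instrument selection keeps variants with p ≤ `p_threshold` (default
5×10⁻⁸, the conventional genome-wide level) and greedily clumps them:
variants are visited in order of ascending p (ties broken lexicographically
by rsid, for determinism) and retained only if r² with every previously
retained variant is below `clump_r2` (default 0.001).  Variants absent from
the supplied LD matrix are treated as independent; the package never
computes LD from genotypes.  Instrument strength is summarized by the
single-instrument approximation F = (β/se)² and per-variant variance
explained r² = 2·eaf·(1−eaf)·β² (valid for a unit-variance trait).

Harmonization aligns outcome effects to the exposure effect allele:
matching pairs kept, reversed pairs sign-flipped with complemented
frequency.  Palindromic variants (A/T, C/G) are kept only when both
frequencies are known, both fall outside [0.5−w, 0.5+w] (default w = 0.08)
and lie on the same side of 0.5 after alignment; otherwise the strand is
ambiguous and the variant is dropped with an explicit action label.

## Estimators

All estimators consume harmonized per-variant pairs (βx_j, βy_j, se_x_j,
se_y_j).

* **Wald ratio** βy/βx with first-order se = se_y/|βx|; a second-order
  option adds the exposure-error term βy²se_x²/βx⁴.
* **IVW**: the zero-intercept weighted regression
  β̂ = Σw_j βx_j βy_j / Σw_j βx_j², w_j = 1/se_y_j².  The default is the
  multiplicative random-effects variant, inflating the fixed-effect se by
  √max(1, Q/(J−1)); p-values from the normal distribution.
* **MR-Egger**: weighted regression with a free intercept after orienting
  every row so βx ≥ 0 (required for the intercept to be interpretable as
  average directional pleiotropy).  Dispersion √max(1, Q_R/(J−2)); slope
  and intercept tested against t with J−2 df.
* **Weighted median**: inverse-variance weights on per-variant Wald
  ratios, linear interpolation at cumulative weight 0.5; se by parametric
  bootstrap of (βx, βy) with a mandatory seed (default 1000 resamples).
  Consistent while ≥ 50% of the weight comes from valid instruments.
* **Bayesian outlier-robust estimator** (BWMR-style): the hierarchical
  model βy_j ~ N(θβx_j, se_y_j² + θ²se_x_j² + τ²) with θ ~ N(0, 5²) and
  τ ~ half-N(0.5).  The posterior is computed on a deterministic 2-D grid
  (θ marginalized over τ); the grid is centred on the IVW estimate, sized
  from the observed excess dispersion, and automatically widened (up to
  twice) if more than 10⁻³ of the posterior mass touches an edge —
  persistent edge mass raises an estimation error with diagnostics.
  Per-variant posterior weights exp(−z_j²/2), evaluated at the posterior
  mean, rank outliers.  This is a reformulation of Bayesian weighted MR as
  a marginal-variance model, not a port of the original variational-EM
  algorithm; agreement is asserted at the contract level (matches IVW when
  τ → 0, downweights gross outliers, nominal null coverage), and exact
  numerical agreement with other implementations is not claimed.

Scale and sign equivariance, the reduction of all estimators to the same
value under exact proportionality, and parameter recovery on synthetic data
are enforced by the test suite.

## Sensitivity diagnostics and method selection

Cochran's Q is computed on the Wald-ratio scale (weights 1/se_ratio², which
is algebraically Σ(βy−β̂βx)²/se_y²), with J−1 df; Rucker's Q is the weighted
residual sum of squares about the Egger fit (weights 1/se_y²), with J−2 df.
The two weight-scale conventions are stated to avoid silent mismatch;
Rucker's Q never exceeds the same-scale IVW heterogeneity.

The MR-PRESSO-style global test sums squared standardized leave-one-out
residuals (each variant's outcome effect against the IVW prediction fitted
without it) and compares the observed sum to a parametric null built by
redrawing each βy_j from N(β̂(−j)βx_j, se_y_j²); p uses the +1 correction so
it is never zero, with `n_sim` = 1000 by default (values below 100 are
rejected as unstable).  The per-variant test compares each squared residual
to its own simulated null with Bonferroni-adjusted flags; dropping flagged
variants and re-running IVW gives the outlier-corrected estimate.

The primary-method rule, applied per trait pair with α = 0.05: a
significant Egger intercept selects MR-Egger (directional pleiotropy); a
significant PRESSO global test with a non-significant intercept selects the
weighted median (the "weighted MR model" branch — the weighted median
rather than a mode estimator, a deliberate disambiguation); otherwise IVW
with multiplicative random effects is primary.  The fired branch is
recorded as free-text rationale in the report.

## Colocalization

Per-variant evidence is Wakefield's approximate Bayes factor,
log ABF = ½[ln(se²/(se²+W)) + z²W/(se²+W)], with prior effect scale
√W = 0.15 for quantitative and 0.2 for binary traits (field-standard
defaults, configurable).  The five-hypothesis posterior uses priors
p1 = p2 = 10⁻⁴, p12 = 10⁻⁵ and the standard sums over shared variants
(H3 as the cross-product sum minus the diagonal), all accumulated in log
space with log-sum-exp; the returned vector is normalized to 1 within
10⁻⁹.  A single shared variant leaves H3 structurally empty and is
flagged.  Windows are ±250 kb around the mediator's lead variant (500 kb
total).  Tiers: PPH4 ≥ 0.8 "colocalized", 0.5–0.8 "suggestive".  The model
assumes at most one causal variant per trait per window; there is no
LD-aware or multi-signal decomposition.

## LD-score regression (simplified)

Single-variance-component, observed scale only: χ²_j regressed on
N·ℓ_j/M with a free intercept (slope = h²), and z1_j·z2_j on
√(N1N2)·ℓ_j/M (slope = genetic covariance); rg = cov/√(h²₁h²₂), clipped to
[−1.25, 1.25] with out-of-[−1,1] values flagged and non-positive h²
leaving rg undefined.  Weights are the standard heteroskedasticity weights
1/(1 + N h² ℓ/M)², iterated twice from an OLS start.  Standard errors come
from a delete-one block jackknife over contiguous equal-count blocks
(default 200; the pipeline uses 100 on its smaller panels), taken over the
rg functional itself for rg.  Sample overlap is handled only through the
free intercept.  Liability-scale conversion is not implemented: binary
traits are reported on the observed scale, which understates h² relative
to liability-scale reports.  The Bonferroni helper α/m gates the phenotype
screen.

## Mediation quantities

indirect = β₁β₂ exactly; proportion = β₁β₂/β₃ exactly (both identities are
asserted).  The indirect se uses the two-term delta method (no covariance:
the three coefficients come from separate GWAS samples); the proportion
variance uses the full three-term form including se₃ by default, with the
two-term variant available (`se3_in_proportion_se=False`) since published
analyses are often ambiguous about whether the total-effect uncertainty is
propagated.  β₃ = 0 leaves the proportion undefined (flagged);
|proportion| > 1 is returned but flagged as inconsistent mediation.
Proportions are reported as percentages to 3 decimals.  Step-2 instrument
sets always exclude step-1 instruments by rsid; an empty remainder is an
error naming the overlap.

Step-1 screening applies Benjamini–Hochberg FDR across the metabolite
family separately per phenotype (per-phenotype families, a deliberate
choice where either convention is defensible), and keeps a metabolite only
if both the primary method and the Bayesian estimator pass q < 0.05 with
concordant signs.  Shared mediators are grouped by their exact phenotype
combination, requiring ≥ 2 phenotypes and excluding the obesity-only
(BMI+WC) pair.  Reverse MR (metabolite → phenotype, outcome → metabolite)
excludes a triangle per phenotype–metabolite pair, never globally.
Evidence tiers: two stars = colocalization pass (PPH4 ≥ 0.5) AND external
replication; one star = exactly one of the two.

## Synthetic data: what it emulates, and what it does not

The generators draw per-variant true effects, then observe them with
sampling noise se_j = 1/√(2·maf_j(1−maf_j)·N) — the standard regression-se
approximation.  The mediation triangle plants γ_j on the exposure
(scaled so the instruments explain a target r², default 0.06 over 100
variants), mediator effects θxm·γ_j plus mediator-specific instruments
(r² = 0.08 over 15 variants), and outcome effects
θdirect·γ_j + θmy·(mediator effect) + α_j, where α_j implements balanced,
directional or correlated (InSIDE-violating) pleiotropy on the
exposure-increasing orientation.  Default sample sizes — exposure 300,000,
mediator 8,000, outcome (effective) 25,000 — mirror the scale of
anthropometric, plasma-metabolome and case-control cancer GWAS
respectively.  All generators are pure functions of (config, seed).

The full-study generator adds an LD-scored polygenic background block
(2,000 variants) shared between phenotypes and outcome with configurable
genetic correlation; its per-variant heritability is deliberately small
(2×10⁻³) so background variants stay below the instrument threshold at the
exposure sample size while the LDSC slope remains estimable — a
deliberately compressed genome.

Not emulated: linkage disequilibrium between instruments (LD matrices are
accepted as input but generated instruments are independent), population
structure, sample overlap between GWAS, allele-frequency mismatch between
cohorts, strand errors, and winner's-curse-free instrument discovery
(instruments are selected in the same data in which their effects are
used, so a few-percent attenuation of downstream ratio estimates is
present by design, as in single-sample instrument selection).  Passing
tests therefore demonstrate correctness of the statistical machinery under
the stated generative model, not robustness to every artefact of real
GWAS data.

## Problem sizes used by the test suite

The calibration and recovery checks run at sizes chosen to make Monte-Carlo
error small relative to the asserted tolerances while keeping the suite
quick: 1000 replicates for the Egger intercept level, 500 for the Cochran/
PRESSO level (PRESSO null of 1000 simulations each), 200 for the
weighted-median robustness and the full two-step recovery study, 10⁶ draws
for the delta-method cross-check.  Null-calibration replicates use a very
large exposure sample (10⁷) so that the χ² reference distribution of the
heterogeneity statistics is exact (no measurement error in the instrument
effects); all other simulations use the default study conditions above.

## Known limitations

* Covariance between β₁, β₂, β₃ is assumed zero; overlapping GWAS samples
  would require a covariance-aware delta method.
* No multivariable MR, mode-based estimators, Steiger filtering, or
  MR-PRESSO distortion test.
* The colocalization and LDSC components are single-signal,
  single-component simplifications.
* The Bayesian robust estimator is a grid-posterior reformulation; its
  per-variant weights are diagnostic ranks, not calibrated posterior
  probabilities of validity.
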