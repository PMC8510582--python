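# Methods

## The generative model

All calculations rest on the liability threshold model with an explicit
family structure. Total liability is standardized (`Var(y) = 1`, in
population-SD units); a person is affected iff `y > z_K = Φ⁻¹(1−K)`.
The PRS carries `r²_ps` of the liability variance on the liability scale.
Within a couple, sibling-embryo scores share the mid-parental component
`c ~ N(0, r²_ps/2)` and differ by segregation noise `x_i ~ N(0, r²_ps/2)`,
which reproduces the sibling score correlation of ½; the residual
`e ~ N(0, 1 − r²_ps)` bundles non-score genetics and environment, drawn
independently per embryo. Assumptions inherited from this construction:
an infinitesimal (normal) genetic architecture, random mating, no shared
family environment, and a PRS whose within-family accuracy equals its
population `r²_ps`.

Percentiles of parental PRSs are lower-tail quantiles of the population
score distribution `N(0, r²_ps)` (so a "98% percentile" parent is in the
top 2%).

## Analytic engine

Two reductions keep everything at one or two quadrature dimensions:

1. Averaging a normal tail over an independent normal component collapses
   into a single tail with inflated variance. In particular the
   unconditional LRP risk is a single integral over the minimum of `n`
   iid `N(0, r²_ps/2)` variables,
   `∫ n φ(x/σ)/σ [1−Φ(x/σ)]ⁿ⁻¹ Φ̄((z_K − x)/√(1 − r²_ps/2)) dx`,
   because `c` simply joins the residual.
2. The HRE mixture is written without dividing by truncation masses.
   With `p = Φ((z_q√r²_ps − c)/σ_x)` the chance one embryo is unflagged,
   the selected-embryo risk conditional on `c` is
   `a(p)·I_low + (1−p)ⁿ⁻¹·I_high`, where `a(p) = [1−(1−p)ⁿ]/p`
   (evaluated via `expm1`/`log1p`; limit `n` as `p→0`) and
   `I_low`, `I_high` are plain integrals of density × residual tail below
   and above the cutoff. The fallback-to-lowest variant replaces the
   second term with the minimum over the all-flagged batch,
   `n ∫_τ^∞ φ(x/σ)/σ [Φ̄(x/σ)]ⁿ⁻¹ Φ̄(...) dx`. This form is exact at the
   degenerate cutoffs (`q = 0, 1`) and stable at extreme `p`.

Order-statistic integrals are evaluated in x-space (smooth integrands
with Gaussian decay) with Gauss–Legendre rules over ±8.5 SD; every
top-level result is recomputed at doubled resolution and required to
agree to 1e-8, else a `NumericalIntegrationError` is raised. An
independent second route (explicit two-level quadrature over `c` then
`x`) is kept for the LRP risk and exercised by the tests. The per-couple
RRR grid uses mid-quantile points `(i−½)/m`, so each grid point carries
equal mass and the weighted conditional risks reproduce the
unconditional values (law of total probability, verified to 1e-3 at
m = 10⁴).

### Parental disease status

Each parent's liability splits into score `s ~ N(0, r²_ps)`, non-score
genetic `g ~ N(0, h² − r²_ps)` and environment `~ N(0, 1 − h²)`; a parent
is affected iff their sum exceeds `z_K`. Only `u = s + g` is heritable,
and the posterior of `u` given status is the prior times the
environmental tail mass. Offspring receive the mid-parental score `c` and
mid-parental non-score component, plus segregation noise with half of
each parental variance and a fresh environment. For LRP the selection
acts only on the within-batch `x_i`, independent of the conditioning, so
the computation is a 2-D posterior integral over `(u₁, u₂)` times a 1-D
order-statistic integral. For the HRE strategies the selection cutoff
depends on `c` itself, which is conditionally normal given
`t = (u₁+u₂)/2` (`c | t ~ N(t·r²_ps/h², r²_ps(h²−r²_ps)/(2h²))`), adding
one inner quadrature; the grid is processed row-wise to bound memory. An
"unknown" status simply drops that parent's tail factor (marginalizes).
Degenerate cases (`h² = 0`, `h² = r²_ps`, `r²_ps = 0`) take exact
short-circuits. The rejection-sampling Monte-Carlo route
(`simulate_selection(..., condition_status=...)`) implements the same
generative story directly and serves as the cross-check; it refuses to
run when the status acceptance rate falls below 1e-5 and points to the
quadrature route instead.

## Monte-Carlo engine

Batches are simulated exactly as generated above, vectorized over
couples × embryos and chunked at ~10⁷ scalar draws so memory stays flat
at any batch count. All randomness flows from one `numpy` Generator with
an explicit seed: same seed, bit-identical results. HRE's "random
unflagged embryo" is drawn by giving every embryo a uniform key, offset
for unflagged ones, and taking the arg-min — one pass, no Python loops.
The baseline arm always selects the first embryo (identical in
distribution to a uniform pick) with its own residual, so conditional
baselines carry Monte-Carlo error too and are reported with it.

For the two-disease pleiotropy experiment the score covariance
`ρ√(r²₁·r²₂)` is split equally between the shared and embryo-specific
components, mirroring the single-disease ½/½ split; the residual
(environmental) components are independent across diseases, making
genetic correlation the only coupling. The bivariate draws use the
lower-triangular Cholesky factor, so the target disease's stream does not
depend on `ρ`: with a fixed seed the target-disease results are identical
across `ρ` values, isolating the pleiotropic effect. Risk changes are
ratios of affected fractions between the selected and random arms, with
delta-method standard errors.

## Dichotomized traits

A disease defined by thresholding a normal quantitative trait is the same
threshold character as a liability: the module converts the trait-scale
specification (mean, SD, cutoff, tail) to an implied prevalence and
delegates to the LRP calculator with the trait PRS `r²`. Selecting the
highest-PRS embryo for an upper-tail disease maps to the lower-tail case
by reflection; no separate integration code exists, by design.
Published trait `r²` values are inputs, not constants of the package.

## Genome-level validation pipeline

The synthetic cohort generator emulates a case-control study under the
same liability model at the genotype level: independent biallelic
variants (linkage equilibrium) with MAFs uniform in a configurable range,
`N(0,1)` effects rescaled so the population score variance equals the
target liability `r²`, and case/control ascertainment by simulating
individuals until the requested numbers of each are collected. The
genetic map is piecewise linear (default 1 cM/Mb). What this does *not*
emulate about real data: linkage disequilibrium, allele-frequency/effect
correlations, strand-ambiguous variants, genotyping error and population
structure — so passing pipeline checks validate the Mendelian and
ascertainment machinery, not robustness to those artefacts.

Meiosis draws per-chromosome crossover counts `Poisson(map length in
Morgan)` with positions uniform in genetic distance, starts each gamete
on a random strand and switches at every crossover; positions are
interpolated cM↔bp with no extrapolation (a variant outside the map is
an error). A crossover landing exactly on a variant (probability zero;
possible only through file rounding) leaves the variant with the
left-hand segment.

Scoring is the raw weighted effect-allele dosage sum by default, with the
per-allele average dialect available; risk reductions are invariant to
this affine choice. Risk prediction is a logistic regression of status on
score whose intercept is shifted by `−log[(P/(1−P))·((1−K)/K)]` to undo
case oversampling (`P` = sample case fraction); population PRS
percentiles come from a normal fitted with case weight `K` and control
weight `1−K`. The observed-scale `R²` (squared status–score correlation)
is mapped to the liability scale with the ascertainment-corrected
transformation `R²_l = R²_o·C/(1 + R²_o·θ·C)`,
`C = K²(1−K)²/(z²P(1−P))`, `θ = m·(P−K)/(1−K)·[m·(P−K)/(1−K) − t]`
(`t` the threshold, `z` its normal density, `m = z/K`), which reduces to
the classical `K(1−K)/z²` factor when `P = K`.

Virtual couples are formed by status according to the prevalence —
fractions `(1−K)²`, `2K(1−K)`, `K²` with largest-remainder rounding — as
unique pairs without self-pairing; individuals may recur across couples
in small cohorts (warned). The empirical risk reduction compares the
strategy-selected embryo's predicted risk with a random embryo's,
averaged over couples; diagnostics check that the pooled within-couple
embryo score variance is half the parental population variance and flat
in the mid-parental score.

## Problem sizes and tolerances

Defaults chosen as the package's own study conditions: 10⁶ batches for
headline Monte-Carlo runs (binomial SEs reported everywhere), 10⁴
quantiles for per-couple grids, 10⁶ couples for the pleiotropy
experiment. The test suite cross-validates analytic vs Monte-Carlo
results at 3 standard errors over the full `K × r² × n` grid with 2×10⁵
batches per cell plus 10⁶-batch spot checks, and runs the genome pipeline
on a 500-sample cohort (600 independent variants, 10 chromosomes) with
400 couples — sized like the smaller case-control study the design
emulates. The variance-halving diagnostic is asserted at ±10% relative;
empirical vs analytic LRP risk reduction at 7 percentage points, which
absorbs both couple-sampling noise and the small downward bias that
finite-cohort score-variance estimation induces.

## Known limitations

- Single-disease selection only; no composite indices over multiple
  diseases, no utility/cost modelling.
- The across-batch (within-couple) distribution of realized outcomes is
  not modelled — per-couple quantities are expectations over batches.
- HRE conditioning on parental status is the slowest path (a 4-level
  quadrature, seconds rather than milliseconds).
- The pleiotropy covariance split between shared and embryo-specific
  components is a modelling choice (equal split); alternatives would
  change conditional, not unconditional, quantities.
- Monte-Carlo and analytic engines share the generative model's
  assumptions; the genome pipeline relaxes normality and infinitesimality
  (finite loci, Bernoulli alleles, real Mendelian segregation) but not
  linkage or ascertainment artefacts of real cohorts.
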