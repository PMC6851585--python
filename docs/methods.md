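# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the design decisions made where the design was
genuinely open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Mixed models

Per trait, stage and scope we fit a generalized linear mixed model with
independent random intercepts,

    g(E[y_i]) = x_i'β + Σ_k z_ik' b_k,   b_k ~ N(0, σ_k² I),

with treatment-coded fixed effects and one variance component per random
term (maternal family nested within population, population, individual for
repeated measures, observation-level for overdispersion). Supported
families/links: Gaussian(identity), Poisson(log), Bernoulli(logit),
Gamma(log).

**Estimation.** Gaussian models are fitted by (restricted) maximum
likelihood with the residual variance profiled out: random-effect SDs are
parametrised relative to σ_e, each objective evaluation is one sparse
penalized least-squares solve, and the REML criterion adds
log det(X'V⁻¹X). Non-Gaussian models use the Laplace approximation: for
given variance parameters the joint mode of (β, b) is found by penalized
iteratively reweighted least squares (PIRLS), and the approximate marginal
deviance is

    −2ℓ ≈ −2 log f(y | η̂) + b̂'D⁻¹b̂ + log det(Z'WZ·D + I).

The outer optimisation over log-SDs (plus log-dispersion for Gamma) uses
Nelder–Mead. Fixed effects are *profiled* at the joint mode rather than
carried in the outer optimisation; this ignores the dependence of the
log-determinant term on β and can differ from a full Laplace optimum by a
small fraction of a standard error (we observed ~0.1 SE on the intercept of
a Poisson example) — immaterial for the response-scale contrasts this
pipeline reports, and it keeps models with many fixed effects (sex ×
population, ~60 columns) tractable. Convergence: relative change below
1e-6 in the inner PIRLS objective, 200 iterations maximum; non-convergence
is flagged on the results object, never silent.

With all random-effect SDs fixed at zero the machinery collapses exactly to
the corresponding GLM; the test suite verifies agreement with an
independent GLM implementation to ≤1e-6 across random designs, and the
Gaussian path against an independent linear-mixed-model implementation.

**Type-2 Wald tests.** Each fixed term is tested after all terms of the
same or lower order: a term with higher-order relatives in the model is
tested by a joint Wald chi-square in a refit omitting those relatives;
terms without relatives are tested in the full fit. For balanced Gaussian
designs this reproduces closed-form F-test p-values in the large-df limit.

**Predicted means.** Group means are computed on the link scale at the
focal factor levels, with non-focal categorical covariates averaged
*uniformly over their levels on the link scale*, numeric covariates at
their centred value, and random effects at zero; Wald 95% intervals on the
link scale are back-transformed. The averaging convention is a documented
choice — equal weights per level rather than observed frequencies — made
so that predicted means are invariant to unbalanced sampling.

**Family selection.** Hard support rules first (binary → Bernoulli;
non-negative integers → {Poisson, Gaussian}; positive continuous →
{Gaussian, Gamma}), then lowest intercept-only AIC among admissible
candidates; diagnostics carry the mean–variance ratio and a quantile
discrepancy against draws simulated from each fitted candidate. Selection
is applied per stage, because stage mixtures masquerade as overdispersion.

**Overdispersion.** For Poisson/binomial fits the ratio of Pearson
chi-square to residual df (n − p − #variance-parameters) is computed; above
1.5 (a documented threshold — the trigger is not standardised in the
field) the model is refitted with an observation-level random intercept.
Binary one-trial responses report the ratio but skip the refit
(non-identifiable).

## Percent sexual dimorphism

%SD = 100(mean_F − mean_M)/mean_M on predicted means; positive =
female-biased. Two intervals are attached to every estimate:

- `ci_low`/`ci_high`: the published propagation rule applied literally,
  √(bound_F² + bound_M²) once with the two lower and once with the two
  upper 95% bounds. Note this yields a magnitude-style band that is not
  centred on the point estimate; whether the rule was meant for raw bounds
  or for half-widths is not stated in the source methods, so the literal
  reading is reported and clearly labelled.
- `delta_low`/`delta_high`: a first-order delta-method interval using the
  link-scale covariance of the two predicted means, mapped through the
  inverse link. Direction calls (female-/male-biased/none) and reversal
  significance use this interval.

Estimates with |mean_M| below 1e-8 are emitted as undefined rather than
exploding. Binary traits are compared on the probability scale. A
temporal **reversal** is flagged when %SD changes sign between two stages
and both delta intervals exclude zero.

Derived traits: total flower number = inflorescence number × mean
inflorescence length; proportion of flowering stems (flowering individuals
only, missing when stems = 0); total biomass = vegetative + reproductive.

## Gradients

Population-level %SD (point estimates, unweighted — no CI weighting is
prescribed for this analysis) is regressed on three predictor categories
with a fixed, documented entry order: demographic (size, density, sex
ratio), geographic (longitude, latitude, elevation), bioclimatic (annual
mean temperature bio1, annual temperature range bio7, annual precipitation
bio12). Forward selection adds predictors in that order, keeping each only
when the nested-model F-test is significant at α = 0.05 (F-tests rather
than likelihood-ratio tests; configurable), so accepted paths have
non-decreasing R² and every kept step a significant improvement. Each
winning model reports coefficients, R², the overall F-test p, and the
Shapiro–Wilk residual-normality p.

The 19 bioclim variables are reduced greedily: candidates visited in a
priority order (bio1, bio7, bio12 first), kept while pairwise |Spearman r|
with all kept variables stays below 0.8 (a documented default; no
standard threshold exists), up to 3 variables. The reduction is checked by
congruence of population scores on the first two principal components of
the selected vs the full set.

Sex-specific slopes: per-sex ordinary regressions of population predicted
means on each selected variable, with the F − M slope difference and a
Wald CI from the independent-fit SEs.

The funnel heterogeneity statistic is this package's own
operationalisation of "more variable dimorphism in sparser populations":
Spearman correlation between density and |%SD − median %SD|, with a
permutation p-value (populations shuffled, 1000 permutations, seeded),
alongside the plain density–%SD Spearman correlation.

## Correlations

Intersex (same trait, F vs M) and intertrait (within sex) Spearman
correlations across population predicted means, per stage; ties get
average ranks. Partial correlations rank-transform all variables and
condition on the remaining traits (cross-sex averages of the remaining
traits for intersex entries); residual-based and precision-matrix routes
are both implemented and agree to ≤1e-8, and the empty-control case equals
the raw Spearman exactly.

**Subsample bootstrap.** Sex-specific 95% percentile intervals for each
trait-pair correlation from 1000 draws of 25 populations; the same draw is
used for both sexes; a sex difference is called significant when the two
intervals do not overlap. The draw is **with replacement** by default:
delete-d subsampling (25 of ~30 without replacement) makes consecutive
subsamples share most populations, understating sampling variability —
under equal true correlations (0.4, 0.4) the non-overlap rule then fires
~19% of the time, whereas the with-replacement draw is conservative (<1%)
with full power at strongly opposite correlations, which is the behaviour
the non-overlap rule presumes. Sampling without replacement remains
available behind `replace=False`. A percentile p-value for r_F − r_M is
reported as a labelled extension.

## Synthetic-data generator

The generator emulates the common-garden design the analysis assumes: 30
populations, two karyotype races split along a west–east cline; 15
maternal families per population with Binomial(4, 0.995) family sizes
(truncated at 1), giving 48–64 planted per population with mean ≈ 59.7;
Bernoulli sex with population sex ratios uniform on 0.54–0.68 and a repair
step guaranteeing both sexes per family where feasible; densities
log-uniform on 0.04–122.4 plants m⁻², population sizes log-uniform on
10–2×10⁶. The 19 bioclim covariates are linear in three latent climate
axes (mean temperature, temperature range, precipitation — themselves
linear in the coordinates, scaled by `cline_strength`) plus independent
noise, with temperature variables rounded to the WorldClim v1.4 °C×10
integer convention; this makes the variable-reduction step recoverable by
construction. Trait values follow the same linear-predictor structure the
models fit (sex, stage, sex×stage, race, sex-specific bio1 slopes,
population/family/individual intercepts), so each trait/stage has a
closed-form true %SD evaluated with random effects at zero, climate at its
mean and race averaged on the link scale — the same conditioning the
predicted means use. With probability `p_unsexed` (default 0.02) an
individual never flowers: its recorded sex is "U", it receives no
reproductive observations, and it is excluded (and counted) downstream.

What the generator does *not* emulate: spatial climate rasters,
germination/viability selection, block effects (generated as labels but
with zero variance — the design randomises blocks and does not model
them), non-linear climate responses, or genetic correlations between
traits beyond what shared random effects induce. Passing recovery tests
therefore demonstrates correctness of the estimators under the assumed
generative structure, not robustness to real-data violations of it.

Gaussian traits with positive support use mean/SD ratios ≥ ~5 and are
floored at zero (the truncation probability is < 1e-6, so closed-form
truths are unaffected at any realistic sample size).

## Validation harness and problem sizes

`dimorph.validation` (used by both `tests/test_acceptance.py` and
`scripts/acceptance.py`) runs: %SD formula vs brute force on 10⁴ random
mean pairs; 50-replicate %SD recovery at truth 25 (bias, RMSE, delta-CI
coverage); 50-replicate reversal detection for the −16.1/+9.4 profile and
a 50-replicate null; 200-replicate gradient type-I calibration and a
50-replicate sex-slope recovery at slope difference 3; 200-replicate
bootstrap null calibration (0.4/0.4) and 50-replicate power (±0.8); the
dual-route partial-correlation check on 100 random instances; and the GLM
limit on 20 random designs. These sizes keep a full validation pass around
a minute on one CPU while leaving Monte-Carlo error well inside the margins
being asserted.

## Known limitations

- Fixed-effect profiling in the Laplace objective (above) trades a small
  approximation for scalability; variance components at the boundary
  (σ → 0) are clamped at 1e-6 rather than tested formally.
- Family selection compares AICs across discrete and continuous families
  on the same data — standard practice for this decision, but the absolute
  AIC values are not comparable across kinds, only the choice is.
- Per-population models with 60 fixed-effect columns can give wide
  predicted-mean intervals for sparsely sampled sexes within populations;
  downstream correlation stages use the point estimates unweighted.
- No multiple-testing correction is applied across traits/stages (raw
  p-values are reported by design); no spatial autocorrelation correction
  in the gradient regressions; no quantitative-genetic decomposition of
  intersex correlations (family sizes in this design are too small).
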