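# Methods

This note documents the models implemented in `aridclines`, the choices
made where the design was genuinely open, and what the synthetic-data
tests do and do not demonstrate about real data.

## Data model and derived traits

One row = one experimental plant with design factors (experiment,
population, patch/family, block, treatment) and either raw measurements
or the 13 derived traits. Derivations:

| trait | formula | units |
|---|---|---|
| growth_rate | (leaf count wk 8 − wk 0) / 8 | leaves wk⁻¹ |
| succulence | (leaf FW − DW) / DW | g water g⁻¹ |
| sla | leaf area / leaf DW | cm² g⁻¹ |
| biomass | shoot DW + root DW | g |
| root_shoot_ratio | root DW / shoot DW | — |

Growth rate is defined as the *linear* rate between the two census
points; with only two counts a difference, ratio or regression slope are
equally defensible, and the linear difference is the simplest. Records
with a zero denominator are excluded from derivation with a logged
count rather than aborting the run. Seed counts estimated from bagged
capitula (seeds g⁻¹ × capitula dry mass) are rounded to integers because
the count likelihoods downstream require them.

Relative fitness is seed count divided by the treatment mean, so it
averages exactly 1 within each treatment; an all-zero treatment is an
error, not a silent zero division.

Transforms: each trait carries a static registry default (log for the
three phenolic concentrations, none elsewhere), but the operative rule is
data-driven (`transform="auto"`): transform when |sample skewness| > 1,
log if strictly positive, square-root if non-negative. Standardization is
z-scoring within experiment × treatment; the group means/SDs are
returned so it is exactly invertible, and it is idempotent to 1e-10.

## Cline analysis

Stage 1 — LSMEANS. The field design uses the saturated fixed model
population × treatment, whose LSMEANS are the cell means for any balance
pattern (this is asserted against direct cell averaging in the tests).
The glasshouse design adds patch-within-population and bench-block
random intercepts, fitted by REML via a variance-components
parameterization that accommodates the crossed patch/block structure.
Boundary variance estimates are returned as 0 with a warning — with one
plant per patch the patch component is confounded with the residual and
0 is the honest REML answer.

Stage 2 — regression of LSMEANS on aridity × treatment, unweighted (each
population counts once; 1/SE² weighting is available behind
`weight_by_precision` but off by default, mirroring the two-stage
LSMEANS-then-regression tradition). The interaction is tested per trait
by partial F at α = 0.05; when dropped, the additive model's Type II
marginal F-tests are reported (well-defined without term ordering for
the unbalanced two-factor case). Per-treatment slopes come from the
fitted model with t-based 95% CIs. Holm's step-down procedure controls
the familywise error across the 13 aridity tests; its decisions are
checked against a literal brute-force step-down oracle.

The fitness cline forces the interaction model because the aridity ×
treatment interaction *is* the local-adaptation hypothesis there; with
8 populations × 2 treatments and 4 parameters its F-test has (1, 12)
degrees of freedom.

Numerical guard: with exactly collinear LSMEANS both SSRs vanish and the
partial F would be 0/0; the implementation returns F = 0 (or ∞ when only
the full model fits perfectly) using a relative tolerance of 1e-12 on
the response scale.

## Selection analysis

β point estimates are always the OLS regression of relative fitness on
the standardized traits plus intercept (classical SEs); the count models
supply inference only, and the two are reported side by side, never
mixed. Preconditions: more observations than traits + intercept, and a
design condition number below 1e8 (the error names the most collinear
columns via the smallest singular vector).

Zero-inflated (dry) seed counts use a two-part hurdle likelihood in
which the traits enter both layers:

* reproduction layer: Bernoulli with logit link;
* count layer: zero-truncated negative binomial, log link, dispersion k
  (variance μ + μ²/k) optimized on the log scale.

Both layers are maximized with L-BFGS-B using analytic gradients
(convergence: relative log-likelihood change < 1e-8, gradient ∞-norm
< 1e-7, iteration cap 500). The joint log-likelihood decomposes exactly
into the two layer likelihoods, which is asserted on every fit. Wald SEs
come from the exact logistic information matrix and from central
differences of the analytic ZTNB gradient; a singular information matrix
yields NaN SEs with a warning rather than spuriously tiny ones. Per-trait
significance defaults to the Wald z on the count layer; a likelihood-
ratio test of both layers' coefficients simultaneously is available
(`inference="lrt"`). A logistic coefficient beyond ±30 is treated as
perfect separation and is an error naming the trait. The hurdle
replaces staged life-history (aster-type) fitness likelihoods with an
explicit, overdispersion-robust two-part model; its z-values are
therefore comparable in spirit, not numerically identical, to an
aster fit.

The wet treatment (all plants reproduce) uses a negative-binomial GLM
with the dispersion estimated jointly by maximum likelihood. The
pipeline selects the hurdle only when zeros are non-trivial
(≥ max(5, 2% of plants)); a stray count-model zero or two cannot
identify the logistic layer and is left to the NB GLM.

## Vector geometry

Angles are reported in degrees on [0, 180]. The implementation uses
Kahan's 2·atan2(‖û−v̂‖, ‖û+v̂‖) form, which equals arccos of the clamped
cosine but is exact at the parallel/antiparallel limits instead of
amplifying rounding error there. Zero-norm vectors are an error (the
angle is undefined). Inference-grade angles are always computed on raw
slope/gradient vectors; the zero-mean/unit-variance rescaling of vector
components exists for display contrast only, since recentring changes
angles.

## Bayesian uncertainty propagation

Priors are weakly informative and config-exposed: normal coefficients
with precision 1e-8 (flat in the limit) and inverse-gamma(0.001, 0.001)
variances, approximating the defaults of the common R samplers this
workflow descends from. Two samplers:

* **Linear models** use the exact conjugate normal–inverse-gamma
  posterior — independent draws, no chain, no burn-in. A per-run
  self-check compares sampled moments with the closed-form posterior
  moments.
* **Mixed models** use a blocked Gibbs sampler. Fixed effects and
  few-level random groupings (treatment, experiment, block) are drawn as
  one joint Gaussian block — updating them separately mixes badly
  because the overall level drifts between blocks — while many-level
  groupings (patch) get cheap per-level updates; all variances have
  inverse-gamma full conditionals. The joint block absorbs groupings
  smallest-first up to a 64-dimensional budget. Defaults: burn-in 2000,
  thinning 1, 10 000 retained draws, split-half R̂ ≤ 1.05 on every fixed
  effect (exceeding it is an error carrying the diagnostics).

Population LSMEAN draws come from the mixed sampler with population as a
fixed cell-mean factor and treatment (plus patch/block where present) as
random intercepts; each draw of the population means is regressed on
aridity to give a draw of the 13-component Δz vector. Selection-gradient
draws come from the conjugate sampler applied to the wet and dry OLS
fitness regressions independently and are differenced draw-by-draw for
Δβ. Angle/norm posteriors are summarized by the mean and the equal-tailed
2.5–97.5% interval (matching the cited samplers' default summaries, not
HPD); the alignment verdict depends solely on whether the angle CI
excludes 90°. Draw pairs with a zero-norm vector are dropped with a
logged count; more than 1% dropped is an error. Note the angle posterior
is a distribution on [0, 180] and can be strongly skewed; the mean can
approach an interval endpoint, which is logged, not fatal.

## Synthetic-data generator

The generator emulates the study design, not raw instrument output: it
emits derived-trait tables (a full raw-measurement table is accepted by
the I/O layer for real data). Per plant, the 13-trait phenotype is
multivariate normal with mean cline_slopes × aridity plus a dry-treatment
plasticity shift, correlation matrix defaulting to identity plus a 0.6
photosynthesis–stomatal conductance correlation and 0.3 among the
phenolics. Expected fecundity is exp(baseline + β_treat · (z − z̄_treat)),
centred on the treatment-mean phenotype at mid-gradient aridity so the
baseline is interpretable as the log fecundity of an average plant and
the fitness-aridity cline emerges from each population's displacement
along the cline. Seed counts are negative binomial (k = 2 by default,
matching visible overdispersion in seed-count data), and the dry
treatment multiplies in a Bernoulli reproductive-failure indicator
(default rate 27/95 ≈ 0.284, optionally trait-dependent through a
logistic term). Defaults encode the empirical study conditions: 8
populations evenly spanning aridity 0.5–4.0, 12 plants per population
per treatment (192 ≈ the real 190), published-scale cline slopes,
plasticity shifts and wet/dry selection gradients, and the glasshouse's
4 patches per population and 3 blocks with patch SD 0.5 and block SD 0.3
(within-population variances and random-effect SDs are not published;
these are chosen so simulated SEs resemble the printed ones).

Determinism: one RNG stream per (population, treatment) cell keyed by
(seed, experiment, population index, treatment index), so regenerating
with more populations leaves existing ones bit-identical.

Because traits are centred multivariate normal within each cell and
fitness is log-linear, Stein's lemma makes the Lande–Arnold OLS gradient
of relative fitness converge exactly to the generator's log-scale β —
this is what makes the generator a genuine ground-truth oracle for the
selection stage.

What passing tests on this generator do *not* show about real data:
phenotypes are exactly Gaussian with homogeneous within-population
covariance, fitness is exactly log-linear (no quadratic/correlational
selection, which the package deliberately does not estimate), maternal
effects, spatial structure, pollinator and herbivore processes are
absent, and reproductive failure is (by default) trait-independent.

## Recovery-test problem sizes

The acceptance checks use deliberately chosen regimes: selection-gradient
recovery runs at n = 2000 plants with gradients at 0.3× the published
dry-treatment values and dispersion k = 10 — a regime where the
Monte-Carlo error of the OLS estimate sits well inside the 0.05
tolerance band, so a failure indicates bias, not noise. Cline-slope CI
coverage uses 500 generator replicates of the default 8 × 2 × 12 design
with a single 0.4-slope trait. End-to-end alignment runs use 2500
posterior draws (the CI endpoints only gain Monte-Carlo precision from
more draws; the full 10 000 is used by `scripts/acceptance.py`); the
aligned regime sets Δβ = 1.2 × Δz/‖Δz‖ in norm with 25 plants per
population per treatment, the large-effect regime in which the angle CI
is expected to exclude 90°.

## Known limitations

* The mixed-model Gibbs sampler handles Gaussian responses and crossed
  random intercepts only — no random slopes, no non-Gaussian traits.
* Variance components for 2-level groupings (treatment-as-random, per
  the descended workflow) are weakly identified; only the derived
  quantities (slopes, angles), which are invariant to the drifting
  overall level, should be interpreted.
* The hurdle model's z-values are an approximation to staged-fitness
  (aster) inference, not a reimplementation of it.
* Angles are estimated with noise-inflated vectors; at small n the
  posterior angle between truly aligned vectors is biased away from 0°.
  The tests characterize this (the median estimated angle shrinks as n
  grows) rather than correcting it.
* ρ_bc — the correlation governing how well aridity predicts local
  optima in the theory model — is reserved in the config but unused,
  pending a precise definition of which vectors it correlates.
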