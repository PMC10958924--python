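# Methods

`adipometry` estimates overweight/obesity prevalence in a surveyed
population by combining two imperfect adiposity classifiers — total
percentage body fat (TPBF, from bioimpedance) and relative fat mass (RFM,
a height/waist index) — in a Bayesian two-test latent-class model, with
the supporting stages a full analysis needs: survey sample-size
arithmetic, non-parametric method comparison, ROC-derived thresholds, and
logistic risk-factor models. This note records the models, the defaults
and why they were chosen, and what the synthetic cohorts do and do not
establish.

## Adiposity indices and thresholds

BMI is weight/height² (kg/m²); subjects are classed by the WHO cutpoints
(overweight ≥ 25, obesity ≥ 30, inclusive on the left). RFM is

    RFM = 64 − 20·(height / waist circumference) + 12·[female],

unit-free in the ratio; heights and waists are carried in centimetres and
the CSV column names declare units to guard against metre/centimetre
mix-ups. TPBF is treated as a measured input — no attempt is made to model
the impedance physics behind it.

TPBF and RFM have no universal cutpoints for this population, so cutoffs
are derived per sex × age band (15–19 / 20–25) by ROC analysis against the
BMI-defined classes, maximizing Youden's J = sensitivity + specificity − 1
(ties broken toward higher specificity). Cutoffs are reported with the
strict "> c" convention, c being the highest value still classed negative
at the optimum; when a cutoff table is *applied*, a value exactly at the
cutoff counts positive by default (`inclusive=True`). The indices are
continuous, so boundary mass is negligible, but one convention has to be
fixed for reproducibility, and it is configurable. AUC is computed both as
the trapezoidal area of the empirical curve and as the tie-corrected
Mann–Whitney concordance; the two are identical by construction and the
identity is asserted in the test suite.

## Method comparison (Passing–Bablok)

Agreement of TPBF and RFM with BMI is summarized by Passing–Bablok
regression: the slope is the shifted median of all pairwise slopes
S_ij = (y_j−y_i)/(x_j−x_i), excluding undefined pairs (tied x) and
S_ij = −1, with the median index offset by K = #{S_ij < −1}; confidence
intervals use the rank-based normal approximation with
C = z·sqrt(n(n−1)(2n+5)/18). The residual standard deviation (RSD) is
computed from vertical residuals about the line, sqrt(Σr²/(n−2)), and
±1.96·RSD defines the random-difference band; the agreement flag trips
when more than 10% of residuals fall outside it.

Linearity is checked with the cusum test: points above the line score
+sqrt(n⁻/n⁺), below −sqrt(n⁺/n⁻), cumulated in rank order of position
along the fitted line (x + y/slope); max|cusum|/sqrt(n⁺+1) is referred to
the Kolmogorov tail. This is the classical 1983 formulation; simulation
under a true line with Gaussian noise puts the realized type-I rate near
(slightly under) 5%, the deficit reflecting the constraint the fitted line
imposes on residual signs. Classification concordance across BMI, TPBF
and RFM is the fraction of subjects with all three labels equal, with an
exact one-sided 95% lower bound from the Clopper–Pearson quantile
Beta(k, n−k+1).

## The latent-class prevalence model

Two binary tests applied to one population cross-classify subjects into
four cells. With prevalence π, sensitivities δ₁, δ₂ and specificities
γ₁, γ₂, and errors conditionally independent given true status,

    p11 = π δ1 δ2 + (1−π)(1−γ1)(1−γ2)        (and cyclic for p10, p01, p00)

and the counts are multinomial. The data carry three degrees of freedom
against five parameters: the model is identified only through informative
priors. All five parameters receive Beta priors; by default π is uniform
and the accuracy priors are elicited from the ROC stage (Beta with mean at
the ROC sensitivity/specificity and effective sample size 50 — strong
enough to anchor the accuracy scale, weak enough to let the counts speak).
A run with all-uniform priors is refused unless explicitly overridden,
because silent non-identifiability is the chief failure mode; the known
reflection mode (δ ↔ 1−γ) is excluded by any prior with δ+γ > 1 mass.

Sampling is by data-augmented Gibbs: the latent true-status split of each
observed cell is Binomial with odds π·P(pattern|diseased) against
(1−π)·P(pattern|healthy), after which every parameter update is a
conjugate Beta draw. The full conditionals are exact, so the posterior is
identical to what any general-purpose MCMC (e.g. HMC) would target; Gibbs
was chosen because it is exact, dependency-free and fast on count data.
Defaults are 4 chains × 2,000 warmup + 2,000 kept draws (the "desk"
preset); a "paper" preset with 20 chains × 25,000/25,000 is available
where a heavier run is wanted. Split-R̂ and bulk ESS are computed on every
run (via ArviZ); R̂ > 1.01 on any parameter attaches an explicit warning.
Credible intervals are equal-tailed (2.5/97.5 percentiles).

Two independent checks guard the sampler. First, with (near-)perfect
tests the model collapses to a Beta-binomial with closed-form posterior.
Second, a lattice-integration oracle integrates prior × likelihood over a
midpoint-rule lattice (default 51 points per axis) of the 5-dimensional
unit cube and marginalizes to π. The 5-d lattice sum is evaluated by
expanding each cell probability binomially over its latent true-status
split, which factorizes the summand across the five axes into 1-d lattice
sums; the reorganization is exact (finite sums commute), so the result
equals the naive full-lattice sum at a small fraction of the cost. The
oracle refuses counts with n > 2000 or too many latent splits — the
likelihood then is too peaked for a fixed lattice and the error message
points to the sampler. Posterior-predictive checks simulate replicate
count vectors from thinned posterior draws and report per-cell tail
probabilities; tails near 0 or 1 flag misfit, e.g. conditional dependence
between the tests' errors. Detecting such dependence requires strong
accuracy priors: with only three degrees of freedom, weakly constrained
accuracies absorb the dependence instead of exposing it.

## Survey design arithmetic

The two-stage cluster sample size is
n = z²·p(1−p)·DEFF / (j·k·l·d²), with response proportion j, cluster size
k, target-population fraction l and precision d; the design effect is
DEFF = 1 + (m−1)·ICC. The unadjusted individual requirement is reported as
a ceiling; the department (cluster) count from the full formula is rounded
half-down, the convention that matches the published survey's printed
department count (227/8 = 28.375 → 28).

## Logistic risk models

One multiple logistic regression per outcome definition (BMI-, TPBF- and
RFM-based overweight/obesity; the combined overweight-or-obese endpoint by
default, obesity-only by flag) on the standard covariate set: sex, age
band, year of study, exercise frequency, alcohol, smoking, and three
family-history flags, dummy-coded against male / <20 years / 1st year /
never exercises / flag absent. Fitting is maximum likelihood by IRLS
(statsmodels GLM binomial); intervals are Wald on the log-odds scale, the
conventional OR (95% CI) presentation. Zero cells in the closed-form 2×2
helper get the Haldane–Anscombe +0.5 correction, flagged; quasi-separation
in the full fit attaches a warning naming the unstable terms rather than
silently penalizing. No cluster (college) adjustment is made.

## The synthetic cohort generator

The generator emulates the study conditions — 1,027 students (573 female)
across six college clusters — so every stage is exercisable with known
ground truth. A single latent adiposity factor z (unit SD) carries a
cluster-shared random intercept sized to the configured intra-cluster
correlation (default 0.1); weight, waist circumference and TPBF are
sex-specific affine functions of z plus independent Gaussian noise, and
weight additionally carries an allometric height term (0.55 kg/cm) so
that height variation does not act as pure noise on BMI. Loadings and
noise SDs are calibrated so the cohort reproduces the surveyed margins
(pooled height ≈ 166 ± 8 cm, weight ≈ 65 ± 10 kg, WC ≈ 73 ± 7 cm,
TPBF ≈ 26 ± 11%) and, crucially, the reported strength of index agreement:
stratified ROC AUCs of TPBF and RFM against BMI fall in ≈ 0.91–0.99,
the range the study reports. Family history of obesity (default +0.75
latent-SD) and year of study (+0.10 per year) shift z, producing odds
ratios of the order reported for those factors; lifestyle flags are
generated independent of adiposity, mirroring the null findings for them.

A second generator draws cross-classified counts for two tests with known
prevalence, sensitivities, specificities and optional within-stratum error
covariance (the standard Dendukuri–Joseph dependence form; default 0,
matching the conditional-independence model fitted downstream).

What the generator does not reproduce: the right skew of real BMI
distributions (a Gaussian latent factor gives symmetric BMI, so the
generator's obesity fractions run a little below the study's at matched
overweight fractions); nonresponse; the full two-stage sampling frame
beyond cluster random intercepts; and any device-specific TPBF error
structure. Passing tests therefore establish that the estimators recover
known truth under a faithful-but-idealized cohort, not that the study's
data-dependent numbers (its AUCs, cutoffs, posterior prevalences, odds
ratios) are reproduced — those depend on the deposited study data, which
this package deliberately does not require.

## Problem sizes and numerical choices

The test suite and the acceptance script run at desk scale, chosen so the
whole suite completes in a couple of minutes on one CPU: prevalence
recovery and interval-coverage simulations use two-test counts at
n = 50,000 (100 replicates for coverage, desk sampler presets);
sampler-vs-oracle agreement uses small counts (n ≤ 50) with 4 × 25,000
kept draws so the Monte-Carlo standard error (~0.001–0.003) sits well
inside the 0.005 agreement tolerance; logistic odds-ratio recovery uses
n = 10⁵; synthetic-cohort pipeline checks use 2,000–4,000 subjects.
Floating-point ties in the Passing–Bablok slope list are handled by exact
comparison against −1 and the K-offset rule; ROC threshold sweeps group
tied scores; all randomness flows through explicitly seeded
`numpy.random.Generator` instances (one per call, no global state), so
identical configurations reproduce byte-identical outputs.

## Known limitations

- With two tests and one population the latent-class model is never
  identified by the data alone; everything rests on the accuracy priors,
  and the posterior prevalence moves with them. This is a property of the
  design, not of the implementation.
- Thresholds are derived on the same cohort they are applied to
  (in-sample), as in the source analysis; an out-of-sample split is not
  built in.
- Wald intervals for sparse covariates (e.g. a 2% smoking flag) undercover
  slightly at cohort sizes in the low thousands; no Firth-type penalty is
  applied — instability is flagged instead.
- The cusum linearity p-value uses the asymptotic Kolmogorov tail and is
  conservative at small n.
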