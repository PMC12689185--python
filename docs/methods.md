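# Methods

This note documents the statistical models implemented in `exdose`, the
defaults they ship with, what the synthetic-data generator does and does not
emulate, and the numerical choices a user re-deriving results should know.

## Dose quantification

A prescription is a list of session phases (warm-up, main, cool-down), each
with an intensity in METs and a duration in minutes, a weekly frequency, and
— for combined training — a split of the main phase into aerobic and
resistance components. The weekly dose is

    dose = session energy × sessions/week,
    session energy = Σ_phases METs × minutes   (METs·min/week),

with combined-training session energy summed over components weighted by
their own METs and durations. Frequency counts every weekly session,
including several on one day. Progressive protocols are collapsed before
the product is taken: each period is summarised by its total session
minutes, minutes-weighted mean METs and frequency, and these three scalars
are averaged across periods weighted by period length in weeks (time
weighting, not a simple mean of listed stages).

Defaults and conventions:

* Warm-up/cool-down intensity defaults to 2.5 METs (mid light band) when a
  protocol reports their duration but not their METs; configurable.
* Dose → weekly minutes conversion rounds half up to the nearest minute.
  This convention reproduces the package's benchmark conversions (850
  METs·min/week → 121 min at 7 METs, 144 at 5.9, 283 at 3.0, 142 at 6.0;
  550 → 92 at 6.0; 350 → 32 at 11).
* Intensity bands: light 1.6–2.9, moderate 3.0–5.9, vigorous ≥6.0 METs;
  values below 1.6 get a below-light sentinel.
* BMI categories follow the Chinese WS/T 428-2013 cuts (18.5–23.9 normal,
  24.0–27.9 overweight, ≥28.0 obesity), appropriate for a literature
  dominated by Asian cohorts; underweight is a sentinel excluded from
  stratified predictions.
* Usual-care arms carry no prescription; the analysis layer maps them to
  dose 0 explicitly.

The bundled MET lookup is a small Compendium-style subset covering the
codes used in the examples and tests; a full table in the same CSV format
can be supplied by path.

## Effect preparation

The analysis outcome is the within-arm change in HbA1c (%). When a trial
reports only baseline and post summaries the change SD is imputed as
`sqrt(sd_b² + sd_p² − 2 r sd_b sd_p)` with r = 0.5 by default (sensitivity
grid 0.3/0.5/0.7); SE, 95% CI and t-statistic conversions are provided,
with CI inversion using the normal quantile (z = 1.96) rather than t.
Contrasts are mean differences against the trial's reference arm — usual
care when present, else the alphabetically first modality — with
`se² = sd_t²/n_t + sd_r²/n_r`. Multi-arm trials keep the shared-reference
structure; the reference arm's sampling variance is stored on each contrast
so network models can reconstruct the within-trial covariance. Adherence
data are completers/assigned per arm; summary odds ratios apply a 0.5
continuity correction only when a zero cell is present (the Bayesian model
needs none).

## Pairwise meta-analysis and small-study diagnostics

Per-comparison pooling is inverse-variance with REML τ² (DerSimonian–Laird
by flag) and Wald 95% CIs. REML was chosen as the contemporary default for
continuous outcomes; the boundary τ² = 0 is compared explicitly so
homogeneous data pool exactly like a fixed-effect analysis. Egger's test
regresses md/se on 1/se by OLS and tests the intercept against t(k−2);
funnel and Egger diagnostics use all versus-UC contrasts pooled across
modalities. The sensitivity suite re-runs the pooling over the r grid,
excluding high risk-of-bias trials, and with versus-UC effects re-centred
at the median covariate profile via a single weighted regression on centred
study covariates. Note that pooled CI widths are *not* monotone in the
assumed r: smaller imputed within-study variances shift variance into τ̂².

## Network meta-analysis

The NMA is a contrast-level normal hierarchical model (see README for the
likelihood). Priors are vague relative to effects of order 0.5% HbA1c:
d_k ~ N(0, 10²) and τ ~ Half-Normal(0.5). Multi-arm trials contribute a
within-trial likelihood covariance equal to the shared arm's sampling
variance and a random-effects covariance of τ²/2. All model flavours —
consistency, unrelated mean effects (one mean per observed design pair),
node-splitting (a dedicated direct-effect parameter for the split pair) and
meta-regression (a shared interaction β·(x − x̄) applied to versus-reference
contrasts) — are one design matrix handed to the same blocked Gibbs
sampler: trial effects and basic parameters have conjugate normal
conditionals (blocks of one and two contrasts vectorised in closed form), τ
is updated by slice sampling. Gibbs sampling was chosen because every
conditional except τ is exactly normal; it is orders of magnitude faster
here than a generic gradient sampler and exactly reproducible.

Conventions and diagnostics:

* Defaults: 4 chains × 2000 post-warmup draws after 1000 warmup; seeds are
  explicit everywhere. Convergence warnings fire when split-chain R̂ > 1.01
  or ESS < 400.
* DIC = mean residual deviance + pD with pD = mean deviance − deviance at
  the posterior-mean trial effects.
* Node-splitting reports p = 2·min(P(diff>0), P(diff<0)); a comparison is
  splittable when it has direct trials and the remaining evidence still
  connects the pair.
* SUCRA is computed per draw as (K − rank)/(K − 1) with the reference at 0;
  the across-treatment mean is 0.5 by arithmetic identity.
* Prediction intervals widen each draw by N(0, τ_draw); with τ → 0 they
  collapse to the credible interval exactly.
* τ² bands: <0.04 low, ≤0.16 low-moderate, ≤0.36 moderate-high, >0.36 high.
* Adherence: binomial likelihood, logit link, one intercept per trial
  (N(0, 3²)) and a log-OR per modality versus UC (N(0, 2²)), sampled with
  the emcee ensemble sampler; weakly-informative priors on the logit scale
  avoid the degenerate tails a N(0, 10²) prior would allow.

## Dose-response model

Arm-level mean changes are modelled as

    y_i ~ N(α_study(i) + B(dose_i)β + γ·(bmi_i − b̄) + (B(dose_i)·(bmi_i − b̄))η,
            se_i² + σ²),

where B is a restricted cubic spline basis (Harrell truncated-power form,
4 knots at the 5th/35th/65th/95th percentiles of nonzero doses, linear
tails, columns scaled by the squared boundary span). Study intercepts are
exchangeable N(0, σ_α²); priors are β, γ, η ~ N(0, 10²), σ ~ Half-Normal(0.3),
σ_α ~ Half-Normal(0.5). Because every basis column vanishes at dose 0, the
MCFB curve is anchored to exactly 0 at zero dose for every BMI, with the α
and γ terms cancelling in the difference — predictions never depend on how
trial-level nuisance means are estimated.

Threshold definitions on the prediction grid (0–1500 in steps of 50, all
reported doses being multiples of 50): optimal = argmin of the posterior
mean (ties to the lowest dose); minimal statistical = smallest positive
grid dose whose 95% interval upper bound is below 0; minimal clinical =
smallest whose upper bound is ≤ −0.2 (the MCID), so the entire interval
lies beyond the clinically meaningful cut. By construction minimal
statistical ≤ minimal clinical whenever both exist. Stratified curves use
representative BMIs of 22 / 26 / 29.5 for normal / overweight / obesity.
Doses beyond the maximum observed dose are flagged as extrapolated, not
refused.

The intensity model replaces the dose spline by additive splines in weekly
minutes and METs (falling back to a linear duration term when durations are
nearly constant) and sweeps intensity at a fixed weekly duration of 150
minutes, reporting the smallest intensity whose interval excludes 0 and the
smallest whose posterior mean reaches the MCID, plus band summaries at 2.25
/ 4.5 / 7.0 METs. Per-modality curves share the global spline shape and add
a modality-specific linear dose adjustment (base = best-represented
modality); a shared shape is the only identifiable choice when most
modalities contribute a handful of trials, and the linear adjustment keeps
every modality curve anchored and continuous at dose 0. Modalities with
fewer than two trials are excluded with a warning.

## Minimally contextualised classification

Effect flags are deterministic functions of an interval and the MCID:
upper bound ≥ 0 → not significant; < 0 but above −0.2 → statistical only;
≤ −0.2 → clinical and statistical. Certainty ratings are inputs (from a
CINeMA-style appraisal), grouped into high (high/moderate) and low
(low/very-low) blocks. Within a block, an intervention is "among the most
effective" when its interval excludes 0, its point estimate reaches the
MCID, and its SUCRA is at least 0.5; significant interventions short of
that are "intermediately effective"; intervals covering 0 are "least
effective". The SUCRA condition is part of the category-2 rule because a
point-estimate cut alone cannot separate borderline cases; it is an
interpretive choice, stated here so users can re-classify with their own
rule from the persisted effect table.

## Synthetic-data generator

The generator emulates: a 39-trial, six-node network (≈3,400–3,700
participants; arm sizes log-normal with median assigned 42, completion
~85% with per-modality odds multipliers), 80% two-arm and 20% three-arm
trials, 85% usual-care-anchored; study-mean BMI ~ N(26.85, 2.5²) truncated
to 20–34; change outcomes with within-arm SD ~0.45% and contrast-level
heterogeneity τ = 0.126 (τ² = 0.016) including the multi-arm τ²/2
correlation; 70% of arms report change summaries directly, the rest
baseline/post pairs that are exactly consistent with r = 0.5; risk-of-bias
ratings 18/69/13% low/some-concerns/high.

The dose-response truth is an Emax (Hill) curve with a quadratic
post-plateau upturn, deliberately not a spline so spline-recovery tests are
not circular:

    E(d, b) = (−0.35 − 0.01·(b − 26.85)) · d⁴/(500⁴ + d⁴)
              + 0.05·((min(d, 1150) − 850)/100)²  for d > 850.

This gives ≈ −0.32% at the 850 METs·min/week plateau for the average BMI,
point crossings of the MCID near 550–600 METs·min/week, loss of benefit by
~1100, and a bounded mild harm (≤ +0.11%) at extreme doses — the harm
saturates at 1150, the top of the generated dose range, because a flat
capped region inside the data range is not representable by a 4-knot
spline and would corrupt recovery tests for reasons unrelated to the
estimators. The steep saturation (h = 4) makes the optimum identifiable at
this noise level; a shallower knee leaves the left shoulder flat within
~0.02% over 250 METs·min/week, which no estimator can localise to ±100.
Prescriptions are drawn so that the dose computed by the dose module from
the stored phases reproduces the drawn dose exactly. Three effect models
link modality and dose: fixed modality effects (used for NMA recovery
tests), pure curve effects (dose-response recovery), and a combined model
scaling each modality's effect along the curve (the end-to-end default).

What the generator does *not* emulate: publication bias and small-study
effects (funnels are symmetric by construction), missing or indirectly
reported SDs (SE/CI/t conversions are exercised by unit tests only),
design inconsistency (injected explicitly in node-split tests), skewed or
rounded outcome scales, and correlation between prescribed dose and trial
quality. Passing recovery tests therefore shows the estimators work under
the assumed data-generating structure, not that real extraction sheets are
free of these complications.

A note on power: with the default BMI interaction of −0.01 %/(kg/m²), the
between-stratum curve separation is comparable to the fitted-curve
uncertainty at 39 trials, and the obesity-versus-normal ordering of
minimal clinical doses is recovered in only ~65–85% of replicates — the
test suite verifies the ordering mechanism at −0.025, where the design has
adequate power, and the acceptance script reports the default-strength
rate as a descriptive quantity.

## Problem sizes and runtime

Recovery batteries use 20 seeded replicates with 2 chains × 1200 post-warmup
draws (NMA fits take ~1–2 s each with the Gibbs sampler; dose-response fits
~1 s), chosen so the full test suite and the acceptance script each finish
in a few minutes on one CPU while keeping Monte-Carlo error well below the
decision margins. Production analyses default to 4 chains × 2000 draws.

## Known limitations

* The contrast-level NMA cannot use arm-level likelihoods or model
  arm-specific variances beyond the shared-arm covariance.
* Node-splitting treats every contrast whose pair equals the split
  comparison as direct, the common approximation for multi-arm trials.
* The per-modality dose-response shares one spline shape across
  modalities; a modality whose true curve differs in shape (not scale)
  from the pooled curve will be misfit.
* The covariate-median sensitivity analysis adjusts versus-UC effects with
  a single shared regression, not per-comparison meta-regressions.
* Egger's test on versus-UC contrasts pooled across modalities ignores
  comparison structure (a comparison-adjusted funnel is out of scope).
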