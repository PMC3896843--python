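# Methods

`bfequity` estimates breastfeeding-indicator prevalence for a panel of
countries over 1990–2010, disaggregates prevalence by asset-based wealth
quintile, and converts prevalence into attributable child-disease burden by
comparative risk assessment. Because the survey microdata such analyses rest
on are not redistributable, the package ships a synthetic-world generator
with full ground truth; every claim the test suite makes is a statement
about recovering that truth.

## Indicators and scales

Six indicators are modelled: breastfeeding initiation within 24 hours of
birth; exclusive, predominant and partial breastfeeding among children under
six months; and continued breastfeeding at 6–11 and 12–23 months. All
modelling happens on the logit scale: prevalences are bounded in (0, 1) and
survey noise is closer to homoscedastic after the transform. Observed
proportions of exactly 0 or 1 are clamped to `[1/(4n), 1 − 1/(4n)]` before
the transform.

The three under-six categories are never modelled directly. Instead the
nested cumulative quantities

    exclusive ⊆ exclusive ∪ predominant ⊆ any breastfeeding

are each modelled as separate streams and differenced per posterior draw
(after a monotone rearrangement that repairs rare order violations between
independently sampled draws). This guarantees, draw by draw, non-negative
exclusive/predominant/partial/none shares that sum to one — a structural
guarantee rather than a post-hoc rescaling, so marginal fits are not
distorted asymmetrically.

## Synthetic world

The default ("desk") world has 3 super-regions × 2 regions × 4 countries =
24 countries observed 1990–2010; a 137-country paper-scale preset exists but
is not exercised by the default test run (desk scale keeps the full
replicate studies within interactive runtimes). Stream logits are linear in
time: country-year covariates (female education, log GDP per capita, child
underweight, total fertility) are themselves linear in time with
region-nested country intercepts and slopes, and enter the prevalence logits
with fixed loadings (education +0.10, ln GDP −0.20, underweight −1.0, TFR
+0.10 per unit). Nested random intercepts (super-region sd 0.20, region
0.25, country 0.30) plus small stream-specific offsets (sd 0.10) and random
country trends (sd 0.015/yr) supply the spatial correlation the stage-2
smoother exploits. Cumulative ordering is enforced with a minimum logit gap
of 0.05, which essentially never binds under these defaults.

Surveys: Poisson(5) surveys per country at uniform years, each drawing a
single multinomial sample of 3,000 children over the four under-six
categories (so reported categories are internally coherent) and independent
binomials for the other indicators. 15% of surveys are subnational, biased
by +0.3 logits; 20% are non-standard-definition, reported as
`expit(logit(p) − 0.4)` for every indicator. Half of the non-standard
surveys also yield a standard-definition re-analysis from an independent
sample of the same population — the DHS-microdata situation that makes the
crosswalk estimable. The pure-binomial design ignores survey design effects
(clustered sampling, weights); passing tests therefore say nothing about
design-effect misspecification in real data, only about the estimators'
behavior under known sampling noise, bias and distortion.

Burden envelopes: deaths = births × a country-specific cause/age rate
declining 1–3%/yr; DALYs = deaths × 86 YLL per under-five death × (1 + a
2–8% morbidity share). Rates are drawn independently of population, making
the table exactly linear in population (a tested invariant).

All randomness flows from one root seed through named CRC32-keyed
substreams, so components regenerate independently and runs are bitwise
reproducible.

## Harmonization (definition crosswalk)

Non-standard estimates are corrected by an additive logit shift per
indicator, estimated from country-years observed under both definitions:
the shift is the precision-weighted mean of paired logit differences
(weights = inverse delta-method variance of each difference), and its
standard error is the weighted empirical spread of the differences — a
perfectly systematic distortion yields se = 0. Corrected observations get
`shift_se²` added to their logit-scale variance and are re-flagged, making
the operation idempotent. Indicators with fewer than two pairs get no
correction; their non-standard points are dropped with a logged reason
rather than passed through uncorrected. Whether real corrections should be
indicator-specific or pooled is unknowable from the outside; the module
implements indicator-specific pooled shifts.

## Three-stage prevalence model

**Stage 1 — covariate regression.** OLS of logit prevalence on the four
covariates plus a subnational-survey indicator that absorbs the mean
representativeness bias; the surface predicted for every country-year is
the national one (indicator = 0). A covariate-screening report (Pearson r of
each candidate with logit prevalence, ranked by |r|) is produced for
inspection, but the four covariates are used regardless — the model is
deliberately not a covariate-selection exercise.

Coefficient *intervals* are a separate concern from the predicted surface:
with ~24 countries, country-level regressors and three levels of spatial
clustering, naive (even cluster-robust) OLS intervals undercover badly. When
a geography table is supplied, intervals come from a REML linear mixed model
with super-region/region/country random intercepts and a country random
trend, referenced to a t distribution on (number of regions − 1) degrees of
freedom — a deliberately conservative small-cluster choice. Optimizer
fallbacks (L-BFGS → BFGS → Powell → CG, then a simplified variance
structure, then cluster-robust OLS) keep the path total.

**Stage 2 — spatio-temporal residual smoothing.** Stage-1 residuals are
smoothed with separable weights. Time: tricube, `(1 − (|Δt|/b)³)³` with
bandwidth b = 10 years. Space: 1 / 0.5 / 0.25 for same country / region /
super-region. Within each source country, whenever both national and
subnational residuals carry positive time weight, their masses are
renormalized to 90% / 10% — subnational data inform but cannot dominate.
Across countries the prediction is `Σ sⱼ ρⱼ(t) / max(1, Σ sⱼ)`: residual
signal borrowed only from neighbours is attenuated toward zero by the space
weight rather than adopted outright, so a data-free country in a region with
residual +0.6 receives +0.3, not +0.6. The smoothed residual is added to the
stage-1 surface. All kernel constants are config-exposed artifact choices.

**Stage 3 — Gaussian-process regression.** Per country and stream, a GP
over years on the logit scale with the stage-1+2 surface as prior mean and a
Matérn 5/2 kernel (length-scale 10 years). The kernel amplitude is estimated
per region as 1.4826 × the median absolute deviation of observation
residuals around the prior (floored at 0.10, global fallback below five
regional observations). Observation noise is the delta-method logit sampling
variance plus any crosswalk inflation, plus a non-sampling floor of 5×10⁻⁴
(logit-sd ≈ 0.022) for all points and an extra 0.09 (sd 0.3) for
subnational points, whose representativeness bias the model cannot observe.
The floor was set so that the posterior's claimed uncertainty matches its
actual error under the generator's survey noise — small relative to the
kernel amplitude, keeping the data weighted over the prior. The posterior is
sampled exactly (Cholesky, with jitter escalation from 10⁻¹⁰ before
failing); 1,000 draws per country-year are transformed back to proportions,
and means and 95% intervals are computed from the draws themselves.
Countries with no data receive the prior mean and kernel-width uncertainty,
so the output grid is always complete.

Calibration, measured on 100 replicate desk worlds (country-years within
three years of an observation), sits around 98–99% coverage for the nominal
95% intervals — slightly conservative, driven by the non-sampling floor —
with mean absolute error under 1 percentage point.

## Wealth quintiles

Household permanent income is a latent standard-normal variable measured by
binary asset indicators: asset k is owned with probability
`Φ(d_k (y − c_k))`. Asset selection: constant columns and exact duplicates
are dropped (duplicates would double-count one signal), reverse goods —
ownership decreasing in the first principal axis of the asset matrix — are
sign-flipped, and the axis loading of every retained asset is reported.
Cutpoints initialize at `Φ⁻¹(1 − ownership rate)` with unit
discriminations, then alternate: households to their posterior modes
(vectorized Newton on a strictly concave log-posterior), assets to per-asset
probit fits of ownership on income. Two stabilizations stop the alternation
from running away: incomes are re-standardized before each probit pass
(the model pins the latent scale), and discriminations are capped at 3 —
probit slopes on estimated incomes are inflated because estimation error is
correlated with the indicators. Ten rounds or relative change < 10⁻⁴.

The posterior *mode* (not mean) is reported: it is deterministic, fast, and
only income ranks feed the quintile split, which is a stable-order division
into five near-equal groups (within one household). On default worlds this
recovers Spearman ≈ 0.89 against true income, ≈ 58% exact and ≈ 95%
adjacent quintile agreement (chance: 20%).

Quintile trend comparison: countries with at least three survey years get
per-quintile WLS slopes (weights 1/se²) and an F-test of the year×quintile
interaction in the pooled model. The verdict is "uniform" unless the test is
significant at 0.05 **and** the slope spread (max − min) reaches 0.005/yr —
half a percentage point per year, i.e. 5 points per decade, a practical
floor that keeps trivially small but statistically detectable differences
from being reported as inequality signals. Otherwise the two largest slopes
locate the verdict: quintiles {4,5} → top-concentrated, {1,2} →
bottom-concentrated, else mixed. The original comparison of such trends was
visual; this explicit test is the package's testable stand-in.

## Attributable burden

For each country-year, age band and outcome, the population attributable
fraction is the exact categorical formula

    PAF = (Σᵢ Pᵢ RRᵢ − Σᵢ P′ᵢ RRᵢ) / (Σᵢ Pᵢ RRᵢ)

with the theoretical-minimum-risk counterfactual P′ degenerate at the
reference category (100% exclusive under six months; 100% continued at
6–23 months). Exposure categories: exclusive/predominant/partial/none for
0–5 months (the coherent composition draws); continued/discontinued for
6–23 months, where continued is the duration-weighted mix (1/3, 2/3) of the
6–11 and 12–23 indicators. Relative risks come from the packaged
meta-analytic table; where only a mortality effect exists, it is applied
equally to incidence (so discontinued-breastfeeding diarrhea incidence
carries the mortality RR of 2.18). Structural exclusions are enforced, not
filtered: no effect exists for (discontinued, pneumonia) — so the
6–23-month band produces no pneumonia cells — and timely initiation carries
no burden at all; tables containing either row are rejected at load.

RR uncertainty is propagated with log-normal draws whose median is the
point estimate and whose 2.5th/97.5th percentiles match the published CI
(`σ = ln(upper/lower)/(2·1.96)`); intervals crossing 1 are sampled as
published, without truncation, so negative PAF draws propagate honestly.
Prevalence and RR draws are paired by index (1,000 each); draws are sampled
independently per (category, outcome, metric) triple. Attributable deaths =
mortality-PAF × background deaths, per draw. DALYs are split: YLL = deaths ×
86 takes the mortality PAF, the YLD remainder takes the incidence PAF.
Aggregation always happens at draw level, grouped never across metrics; risk
rankings are dense, descending, with ties broken by risk name and flagged.

## Numerical and degenerate-input conventions

Logit clamping at 1/(4n); GP jitter escalation 10⁻¹⁰ → 10⁻⁴ before a hard
error; quintile ties broken by stable input order; households with every
asset missing are excluded from quintiles with a logged count; a survey
missing any of the three under-six categories contributes nothing to the
cumulative streams; an empty residual set yields a zero stage-2 surface with
a warning.

## Limitations

The generator's surveys are simple multinomial/binomial draws — no design
effects, no seasonality, no age-composition drift — so recovery results
bound estimator behavior only under those idealized error structures. The
stage-2 kernel constants and GP hyperparameters are artifact defaults, not
estimated from data. The income model is single-survey (no pooled
multi-country hierarchy), and the prior-construction details of the
original two-step income method are underdetermined in the literature; the
standard-normal prior refined by the asset likelihood is one consistent
reading. Whether initiation should be modelled jointly with the under-six
composition is unknown; it is modelled independently here.
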