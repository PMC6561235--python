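# Methods

## The task model

One session is a 40-minute clock over serial offer encounters. Galleries
cycle in a fixed order of four. Each offer presents three integer delays in
[3, 30] s: identical on non-risky trials, equally spaced (`low`,
`low + spread/2`, `low + spread`) on risky ones. Risky offers arise with
probability `risky_fraction` (default 0.6); the spread is drawn from
{4, 8, 12, 16, 20} s (even values only, so the mid delay is an integer) and
the low delay uniformly over its feasible range. The generation law for
risky offers is a package design choice — the paradigm constrains only the
range, integer mids, and the presence of a spread. On a stay, the realized
delay is drawn from {low, mid, high} with equal probability (subjects are
never told these probabilities; the probability vector is configurable for
sensitivity analyses); the low delay is framed *good*, the high delay
*bad*. On non-risky trials the known delay is delivered and framed
*nonrisk*. Skips reveal nothing.

Clock accounting per trial: decision RT, plus (on stays) the realized
delay, a 4 s video, and 1 s of rating input, plus a travel task of
5 clicks × log-normal per-click latency (median 0.6 s). Rating-input and
travel durations are not reported for the original paradigm; these defaults
produce ≈180 encounters per 40-minute session. A new trial starts whenever
the clock has not expired, so the last trial may overrun it.

## The generative subject

Each synthetic subject carries ground truth used later for recovery:

| parameter | meaning | default |
| --- | --- | --- |
| τ_g | per-gallery delay threshold (s) | Normal(16.5, 4), clipped to [4, 29] |
| β | choice inverse temperature (logit/s) | 0.2 (SD 0.06) |
| γ₀ | post-loss framing shift (logit) | −0.6 |
| γ_E | trait link: γᵢ = γ₀ + γ_E·Eᵢ | 0.8 |
| E | latent externalizing | Normal(0, 1) |
| η | value × loss interaction (logit/s) | 0.05 |
| ratings | ordered-latent: μ_g + aV + b·bad + c·V·bad + ε | a=0.02, b=0.3, c=0.02, σ_r=1, cutpoints (−1.2, 0, 1.2) |
| RT | log-normal, post-loss slowing δ | α₀=ln 1.5, δ=0.15, σ=0.35 |
| ln k (delay) | hyperbolic discount rate, per day | Normal(−5.26, 2.05) |
| ln h (probability) | per unit odds-against | Normal(0.28, 0.84) |

Choices are logistic in β(τ_g − d) with d the offer's mid delay; after a
risky loss the logit shifts by γᵢ + η·V_prev. Ratings discretize a latent
normal at fixed cutpoints into 1–4. Questionnaire items follow a
two-parameter logistic item-response model, P(endorse) =
logistic(a_f·E + b_f·F_f − c_j), with 40 disinhibition, 36 substance-abuse
(6 each for alcohol/marijuana/drug problems), and 24 callous-aggression
items; problem items carry difficulties of 3.6–4.4 so most subjects endorse
none, reproducing the zero inflation the retention rule (≥1 endorsed item)
exists for (≈10–20% retained per subscale). Discounting choices are
softmax (sharpness 3 $⁻¹) over hyperbolically discounted values on a
titration grid of $0.50–$10 in $0.50 steps against a fixed $10 reward
(seven delays 1–180 days; six probabilities 0.95–0.10).

Two default choices deserve emphasis:

- **Equal gallery threshold means.** Gallery preferences vary per subject
  (SD 4 s) but share one population mean. Population-level gallery ordering
  combined with the deterministic gallery cycle would let the previous
  trial's value predict the *next* gallery's threshold, biasing the
  sequential choice models' framing contrast even under a null generator;
  subject-specific preference order is also the more realistic reading of
  "different preferences per gallery".
- **Flat choice noise (β = 0.2).** Defaults are calibrated so group and
  individual-difference effects are detectable in a cohort of ~100 subjects
  with 40-minute sessions; sharper choices leave too few informative trials
  around threshold for per-subject framing contrasts. Tests that
  characterize threshold recovery per se set β = 0.5 explicitly.

E enters only the choice pathway by default (γ_E > 0, zero rating link),
mirroring the dissociation the paradigm probes; both links are config.

## Threshold estimation

The step fit minimizes SSE between 0/1 choices and 1 − H(delay − T) over
the candidate set {3, midpoints of adjacent unique presented delays, 30};
ties return the midpoint of the tied candidate span (unbiased between the
last stay and first skip). All-stay galleries return the maximum presented
delay, all-skip the minimum — the step estimator's graceful handling of
extreme cases. Fits use risky trials only, represented by their mid delay
(a switch admits non-risky trials). Leave-one-out vectors refit the gallery
with each risky trial excluded; non-risky trials and the subject-level
gallery threshold use the vector mean. Galleries with fewer than two fit
trials are flagged and left absent rather than guessed.

## Model suite

Continuous outcomes (centered ratings, log RT) use linear mixed models
(statsmodels `MixedLM`, REML) with a subject random intercept, or a
correlated random intercept + slope of previous value in the matched
follow-ups. Binary outcomes use logistic mixed models fit by maximum
likelihood through lme4's `glmer` (Rscript subprocess, bobyqa, Wald
p-values); if R is unavailable a statsmodels Laplace approximation stands
in and the backend is recorded on the result. The Laplace route's Wald test
is conservative when the random-intercept variance sits near zero, which is
why the likelihood route is the default. Random slopes in the binary
backend are independent components (`(0 + V|subject)`), the closest
specification both backends support.

Row filters per family: primary choice = previous risky stay and current
risky offer; ratings = risky stays, modeled against the *current* trial's
value and framing (the lag-1 variant backs the matched rating follow-ups);
RT = trials following a risky stay; global models = all trials (choice) or
all stays (rating); the integrated model adds the previous trial's centered
rating and uses a three-level framing code (good/bad/nonrisk, reference
bad) with rating × outcome and value × rating interactions. Ratings are
mean-centered within subject × gallery; consumption counts stays strictly
before the trial. Matched follow-ups pair each bad-outcome trial greedily
with the nearest unused comparison trial within ±0.5 s of previous value,
per subject (tolerance configurable; the pairing rule is a package choice —
only "matched by actual value" is inherited). Within-class simple slopes
accompany every interaction. BH step-up FDR is applied within each model's
fixed effects (the table layout implies per-model adjustment); the six
trait follow-up correlations get their own BH family.

## Individual differences

Per-subject choice models are **Firth bias-reduced logistic** fits of
`stay ~ V_prev + outcome_prev`: ordinary ML on a few dozen trials is
heavy-tailed and explodes under quasi-separation, which wrecks
between-subject correlations; Firth's penalized score keeps every estimate
finite with negligible bias. Subjects lacking both a bad and a good prior
outcome remain flagged and excluded. Rating models are OLS on the same
terms (current-trial framing by default, lag-1 by config). ESI totals are
summed and transformed ln(total + 1) (defined at zero; base/offset are
package choices). Robust correlations are percentage-bend (bend 0.2,
via pingouin) on least-squares residuals after regressing out age, sex,
and dummy-coded ethnicity; one-tailed p-values halve the two-tailed value
when the sign matches the expected positive direction. Subscale
correlations require ≥8 retained subjects.

## Discounting

Indifference points are the midpoint between the largest sooner amount
passed over and the smallest accepted; censored or non-monotone runs are
flagged (non-monotone runs use the enclosing switch envelope). Hyperbolic
fits minimize SSE over ln k in [−15, 5] (bounded scalar minimization), so
k stays positive; R² is computed on the points. A linear $0.50 titration
grid replaces a geometric one so indifference points resolve to ±$0.25
across the whole range. The nonsystematic screen flags any point rising
more than 20% of the delayed amount above its predecessor (C1) and
profiles whose total drop is under 10% (C2); both thresholds are config.
The probability task's published parameter is treated as ln h (the raw-h
reading prices $10 at 90% chance near $9.70, inconsistent with the
published ≈$8.75, so the log reading is forced).

## Power

The a-priori sample-size computation uses Fisher's exact density of the
sample correlation under bivariate normality (Gauss hypergeometric form),
integrating the tail beyond the two-sided t critical value; the smallest n
with power ≥ 0.80 for ρ = 0.3 at α = 0.05 is 84.

## What the synthetic cohorts do and do not show

Passing recovery tests shows the estimators retrieve the parameters of
data generated by the matching model family at realistic sizes (100–105
subjects, ~180 encounters each; replicate counts of 20 for sign-recovery
suites, 60 for the null rejection rate, where a coarser estimate would be
dominated by binomial noise). Real sessions differ in ways the generator
deliberately omits: no session-level drift (satiation or fatigue), no
sequential dependence beyond lag 1, no rating drift-diffusion or RT
autocorrelation, questionnaire items without real psychometric norms, and
demographics independent of behavior. Group-level logit coefficients are
attenuated relative to the generative γ because the current offer's value
is (by design of the analysis model) an omitted covariate — the
non-collapsibility of logistic regression, shared with any real analysis
of this form.

## Known limitations

- The glmer subprocess adds per-fit overhead (~2–4 s); large suites are
  minutes, not seconds.
- Threshold recovery degrades for subjects whose thresholds sit near the
  delay bounds (estimates clip at the extreme presented delays).
- The travel/rating time defaults are unvalidated against human timing
  data; they matter only through the trial count per session.
- Mid-vs-good contrasts inherit a small model-misspecification artifact
  when η ≠ 0 (the analysis model fits one pooled value slope); bad-vs-good
  contrasts, the quantities of interest, are unaffected under the null.
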