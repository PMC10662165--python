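# Methods

`chronosynd` implements a complete chronotype–personality inference pipeline
for repeatedly assayed, acoustically tracked fish: behavioural metrics from
arena trajectories, PCA trait scores, chronotype decoding from detection time
series with a zero-inflated-Poisson hidden Markov model (ZIP-HMM),
mixed-model repeatability, and syndrome detection via between-/within-
individual correlation decomposition.  This note records the models, the
defaults and why they were chosen, the numerical decisions, and what the
synthetic-data tests do and do not demonstrate.

## Study system and data model

The motivating system is a sand-burying wrasse (the pearly razorfish,
*Xyrichtys novacula*) whose acoustic transmitter is silenced whenever the
fish buries to rest.  Detection counts per time bin therefore alternate
between a near-silent Rest regime and an Active regime whose counts are
over-dispersed toward zero (tag collisions, detection dropouts).  Laboratory
personality assays film each fish in its arena and reduce the video to a 2-D
position six times per minute, with undetected frames meaning the fish is in
the sand.

## Arena trajectory metrics

* **Per-minute reduction.**  The six frames of each minute are reduced to one
  representative position, the component-wise median of the detected frames.
  The median resists single-frame detector glitches; minutes with no detected
  frame are absent.  Cumulative distance is then the sum of Euclidean gaps
  between consecutive available minute positions, with buried gaps bridged by
  one straight segment — the cheapest reading of "cumulative distance between
  consecutive positions every minute", pinned by tests.
* **Utilization areas.**  `Area` (95%) and `CoreArea` (50%) are the p-volume
  contour areas of a bivariate Gaussian kernel density with the reference
  bandwidth h = sigma_hat * n^(-1/6) per axis (sigma_hat = mean of the axis
  SDs), evaluated on a 200x200 grid padded by 3h; grid cells are accumulated
  in decreasing density order until they hold mass p.  Against the closed
  form for a circular Gaussian (area = pi * 5.991 * sigma^2) the estimator is
  within 10% at n = 5000.
* **Circular statistics.**  Turning angles between successive displacement
  vectors are signed (counter-clockwise positive, camera frame x right / y
  up) and wrapped to (-pi, pi]; zero-length displacements are skipped.
  `MeanAngle` is the argument of the mean resultant vector; `KappaAngle` is
  the maximum-likelihood Von Mises concentration via the Best–Fisher
  piecewise inverse of A1(kappa) = I1/I0, with resultant length 1 mapped to a
  documented cap (1e6) and 0 to kappa = 0.
* **Time-based metrics.**  `TimeOut` = detected-frame fraction x test
  duration; `TimeToy` applies the same scaling to frames within 6 cm of the
  novel object, so `TimeToy <= TimeOut` by construction.  Boldness is the
  emergence latency after a simulated predator attack: 0 if the fish never
  buried, the observed time if it emerged, and the window end with a
  `censored` flag if it never emerged (latency is never silently truncated).
* **Exposure filter.**  All metrics of a trial are missing unless the fish
  was detected outside the sand for at least 20 s, a pure function of the
  detected-frame count.

## Trait scores

Metrics of one trait (per trial observation, pooled across individuals and
days) are z-scored with the sample (n-1) SD and collapsed to the first
principal component of their covariance (equivalently, correlation) matrix.
Scores are oriented so an anchor metric loads positively — TimeOut for
exploration, Distance for activity, Bites for aggressiveness — making
"higher = more of the trait"; boldness is a single raw metric and is not
PCA-scored.  Latency and agonistic counts contain legitimate zeros, so the
log transform used for boldness and aggressiveness responses is log(1+x).
The condition index is predicted allometric weight a*L^b over fresh weight,
exactly in that orientation (a config switch provides the conventional
inverse); the length–weight parameters are configurable inputs with
placeholder defaults, as they are population-specific.

## Chronotype decoding

Detections are binned into 5-min, left-closed/right-open intervals aligned to
local midnight (binning conserves counts exactly and is invariant to where a
detection falls inside a bin).  A two-state HMM with ZIP emissions in both
states is fitted to each individual's series separately — tag power and
detectability differ among fish — by Baum–Welch EM with an inner latent-zero
E-step, multi-start (default 5 seeded restarts, a two-means style split plus
jittered variants), convergence at |delta loglik| < 1e-6.  The
log-likelihood is non-decreasing up to 1e-8 per iteration; the forward
recursion is checked against brute-force path enumeration for T <= 8.  The
Rest state typically collapses toward zero mean; labels are fixed by expected
count, Active = larger (1-pi_zero)*lambda.  Decoding is global (Viterbi) by
default with posterior (local) decoding behind a flag.

Per local day, awakening = start of the first Active bin preceded by at least
one Rest bin since midnight, minus sunrise; rest onset = start of the first
Rest bin after the day's last Active bin, minus sunset.  Days without both
transitions yield no observation.  Because decoded onsets are bin-aligned,
recovery is assessed against the bin-aligned truth (the first truly-Active
bin), with a one-bin (5-min) tolerance; at the default emission rates
(lambda = 4, pi_zero = 0.2, silent rest) >= 90% of individual-days decode
within one bin.  Solar times are an input table; a NOAA-style helper can
compute them from coordinates as a convenience.  All timestamps are naive
local times; day boundary is local midnight.

## Mixed models and repeatability

Trait and chronotype responses are modelled as Gaussian random-intercept
LMMs, individuals (optionally) nested in experimental batches, fixed
covariates z-scaled.  The engine profiles beta and the residual variance out
of the (RE)ML criterion and optimises the variance ratios numerically via the
Woodbury identity, making each fit ~milliseconds so that parametric-bootstrap
confidence intervals (1000 refits by default) are practical; it reproduces
lme4-style REML components (validated against an independent implementation
to ~1e-4 in the tests).  Conventions:

* ML deviances for AIC comparisons of fixed structures; REML for reported
  variance components; k = fixed coefficients + variance components +
  residual.
* Variance components bounded at 0 (no negative-variance parameterisation).
* Adjusted repeatability R = V_ind0 / (V_ind0 + V_e0); batch variance is
  excluded from the denominator, matching the estimand's definition.  CI by
  percentile parametric bootstrap; significance requires the constrained
  model (individual term removed) to carry an AIC more than 2 points above
  the full model.  Both AICs are reported explicitly.
* Stepwise reduction is bidirectional with a 2-point parsimony cut-off: a
  single-term drop is accepted when it worsens AIC by at most 2, an addition
  only when it improves AIC by more than 2 (the simpler of two nested models
  within 2 points is preferred).  A strict "only moves that lower AIC by
  more than 2" rule would be inert for drops — removing a term changes AIC
  by 2 - LRT with LRT >= 0 — and could never reduce a model.  Moves are
  scanned deterministically (lowest resulting AIC; drops before adds;
  lexicographic term order).
* Individual behavioural scores are the conditional modes (BLUPs) of the
  individual random intercepts given the fitted parameters; their SDs come
  from simulated draws of the conditional distribution, mirroring
  posterior-simulation practice (fixed-effect uncertainty is not propagated,
  a known approximation).

## Syndrome decomposition

For each trait pair a bivariate Gaussian random-intercept model is sampled by
a conjugate Gibbs sampler: normal updates for fixed effects and individual
effects, inverse-Wishart updates for the 2x2 individual and residual
covariance matrices.  Responses are standardised to unit variance internally
(correlations are scale-invariant), so the weak prior is exactly
IW(nu = 3, scale = 0.5 I) — half the phenotypic variance — with diffuse
normal (variance 1e8) fixed effects; halving/doubling the prior scale moves
recovered r_ind by < 0.05 at n = 100x4.  Default chain 13,000 iterations,
3,000 burn-in, thinning 10 (1,000 stored draws); all configurable.  Per draw,
r_ind, r_e and r_phe are computed from the individual, residual and summed
matrices; summaries are the posterior mean and 2.5/97.5 percentiles, and a
pair is a syndrome when the r_ind interval excludes zero.  Calibration note:
at n = 50 individuals x 4 trials the equal-tailed 95% credible interval for
r_ind = 0 has measured frequentist coverage of about 90% (invariant to chain
length once ~1000 draws are stored); users should read the intervals as
credible, not exact confidence, intervals at such sample sizes.

The chronotype–personality association refits each trait's LMM with the
standardised awakening and rest-onset individual scores as additional fixed
covariates; standardised slopes with 2.5/97.5% CIs are reported and labelled
as slopes (not correlations).  Score SDs are carried in the output for
sensitivity reporting but not propagated into the fit — a flagged
limitation.  Boldness is latency-coded (lower = bolder) and no sign flip is
applied.

## Synthetic data: what it emulates, and what it does not

The generators define the study conditions:

* **Chronotype series** (`ChronoSimConfig`): each individual carries latent
  wake/rest offsets a_i ~ N(mu_wake, sd_between^2) relative to
  sunrise/sunset; each day adds environmental shifts beta.x_day and daily
  noise.  Defaults: 30 fish, 14 days, wake +20 +/- 30 (between) +/- 10
  (within) min, rest -10 min before sunset with the same spreads, sunrise
  07:00 / sunset 19:00 (the laboratory light regime), lambda_active = 4
  detections per 5-min bin with pi_zero = 0.2, silent rest (Poisson(0),
  structural silence of a buried fish).  The detection rate of an active
  fish is a free choice — field rates per 5-min bin are not published for
  this system — set once to a mid-range plausible value.  A free
  Markov-switching mode (`gen_markov_series`) provides decoder stress-tests
  with exact transition-matrix ground truth.  Configs whose schedules would
  invert (rest before wake) with probability > 1% are rejected.
* **Trial tables** (`TraitSimConfig`): multi-trait observations with
  specified between-individual (Sigma_ind) and within-individual (Sigma_e)
  covariance, batch intercepts (12 fish per batch, mirroring the arena
  capacity), body size 15.30 +/- 2.43 cm as in the study cohort, condition
  from an allometric weight with noise.
* **Trajectories** (`TrajSimConfig`): correlated random walk (Von Mises
  turns, exponential steps) reflected at the walls of an 80 x 40 cm frontal
  plane, with per-minute burial-bout switching; buried frames are
  undetected.  The 80 x 40 default is a plausible frontal plane for a 120-L
  arena; any positive dimensions are accepted.
* **Joint datasets** couple the wild and laboratory layers by shifting the
  aggressiveness intercepts by coupling_beta x (wake offset - mean),
  creating a known chronotype–aggressiveness association while all other
  traits stay uncoupled.

Not emulated: receiver geometry and acoustic propagation, tag collisions as
a process (only their zero-inflation signature), non-Gaussian trait
distributions, missing trials beyond an optional missingness fraction,
drifting solar times within the simulated fortnight, and behavioural
plasticity trends other than a linear day effect.  Passing tests therefore
demonstrate that the estimators recover the truth under the model's own
assumptions at realistic sizes — not that those assumptions hold in any
particular field dataset.

## Problem sizes and numerical choices

Replicated checks use the sizes stated with each test: e.g. 50 individuals
x 4 trials x 100 replicates for repeatability coverage (200 bootstrap
refits per replicate), 100 x 4 for syndrome recovery, 50 replicates of 100
individuals for the joint association, T = 2000 bins for HMM parameter
recovery, 10 fish x 10 days for chronotype decoding.  EM tolerance 1e-6 on
the log-likelihood; variance-ratio optimisation on the log scale bounded in
[1e-8, 1e6]; KDE grid 200x200; all random streams flow from explicit seeds
(per-stage seeds derived from the root seed via `SeedSequence` with a CRC of
the stage name, so stages are independently reproducible).

## Known limitations

* One HMM per individual; no pooling or hierarchical sharing of emission
  parameters across fish.
* Two states only; crepuscular or multi-modal activity is out of scope.
* Chronotype scores enter trait models as fixed point values; their
  uncertainty is reported but not propagated.
* The bivariate sampler handles pairs, not the full multi-trait covariance.
* Gaussian responses throughout; heavy-tailed or count responses must be
  transformed first.
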