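# chronosynd

Chronotype–personality behavioural syndrome analysis for repeatedly assayed,
acoustically tracked fish.

Animal personality research asks whether individuals differ consistently in
behaviour (behavioural *types*), whether those differences covary across
traits (behavioural *syndromes*), and — here — whether they covary with
*chronotypes*: an individual's consistent timing of daily activity, measured
as awakening time relative to sunrise and rest onset relative to sunset.  The
package was built for the study design of sand-burying marine fish (e.g. the
pearly razorfish) that are assayed for exploration, activity, boldness and
aggressiveness in arena trials, then released and tracked with high-resolution
acoustic telemetry; because a buried fish is acoustically silent, its
detection time series encodes its daily rest/activity schedule.

## What it computes

* **Trajectory metrics** (`chronosynd.trajectory`): distance travelled, 95%
  and 50% kernel utilization-distribution areas, Von Mises turning-angle mean
  and concentration, time out of the sand, novel-object metrics (time near
  the object, minimum distance), emergence latency; a 20-s minimum-exposure
  filter gates every trial.
* **Trait scores** (`chronosynd.scoring`): PCA on z-scored metrics per trait;
  the first principal component, sign-anchored (TimeOut / Distance / Bites
  positive), is the trait score.  Condition index = predicted allometric
  weight / fresh weight.
* **Chronotypes** (`chronosynd.hmm`): detections binned into 5-min intervals;
  a two-state zero-inflated-Poisson hidden Markov model fitted per individual
  by Baum–Welch EM; Viterbi decoding; daily awakening (first Rest→Active
  transition minus sunrise) and rest onset (first Active→Rest after the last
  activity, minus sunset), in minutes:

  counts_t | S_t=s ~ pi_s δ0 + (1 − pi_s) Poisson(λ_s),  S_t a 2-state
  Markov chain with transition matrix Γ; Active is the state with larger
  (1 − pi) λ.

* **Repeatability** (`chronosynd.mixed`): random-intercept LMMs (individual,
  batch) with profiled REML/ML; adjusted repeatability
  R = V_ind0 / (V_ind0 + V_e0) with parametric-bootstrap CI; significance via
  the AIC of the constrained (no-individual) model (ΔAIC > 2); bidirectional
  stepwise fixed-effect reduction with a 2-point cut-off; BLUP individual
  scores with simulation-based SDs.
* **Syndromes** (`chronosynd.syndrome`): bivariate Gaussian random-intercept
  models sampled by a conjugate Gibbs sampler, decomposing each trait-pair
  correlation into between-individual (r_ind), within-individual (r_e) and
  phenotypic (r_phe) parts; a pair is a syndrome when the r_ind 95% credible
  interval excludes zero.  The chronotype–personality association refits each
  trait LMM with standardised awakening / rest-onset scores as covariates.
* **Synthetic data** (`chronosynd.synthetic`): generators for every input
  with known ground truth — chronotype detection series, multi-trait trial
  tables with specified Sigma_ind / Sigma_e, arena trajectories, and joint
  datasets with a known chronotype–aggressiveness coupling.

See `docs/methods.md` for models, defaults, and numerical choices.

## Worked example

```python
import numpy as np
import chronosynd as cs

# traits with a known exploration-activity syndrome (r_ind = 0.6)
S_ind = 0.4 * np.array([[1.0, 0.6], [0.6, 1.0]])
cfg = cs.TraitSimConfig(n_individuals=100, n_trials=4,
                        trait_names=("exploration", "activity"),
                        Sigma_ind=S_ind, Sigma_e=0.6 * np.eye(2),
                        sd_batch=0.0, seed=1)
trials, truth = cs.gen_personality_dataset(cfg)

fit = cs.fit_lmm(cs.LmmSpec("value", ("size_cm", "condition", "day"),
                            ("individual",)),
                 trials[trials.trait == "activity"])
rep = cs.adjusted_repeatability(fit, n_boot=500, seed=2)
print(f"activity R = {rep.R:.2f} [{rep.ci_low:.2f}, {rep.ci_high:.2f}], "
      f"significant={rep.significant}")

est = cs.correlations(cs.fit_bivariate(trials, "exploration", "activity",
                                       chain=cs.ChainConfig(seed=3)))
print(f"r_ind = {est.r_ind:.2f} [{est.r_ind_ci[0]:.2f}, {est.r_ind_ci[1]:.2f}], "
      f"syndrome={est.is_syndrome}")
```

Output:

```
activity R = 0.36 [0.25, 0.46], significant=True
r_ind = 0.48 [0.19, 0.71], syndrome=True
```

The activity repeatability estimate brackets the simulated truth
(0.4 / (0.4 + 0.6) = 0.4), the AIC of the model without the individual term
is more than 2 points worse (so between-individual differences are real), and
the between-individual correlation credible interval excludes zero — the two
traits form a syndrome, as simulated (the point estimate 0.48 sits below the
generative 0.6 within one posterior SD; a single cohort of 100 fish carries
that much sampling noise).

A YAML-driven end-to-end run (simulate → decode chronotypes → repeatability →
syndromes → association) is available from the shell:

```bash
chronosynd run-all --config cfg.yaml     # cfg.yaml must contain a seed
chronosynd simulate|traj-metrics|score|chronotype|repeatability|syndrome ...
```

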