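# stnadapt

Analysis pipeline for studying how subthalamic nucleus (STN) beta-band
activity (13–30 Hz) relates to action evaluation and adaptation, and how
timed bursts of deep brain stimulation (DBS) alter both — implemented and
validated entirely on a synthetic cohort generator.

The experimental setting: a participant squeezes a dynamometer to match a
hidden target force (in %MVC, percent of maximum voluntary contraction).
The target drifts as a decaying Gaussian random walk,

    mu[t+1] = lam * mu[t] + (1 - lam) * theta + nu,    nu ~ N(0, 2),

with `lam = 0.98` and attractor `theta = 25 %MVC`.  After each press two
cues appear: **Value** (0–10 points, one point lost per %MVC of absolute
error, 0 beyond 10 %MVC) and, 1 s later, **Direction** (too high / too
low), scalarized as `(10 - value) * sign(error)`.  Bilateral STN local
field potentials (LFPs) are recorded from 8-contact directional leads;
in a second session randomized DBS bursts (150–350 ms plateaus, 75–225 ms
intervals, ramped on/off) are delivered while recording continues.

The core statistical machinery, for each 100-ms window stepped by 10 ms
(0–2 s after the Value-cue; −1–0 s before peak force):

    beta_power ~ b0_j + b1 * Value        + b2 * Direction        (feedback)
    beta_power ~ b0_j + b1 * |dforce|     + b2 * dforce           (movement)

a linear mixed-effects model with a random intercept per subject `j`, fit
by maximum likelihood; multiple comparisons across windows are corrected by
cluster-mass permutation (trial order of the dependent variable shuffled
within subject, 1,000 permutations, clusters above the two-sided p<0.05
threshold, mass compared to the 95th percentile of permutation maxima).
The stimulation analysis labels each trial × window ON/OFF from the
intensity channel (plateaus only; ramps are sub-threshold), contrasts the
absolute change in force between ON and OFF trials per window, and tests
the group effect by sign-flip permutation of per-subject ON−OFF
differences.  Stimulation sessions are cleaned by removing samples
exceeding 10 μV after 4–100 Hz filtering and interpolating across them,
and burst-locked beta suppression is quantified against stimulation-free
periods.

Because no patient recordings ship with the package, a first-class
synthetic cohort generator emulates the study: a delta-rule agent plays the
task, and multi-contact LFPs are rendered with a 1/f background, a
dorsally-weighted beta source whose amplitude dips with movement (deeper
for larger force changes) and scales with Value after feedback, alpha and
gamma responses, and optional burst stimulation with beta suppression and
a realistic, removable artifact.  `docs/methods.md` describes every model
and default.

## Worked example

```python
import numpy as np
from stnadapt import TaskConfig, AgentConfig, LfpGenConfig, simulate_cohort
from stnadapt.pipeline import behavior_summary, single_trial_regression

cohort = simulate_cohort(
    n_subjects=8,
    task=TaskConfig(n_trials=60),
    agent=AgentConfig(),
    lfp_cfg=LfpGenConfig(rate=400.0),   # scaled-down sampling rate
    n_hemispheres=1,
    seed=7,
)

behavior = behavior_summary(cohort)
print(behavior[["subject", "mean_value", "cv", "mean_abs_change",
                "corr_actual_target", "corr_value_next_abs_change"]]
      .round(3).head(3).to_string(index=False))

res = single_trial_regression(cohort, "value_cue", n_perm=500, seed=7)
for r in res["results"]:
    for c in r.clusters:
        if c["p"] <= 0.05:
            t0 = res["design"].starts[c["start"]]
            t1 = res["design"].starts[c["stop"] - 1] + 0.1
            print(f"{r.predictor}: cluster {t0:.2f}-{t1:.2f} s, "
                  f"mass {c['mass']:.1f}, p = {c['p']:.3f}")
```

prints

```
subject  mean_value    cv  mean_abs_change  corr_actual_target  corr_value_next_abs_change
 sub-01       7.492 0.366            3.182               0.893                      -0.471
 sub-02       8.068 0.339            2.954               0.868                      -0.614
 sub-03       7.333 0.321            3.407               0.926                      -0.461
value: cluster 0.37-0.74 s, mass 113.2, p = 0.002
```

Reading the output: the agents earn ~7.5 points per trial, adapt their
force (Value on trial *t* anticorrelates with the absolute force change on
trial *t+1*), and the sliding mixed-model regression recovers a positive
beta–Value cluster at 0.37–0.74 s after the Value-cue — the generator
injected that coupling at 0.4–0.7 s — while Direction shows no cluster, as
constructed.

## Command-line interface

`stnadapt simulate|preprocess|tfr|regress|stim|report` runs the pipeline
stages from a YAML configuration, e.g.

```
stnadapt simulate --config analysis.yaml --seed 1 --out runs/demo
stnadapt regress  --config analysis.yaml --seed 1 --out runs/demo
```

Every run writes a `manifest.json` with the configuration hash, seeds,
stage timings, and the complete output inventory; identical configurations
and seeds reproduce identical outputs.

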