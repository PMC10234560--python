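# Methods

`stnadapt` re-implements, end to end, the computational machinery of a
force-adaptation experiment with subthalamic nucleus (STN) recordings and
burst stimulation: the task model, a synthetic cohort generator that stands
in for patient data, the spectral preprocessing chain, the sliding-window
mixed-effects statistics with cluster-based permutation correction, and the
timing-specific stimulation analyses.  This note documents the models, the
parameters that matter, the numerical choices, and what the synthetic data
can and cannot show.

## Task model

The hidden target force follows a decaying Gaussian random walk in %MVC
(percent of maximum voluntary contraction),

    mu[t+1] = lam * mu[t] + (1 - lam) * theta + nu,   nu ~ N(0, sd_nu),

with `lam = 0.98`, attractor `theta = 25 %MVC`, `sd_nu = 2`, and
`mu[1] ~ N(25, 2)`.  `theta` is interpreted in %MVC (0.25 as a fraction of
MVC); the stationary mean of the AR(1) process equals `theta`, and
individual finite trajectories sit somewhat below it.

Feedback after each press:

* **Value** (0–10 points): absolute error `e = |actual - target|` binned
  per 1 %MVC, upper-inclusive — `e in [0, 1] -> 10`, `(1, 2] -> 9`, …,
  `(9, 10] -> 1`, `e > 10 -> 0`.  The bin-edge convention (exact 1.0 still
  scores 10) is ours; only the ranges are prescribed.
* **Direction**: scalarized as `(10 - value) * sign(actual - target)`,
  ranging -10…+10, 0 at full points.

Trial-to-trial predictors are the signed change in force
`force[t] - force[t-1]` and its magnitude, defined only for pairs of
consecutive valid trials.

Trial timing: jittered fixation 0.5–1 s, a 2.5 s response window, 1–1.5 s
blank, then the Value-cue and, exactly 1 s later, the Direction-cue, 1 s
each.  Sessions default to 100 trials (~11 min).

## Synthetic cohort

### Behaving agent

A delta-rule tracker plays the task: it keeps a target estimate, presses
with `estimate + N(0, motor_noise_sd)`, and updates
`estimate -= learning_rate * direction` (the Direction scalar approximates
the signed error in %MVC).  Defaults `learning_rate = 0.5`,
`motor_noise_sd = 2 %MVC` yield actual-vs-target correlations ~0.5–0.7 and
Value-vs-next-|change| correlations ~-0.4 to -0.6, the qualitative behavior
of real participants.  Occasional invalid trials are simulated by a 2% miss
rate and a 2% double-press rate.  The force channel renders one smooth
Hann pulse per press (width 0.6 s) peaking at the peak-force event with the
produced force as amplitude.

### LFP synthesis

Each hemisphere carries an 8-contact directional lead (ventral ring, 3+3
directional contacts on two levels, dorsal ring).  Every contact mixes

* a shared 1/f background (cancels in bipolar montages),
* independent white sensor noise plus independent narrowband beta-band
  noise per contact ("local" beta, task-uncoupled),
* three shared band oscillators — alpha 8–12 Hz, beta 16–24 Hz, gamma
  55–80 Hz — realized as Gaussian-spectral-window filtered noise (never a
  pure sinusoid, to avoid spurious phase locking), weighted along the
  dorsoventral axis.  Beta weights rise dorsally ([0.20, 0.45, 0.90, 1.70]
  by level, directional contacts scaled by [0.5, 1.1, 1.1]), so the
  dorsal-ring-to-first-dorsal-directional pair has the steepest beta
  gradient and is, by construction, the functional localizer's ground
  truth.  The task-uncoupled local beta is what makes the localizer
  discriminative at all: without it, relative movement modulation saturates
  and the three dorsal pairs tie.

Amplitude-envelope couplings (all multiplicative, Tukey-edged windows):

| coupling | window | default gain |
|---|---|---|
| movement beta desynchronization (all trials) | -0.5–0.25 s re peak force | dip 0.45 |
| beta dip scaling with abs. force change | -0.46–-0.30 s re peak force | 0.9 × min(change, 8)/8 |
| beta level scaling with Value | 0.4–0.7 s re Value-cue | 0.4 × (value-5)/5 |
| alpha increase (value-independent) | 0–0.5 s re Value-cue | 0.6 |
| gamma increase (adaptation-independent) | -0.3–0 s re peak force | 0.8 |

The coupling windows default to the latencies the analyses are meant to
recover; the gains are deliberately strong — sized so that the full
pipeline recovers each effect in >=90% of scaled cohorts — because the
recovery suites are parameter-recovery tests, not effect-size estimates.

### Burst stimulation

Schedules alternate plateaus (uniform 150–350 ms), linear ramps (175 ms
each, capped at 95% of the plateau amplitude so they are unambiguously
sub-threshold), and inter-burst intervals (uniform 75–225 ms).  Only
plateau samples count as stimulation ON; the binarization threshold is
99% of the programmed amplitude.  These parameters put the fraction of
trials with plateau stimulation in any 100-ms analysis window at ~45%.

During plateaus the generator multiplies all beta-band components (shared
oscillator and local beta) by `sqrt(1 - g)`, i.e. beta *power* is reduced
by `g` (default 0.4), relaxing back with a 70 ms time constant after each
plateau, so burst-aligned beta returns to baseline roughly half a second
after burst onset.

The artifact (default 100 uV, per-contact gains largest near the stimulated
level, asymmetric enough that wide bipolar montages retain ~30% of it) has
two components: an asymmetric biphasic pulse train at 130 Hz, and damped
80 Hz ringing transients at every plateau onset and offset.  The transients
are what keeps the artifact inside the 4–100 Hz analysis band: filtering
alone cannot remove it, and the 10 uV threshold-and-interpolate cleaning
removes ~1–5% of samples.

An optional behavioral effect pushes the produced force `gain` %MVC
*further along the intended change* whenever a plateau overlaps a
configurable window (default 0.18–0.34 s after the Value-cue acting on the
next trial, or a pre-peak window acting on the current trial).  The push is
directional by design: a random-sign push is unrecoverable in principle,
because it inflates the across-trial variance of the absolute change as
fast as it inflates its mean.

## Spectral pipeline

Conventions: seconds, t = 0 at the alignment event, half-open windows,
zero-phase (forward-backward) fourth-order Butterworth filters throughout —
latency-window analyses only make sense if filtering does not shift
events.

* Preprocessing: 1 Hz high-pass, 49–51 Hz band-stop, 90 Hz low-pass (the
  anti-alias edge needs a guard band below the 100 Hz Nyquist of the
  output), resample to 200 Hz.
* Montages: narrow = 9 neighboring bipolar pairs per lead; wide = ring
  levels (directional contacts averaged) differenced across the stimulated
  level, 2 channels.
* Morlet transform: width 7 cycles, 2–100 Hz in 1 Hz steps, computed at
  the signal rate and decimated to a 20 ms grid.  Power is normalized per
  frequency by its whole-recording mean over unmasked samples.
* Functional localizer: per hemisphere, the bipolar channel with the
  strongest movement-related beta decrease at its individual beta peak
  (13–30 Hz, band peak ± 3 Hz); hemispheres flagged if no channel reaches a
  15% reduction; selected channels averaged into one subject series.  For
  speed the scan runs at 2 Hz frequency resolution and the winning channel
  is re-transformed at 1 Hz.
* Stimulation-session cleaning: 4 Hz high-pass, 100 Hz low-pass, demean,
  detrend; samples with |x| > 10 uV replaced by linear interpolation
  between retained neighbors (edges hold the nearest retained value);
  a quality flag is raised if more than half the data is interpolated.

## Statistics

Single-trial band power (mean over each 100-ms window, stepped 10 ms;
feedback range 0–2 s, 191 windows; movement range -1–0 s, 91 windows) is
z-scored within subject, pooling over that subject's trials and windows;
trials whose epoch-mean |z| exceeds 3 are excluded (typically <5% on
synthetic cohorts).

The test statistic at each window is the fixed-slope t from a mixed model
with a random intercept per subject and both trial predictors (Value +
Direction, or absolute + signed change) fit together, by maximum
likelihood.  ML rather than REML so that BIC comparisons across
fixed-effect structures are valid; parameter counts include the two
variance components.  The fitter (`lme.py`) implements the exact profiled
ML solution of this one model family through per-group sufficient
statistics, with the variance ratio maximized by a log-grid plus
golden-section refinement — the cluster permutation refits the model
windows x permutations times, which rules out a generic optimizer.  Its
fits match statsmodels `MixedLM(reml=False)` to ~1e-8 in log-likelihood.

Cluster correction: windows exceeding the two-sided p<0.05 t threshold form
maximal same-sign runs; the cluster statistic is the mass (sum of |t|),
positive and negative clusters handled separately.  The null shuffles the
dependent variable's trial order within subject (window order inside a
trial preserved, regressors fixed); a cluster is significant when its mass
exceeds the 95th percentile of the permutation maxima.  Windows with
singular fits are dropped from observed and permuted statistics alike.
P-values use the (1 + exceedances)/(n_perm + 1) estimator.

The stimulation contrast labels each trial x window ON if any plateau
sample overlaps it, pairs feedback-aligned labels with the *next* trial's
absolute change and movement-aligned labels with the *current* one, forms
per-subject per-window ON-OFF means (subjects missing a condition in a
window are dropped there), and permutes by sign-flipping whole per-subject
difference rows.  With very few subjects this null is granular (2^J
distinct patterns), which bounds attainable p-values; cohorts of 8+ are
used throughout.

Burst-aligned beta is normalized to stimulation-free periods: inter-burst
samples at least 0.1 s before and 0.4 s after any plateau and at least 3 s
from the recording edges — edge transients of the filters and wavelets
otherwise contaminate the small stimulation-free sample.  The suppression
estimate averages normalized power from 0.08 s after plateau onset to
0.03 s before plateau end, over bursts with plateaus of at least 0.18 s, so
that spectral smoothing at burst edges does not dilute it; it still reads
~0.05 low at g = 0.4, which is inherent to 7-cycle wavelet smoothing of
250-ms episodes.

## Problem sizes

Default generator settings are the full study conditions: 16 subjects, 100
trials, 2 hemispheres, 2048 Hz.  The repeated-simulation suites (type-I
calibration: 200 cohorts; recovery: 50 cohorts each) run scaled conditions
chosen as 8 subjects x 60 trials x 1 hemisphere at 400 Hz native rate with
200 permutations, and evaluate the spectral chain on the designated dorsal
pair with the generator's beta band instead of re-running the localizer
scan in every replicate (the localizer has its own tests).  Artifact
removal is validated at the native 2048 Hz on paired
contaminated/artifact-free sessions generated from identical seeds.

## What the synthetic data do and do not show

The generator reproduces the *structure* of the study — trial flow,
feedback coupling to behavior, dorsoventral beta gradients, latency-specific
couplings, burst schedules, artifacts — but none of the biology: no
biophysical STN network, no tremor, no clinical heterogeneity, no
session-order or medication effects, and the behavioral agent is a one-line
delta rule.  Passing tests therefore demonstrate that the analysis chain is
correctly implemented and statistically calibrated (nominal false-positive
rates, sign- and latency-correct recovery, artifact-robust beta
estimation) — not that the scientific conclusions would replicate on new
patients.  Real-data effect sizes, latencies, and model-evidence values are
out of scope by design.

## Known limitations

* A full-size cohort held in memory at 2048 Hz is several GB; process
  sessions one at a time (as the CLI stages do) for full-size work.
* The profiled-ML fitter covers exactly one random-effects structure
  (random intercept); richer structures should go through statsmodels.
* EDF export is not provided; the session container is HDF5 + TSV.
* The suppression estimator is mildly biased low (see above); the
  tolerance of the recovery check absorbs this.
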