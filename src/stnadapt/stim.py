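"""Timing-specific burst-stimulation analysis.

The moving-window approach labels each trial x 100-ms window as stimulation
ON (any plateau sample inside the window) or OFF; behavioral contrasts
compare the mean absolute change in force between ON and OFF trials per
window, with group-level significance from a cluster-mass permutation that
shuffles each participant's condition labels (sign-flipping the paired
ON-OFF differences).  Neural effects are quantified as burst-aligned beta
power normalized to stimulation-free periods.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .schedule import StimSchedule
from .stats import ClusterTestResult, SlidingWindowDesign, find_clusters

__all__ = [
    "StimWindowLabels",
    "binarize_stimulation",
    "window_stim_labels",
    "stim_behavior_contrast",
    "group_t_series",
    "cluster_permutation_labels",
    "stim_aligned_beta",
    "windowed_beta_contrast",
    "conditional_effects",
]

PLATEAU_FRACTION = 0.99  # of the programmed amplitude counts as ON


def binarize_stimulation(intensity: np.ndarray, effective_amplitude: float) -> np.ndarray:
    """Per-sample stimulation boolean: ON on plateaus (>= 99% of the
    programmed amplitude); ramp intensities are below the clinically
    effective level and count as OFF."""
    intensity = np.asarray(intensity, dtype=float)
    if np.any(intensity < 0):
        raise ValueError("negative stimulation intensities")
    if effective_amplitude <= 0:
        raise ValueError("effective amplitude must be positive")
    return intensity >= PLATEAU_FRACTION * effective_amplitude


@dataclass
class StimWindowLabels:
    """Trial x window ON/OFF booleans on a sliding-window grid."""

    labels: np.ndarray  # (n_trials, n_windows) bool
    trial_index: np.ndarray
    alignment: str
    design: SlidingWindowDesign

    def on_fraction(self) -> np.ndarray:
        """Per-window fraction of trials with any plateau stimulation."""
        return self.labels.mean(axis=0)


def window_stim_labels(
    stim_on: np.ndarray,
    rate: float,
    event_times: np.ndarray,
    design: SlidingWindowDesign,
    alignment: str = "value_cue",
    trial_index: np.ndarray | None = None,
) -> StimWindowLabels:
    """Label each trial x window ON if any ON sample falls in
    [event + t, event + t + 0.1); half-open in both time and samples."""
    stim_on = np.asarray(stim_on, dtype=bool)
    event_times = np.asarray(event_times, dtype=float)
    if trial_index is None:
        trial_index = np.arange(event_times.size)
    csum = np.concatenate([[0], np.cumsum(stim_on)])
    n = stim_on.size
    starts = design.starts
    out = np.zeros((event_times.size, starts.size), dtype=bool)
    for k, ev in enumerate(event_times):
        if not np.isfinite(ev):
            continue
        i0 = np.ceil((ev + starts) * rate - 1e-9).astype(int)
        i1 = np.ceil((ev + starts + design.length) * rate - 1e-9).astype(int)
        i0 = np.clip(i0, 0, n)
        i1 = np.clip(i1, 0, n)
        out[k] = (csum[i1] - csum[i0]) > 0
    return StimWindowLabels(out, np.asarray(trial_index), alignment, design)


def stim_behavior_contrast(
    labels: StimWindowLabels,
    behavior: np.ndarray,
    subjects: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-subject, per-window mean ON minus mean OFF of a behavior metric.

    ``behavior`` holds the metric for the trial each label row refers to
    (the caller pairs feedback-aligned labels with the *next* trial's
    absolute change and movement-aligned labels with the current trial's).
    Subjects lacking either condition in a window get NaN there.  Returns
    (diffs (n_subjects, n_windows), subject ids).
    """
    behavior = np.asarray(behavior, dtype=float)
    subjects = np.asarray(subjects)
    if behavior.size != labels.labels.shape[0]:
        raise ValueError("behavior must be defined per labeled trial")
    uniq = np.unique(subjects)
    W = labels.labels.shape[1]
    diffs = np.full((uniq.size, W), np.nan)
    for si, s in enumerate(uniq):
        rows = (subjects == s) & np.isfinite(behavior)
        lab = labels.labels[rows]
        beh = behavior[rows]
        n_on = lab.sum(axis=0)
        n_off = (~lab).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean_on = (beh[:, None] * lab).sum(axis=0) / n_on
            mean_off = (beh[:, None] * ~lab).sum(axis=0) / n_off
        d = mean_on - mean_off
        d[(n_on == 0) | (n_off == 0)] = np.nan
        diffs[si] = d
    return diffs, uniq


def group_t_series(diffs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One-sample t across subjects per window, NaN-aware.

    Returns (t (W,), n_subjects per window)."""
    diffs = np.asarray(diffs, dtype=float)
    m = np.isfinite(diffs)
    n = m.sum(axis=0)
    d0 = np.where(m, diffs, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = d0.sum(axis=0) / n
        var = (d0**2).sum(axis=0) - n * mean**2
        var = var / np.maximum(n - 1, 1)
        t = mean / np.sqrt(var / n)
    t[n < 2] = np.nan
    return t, n


def cluster_permutation_labels(
    diffs: np.ndarray,
    design: SlidingWindowDesign,
    n_perm: int = 1000,
    cluster_alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
    name: str = "stim_on_minus_off",
) -> ClusterTestResult:
    """Group-level cluster-mass permutation for paired ON-OFF differences.

    The null swaps each participant's condition means, i.e. it flips the
    sign of whole per-subject difference rows; cluster mass is compared to
    the 95th percentile of the permutation maxima.
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is low; permutation p-values are coarse")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seed_val = None if isinstance(seed, np.random.Generator) else int(seed)
    diffs = np.asarray(diffs, dtype=float)
    if diffs.shape[0] < 5:
        raise ValueError("need at least 5 subjects")
    t_obs, n_per_win = group_t_series(diffs)
    df = np.maximum(n_per_win - 1, 1)
    threshold = float(sps.t.ppf(1.0 - cluster_alpha / 2.0, df=diffs.shape[0] - 1))
    clusters = find_clusters(t_obs, threshold)

    m = np.isfinite(diffs)
    d0 = np.where(m, diffs, 0.0)
    ss = (d0**2).sum(axis=0)
    n = m.sum(axis=0).astype(float)
    flips = rng.choice([-1.0, 1.0], size=(n_perm, diffs.shape[0]))
    sums = flips @ d0  # (n_perm, W)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = sums / n
        var = (ss[None, :] - n * mean**2) / np.maximum(n - 1, 1)
        t_perm = mean / np.sqrt(var / n)
    t_perm[:, n < 2] = np.nan
    null_max = np.zeros(n_perm)
    for b in range(n_perm):
        cl = find_clusters(t_perm[b], threshold)
        null_max[b] = max((c["mass"] for c in cl), default=0.0)
    for c in clusters:
        c["p"] = float((1 + np.sum(null_max >= c["mass"])) / (n_perm + 1))
    return ClusterTestResult(
        predictor=name,
        tvalues=t_obs,
        threshold=threshold,
        clusters=clusters,
        null_max=null_max,
        n_perm=n_perm,
        window_starts=design.starts,
        seed=seed_val,
    )


def stim_aligned_beta(
    beta_power: np.ndarray,
    times: np.ndarray,
    schedule: StimSchedule,
    window: tuple[float, float] = (-0.2, 0.7),
    free_buffer: tuple[float, float] = (0.1, 0.4),
    edge_guard: float = 3.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Burst-aligned beta power normalized to stimulation-free periods.

    Epochs ``beta_power`` (a continuous series on the ``times`` grid) on
    plateau onsets (post-ramp) and divides by the mean power over
    inter-burst samples, excluding ``free_buffer[0]`` s before each plateau
    and ``free_buffer[1]`` s after it (suppression decays back after the
    burst, so the trailing guard is longer).  The first and last
    ``edge_guard`` seconds are excluded from the normalization: filter and
    wavelet transients inflate power estimates at the recording edges.
    Returns (epochs (n_bursts, n_times), relative times, plateau durations
    of the epoched bursts).
    """
    beta_power = np.asarray(beta_power, dtype=float).ravel()
    times = np.asarray(times, dtype=float)
    if schedule.n_bursts == 0:
        raise ValueError("schedule has no bursts")
    free = (times >= times[0] + edge_guard) & (times <= times[-1] - edge_guard)
    for _, p0, p1, _ in schedule.segments:
        free &= ~((times >= p0 - free_buffer[0]) & (times < p1 + free_buffer[1]))
    if not free.any():
        raise ValueError("no stimulation-free samples for normalization")
    norm = beta_power / beta_power[free].mean()
    step = times[1] - times[0]
    rel = np.arange(int(np.round(window[0] / step)), int(np.round(window[1] / step)) + 1)
    out, durs = [], []
    for _, p0, p1, _ in schedule.segments:
        ic = int(np.round((p0 - times[0]) / step))
        idx = ic + rel
        if idx[0] < 0 or idx[-1] >= times.size:
            continue
        out.append(norm[idx])
        durs.append(p1 - p0)
    if not out:
        raise ValueError("no bursts with a complete epoch window")
    return np.stack(out), rel * step, np.asarray(durs)


def windowed_beta_contrast(
    beta_windows: np.ndarray,
    on_a: np.ndarray,
    on_b: np.ndarray,
    subjects: np.ndarray,
    design: SlidingWindowDesign,
    exclusive: bool = True,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> ClusterTestResult:
    """Beta power for trials stimulated in window-of-interest A versus
    trials stimulated in control window B, as a group cluster test over a
    spanning window.

    ``beta_windows`` is (trials, windows) band power over the spanning grid;
    ``on_a``/``on_b`` are per-trial booleans.  With ``exclusive`` (default)
    condition A requires ON in A and OFF in B and vice versa.  Subjects with
    an empty condition are dropped.
    """
    beta_windows = np.asarray(beta_windows, dtype=float)
    on_a = np.asarray(on_a, dtype=bool)
    on_b = np.asarray(on_b, dtype=bool)
    subjects = np.asarray(subjects)
    if exclusive:
        cond_a = on_a & ~on_b
        cond_b = on_b & ~on_a
    else:
        cond_a, cond_b = on_a, on_b
    uniq = np.unique(subjects)
    rows = []
    for s in uniq:
        sel = subjects == s
        a, b = cond_a & sel, cond_b & sel
        if not a.any() or not b.any():
            continue
        rows.append(np.nanmean(beta_windows[a], axis=0) - np.nanmean(beta_windows[b], axis=0))
    if len(rows) < 5:
        raise ValueError("fewer than 5 subjects with both conditions")
    diffs = np.stack(rows)
    return cluster_permutation_labels(
        diffs, design, n_perm=n_perm, seed=seed, name="window_A_minus_B"
    )


def conditional_effects(
    stim_on: np.ndarray,
    behavior: np.ndarray,
    strata: np.ndarray,
    subjects: np.ndarray,
    n_comparisons: int = 2,
) -> dict:
    """Effect of a named stimulation window recomputed per stratum.

    ``stim_on`` marks trials stimulated in the window of interest,
    ``behavior`` is the per-trial metric (e.g. next-trial absolute change in
    force), and ``strata`` assigns each trial to one of two conditions
    (Direction sign, Value median split at 5 points, or presence of
    premovement stimulation).  Per subject and stratum the ON-OFF difference
    of the behavior means is formed; each stratum is tested against zero and
    the two strata are compared by a paired t-test, Bonferroni-corrected
    over ``n_comparisons``.
    """
    stim_on = np.asarray(stim_on, dtype=bool)
    behavior = np.asarray(behavior, dtype=float)
    strata = np.asarray(strata)
    subjects = np.asarray(subjects)
    levels = np.unique(strata[~_isnan(strata)])
    if levels.size != 2:
        raise ValueError("need exactly two strata")
    per_level = {}
    uniq = np.unique(subjects)
    for lev in levels:
        vals = []
        for s in uniq:
            rows = (subjects == s) & (strata == lev) & np.isfinite(behavior)
            on = behavior[rows & stim_on]
            off = behavior[rows & ~stim_on]
            vals.append(on.mean() - off.mean() if on.size and off.size else np.nan)
        per_level[lev] = np.asarray(vals)
    a, b = (per_level[lev] for lev in levels)
    ok = np.isfinite(a) & np.isfinite(b)
    degenerate = int((~ok).sum())
    if ok.sum() < 3:
        raise ValueError("too few subjects with both strata")
    tstat, p = sps.ttest_rel(a[ok], b[ok])
    stratum_tests = {}
    for lev in levels:
        v = per_level[lev]
        v = v[np.isfinite(v)]
        t1, p1 = sps.ttest_1samp(v, 0.0)
        stratum_tests[str(lev)] = dict(
            t=float(t1), p=float(p1),
            p_bonferroni=float(min(1.0, p1 * n_comparisons)),
            mean=float(v.mean()), n=int(v.size),
        )
    return dict(
        strata=[str(lev) for lev in levels],
        per_subject=per_level,
        paired_t=float(tstat),
        paired_p=float(p),
        paired_p_bonferroni=float(min(1.0, p * n_comparisons)),
        stratum_tests=stratum_tests,
        degenerate_subjects=degenerate,
    )


def _isnan(x: np.ndarray) -> np.ndarray:
    try:
        return np.isnan(x)
    except TypeError:
        return np.zeros(x.shape, dtype=bool)
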