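"""Synthetic cohort generator: behaving agents, force traces, multi-contact
STN-like LFPs, and burst stimulation with artifacts.

This module is the stand-in for patient recordings.  A delta-rule agent plays
the force-tracking task; its trial table drives an LFP synthesizer that mixes
a 1/f background with amplitude-modulated narrowband oscillators (alpha,
beta, gamma) onto an 8-contact directional DBS lead per hemisphere.  The
couplings mirror the phenomena the analysis pipeline is built to detect:

* a movement-locked beta desynchronization whose depth grows with the
  absolute trial-to-trial change in force,
* a post-feedback beta level that increases with the Value score,
* a value-independent post-feedback alpha increase and a pre-peak gamma
  increase,
* optional burst stimulation that suppresses beta power and adds a
  large-amplitude pulse-train artifact.

Every generated quantity is reproducible from the configured seeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import fft
from scipy.signal.windows import tukey

from .schedule import StimSchedule, StimScheduleConfig, generate_dbs_schedule
from .task import (
    TaskConfig,
    compute_change_predictors,
    score_direction_feedback,
    score_value_feedback,
    simulate_target_trajectory,
)

__all__ = [
    "AgentConfig",
    "LfpGenConfig",
    "StimBehaviorEffect",
    "SessionRecording",
    "simulate_agent_session",
    "synthesize_force_trace",
    "synthesize_lfp",
    "inject_stim_artifact",
    "simulate_session",
    "simulate_cohort",
]

# Trial timing (seconds): jittered fixation, fixed response window, jittered
# blank, then two 1-s feedback cues.
FIXATION_RANGE = (0.5, 1.0)
RESPONSE_WINDOW = 2.5
BLANK_RANGE = (1.0, 1.5)
CUE_DURATION = 1.0  # each of Value- and Direction-cue
SESSION_LEAD_IN = 2.0
SESSION_TAIL = 3.0

# Lead geometry: contact 0 = ventral ring, 1-3 ventral directional,
# 4-6 dorsal directional, 7 = dorsal ring (4 vertical levels).
N_CONTACTS = 8
_CONTACT_LEVEL = np.array([0, 1, 1, 1, 2, 2, 2, 3])
_DIR_OFFSETS = np.array([0.50, 1.10, 1.10])
_BETA_LEVEL_W = np.array([0.20, 0.45, 0.90, 1.70])
_ALPHA_LEVEL_W = np.array([1.20, 1.00, 0.70, 0.50])
_GAMMA_LEVEL_W = np.array([0.40, 0.60, 0.80, 0.70])
# Per-contact stimulation-artifact gains.  The stimulated (virtual) contact
# sits at level 2, so its directional contacts carry the largest artifact;
# residual asymmetry keeps the wide bipolar montage from cancelling it fully.
_ARTIFACT_GAIN = np.array([0.40, 0.90, 1.10, 0.85, 2.80, 3.20, 2.90, 1.25])


def contact_weights(level_weights: np.ndarray) -> np.ndarray:
    """Spread per-level weights onto the 8 physical contacts."""
    w = np.empty(N_CONTACTS)
    w[0] = level_weights[0]
    w[1:4] = level_weights[1] * _DIR_OFFSETS
    w[4:7] = level_weights[2] * _DIR_OFFSETS
    w[7] = level_weights[3]
    return w


# By construction the dorsal-ring <-> first dorsal-directional pair has the
# steepest beta-weight gradient, giving the functional localizer its ground
# truth.
DESIGNATED_DORSAL_PAIR = (7, 4)


@dataclass(frozen=True)
class AgentConfig:
    """Delta-rule force-tracking agent.

    The agent keeps a running estimate of the target, produces
    ``estimate + motor noise`` as peak force, and after feedback moves the
    estimate against the Direction scalar (which approximates the signed
    error in %MVC) scaled by ``learning_rate``.
    """

    learning_rate: float = 0.5
    motor_noise_sd: float = 2.0
    start_estimate: float = 25.0
    miss_rate: float = 0.02  # trials with no press
    double_press_rate: float = 0.02  # trials with a second, spurious press
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.learning_rate <= 1.0:
            raise ValueError("learning_rate must lie in [0, 1]")
        if self.motor_noise_sd < 0:
            raise ValueError("motor_noise_sd must be non-negative")
        if not (0 <= self.miss_rate < 1 and 0 <= self.double_press_rate < 1):
            raise ValueError("miss/double-press rates must lie in [0, 1)")


@dataclass(frozen=True)
class StimBehaviorEffect:
    """Ground-truth behavioral stimulation effect.

    If any burst plateau overlaps ``window`` relative to ``alignment``
    (``value_cue`` perturbs the *next* trial's force, ``peak_force`` the
    *current* one), the produced force is pushed ``gain`` %MVC further in
    the direction the agent was already moving, so the trial's absolute
    change in force grows by ``gain`` while its sign is preserved.
    """

    alignment: str = "value_cue"
    window: tuple[float, float] = (0.18, 0.34)
    gain: float = 2.0

    def __post_init__(self) -> None:
        if self.alignment not in ("value_cue", "peak_force"):
            raise ValueError("alignment must be 'value_cue' or 'peak_force'")


@dataclass(frozen=True)
class LfpGenConfig:
    """Parameters of the LFP synthesizer (amplitudes in uV, times in s).

    Coupling gains modulate oscillator *amplitude* envelopes inside the
    configured latency windows; ``dbs_beta_suppression`` is the fractional
    reduction of beta *power* during stimulation plateaus.
    """

    rate: float = 2048.0
    background_exponent: float = 1.0
    background_amp: float = 4.0  # shared 1/f, per hemisphere
    contact_noise_amp: float = 1.4  # independent white noise floor per contact
    contact_beta_noise_amp: float = 0.6  # independent beta-band noise per contact
    alpha_band: tuple[float, float] = (8.0, 12.0)
    beta_band: tuple[float, float] = (16.0, 24.0)
    gamma_band: tuple[float, float] = (55.0, 80.0)
    alpha_amp: float = 2.0
    beta_amp: float = 2.2
    gamma_amp: float = 1.4
    movement_dip: float = 0.45  # generic peri-movement beta amplitude dip
    movement_dip_window: tuple[float, float] = (-0.5, 0.25)  # re peak force
    beta_value_gain: float = 0.4
    value_window: tuple[float, float] = (0.4, 0.7)  # re Value-cue
    beta_change_gain: float = 0.9
    change_saturation: float = 8.0  # %MVC change at which the dip saturates
    move_window: tuple[float, float] = (-0.46, -0.30)  # re peak force
    alpha_feedback_gain: float = 0.6
    alpha_window: tuple[float, float] = (0.0, 0.5)  # re Value-cue
    gamma_move_gain: float = 0.8
    gamma_window: tuple[float, float] = (-0.3, 0.0)  # re peak force
    dbs_beta_suppression: float = 0.4
    suppression_tau: float = 0.07  # recovery time constant after a plateau
    artifact_amplitude: float = 100.0
    stim_frequency: float = 130.0

    def __post_init__(self) -> None:
        gains = (
            self.beta_value_gain,
            self.beta_change_gain,
            self.alpha_feedback_gain,
            self.gamma_move_gain,
        )
        if not all(math.isfinite(g) for g in gains):
            raise ValueError("coupling gains must be finite")
        if not 0.0 <= self.dbs_beta_suppression <= 1.0:
            raise ValueError("dbs_beta_suppression must lie in [0, 1]")
        if self.rate <= 2.0 * self.gamma_band[1]:
            raise ValueError("sampling rate must exceed twice the highest band edge")


@dataclass
class SessionRecording:
    """One synthetic recording session.

    ``lfp`` is (n_channels, n_samples) in uV with monopolar contact channels
    named e.g. ``L0``..``L7`` (ventral ring -> dorsal ring), force in %MVC
    and stimulation intensity in mA at the same rate.
    """

    subject: str
    rate: float
    lfp: np.ndarray
    channel_names: list[str]
    force: np.ndarray
    stim_intensity: np.ndarray
    events: pd.DataFrame
    trials: pd.DataFrame
    schedule: StimSchedule | None = None
    components: dict | None = field(default=None, repr=False)

    @property
    def n_samples(self) -> int:
        return self.lfp.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    @property
    def n_hemispheres(self) -> int:
        return self.lfp.shape[0] // N_CONTACTS

    def hemisphere_contacts(self, h: int) -> np.ndarray:
        return self.lfp[h * N_CONTACTS : (h + 1) * N_CONTACTS]

    def event_times(self, event_type: str) -> pd.Series:
        ev = self.events[self.events.event_type == event_type]
        return ev.set_index("trial")["onset"]


def simulate_agent_session(
    task: TaskConfig,
    agent: AgentConfig,
    rng: np.random.Generator | None = None,
    schedule: StimSchedule | None = None,
    stim_effect: StimBehaviorEffect | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Play the task with a delta-rule agent; return (trials, events).

    Events follow the task timing: jittered fixation 0.5-1 s, a 2.5 s
    response window, 1-1.5 s blank, then the two feedback cues of 1 s each
    (the Direction-cue always 1 s after the Value-cue).
    """
    if rng is None:
        rng = np.random.default_rng(agent.seed)
    targets = simulate_target_trajectory(task, rng)
    estimate = agent.start_estimate
    last_force = float("nan")
    t = SESSION_LEAD_IN
    rows, ev = [], []
    amplify_next = False  # feedback-window stim effect acts on the next trial
    for i in range(task.n_trials):
        fix = rng.uniform(*FIXATION_RANGE)
        go = t + fix
        rt = float(np.clip(rng.normal(0.9, 0.15), 0.4, 2.0))
        peak = go + rt
        blank = rng.uniform(*BLANK_RANGE)
        value_cue = go + RESPONSE_WINDOW + blank
        direction_cue = value_cue + CUE_DURATION
        ev.append((go, 0.0, i, "go"))

        missed = rng.random() < agent.miss_rate
        double = (not missed) and rng.random() < agent.double_press_rate
        # draw motor noise unconditionally to keep the stream aligned
        noise = agent.motor_noise_sd * rng.standard_normal()
        amplify = amplify_next
        amplify_next = False
        if (
            stim_effect is not None
            and schedule is not None
            and stim_effect.alignment == "peak_force"
            and _any_plateau_overlap(schedule, peak, stim_effect.window)
        ):
            amplify = True

        if missed:
            rows.append(
                dict(trial=i, target=targets[i], actual=np.nan, value=np.nan,
                     direction=np.nan, signed_error=np.nan, n_presses=0,
                     valid=False, peak_time=np.nan)
            )
            last_force = float("nan")
        else:
            planned = estimate + noise
            push = 0.0
            if amplify and stim_effect is not None and np.isfinite(last_force):
                step = planned - last_force
                push = stim_effect.gain * (np.sign(step) if step != 0 else 1.0)
            force = planned + push
            err = force - targets[i]
            value = score_value_feedback(force, targets[i])
            direction = score_direction_feedback(value, err)
            estimate = estimate - agent.learning_rate * direction
            n_presses = 2 if double else 1
            rows.append(
                dict(trial=i, target=targets[i], actual=force, value=float(value),
                     direction=float(direction), signed_error=err,
                     n_presses=n_presses, valid=n_presses == 1, peak_time=peak)
            )
            ev.append((peak, 0.0, i, "peak_force"))
            ev.append((value_cue, CUE_DURATION, i, "value_cue"))
            ev.append((direction_cue, CUE_DURATION, i, "direction_cue"))
            last_force = force
            if (
                stim_effect is not None
                and schedule is not None
                and stim_effect.alignment == "value_cue"
                and _any_plateau_overlap(schedule, value_cue, stim_effect.window)
            ):
                amplify_next = True
        t = direction_cue + CUE_DURATION

    trials = pd.DataFrame(rows)
    changes = compute_change_predictors(
        trials["actual"].to_numpy(), trials["valid"].to_numpy()
    )
    trials = pd.concat([trials, changes], axis=1)
    events = pd.DataFrame(ev, columns=["onset", "duration", "trial", "event_type"])
    return trials, events


def _any_plateau_overlap(
    schedule: StimSchedule, event_time: float, window: tuple[float, float]
) -> bool:
    if schedule.n_bursts == 0:
        return False
    w0, w1 = event_time + window[0], event_time + window[1]
    p0, p1 = schedule.segments[:, 1], schedule.segments[:, 2]
    return bool(np.any((p0 < w1) & (p1 > w0)))


def synthesize_force_trace(
    trials: pd.DataFrame,
    events: pd.DataFrame,
    rate: float,
    duration: float,
    pulse_width: float = 0.6,
    double_press_offset: float = 0.7,
) -> np.ndarray:
    """Smooth unimodal Hann pulse per press, peaking at the trial's
    peak-force event with amplitude equal to the produced force."""
    n = int(round(duration * rate))
    force = np.zeros(n)
    half = pulse_width / 2.0
    peaks = []
    for row in trials.itertuples():
        if row.n_presses == 0 or not np.isfinite(row.peak_time):
            continue
        peaks.append((row.peak_time, row.actual))
        if row.n_presses > 1:
            peaks.append((row.peak_time + double_press_offset, 0.6 * row.actual))
    peaks.sort()
    for (t0, _), (t1, _) in zip(peaks, peaks[1:]):
        if t1 - t0 < pulse_width:
            raise ValueError("overlapping force pulses")
    for t_peak, amp in peaks:
        i_peak = int(round(t_peak * rate))
        m = int(round(half * rate))
        i0, i1 = i_peak - m, i_peak + m + 1
        w = np.hanning(2 * m + 1)
        s0, s1 = max(i0, 0), min(i1, n)
        force[s0:s1] += amp * w[s0 - i0 : s1 - i0]
    return force


def _one_over_f_noise(
    rng: np.random.Generator, n: int, exponent: float, rate: float
) -> np.ndarray:
    m = fft.next_fast_len(n)
    spec = fft.rfft(rng.standard_normal(m))
    f = fft.rfftfreq(m, 1.0 / rate)
    scale = np.zeros_like(f)
    scale[1:] = f[1:] ** (-exponent / 2.0)
    y = fft.irfft(spec * scale, m)[:n]
    return y / np.std(y)


def _narrowband_noise(
    rng: np.random.Generator, n: int, band: tuple[float, float], rate: float
) -> np.ndarray:
    """Amplitude-modulatable oscillator: white noise shaped by a Gaussian
    spectral window centered mid-band (sigma = bandwidth/4), which avoids
    the phase-locking a pure sinusoid would create."""
    m = fft.next_fast_len(n)
    spec = fft.rfft(rng.standard_normal(m))
    f = fft.rfftfreq(m, 1.0 / rate)
    center = 0.5 * (band[0] + band[1])
    sigma = (band[1] - band[0]) / 4.0
    y = fft.irfft(spec * np.exp(-0.5 * ((f - center) / sigma) ** 2), m)[:n]
    return y / np.std(y)


def _narrowband_noise_batch(
    rng: np.random.Generator,
    n_channels: int,
    n: int,
    band: tuple[float, float],
    rate: float,
) -> np.ndarray:
    """Batched variant of :func:`_narrowband_noise`, one row per channel."""
    m = fft.next_fast_len(n)
    spec = fft.rfft(rng.standard_normal((n_channels, m)), axis=-1)
    f = fft.rfftfreq(m, 1.0 / rate)
    center = 0.5 * (band[0] + band[1])
    sigma = (band[1] - band[0]) / 4.0
    y = fft.irfft(spec * np.exp(-0.5 * ((f - center) / sigma) ** 2), m, axis=-1)[:, :n]
    return y / y.std(axis=-1, keepdims=True)


def _modulate(env: np.ndarray, rate: float, t0: float, t1: float, delta: float) -> None:
    """Multiply env by (1 + delta * tukey) on [t0, t1); smooth 30% edges."""
    i0, i1 = int(round(t0 * rate)), int(round(t1 * rate))
    i0, i1 = max(i0, 0), min(i1, len(env))
    if i1 <= i0:
        return
    env[i0:i1] *= 1.0 + delta * tukey(i1 - i0, alpha=0.3)


def synthesize_lfp(
    trials: pd.DataFrame,
    events: pd.DataFrame,
    cfg: LfpGenConfig,
    duration: float,
    rng: np.random.Generator,
    n_hemispheres: int = 2,
) -> tuple[np.ndarray, list[str], dict]:
    """Render multi-contact LFPs; returns (lfp, channel_names, components).

    Each contact mixes a shared 1/f background, an independent 1/f noise
    floor, and the three band oscillators weighted along the dorsoventral
    axis (beta strongest dorsally).  ``components`` retains the beta
    oscillator decomposition so stimulation effects can be injected exactly.
    """
    n = int(round(duration * rate_of(cfg)))
    epoch_pad = max(
        abs(cfg.value_window[0]), abs(cfg.value_window[1]),
        abs(cfg.move_window[0]), abs(cfg.movement_dip_window[0]),
    )
    if epoch_pad > SESSION_LEAD_IN + 0.5:
        raise ValueError("coupling window extends outside epoch bounds")
    value_times = events.query("event_type == 'value_cue'").set_index("trial")["onset"]
    peak_times = events.query("event_type == 'peak_force'").set_index("trial")["onset"]
    rate = cfg.rate

    w_beta = contact_weights(_BETA_LEVEL_W)
    w_alpha = contact_weights(_ALPHA_LEVEL_W)
    w_gamma = contact_weights(_GAMMA_LEVEL_W)

    lfp = np.empty((n_hemispheres * N_CONTACTS, n))
    names: list[str] = []
    beta_osc = np.empty((n_hemispheres, n))
    beta_env = np.empty((n_hemispheres, n))
    beta_suppressible: list[np.ndarray] = []
    for h in range(n_hemispheres):
        side = "LR"[h] if n_hemispheres <= 2 else f"H{h}"
        names += [f"{side}{c}" for c in range(N_CONTACTS)]

        alpha = _narrowband_noise(rng, n, cfg.alpha_band, rate)
        beta = _narrowband_noise(rng, n, cfg.beta_band, rate)
        gamma = _narrowband_noise(rng, n, cfg.gamma_band, rate)

        env_a = np.ones(n)
        env_b = np.ones(n)
        env_g = np.ones(n)
        for row in trials.itertuples():
            tr = row.trial
            if tr in peak_times.index:
                pk = peak_times.loc[tr]
                _modulate(env_b, rate, pk + cfg.movement_dip_window[0],
                          pk + cfg.movement_dip_window[1], -cfg.movement_dip)
                if np.isfinite(row.abs_change) and cfg.beta_change_gain != 0.0:
                    depth = cfg.beta_change_gain * min(
                        row.abs_change, cfg.change_saturation
                    ) / cfg.change_saturation
                    _modulate(env_b, rate, pk + cfg.move_window[0],
                              pk + cfg.move_window[1], -depth)
                if cfg.gamma_move_gain != 0.0:
                    _modulate(env_g, rate, pk + cfg.gamma_window[0],
                              pk + cfg.gamma_window[1], cfg.gamma_move_gain)
            if tr in value_times.index:
                vc = value_times.loc[tr]
                if cfg.alpha_feedback_gain != 0.0:
                    _modulate(env_a, rate, vc + cfg.alpha_window[0],
                              vc + cfg.alpha_window[1], cfg.alpha_feedback_gain)
                if cfg.beta_value_gain != 0.0 and np.isfinite(row.value):
                    delta = cfg.beta_value_gain * (row.value - 5.0) / 5.0
                    _modulate(env_b, rate, vc + cfg.value_window[0],
                              vc + cfg.value_window[1], delta)
        np.clip(env_b, 0.05, None, out=env_b)

        shared_bg = cfg.background_amp * _one_over_f_noise(
            rng, n, cfg.background_exponent, rate
        )
        beta_osc[h] = beta
        beta_env[h] = cfg.beta_amp * env_b
        block = lfp[h * N_CONTACTS : (h + 1) * N_CONTACTS]
        a_mod = cfg.alpha_amp * env_a * alpha
        g_mod = cfg.gamma_amp * env_g * gamma
        b_mod = beta_env[h] * beta
        supp = np.empty((N_CONTACTS, n), dtype=np.float32)
        # independent white sensor noise plus local (uncorrelated) beta-band
        # activity per contact; the local beta is task-uncoupled, which
        # dilutes movement-related modulation on low-gradient bipolar pairs
        # and lets the functional localizer separate the dorsal pairs, but
        # it is still suppressed by stimulation
        white = cfg.contact_noise_amp * rng.standard_normal((N_CONTACTS, n))
        local_beta = (
            cfg.contact_beta_noise_amp
            * _narrowband_noise_batch(rng, N_CONTACTS, n, cfg.beta_band, rate)
            if cfg.contact_beta_noise_amp > 0
            else np.zeros((N_CONTACTS, 1))
        )
        for c in range(N_CONTACTS):
            beta_c = w_beta[c] * b_mod + local_beta[c]
            supp[c] = beta_c
            block[c] = (
                shared_bg + white[c]
                + beta_c + w_alpha[c] * a_mod + w_gamma[c] * g_mod
            )
        beta_suppressible.append(supp)
    components = {
        "beta_osc": beta_osc,
        "beta_env": beta_env,
        "beta_weights": w_beta,
        "beta_suppressible": beta_suppressible,
        "dorsal_pair": DESIGNATED_DORSAL_PAIR,
    }
    return lfp, names, components


def rate_of(cfg: LfpGenConfig) -> float:
    return cfg.rate


def _suppression_drive(schedule: StimSchedule, rate: float, n: int, tau: float) -> np.ndarray:
    """Unit drive: 1 on plateaus, exponential recovery with time constant
    ``tau`` after each plateau offset, 0 elsewhere."""
    u = np.zeros(n)
    k = int(round(5 * tau * rate))
    decay = np.exp(-np.arange(1, k + 1) / (tau * rate))
    for _, p0, p1, _ in schedule.segments:
        i0 = max(int(np.ceil(p0 * rate)), 0)
        i1 = min(int(np.ceil(p1 * rate)), n)
        if i1 <= i0:
            continue
        u[i0:i1] = 1.0
        j1 = min(i1 + k, n)
        np.maximum(u[i1:j1], decay[: j1 - i1], out=u[i1:j1])
    return u


def _artifact_train(
    rng: np.random.Generator,
    n: int,
    rate: float,
    freq: float,
    intensity_frac: np.ndarray,
    schedule: StimSchedule,
    transient_gain: float = 1.0,
    transient_tau: float = 0.008,
    transient_freq: float = 80.0,
) -> np.ndarray:
    """Stimulation artifact in units of the configured amplitude.

    Two components mirror what survives common-mode rejection in practice:
    an asymmetric biphasic (net rectified) pulse train at the stimulation
    frequency, gated by intensity; and damped high-gamma ringing transients
    (amplifier settling) at every plateau onset and offset.  The transients
    sit inside the 4-100 Hz analysis band, so band-pass filtering alone
    cannot remove the artifact and threshold-based cleaning is required.
    """
    period = rate / freq
    onsets = np.arange(0.0, n - 2, period)
    k = onsets.astype(int)
    amp = rng.uniform(0.85, 1.15, size=k.size)
    a = np.zeros(n)
    np.add.at(a, k, amp)
    np.add.at(a, k + 1, -0.65 * amp)
    a *= intensity_frac
    m = int(round(6 * transient_tau * rate))
    tt = np.arange(m) / rate
    ring = np.cos(2.0 * np.pi * transient_freq * tt) * np.exp(-tt / transient_tau)
    for _, p0, p1, _ in schedule.segments:
        for t0, sign in ((p0, 1.0), (p1, -1.0)):
            i0 = int(np.ceil(t0 * rate))
            if 0 <= i0 < n:
                j1 = min(i0 + m, n)
                a[i0:j1] += (
                    sign * transient_gain * rng.uniform(0.7, 1.3) * ring[: j1 - i0]
                )
    return a


def inject_stim_artifact(
    session: SessionRecording,
    schedule: StimSchedule,
    cfg: LfpGenConfig,
    rng: np.random.Generator | None = None,
) -> SessionRecording:
    """Apply burst stimulation to a clean session.

    During plateaus the beta oscillator power is multiplied by
    ``1 - dbs_beta_suppression`` (relaxing back with ``suppression_tau``
    after each burst), and a pulse-train artifact of ``artifact_amplitude``
    uV (scaled per contact) is added wherever stimulation intensity is
    non-zero.  Returns a new SessionRecording; the input is untouched.
    """
    if session.components is None:
        raise ValueError("session lacks oscillator components; regenerate it")
    if schedule.duration > session.duration + 1.0 / session.rate:
        raise ValueError("schedule extends past the recording")
    if rng is None:
        rng = np.random.default_rng(0)
    n, rate = session.n_samples, session.rate
    lfp = session.lfp.copy()
    comp = {}
    for k, v in session.components.items():
        if isinstance(v, np.ndarray):
            comp[k] = v.copy()
        elif isinstance(v, list):
            comp[k] = [x.copy() for x in v]
        else:
            comp[k] = v
    intensity = schedule.intensity(rate, n)
    if schedule.n_bursts:
        g = cfg.dbs_beta_suppression
        if g > 0:
            u = _suppression_drive(schedule, rate, n, cfg.suppression_tau)
            factor = np.sqrt(1.0 - g * u)  # power scaled by 1 - g*u
            fm1 = factor - 1.0
            for h in range(session.n_hemispheres):
                supp = comp["beta_suppressible"][h]
                for c in range(N_CONTACTS):
                    lfp[h * N_CONTACTS + c] += fm1 * supp[c]
                comp["beta_suppressible"][h] = (supp * factor).astype(np.float32)
                comp["beta_env"][h] *= factor
        if cfg.artifact_amplitude > 0:
            train = _artifact_train(
                rng, n, rate, cfg.stim_frequency, intensity / schedule.amplitude,
                schedule,
            )
            art = cfg.artifact_amplitude * train
            for h in range(session.n_hemispheres):
                for c in range(N_CONTACTS):
                    lfp[h * N_CONTACTS + c] += _ARTIFACT_GAIN[c] * art
    return SessionRecording(
        subject=session.subject,
        rate=rate,
        lfp=lfp,
        channel_names=list(session.channel_names),
        force=session.force.copy(),
        stim_intensity=intensity,
        events=session.events.copy(),
        trials=session.trials.copy(),
        schedule=schedule,
        components=comp,
    )


def _session_duration(task: TaskConfig) -> float:
    """Upper bound on session length for schedule pre-generation."""
    per_trial = FIXATION_RANGE[1] + RESPONSE_WINDOW + BLANK_RANGE[1] + 2 * CUE_DURATION
    return SESSION_LEAD_IN + task.n_trials * per_trial + SESSION_TAIL


def simulate_session(
    subject: str,
    task: TaskConfig,
    agent: AgentConfig,
    lfp_cfg: LfpGenConfig,
    stim_cfg: StimScheduleConfig | None = None,
    stim_effect: StimBehaviorEffect | None = None,
    n_hemispheres: int = 2,
    seed: int | np.random.SeedSequence = 0,
) -> SessionRecording:
    """Generate one full session: behavior, force channel, LFPs, and
    (optionally) burst stimulation with its behavioral and neural effects."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s_sched, s_beh, s_lfp, s_art = [np.random.default_rng(c) for c in ss.spawn(4)]
    horizon = _session_duration(task)
    schedule = None
    if stim_cfg is not None and stim_cfg.enabled:
        schedule = generate_dbs_schedule(stim_cfg, horizon, s_sched)
    trials, events = simulate_agent_session(
        task, agent, s_beh, schedule=schedule, stim_effect=stim_effect
    )
    duration = events["onset"].max() + SESSION_TAIL
    n = int(round(duration * lfp_cfg.rate))
    force = synthesize_force_trace(trials, events, lfp_cfg.rate, duration)
    lfp, names, components = synthesize_lfp(
        trials, events, lfp_cfg, duration, s_lfp, n_hemispheres
    )
    session = SessionRecording(
        subject=subject,
        rate=lfp_cfg.rate,
        lfp=lfp,
        channel_names=names,
        force=force,
        stim_intensity=np.zeros(n),
        events=events,
        trials=trials,
        schedule=None,
        components=components,
    )
    if schedule is not None:
        # clip schedule bursts to the realized duration
        keep = schedule.segments[:, 2] <= duration if schedule.n_bursts else []
        schedule = StimSchedule(
            schedule.segments[keep] if schedule.n_bursts else schedule.segments,
            duration, schedule.amplitude, schedule.config,
        )
        session = inject_stim_artifact(session, schedule, lfp_cfg, s_art)
    return session


def simulate_behavior_session(
    subject: str,
    task: TaskConfig,
    agent: AgentConfig,
    stim_cfg: StimScheduleConfig | None = None,
    stim_effect: StimBehaviorEffect | None = None,
    raster_rate: float = 1000.0,
    seed: int | np.random.SeedSequence = 0,
) -> SessionRecording:
    """Behavior-only session (no LFP/force channels) for schedule and
    stimulation-behavior analyses: trial table, events, stimulation
    intensity channel at ``raster_rate``."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s_sched, s_beh = [np.random.default_rng(c) for c in ss.spawn(2)]
    horizon = _session_duration(task)
    schedule = None
    if stim_cfg is not None and stim_cfg.enabled:
        schedule = generate_dbs_schedule(stim_cfg, horizon, s_sched)
    trials, events = simulate_agent_session(
        task, agent, s_beh, schedule=schedule, stim_effect=stim_effect
    )
    duration = events["onset"].max() + SESSION_TAIL
    n = int(round(duration * raster_rate))
    intensity = schedule.intensity(raster_rate, n) if schedule is not None else np.zeros(n)
    if schedule is not None:
        keep = schedule.segments[:, 2] <= duration if schedule.n_bursts else []
        schedule = StimSchedule(
            schedule.segments[keep] if schedule.n_bursts else schedule.segments,
            duration, schedule.amplitude, schedule.config,
        )
    return SessionRecording(
        subject=subject,
        rate=raster_rate,
        lfp=np.empty((0, n)),
        channel_names=[],
        force=np.zeros(0),
        stim_intensity=intensity,
        events=events,
        trials=trials,
        schedule=schedule,
        components=None,
    )


def simulate_cohort(
    n_subjects: int = 16,
    task: TaskConfig = TaskConfig(),
    agent: AgentConfig = AgentConfig(),
    lfp_cfg: LfpGenConfig = LfpGenConfig(),
    stim_cfg: StimScheduleConfig | None = None,
    stim_effect: StimBehaviorEffect | None = None,
    n_hemispheres: int = 2,
    seed: int = 0,
) -> list[SessionRecording]:
    """Generate a cohort of independent subjects from one master seed."""
    root = np.random.SeedSequence(seed)
    sessions = []
    for i, child in enumerate(root.spawn(n_subjects)):
        sessions.append(
            simulate_session(
                f"sub-{i + 1:02d}", task, agent, lfp_cfg,
                stim_cfg=stim_cfg, stim_effect=stim_effect,
                n_hemispheres=n_hemispheres, seed=child,
            )
        )
    return sessions
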