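"""Spectral pipeline: preprocessing, bipolar montages, Morlet time-frequency
maps, whole-recording normalization, epoching, functional contact selection,
and stimulation-artifact removal.

Conventions: seconds everywhere, t = 0 at the alignment event, half-open
windows, zero-phase (forward-backward) Butterworth filtering so event
latencies are preserved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from mne.time_frequency import tfr_array_morlet
from scipy.signal import butter, resample_poly, sosfiltfilt
from scipy.signal import detrend as _detrend

__all__ = [
    "BandSpec",
    "TimeFrequencyMap",
    "Epochs",
    "ContactSelection",
    "preprocess_signal",
    "build_bipolar_montage",
    "narrow_pairs",
    "morlet_tfr",
    "baseline_normalize",
    "epoch_align",
    "select_functional_contact",
    "remove_stim_artifact",
]

PROC_RATE = 200.0  # analysis sampling rate after downsampling, Hz
TFR_STEP = 0.02  # time-frequency output grid, s

DEFAULT_BANDS = {
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (13.0, 30.0),
    "gamma": (55.0, 80.0),
}


@dataclass(frozen=True)
class BandSpec:
    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError("band bounds must satisfy low < high")

    @classmethod
    def default(cls, name: str) -> "BandSpec":
        lo, hi = DEFAULT_BANDS[name]
        return cls(name, lo, hi)


@dataclass
class TimeFrequencyMap:
    """Power by (channel, frequency, time) with normalization state."""

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    normalized: bool = False
    mask: np.ndarray | None = None  # True where artifactual, per time sample

    @property
    def step(self) -> float:
        return float(self.times[1] - self.times[0])

    def band_power(self, low: float, high: float) -> np.ndarray:
        """(channel, time) mean power over [low, high] Hz inclusive."""
        sel = (self.freqs >= low) & (self.freqs <= high)
        if not sel.any():
            raise ValueError(f"no frequencies in [{low}, {high}] Hz")
        return self.power[:, sel, :].mean(axis=1)


@dataclass
class Epochs:
    """Per-trial slices of a TimeFrequencyMap: (trial, channel, freq, time)."""

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray  # relative to the alignment event
    trial_index: np.ndarray  # trial ids, aligned with axis 0
    flagged: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


def preprocess_signal(x: np.ndarray, rate: float) -> tuple[np.ndarray, float]:
    """High-pass 1 Hz, band-stop 49-51 Hz, anti-alias low-pass, resample to
    200 Hz.  All filters are fourth-order zero-phase Butterworth.

    Returns (signal, 200.0).  Accepts (n,) or (channels, n).
    """
    if rate < 400.0:
        raise ValueError("input rate must be >= 400 Hz")
    x = np.atleast_2d(np.asarray(x, dtype=float))
    hp = butter(4, 1.0, btype="highpass", fs=rate, output="sos")
    bs = butter(4, (49.0, 51.0), btype="bandstop", fs=rate, output="sos")
    lp = butter(4, 90.0, btype="lowpass", fs=rate, output="sos")
    sos = np.vstack([hp, bs, lp])  # one cascade, one zero-phase pass
    y = sosfiltfilt(sos, x, axis=-1)
    up, down = _resample_ratio(rate, PROC_RATE)
    y = resample_poly(y, up, down, axis=-1)
    return np.squeeze(y), PROC_RATE


def _resample_ratio(rate_in: float, rate_out: float) -> tuple[int, int]:
    from fractions import Fraction

    fr = Fraction(rate_out / rate_in).limit_denominator(10000)
    return fr.numerator, fr.denominator


#: narrow-montage bipolar pairs (minuend, subtrahend) on the 8-contact lead:
#: dorsal ring vs the 3 dorsal directionals, dorsal vs corresponding ventral
#: directionals, ventral directionals vs ventral ring -> 9 channels.
NARROW_PAIRS = [
    (7, 4), (7, 5), (7, 6),
    (4, 1), (5, 2), (6, 3),
    (1, 0), (2, 0), (3, 0),
]


def narrow_pairs() -> list[tuple[int, int]]:
    return list(NARROW_PAIRS)


def build_bipolar_montage(
    contacts: np.ndarray, mode: str = "narrow"
) -> tuple[np.ndarray, list[str]]:
    """Construct bipolar channels from the 8 monopolar contacts of one lead.

    ``narrow`` gives the 9 neighboring pairs used off stimulation; ``wide``
    averages directional contacts into 4 ring levels and returns the two
    wide pairs (most-dorsal minus second-most-ventral level and most-ventral
    minus second-most-dorsal level) that straddle a stimulation contact.
    """
    contacts = np.asarray(contacts)
    if contacts.ndim != 2 or contacts.shape[0] != 8:
        raise ValueError("expected 8 monopolar contacts as (8, n_samples)")
    if mode == "narrow":
        sig = np.stack([contacts[a] - contacts[b] for a, b in NARROW_PAIRS])
        names = [f"{a}-{b}" for a, b in NARROW_PAIRS]
        return sig, names
    if mode == "wide":
        levels = np.stack(
            [contacts[0], contacts[1:4].mean(0), contacts[4:7].mean(0), contacts[7]]
        )
        sig = np.stack([levels[3] - levels[1], levels[0] - levels[2]])
        return sig, ["L3-L1", "L0-L2"]
    raise ValueError(f"unknown montage mode {mode!r}")


def morlet_tfr(
    x: np.ndarray,
    rate: float = PROC_RATE,
    freqs: np.ndarray | None = None,
    width: float = 7.0,
    step: float = TFR_STEP,
) -> TimeFrequencyMap:
    """Continuous Morlet transform (width = 7 cycles), power on a
    2-100 Hz x 1 Hz grid at 20 ms steps by default.

    The transform runs at the signal rate and the power series is decimated
    to the output grid.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if freqs is None:
        freqs = np.arange(2.0, 101.0, 1.0)
    freqs = np.asarray(freqs, dtype=float)
    min_len = width / freqs.min() * rate
    if x.shape[-1] < min_len:
        raise ValueError("recording shorter than the lowest-frequency wavelet")
    decim = int(round(step * rate))
    if abs(decim - step * rate) > 1e-9:
        raise ValueError("step must be an integer number of samples")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # mne chunking notices
        power = tfr_array_morlet(
            x[np.newaxis], sfreq=rate, freqs=freqs, n_cycles=width,
            output="power", decim=decim, verbose="error",
        )[0]
    times = np.arange(power.shape[-1]) * (decim / rate)
    return TimeFrequencyMap(power=power, freqs=freqs, times=times)


def baseline_normalize(
    tfr: TimeFrequencyMap, mask: np.ndarray | None = None
) -> TimeFrequencyMap:
    """Divide each frequency row by its mean power across the whole
    recording, excluding masked (artifactual) time samples."""
    if tfr.normalized:
        raise ValueError("map is already normalized")
    if mask is None:
        mask = np.zeros(tfr.power.shape[-1], dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape[-1] != tfr.power.shape[-1]:
        raise ValueError("mask length must equal the time axis")
    keep = ~mask
    if not keep.any():
        raise ValueError("all time samples are masked")
    denom = tfr.power[..., keep].mean(axis=-1, keepdims=True)
    if np.any(denom <= 0):
        raise ValueError("non-positive mean power in some frequency row")
    return TimeFrequencyMap(
        power=tfr.power / denom, freqs=tfr.freqs, times=tfr.times,
        normalized=True, mask=mask,
    )


def epoch_align(
    tfr: TimeFrequencyMap,
    event_times: np.ndarray,
    window: tuple[float, float],
    trial_index: np.ndarray | None = None,
) -> Epochs:
    """Slice the continuous map around each event; t = 0 at the event.

    Trials whose epoch would extend past the recording edges are flagged and
    dropped from the output.
    """
    event_times = np.asarray(event_times, dtype=float)
    if trial_index is None:
        trial_index = np.arange(event_times.size)
    trial_index = np.asarray(trial_index)
    step = tfr.step
    n_t = tfr.times.size
    i_rel0 = int(np.round(window[0] / step))
    i_rel1 = int(np.round(window[1] / step))
    rel = np.arange(i_rel0, i_rel1 + 1)
    out, keep, flagged = [], [], []
    for k, t0 in enumerate(event_times):
        ic = int(np.round((t0 - tfr.times[0]) / step))
        idx = ic + rel
        if idx[0] < 0 or idx[-1] >= n_t:
            flagged.append(trial_index[k])
            continue
        out.append(tfr.power[..., idx])
        keep.append(trial_index[k])
    if not out:
        raise ValueError("no epochs fall inside the recording")
    return Epochs(
        power=np.stack(out),
        freqs=tfr.freqs,
        times=rel * step,
        trial_index=np.asarray(keep),
        flagged=np.asarray(flagged, dtype=int),
    )


@dataclass
class ContactSelection:
    channel: int
    beta_peak: float  # Hz, frequency of maximal movement modulation
    modulation: float  # fractional beta reduction during movement
    reached_threshold: bool  # >15% reduction reached


def select_functional_contact(
    epochs: Epochs,
    beta_range: tuple[float, float] = (13.0, 30.0),
    movement_window: tuple[float, float] = (-0.5, 0.25),
    threshold: float = 0.15,
    peak_halfwidth: float = 3.0,
) -> ContactSelection:
    """Functional localizer on movement-aligned, normalized epochs.

    For every candidate bipolar channel, find the frequency of maximal
    movement-related modulation within the beta range, measure the mean
    normalized power reduction in ``movement_window`` over the subject beta
    band (peak +/- 3 Hz), and pick the channel with the strongest decrease.
    Hemispheres where no channel reaches the 15% reduction are flagged via
    ``reached_threshold``.
    """
    if epochs.power.ndim != 4 or epochs.power.shape[1] < 1:
        raise ValueError("need movement-aligned epochs as (trial, ch, freq, time)")
    f = epochs.freqs
    in_beta = (f >= beta_range[0]) & (f <= beta_range[1])
    if not in_beta.any():
        raise ValueError("no frequencies inside the beta range")
    tsel = (epochs.times >= movement_window[0]) & (epochs.times < movement_window[1])
    mean_map = epochs.power.mean(axis=0)  # (ch, freq, time)
    move = mean_map[:, :, tsel].mean(axis=-1)  # (ch, freq), normalized power
    best_mod, best_ch, best_peak = -np.inf, -1, np.nan
    beta_freqs = f[in_beta]
    for ch in range(move.shape[0]):
        reduction = 1.0 - move[ch, in_beta]
        i_pk = int(np.argmax(reduction))
        pk = beta_freqs[i_pk]
        band = (f >= pk - peak_halfwidth) & (f <= pk + peak_halfwidth) & in_beta
        mod = 1.0 - move[ch, band].mean()
        if mod > best_mod:
            best_mod, best_ch, best_peak = mod, ch, pk
    return ContactSelection(
        channel=best_ch,
        beta_peak=float(best_peak),
        modulation=float(best_mod),
        reached_threshold=bool(best_mod > threshold),
    )


def remove_stim_artifact(
    x: np.ndarray,
    rate: float,
    threshold: float = 10.0,
) -> tuple[np.ndarray, float, dict]:
    """Clean a wide-bipolar channel recorded during burst stimulation.

    Band-pass 4-100 Hz (fourth-order zero-phase Butterworth), demean and
    detrend, replace samples with |x| > ``threshold`` uV by linear
    interpolation between neighboring retained samples (edges hold the
    nearest retained sample), then downsample to 200 Hz.

    Returns (cleaned_signal, 200.0, info) where ``info`` holds the fraction
    of samples removed and a quality flag when more than half the data was
    interpolated.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a single channel")
    hp = butter(4, 4.0, btype="highpass", fs=rate, output="sos")
    lp = butter(4, min(100.0, 0.45 * rate), btype="lowpass", fs=rate, output="sos")
    y = sosfiltfilt(lp, sosfiltfilt(hp, x))
    y = _detrend(y - y.mean())
    bad = np.abs(y) > threshold
    frac = float(bad.mean())
    if bad.any():
        good = np.flatnonzero(~bad)
        if good.size == 0:
            raise ValueError("every sample exceeds the artifact threshold")
        y[bad] = np.interp(np.flatnonzero(bad), good, y[good])
    if frac > 0.5:
        warnings.warn(f"{frac:.0%} of samples exceeded the artifact threshold")
    up, down = _resample_ratio(rate, PROC_RATE)
    y = resample_poly(y, up, down)
    return y, PROC_RATE, {"removed_fraction": frac, "quality_flag": frac > 0.5}
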