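"""Trial validity filtering, kinetic feature extraction, and force-adaptation
summaries.

Validity follows the task rule: a trial counts only if exactly one press
occurred inside the response window, and between-trial measures additionally
require the previous trial to be valid.  Kinetic features are computed per
press against a robust baseline (median of a 5 s window centered on the
Go-cue).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "KineticFeatures",
    "AdaptationSummary",
    "count_presses",
    "filter_valid_trials",
    "estimate_baseline",
    "extract_kinetics",
    "adaptation_summaries",
]


@dataclass(frozen=True)
class KineticFeatures:
    baseline: float  # %MVC
    peak_force: float  # peak minus baseline, %MVC
    peak_yank: float  # %MVC/s
    peak_negative_yank: float  # %MVC/s
    auc: float  # %MVC * s
    reaction_time: float  # s, Go-cue to peak force


@dataclass(frozen=True)
class AdaptationSummary:
    rmse: float
    mean_value: float
    mean_force_error: float
    cv: float
    mean_abs_change: float
    corr_actual_target: float
    corr_value_next_abs_change: float
    n_valid: int


def count_presses(
    force: np.ndarray,
    rate: float,
    window: tuple[float, float],
    baseline: float = 0.0,
    threshold: float = 5.0,
    min_duration: float = 0.1,
) -> int:
    """Number of presses in a response window.

    A press is a supra-baseline excursion exceeding ``threshold`` %MVC for at
    least ``min_duration`` s.
    """
    i0 = max(int(np.ceil(window[0] * rate)), 0)
    i1 = min(int(np.ceil(window[1] * rate)), force.size)
    above = force[i0:i1] > baseline + threshold
    if not above.any():
        return 0
    edges = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        ends = np.r_[ends, above.size]
    lengths = (ends - starts) / rate
    return int(np.sum(lengths >= min_duration))


def filter_valid_trials(
    trials: pd.DataFrame, press_counts: np.ndarray | pd.Series
) -> pd.DataFrame:
    """Attach validity flags: ``valid`` iff exactly one press, and
    ``previous_valid`` (for between-trial measures) iff the preceding trial
    was valid too."""
    counts = np.asarray(press_counts)
    if counts.size != len(trials):
        raise ValueError("press counts must match the trial table")
    valid = counts == 1
    prev = np.zeros_like(valid)
    prev[1:] = valid[1:] & valid[:-1]
    out = trials.copy()
    out["valid"] = valid
    out["previous_valid"] = prev
    return out


def estimate_baseline(force: np.ndarray, rate: float, go_time: float,
                      half_width: float = 2.5) -> float:
    """Median force in [go - 2.5 s, go + 2.5 s], truncated at the edges."""
    i0 = max(int(np.ceil((go_time - half_width) * rate)), 0)
    i1 = min(int(np.ceil((go_time + half_width) * rate)), force.size)
    if i1 <= i0:
        raise ValueError("baseline window lies outside the recording")
    return float(np.median(force[i0:i1]))


def extract_kinetics(
    force: np.ndarray,
    rate: float,
    go_time: float,
    press_window: tuple[float, float] | None = None,
    baseline: float | None = None,
) -> KineticFeatures:
    """Kinetic features of the press following ``go_time``.

    Yank is the central finite difference of the raw force channel; AUC
    integrates force minus baseline over the press window (where force
    exceeds the baseline); reaction time runs from Go-cue to peak force.
    """
    if rate <= 0:
        raise ValueError("non-monotone or invalid time base")
    if baseline is None:
        baseline = estimate_baseline(force, rate, go_time)
    if press_window is None:
        press_window = (go_time, go_time + 2.5)
    i0 = max(int(np.ceil(press_window[0] * rate)), 0)
    i1 = min(int(np.ceil(press_window[1] * rate)), force.size)
    seg = force[i0:i1]
    ipk = i0 + int(np.argmax(seg))
    peak_force = float(force[ipk] - baseline)
    yank = np.gradient(force, 1.0 / rate)
    above = seg > baseline
    auc = float(np.sum((seg[above] - baseline)) / rate)
    return KineticFeatures(
        baseline=float(baseline),
        peak_force=peak_force,
        peak_yank=float(yank[i0:i1].max()),
        peak_negative_yank=float(yank[i0:i1].min()),
        auc=auc,
        reaction_time=float(ipk / rate - go_time),
    )


def _corr(x: np.ndarray, y: np.ndarray) -> float:
    if x.size < 2 or np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(stats.pearsonr(x, y)[0])


def adaptation_summaries(trials: pd.DataFrame) -> AdaptationSummary:
    """Session-level adaptation measures on valid trials.

    RMSE, mean Value, mean signed force error, coefficient of variation
    (sd of force / mean force), mean absolute by-trial change, the
    actual-vs-target correlation, and the Value(t) vs |change|(t+1)
    correlation.  Between-trial quantities use consecutive-valid pairs only.
    """
    v = trials[trials["valid"].astype(bool)]
    if len(v) < 2:
        raise ValueError("need at least 2 valid trials")
    err = (v["actual"] - v["target"]).to_numpy()
    force = v["actual"].to_numpy()
    rmse = float(np.sqrt(np.mean(err**2)))
    cv = float(np.std(force) / np.mean(force))
    pv = trials["previous_valid"].astype(bool)
    abs_change = trials.loc[pv, "abs_change"].to_numpy()
    if abs_change.size == 0:
        warnings.warn("no consecutive valid trial pairs; lagged measures undefined")
    # pair Value on trial t with |change| on trial t+1 (both trials valid)
    val = trials["value"].to_numpy()
    nxt = np.flatnonzero(pv.to_numpy())
    corr_v_c = _corr(val[nxt - 1], trials["abs_change"].to_numpy()[nxt]) if nxt.size else float("nan")
    return AdaptationSummary(
        rmse=rmse,
        mean_value=float(v["value"].mean()),
        mean_force_error=float(err.mean()),
        cv=cv,
        mean_abs_change=float(abs_change.mean()) if abs_change.size else float("nan"),
        corr_actual_target=_corr(force, v["target"].to_numpy()),
        corr_value_next_abs_change=corr_v_c,
        n_valid=int(len(v)),
    )
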