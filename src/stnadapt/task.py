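"""Force-tracking task model.

The task asks a participant (or synthetic agent) to squeeze a dynamometer so
that peak grip force matches a hidden target, expressed in percent of maximum
voluntary contraction (%MVC).  The target follows a decaying Gaussian random
walk

    mu[t+1] = mu[t] * lam + (1 - lam) * theta + nu,   nu ~ N(0, noise_sd),

i.e. an AR(1) process pulled towards an attractor ``theta``.  After each
press two feedback cues are shown: a Value score (0-10 points, decreasing
with absolute force error) and a Direction cue scalarized as
``(10 - value) * sign(actual - target)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TaskConfig",
    "simulate_target_trajectory",
    "score_value_feedback",
    "score_direction_feedback",
    "compute_change_predictors",
]


@dataclass(frozen=True)
class TaskConfig:
    """Parameters of the target-force random walk.

    decay
        AR(1) decay ``lam`` in (0, 1]; the closer to 1 the slower the pull
        towards the attractor.
    attractor
        Stationary mean ``theta`` of the walk, %MVC.
    noise_sd
        Standard deviation of the innovation ``nu``, %MVC.
    start_mean, start_sd
        The first target is drawn from N(start_mean, start_sd), %MVC.
    """

    decay: float = 0.98
    attractor: float = 25.0
    noise_sd: float = 2.0
    start_mean: float = 25.0
    start_sd: float = 2.0
    n_trials: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("decay", "attractor", "noise_sd", "start_mean", "start_sd"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"TaskConfig.{name} must be finite, got {v!r}")
        if not 0.0 < self.decay <= 1.0:
            raise ValueError(f"decay must lie in (0, 1], got {self.decay}")
        if self.noise_sd < 0 or self.start_sd < 0:
            raise ValueError("noise_sd and start_sd must be non-negative")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")


def simulate_target_trajectory(
    config: TaskConfig, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Simulate the per-trial target force, %MVC.

    Reproducible: with ``rng`` omitted a fresh generator is seeded from
    ``config.seed``.  Draws are consumed in trial order (start value first,
    then one innovation per transition).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    mu = np.empty(config.n_trials)
    mu[0] = config.start_mean + config.start_sd * rng.standard_normal()
    lam, theta = config.decay, config.attractor
    for t in range(config.n_trials - 1):
        nu = config.noise_sd * rng.standard_normal()
        mu[t + 1] = mu[t] * lam + (1.0 - lam) * theta + nu
    return mu


def score_value_feedback(actual: float, target: float) -> int:
    """Points (0-10) for a press: 10 for error <=1 %MVC, 9 for (1,2], ...,
    1 for (9,10], 0 beyond 10 %MVC.

    Bin edges are upper-inclusive, so an error of exactly 1.0 still scores 10.
    """
    if not (math.isfinite(actual) and math.isfinite(target)):
        raise ValueError("actual and target force must be finite")
    err = abs(actual - target)
    if err == 0.0:
        return 10
    return max(0, 11 - math.ceil(err))


def score_direction_feedback(value: int, signed_error: float) -> int:
    """Direction scalar ``(10 - value) * sign(signed_error)`` in [-10, 10].

    Negative means the force was too low, positive too high; 0 when the press
    earned full points.
    """
    if not 0 <= value <= 10:
        raise ValueError(f"value must lie in [0, 10], got {value}")
    if value == 10:
        return 0
    return int((10 - value) * np.sign(signed_error))


def compute_change_predictors(
    forces: np.ndarray, valid: np.ndarray | None = None
) -> pd.DataFrame:
    """Trial-to-trial force-change predictors.

    ``signed_change[t] = force[t] - force[t-1]`` and its absolute value,
    defined only when trial ``t`` and trial ``t-1`` are both valid.  Undefined
    entries are NaN with ``previous_valid`` False.
    """
    forces = np.asarray(forces, dtype=float)
    if forces.ndim != 1 or forces.size < 2:
        raise ValueError("need a 1-D sequence of at least 2 trial forces")
    if valid is None:
        valid = np.ones(forces.size, dtype=bool)
    valid = np.asarray(valid, dtype=bool)
    if valid.shape != forces.shape:
        raise ValueError("validity flags must match the force sequence")
    if not valid.any():
        import warnings

        warnings.warn("all trials invalid; change predictors are all undefined")
    signed = np.full(forces.size, np.nan)
    prev_ok = np.zeros(forces.size, dtype=bool)
    prev_ok[1:] = valid[1:] & valid[:-1]
    signed[prev_ok] = forces[prev_ok] - forces[np.flatnonzero(prev_ok) - 1]
    return pd.DataFrame(
        {
            "signed_change": signed,
            "abs_change": np.abs(signed),
            "previous_valid": prev_ok,
        }
    )
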