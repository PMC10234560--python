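"""Randomized DBS burst schedules.

Stimulation is delivered in short bursts rather than continuously so that
timing-specific effects can be inferred: plateau durations and inter-burst
intervals are drawn from uniform distributions (defaults 150-350 ms and
75-225 ms), and every plateau is flanked by linear intensity ramps whose
intensity stays below the clinically effective amplitude.  Only plateau
samples count as stimulation ON.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["StimScheduleConfig", "StimSchedule", "generate_dbs_schedule"]

_RAMP_CEIL = 0.95  # ramp peak as a fraction of the plateau amplitude


@dataclass(frozen=True)
class StimScheduleConfig:
    """Burst schedule parameters (all durations in seconds)."""

    burst_min: float = 0.150
    burst_max: float = 0.350
    interval_min: float = 0.075
    interval_max: float = 0.225
    ramp_up: float = 0.175
    ramp_down: float = 0.175
    frequency: float = 130.0  # stimulation pulse rate, Hz
    amplitude: float = 2.0  # programmed plateau intensity, mA
    enabled: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burst_min > self.burst_max or self.interval_min > self.interval_max:
            raise ValueError("uniform bounds must satisfy min <= max")
        if min(self.burst_min, self.interval_min) < 0:
            raise ValueError("durations must be non-negative")
        if self.ramp_up < 0 or self.ramp_down < 0:
            raise ValueError("ramps must be non-negative")


@dataclass
class StimSchedule:
    """Burst segment list plus helpers to rasterize it.

    ``segments`` has one row per burst:
    (ramp_up_start, plateau_start, plateau_end, ramp_down_end), seconds,
    non-overlapping and ordered.
    """

    segments: np.ndarray  # (n_bursts, 4)
    duration: float
    amplitude: float = 2.0
    config: StimScheduleConfig | None = field(default=None, repr=False)

    @property
    def n_bursts(self) -> int:
        return len(self.segments)

    def suprathreshold(self, rate: float, n_samples: int) -> np.ndarray:
        """Per-sample boolean, True exactly on plateau samples.

        Sample i covers time [i/rate, (i+1)/rate); half-open plateau
        [start, end) convention.
        """
        on = np.zeros(n_samples, dtype=bool)
        for _, p0, p1, _ in self.segments:
            i0 = int(np.ceil(p0 * rate))
            i1 = int(np.ceil(p1 * rate))
            on[max(i0, 0) : min(i1, n_samples)] = True
        return on

    def intensity(self, rate: float, n_samples: int) -> np.ndarray:
        """Stimulation intensity channel (mA): linear ramps up to the
        programmed amplitude, constant on plateaus, zero elsewhere."""
        out = np.zeros(n_samples)

        def _idx(t0: float, t1: float) -> tuple[int, int]:
            return (max(int(np.ceil(t0 * rate - 1e-9)), 0),
                    min(int(np.ceil(t1 * rate - 1e-9)), n_samples))

        for r0, p0, p1, r1 in self.segments:
            # ramps stay below the clinically effective plateau intensity
            if p0 > r0:
                i0, i1 = _idx(r0, p0)
                if i1 > i0:
                    t = np.arange(i0, i1) / rate
                    out[i0:i1] = _RAMP_CEIL * (t - r0) / (p0 - r0)
            i0, i1 = _idx(p0, p1)
            out[i0:i1] = 1.0
            if r1 > p1:
                i0, i1 = _idx(p1, r1)
                if i1 > i0:
                    t = np.arange(i0, i1) / rate
                    out[i0:i1] = _RAMP_CEIL * (1.0 - (t - p1) / (r1 - p1))
        return out * self.amplitude


def generate_dbs_schedule(
    cfg: StimScheduleConfig, duration: float, rng: np.random.Generator | None = None
) -> StimSchedule:
    """Draw an alternating burst/interval schedule covering ``duration`` s.

    The sequence starts with an inter-burst interval, then repeats
    ramp-up -> plateau -> ramp-down -> interval until the recording ends.
    Deterministic under ``cfg.seed`` when ``rng`` is omitted.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if not cfg.enabled:
        return StimSchedule(np.empty((0, 4)), duration, cfg.amplitude, cfg)
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    rows = []
    t = rng.uniform(cfg.interval_min, cfg.interval_max)
    while t < duration:
        r0 = t
        p0 = r0 + cfg.ramp_up
        p1 = p0 + rng.uniform(cfg.burst_min, cfg.burst_max)
        r1 = p1 + cfg.ramp_down
        if p1 > duration:
            break
        rows.append((r0, p0, p1, r1))
        t = r1 + rng.uniform(cfg.interval_min, cfg.interval_max)
    seg = np.array(rows) if rows else np.empty((0, 4))
    return StimSchedule(seg, duration, cfg.amplitude, cfg)
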