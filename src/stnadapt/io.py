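"""Session container I/O.

A session is stored as an HDF5 file (datasets ``/lfp``, ``/force``,
``/stim_intensity``, optional ``/schedule_segments``; attributes hold rates,
units, channel names) with sidecar TSV tables for events and trials.  The
events table uses BIDS-events-style columns (onset, duration, trial,
event_type) in seconds.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .cohort import SessionRecording
from .schedule import StimSchedule

__all__ = [
    "write_session",
    "read_session",
    "write_tfr",
    "read_tfr",
    "events_path",
    "trials_path",
]

EVENT_COLUMNS = ["onset", "duration", "trial", "event_type"]


def events_path(path: Path | str) -> Path:
    p = Path(path)
    return p.with_name(p.stem + "_events.tsv")


def trials_path(path: Path | str) -> Path:
    p = Path(path)
    return p.with_name(p.stem + "_trials.tsv")


def write_session(path: Path | str, session: SessionRecording) -> list[Path]:
    """Write a session container; returns the files written."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.attrs["subject"] = session.subject
        f.attrs["rate_hz"] = session.rate
        f.attrs["channel_names"] = json.dumps(session.channel_names)
        f.attrs["units"] = json.dumps(
            {"lfp": "uV", "force": "%MVC", "stim_intensity": "mA"}
        )
        f.create_dataset("lfp", data=session.lfp)
        f.create_dataset("force", data=session.force)
        f.create_dataset("stim_intensity", data=session.stim_intensity)
        if session.schedule is not None and session.schedule.n_bursts:
            d = f.create_dataset("schedule_segments", data=session.schedule.segments)
            d.attrs["amplitude_mA"] = session.schedule.amplitude
            d.attrs["duration_s"] = session.schedule.duration
    ev, tr = events_path(path), trials_path(path)
    session.events.to_csv(ev, sep="\t", index=False)
    session.trials.to_csv(tr, sep="\t", index=False)
    return [path, ev, tr]


def write_tfr(path: Path | str, tfr) -> Path:
    """Persist a TimeFrequencyMap (power + axis vectors + artifact mask)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.create_dataset("power", data=tfr.power)
        f.create_dataset("freqs", data=tfr.freqs)
        f.create_dataset("times", data=tfr.times)
        f.attrs["normalized"] = bool(tfr.normalized)
        if tfr.mask is not None:
            f.create_dataset("mask", data=tfr.mask.astype(bool))
    return path


def read_tfr(path: Path | str):
    from .spectral import TimeFrequencyMap

    with h5py.File(path, "r") as f:
        return TimeFrequencyMap(
            power=f["power"][()],
            freqs=f["freqs"][()],
            times=f["times"][()],
            normalized=bool(f.attrs["normalized"]),
            mask=f["mask"][()] if "mask" in f else None,
        )


def read_session(path: Path | str) -> SessionRecording:
    """Read a session container written by :func:`write_session`.

    Oscillator components are not persisted, so stimulation effects cannot
    be re-injected into a re-read session.
    """
    path = Path(path)
    with h5py.File(path, "r") as f:
        for name in ("lfp", "force", "stim_intensity"):
            if name not in f:
                raise ValueError(f"session file {path} lacks dataset /{name}")
        lfp = f["lfp"][()]
        force = f["force"][()]
        stim = f["stim_intensity"][()]
        rate = float(f.attrs["rate_hz"])
        subject = str(f.attrs["subject"])
        channel_names = json.loads(f.attrs["channel_names"])
        schedule = None
        if "schedule_segments" in f:
            d = f["schedule_segments"]
            schedule = StimSchedule(
                d[()], float(d.attrs["duration_s"]), float(d.attrs["amplitude_mA"])
            )
    ev_file, tr_file = events_path(path), trials_path(path)
    if not ev_file.exists():
        raise ValueError(f"missing events sidecar {ev_file}")
    events = pd.read_csv(ev_file, sep="\t")
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise ValueError(f"events table {ev_file} lacks column(s): {', '.join(missing)}")
    trials = pd.read_csv(tr_file, sep="\t")
    return SessionRecording(
        subject=subject,
        rate=rate,
        lfp=lfp,
        channel_names=channel_names,
        force=force,
        stim_intensity=stim,
        events=events,
        trials=trials,
        schedule=schedule,
        components=None,
    )
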