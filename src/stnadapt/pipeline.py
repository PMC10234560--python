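"""End-to-end analyses composed from the library modules.

These are the session-to-statistics paths the command-line interface and the
reproduction script call: behavior summaries, the functional-localizer +
sliding mixed-model regressions (feedback- and movement-aligned), the
timing-specific stimulation contrasts, schedule coverage, and the
artifact-removal / burst-suppression quantifications.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import behavior as beh
from .cohort import SessionRecording
from .task import compute_change_predictors
from .schedule import StimScheduleConfig, generate_dbs_schedule
from .spectral import (
    ContactSelection,
    baseline_normalize,
    build_bipolar_montage,
    epoch_align,
    morlet_tfr,
    preprocess_signal,
    remove_stim_artifact,
    select_functional_contact,
)
from .stats import (
    SlidingWindowDesign,
    cluster_permutation_trials,
    window_means,
    zscore_and_prune,
)
from .stim import (
    binarize_stimulation,
    cluster_permutation_labels,
    stim_aligned_beta,
    stim_behavior_contrast,
    window_stim_labels,
)

__all__ = [
    "subject_beta_series",
    "beta_window_matrix",
    "single_trial_regression",
    "stim_behavior_test",
    "schedule_coverage",
    "clean_wide_beta",
    "artifact_recovery",
    "behavior_summary",
    "run_pipeline",
]

BETA_RANGE = (13.0, 30.0)


def _beta_freqs(beta_range: tuple[float, float]) -> np.ndarray:
    return np.arange(beta_range[0], beta_range[1] + 0.5, 1.0)


def subject_beta_series(
    session: SessionRecording,
    beta_range: tuple[float, float] = BETA_RANGE,
    peak_halfwidth: float = 3.0,
    localize: bool = True,
    localizer_freq_step: float = 2.0,
    fixed_band: tuple[float, float] = (17.0, 23.0),
) -> tuple[np.ndarray, np.ndarray, list[ContactSelection]]:
    """One normalized beta-power series per subject via the functional
    localizer.

    Per hemisphere: preprocess the 8 monopolar contacts, build the 9-channel
    narrow bipolar montage, Morlet-transform the beta range, normalize each
    frequency to its whole-recording mean, and pick the channel with the
    strongest movement-related beta decrease (>15% required; flagged
    otherwise).  The selected channels' subject-specific beta-band
    (peak +/- 3 Hz) power is averaged across hemispheres.  To save compute,
    the per-channel localizer scan uses a 2 Hz frequency step and the
    selected channel is then re-transformed at 1 Hz resolution.

    With ``localize=False`` the scan is skipped: the dorsal-ring/dorsal-
    directional pair with the steepest beta gradient is taken directly with
    the ``fixed_band`` beta definition (used by large calibration batteries
    where channel selection is not under study).

    Returns (beta_power (n_times,), times, per-hemisphere selections).
    """
    peak_times = session.event_times("peak_force").to_numpy()
    series = []
    selections: list[ContactSelection] = []
    for h in range(session.n_hemispheres):
        contacts = session.hemisphere_contacts(h)
        if not localize:
            from .cohort import DESIGNATED_DORSAL_PAIR

            a, b = DESIGNATED_DORSAL_PAIR
            proc, rate = preprocess_signal(contacts[a] - contacts[b], session.rate)
            freqs = np.arange(fixed_band[0], fixed_band[1] + 0.5, 1.0)
            tfr = baseline_normalize(morlet_tfr(proc, rate, freqs=freqs))
            series.append(tfr.band_power(*fixed_band)[0])
            times = tfr.times
            selections.append(ContactSelection(
                channel=0, beta_peak=0.5 * sum(fixed_band),
                modulation=float("nan"), reached_threshold=True,
            ))
            continue
        bip, _ = build_bipolar_montage(contacts, "narrow")
        proc, rate = preprocess_signal(bip, session.rate)
        scan_freqs = np.arange(beta_range[0], beta_range[1] + 0.5,
                               localizer_freq_step)
        tfr = baseline_normalize(morlet_tfr(proc, rate, freqs=scan_freqs))
        mov = epoch_align(tfr, peak_times, (-1.0, 0.5))
        sel = select_functional_contact(mov, beta_range=beta_range,
                                        peak_halfwidth=peak_halfwidth)
        selections.append(sel)
        lo = max(sel.beta_peak - peak_halfwidth, beta_range[0])
        hi = min(sel.beta_peak + peak_halfwidth, beta_range[1])
        fine = baseline_normalize(
            morlet_tfr(proc[sel.channel], rate, freqs=np.arange(lo, hi + 0.5, 1.0))
        )
        series.append(fine.band_power(lo, hi)[0])
        times = fine.times
    return np.mean(series, axis=0), times, selections


def _predictor_table(session: SessionRecording, alignment: str) -> pd.DataFrame:
    """Trials usable for the given alignment, with their predictors and the
    alignment event time."""
    tr = session.trials
    if alignment == "value_cue":
        ev = session.event_times("value_cue")
        use = tr[tr["valid"] & tr["value"].notna() & tr["trial"].isin(ev.index)]
        return pd.DataFrame(
            {
                "trial": use["trial"].to_numpy(),
                "onset": ev.loc[use["trial"]].to_numpy(),
                "x1": use["value"].to_numpy(),
                "x2": use["direction"].to_numpy(),
            }
        )
    if alignment == "peak_force":
        ev = session.event_times("peak_force")
        use = tr[tr["previous_valid"] & tr["trial"].isin(ev.index)]
        return pd.DataFrame(
            {
                "trial": use["trial"].to_numpy(),
                "onset": ev.loc[use["trial"]].to_numpy(),
                "x1": use["abs_change"].to_numpy(),
                "x2": use["signed_change"].to_numpy(),
            }
        )
    raise ValueError(f"unknown alignment {alignment!r}")


PREDICTOR_NAMES = {
    "value_cue": ["value", "direction"],
    "peak_force": ["abs_change", "signed_change"],
}


def beta_window_matrix(
    beta: np.ndarray,
    times: np.ndarray,
    onsets: np.ndarray,
    design: SlidingWindowDesign,
) -> tuple[np.ndarray, np.ndarray]:
    """Sliding-window means of a continuous power series around events.

    Returns (matrix (n_events, n_windows), kept event row indices)."""
    from .spectral import TimeFrequencyMap

    tfr = TimeFrequencyMap(
        power=beta[np.newaxis, np.newaxis], freqs=np.array([0.0]), times=times,
        normalized=True,
    )
    pad = design.step  # guard one step beyond the last window edge
    ep = epoch_align(tfr, onsets, (design.start - pad, design.stop + pad))
    vals = ep.power[:, 0, 0, :]
    return window_means(vals, ep.times, design), ep.trial_index


def single_trial_regression(
    sessions: list[SessionRecording],
    alignment: str = "value_cue",
    design: SlidingWindowDesign | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    beta_range: tuple[float, float] = BETA_RANGE,
    localize: bool = True,
):
    """Sliding mixed-model regression of single-trial beta power on the
    trial predictors, cluster-permutation corrected.

    Feedback alignment regresses on Value and Direction over 0-2 s after
    the Value-cue; movement alignment on absolute and signed force change
    over -1-0 s before peak force.  Returns a dict with the per-predictor
    ClusterTestResults and the standardized data that entered the model.
    """
    if design is None:
        design = (SlidingWindowDesign.feedback() if alignment == "value_cue"
                  else SlidingWindowDesign.movement())
    values, preds, subjects = [], [], []
    flags = []
    for session in sessions:
        table = _predictor_table(session, alignment)
        beta, times, sel = subject_beta_series(session, beta_range,
                                               localize=localize)
        flags.append(sel)
        mat, kept = beta_window_matrix(beta, times, table["onset"].to_numpy(), design)
        values.append(mat)
        preds.append(table.iloc[kept][["x1", "x2"]].to_numpy())
        subjects.append(np.repeat(session.subject, mat.shape[0]))
    V = np.vstack(values)
    P = np.vstack(preds)
    S = np.concatenate(subjects)
    z, keep = zscore_and_prune(V, S)
    results = cluster_permutation_trials(
        z[keep], P[keep], S[keep], design,
        predictor_names=PREDICTOR_NAMES[alignment],
        n_perm=n_perm, seed=seed,
    )
    return {
        "results": results,
        "values_z": z,
        "kept": keep,
        "predictors": P,
        "subjects": S,
        "design": design,
        "selections": flags,
        "excluded_fraction": float(1.0 - keep.mean()),
    }


def _stim_behavior_table(session: SessionRecording, alignment: str) -> pd.DataFrame:
    """Alignment events paired with the behavior the contrast uses: the
    *next* trial's absolute change for feedback alignment, the *current*
    trial's for movement alignment."""
    tr = session.trials.set_index("trial")
    if alignment == "value_cue":
        ev = session.event_times("value_cue")
        rows = []
        for t, onset in ev.items():
            if t + 1 in tr.index and bool(tr.loc[t + 1, "previous_valid"]):
                rows.append((t, onset, float(tr.loc[t + 1, "abs_change"])))
        return pd.DataFrame(rows, columns=["trial", "onset", "behavior"])
    if alignment == "peak_force":
        ev = session.event_times("peak_force")
        rows = []
        for t, onset in ev.items():
            if t in tr.index and bool(tr.loc[t, "previous_valid"]):
                rows.append((t, onset, float(tr.loc[t, "abs_change"])))
        return pd.DataFrame(rows, columns=["trial", "onset", "behavior"])
    raise ValueError(f"unknown alignment {alignment!r}")


def stim_behavior_test(
    sessions: list[SessionRecording],
    alignment: str = "value_cue",
    design: SlidingWindowDesign | None = None,
    n_perm: int = 1000,
    seed: int = 0,
):
    """Timing-specific stimulation effect on the absolute change in force.

    Labels every trial x window ON/OFF from the binarized intensity channel,
    forms per-subject per-window ON-OFF means of the aligned behavior, and
    runs the label-shuffle (sign-flip) cluster permutation.
    """
    if design is None:
        design = (SlidingWindowDesign.feedback() if alignment == "value_cue"
                  else SlidingWindowDesign.movement())
    diffs = []
    for session in sessions:
        if session.schedule is None or session.schedule.n_bursts == 0:
            raise ValueError(f"session {session.subject} has no stimulation")
        on = binarize_stimulation(session.stim_intensity, session.schedule.amplitude)
        table = _stim_behavior_table(session, alignment)
        labels = window_stim_labels(
            on, session.rate, table["onset"].to_numpy(), design, alignment,
            trial_index=table["trial"].to_numpy(),
        )
        d, _ = stim_behavior_contrast(
            labels, table["behavior"].to_numpy(),
            np.repeat(session.subject, len(table)),
        )
        diffs.append(d[0])
    diffs = np.stack(diffs)
    result = cluster_permutation_labels(diffs, design, n_perm=n_perm, seed=seed)
    return {"result": result, "diffs": diffs, "design": design}


def schedule_coverage(
    n_trials: int = 1000,
    stim_cfg: StimScheduleConfig | None = None,
    seed: int = 0,
    raster_rate: float = 1000.0,
    alignment: str = "value_cue",
) -> dict:
    """Fraction of trials with any plateau stimulation per 100-ms window.

    Simulates the task's trial timing for ``n_trials`` trials, draws a burst
    schedule over the whole session, rasterizes the plateau boolean at 1 kHz
    and labels the sliding windows.  Returns the per-window percentages and
    their mean.
    """
    from .cohort import AgentConfig, simulate_agent_session
    from .task import TaskConfig

    if stim_cfg is None:
        stim_cfg = StimScheduleConfig(seed=seed)
    rng = np.random.default_rng(seed)
    task = TaskConfig(n_trials=n_trials, seed=seed)
    agent = AgentConfig(miss_rate=0.0, double_press_rate=0.0, seed=seed)
    trials, events = simulate_agent_session(task, agent, np.random.default_rng(rng.integers(2**31)))
    duration = float(events["onset"].max()) + 3.0
    schedule = generate_dbs_schedule(stim_cfg, duration, np.random.default_rng(rng.integers(2**31)))
    on = schedule.suprathreshold(raster_rate, int(round(duration * raster_rate)))
    design = (SlidingWindowDesign.feedback() if alignment == "value_cue"
              else SlidingWindowDesign.movement())
    ev_name = "value_cue" if alignment == "value_cue" else "peak_force"
    onsets = events.query("event_type == @ev_name")["onset"].to_numpy()
    labels = window_stim_labels(on, raster_rate, onsets, design, alignment)
    pct = 100.0 * labels.on_fraction()
    return {"per_window_pct": pct, "mean_pct": float(pct.mean()),
            "design": design, "n_trials": int(onsets.size)}


def clean_wide_beta(
    session: SessionRecording,
    beta_range: tuple[float, float] = BETA_RANGE,
    threshold: float = 10.0,
    peak_halfwidth: float = 3.0,
):
    """Artifact-removal chain for stimulation sessions.

    Builds the two wide bipolar channels per hemisphere at the native rate,
    removes suprathreshold artifact samples, Morlet-transforms the beta
    range, normalizes, picks the wide channel with the clearest
    movement-related beta modulation, and averages hemispheres.

    Returns (beta_power, times, info dict).
    """
    peak_times = session.event_times("peak_force").to_numpy()
    freqs = _beta_freqs(beta_range)
    series, infos = [], []
    for h in range(session.n_hemispheres):
        wide, names = build_bipolar_montage(session.hemisphere_contacts(h), "wide")
        cleaned = []
        fracs = []
        for ch in wide:
            y, rate, info = remove_stim_artifact(ch, session.rate, threshold)
            cleaned.append(y)
            fracs.append(info["removed_fraction"])
        tfr = baseline_normalize(morlet_tfr(np.stack(cleaned), rate, freqs=freqs))
        mov = epoch_align(tfr, peak_times, (-1.0, 0.5))
        sel = select_functional_contact(mov, beta_range=beta_range,
                                        peak_halfwidth=peak_halfwidth)
        lo, hi = sel.beta_peak - peak_halfwidth, sel.beta_peak + peak_halfwidth
        series.append(tfr.band_power(lo, hi)[sel.channel])
        times = tfr.times
        infos.append({"channel": names[sel.channel], "selection": sel,
                      "removed_fraction": fracs[sel.channel]})
    return np.mean(series, axis=0), times, infos


def artifact_recovery(
    contaminated: SessionRecording,
    clean_twin: SessionRecording,
    beta_range: tuple[float, float] = BETA_RANGE,
    threshold: float = 10.0,
    onset_guard: float = 0.08,
    offset_guard: float = 0.03,
    min_plateau: float = 0.18,
) -> dict:
    """Quantify the artifact-removal chain against a paired clean session.

    Returns the correlation between the cleaned and twin beta-power series
    and the burst-locked suppression estimate: one minus the mean normalized
    beta power inside each plateau, read from ``onset_guard`` after plateau
    onset to ``offset_guard`` before its end (bursts shorter than
    ``min_plateau`` are skipped) so that spectral smoothing at the burst
    edges does not dilute the estimate.
    """
    beta_c, times, info_c = clean_wide_beta(contaminated, beta_range, threshold)
    beta_t, _, _ = clean_wide_beta(clean_twin, beta_range, threshold)
    n = min(beta_c.size, beta_t.size)
    corr = float(np.corrcoef(beta_c[:n], beta_t[:n])[0, 1])
    schedule = contaminated.schedule
    epochs, rel, durs = stim_aligned_beta(beta_c, times, schedule)
    vals = []
    for ep, d in zip(epochs, durs):
        if d < min_plateau:
            continue
        tsel = (rel >= onset_guard) & (rel <= d - offset_guard)
        if tsel.any():
            vals.append(ep[tsel].mean())
    if not vals:
        raise ValueError("no bursts long enough for the suppression estimate")
    suppression = float(1.0 - np.mean(vals))
    return {
        "beta_correlation": corr,
        "suppression_estimate": suppression,
        "burst_aligned": epochs.mean(axis=0),
        "burst_times": rel,
        "removed_fraction": float(np.mean([i["removed_fraction"] for i in info_c])),
    }


def behavior_summary(sessions: list[SessionRecording]) -> pd.DataFrame:
    """Per-subject behavior table: press validity re-derived from the force
    channel, kinetic features of valid presses, and adaptation summaries."""
    rows = []
    for s in sessions:
        go = s.event_times("go")
        counts = []
        kin = []
        for t, g in go.items():
            baseline = beh.estimate_baseline(s.force, s.rate, g)
            c = beh.count_presses(s.force, s.rate, (g, g + 2.5), baseline)
            counts.append(c)
            if c == 1:
                kin.append(beh.extract_kinetics(s.force, s.rate, g, baseline=baseline))
        trials = beh.filter_valid_trials(s.trials.drop(columns=["valid", "previous_valid"]),
                                         np.asarray(counts))
        changes = compute_change_predictors(trials["actual"].to_numpy(),
                                            trials["valid"].to_numpy())
        for col in ("signed_change", "abs_change", "previous_valid"):
            trials[col] = changes[col].to_numpy()
        summ = beh.adaptation_summaries(trials)
        rows.append(
            dict(
                subject=s.subject,
                n_valid=summ.n_valid,
                rmse=summ.rmse,
                mean_value=summ.mean_value,
                mean_force_error=summ.mean_force_error,
                cv=summ.cv,
                mean_abs_change=summ.mean_abs_change,
                corr_actual_target=summ.corr_actual_target,
                corr_value_next_abs_change=summ.corr_value_next_abs_change,
                mean_peak_force=float(np.mean([k.peak_force for k in kin])),
                mean_peak_yank=float(np.mean([k.peak_yank for k in kin])),
                mean_reaction_time=float(np.mean([k.reaction_time for k in kin])),
                mean_auc=float(np.mean([k.auc for k in kin])),
            )
        )
    return pd.DataFrame(rows)


def run_pipeline(config, out_dir):
    """Full orchestration: simulate -> behavior -> spectral + regression ->
    stimulation analyses, all reproducible from the configuration's seeds.

    ``config`` is an :class:`stnadapt.config.AnalysisConfig`; every stage's
    wall time and every written file are recorded in the returned
    RunManifest (also written to ``out_dir/manifest.json`` atomically).
    Stimulation stages are skipped, with a log line, when no stimulation is
    configured or it is disabled.
    """
    import json
    import logging
    from dataclasses import replace
    from pathlib import Path

    from . import __version__
    from .cohort import simulate_cohort, simulate_session
    from .config import RunManifest

    log = logging.getLogger("stnadapt.pipeline")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config.hash(), __version__, config.seed)

    with manifest.time_stage("simulate"):
        sessions = simulate_cohort(
            n_subjects=config.n_subjects, task=config.task, agent=config.agent,
            lfp_cfg=config.lfp, stim_cfg=config.stim,
            stim_effect=config.stim_effect,
            n_hemispheres=config.n_hemispheres, seed=config.seed,
        )

    with manifest.time_stage("behavior"):
        table = behavior_summary(sessions)
        f = out / "behavior_summary.tsv"
        table.to_csv(f, sep="\t", index=False)
        manifest.add_outputs([f])

    for alignment in ("value_cue", "peak_force"):
        with manifest.time_stage(f"regress_{alignment}"):
            res = single_trial_regression(
                sessions, alignment, n_perm=config.n_perm, seed=config.seed
            )
            stem = out / f"regression_{alignment}"
            cols = {"window_start_s": res["design"].starts}
            for r in res["results"]:
                cols[f"t_{r.predictor}"] = r.tvalues
            pd.DataFrame(cols).to_csv(f"{stem}.tsv", sep="\t", index=False)
            with open(f"{stem}.json", "w") as fh:
                json.dump([r.to_dict() for r in res["results"]], fh, indent=2)
            manifest.add_outputs([f"{stem}.tsv", f"{stem}.json"])

    stim_on = config.stim is not None and config.stim.enabled
    if not stim_on:
        log.info("stimulation disabled; skipping stimulation stages")
    else:
        for alignment in ("value_cue", "peak_force"):
            with manifest.time_stage(f"stim_behavior_{alignment}"):
                res = stim_behavior_test(sessions, alignment,
                                         n_perm=config.n_perm, seed=config.seed)
                stem = out / f"stim_behavior_{alignment}"
                with open(f"{stem}.json", "w") as fh:
                    json.dump([res["result"].to_dict()], fh, indent=2)
                manifest.add_outputs([f"{stem}.json"])
        with manifest.time_stage("stim_aligned_beta"):
            child = np.random.SeedSequence(config.seed).spawn(config.n_subjects)[0]
            twin = simulate_session(
                sessions[0].subject, config.task, config.agent,
                replace(config.lfp, artifact_amplitude=0.0),
                stim_cfg=config.stim, stim_effect=config.stim_effect,
                n_hemispheres=config.n_hemispheres, seed=child,
            )
            rep = artifact_recovery(sessions[0], twin)
            f = out / "stim_beta.json"
            with open(f, "w") as fh:
                json.dump({k: (v.tolist() if isinstance(v, np.ndarray) else v)
                           for k, v in rep.items()}, fh, indent=2)
            manifest.add_outputs([f])

    manifest.add_outputs([out / "manifest.json"])
    manifest.write(out / "manifest.json")
    return manifest
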