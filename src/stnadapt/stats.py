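"""Single-trial inference: within-subject z-scoring, sliding-window
mixed-effects regression, cluster-based permutation correction, per-subject
regression fallback, and BIC model comparison.

The workhorse test regresses z-scored single-trial band power on two
trial-level predictors (Value + Direction after the feedback cues, absolute
change + signed change of force around the movement) in a random-intercept
mixed model, refit in 100-ms windows stepped by 10 ms.  Multiple comparisons
over windows are corrected by cluster-mass permutation: the null shuffles
the dependent variable's trial order within subject while the window order
inside each trial is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .lme import LmeFitResult, RandomInterceptDesign

__all__ = [
    "SlidingWindowDesign",
    "ClusterTestResult",
    "zscore_and_prune",
    "window_means",
    "sliding_lme",
    "cluster_permutation_trials",
    "find_clusters",
    "per_subject_regression",
    "compare_bic",
    "bic",
    "evidence_label",
]

FEEDBACK_RANGE = (0.0, 2.0)  # s relative to the Value-cue
MOVEMENT_RANGE = (-1.0, 0.0)  # s relative to peak force


@dataclass(frozen=True)
class SlidingWindowDesign:
    """100-ms windows stepped by 10 ms over an analysis range; half-open
    [t, t + length)."""

    start: float
    stop: float
    length: float = 0.1
    step: float = 0.01

    def __post_init__(self) -> None:
        if self.step > self.length:
            raise ValueError("step must not exceed the window length")
        if self.stop <= self.start:
            raise ValueError("range endpoints must be ordered")

    @property
    def starts(self) -> np.ndarray:
        n = int(round((self.stop - self.start - self.length) / self.step)) + 1
        return self.start + self.step * np.arange(n)

    @property
    def n_windows(self) -> int:
        return self.starts.size

    @classmethod
    def feedback(cls) -> "SlidingWindowDesign":
        return cls(*FEEDBACK_RANGE)

    @classmethod
    def movement(cls) -> "SlidingWindowDesign":
        return cls(*MOVEMENT_RANGE)


def window_means(
    values: np.ndarray, times: np.ndarray, design: SlidingWindowDesign
) -> np.ndarray:
    """Mean over each sliding window: (trials, samples) -> (trials, windows)."""
    values = np.asarray(values, dtype=float)
    out = np.empty((values.shape[0], design.n_windows))
    for w, t0 in enumerate(design.starts):
        sel = (times >= t0 - 1e-9) & (times < t0 + design.length - 1e-9)
        if not sel.any():
            raise ValueError(f"window at {t0:.3f}s contains no samples")
        out[:, w] = values[:, sel].mean(axis=1)
    return out


def zscore_and_prune(
    values: np.ndarray,
    subjects: np.ndarray,
    z_max: float = 3.0,
    min_trials: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """Standardize single-trial values within subject and flag outliers.

    The mean and standard deviation are pooled over each subject's trials
    and windows; a trial is excluded when the magnitude of its epoch-mean
    z-score exceeds ``z_max``.  Returns (z, keep) with z NaN on excluded
    trials.
    """
    values = np.asarray(values, dtype=float)
    subjects = np.asarray(subjects)
    z = np.empty_like(values)
    keep = np.ones(values.shape[0], dtype=bool)
    for s in np.unique(subjects):
        rows = subjects == s
        if rows.sum() < min_trials:
            raise ValueError(f"subject {s!r} has fewer than {min_trials} trials")
        block = values[rows]
        sd = block.std()
        if sd == 0:
            raise ValueError(f"zero variance for subject {s!r}")
        z[rows] = (block - block.mean()) / sd
    keep &= np.abs(np.nanmean(z, axis=1)) <= z_max
    z[~keep] = np.nan
    return z, keep


def sliding_lme(
    values: np.ndarray,
    predictors: np.ndarray,
    subjects: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-window mixed-model slope t-statistics.

    ``values`` is (trials, windows); ``predictors`` (trials, k) enters one
    model with a random intercept per subject.  Rows with NaN values or
    predictors are dropped.  Returns (t (k, windows), singular flags).
    """
    values = np.asarray(values, dtype=float)
    predictors = np.atleast_2d(np.asarray(predictors, dtype=float))
    if predictors.shape[0] != values.shape[0]:
        predictors = predictors.T
    ok = np.isfinite(values).all(axis=1) & np.isfinite(predictors).all(axis=1)
    X = np.column_stack([np.ones(ok.sum()), predictors[ok]])
    t, _, _, singular = RandomInterceptDesign(X, np.asarray(subjects)[ok]).fit(values[ok])
    return t[1:], singular


def find_clusters(t: np.ndarray, threshold: float) -> list[dict]:
    """Maximal runs of same-sign suprathreshold windows with their mass
    (sum of |t|); NaN windows break runs."""
    clusters = []
    for sign in (1.0, -1.0):
        above = np.where(np.isfinite(t), sign * t > threshold, False)
        d = np.diff(above.astype(np.int8))
        starts = list(np.flatnonzero(d == 1) + 1)
        ends = list(np.flatnonzero(d == -1) + 1)
        if above.size and above[0]:
            starts.insert(0, 0)
        if above.size and above[-1]:
            ends.append(above.size)
        for s, e in zip(starts, ends):
            clusters.append(
                dict(start=int(s), stop=int(e), sign=int(sign),
                     mass=float(np.abs(t[s:e]).sum()))
            )
    clusters.sort(key=lambda c: c["start"])
    return clusters


@dataclass
class ClusterTestResult:
    """Cluster-mass permutation test over sliding windows."""

    predictor: str
    tvalues: np.ndarray
    threshold: float
    clusters: list[dict]
    null_max: np.ndarray
    n_perm: int
    window_starts: np.ndarray
    seed: int | None = None
    singular: np.ndarray | None = field(default=None, repr=False)

    @property
    def significant(self) -> list[dict]:
        return [c for c in self.clusters if c["p"] <= 0.05]

    def to_dict(self) -> dict:
        return {
            "predictor": self.predictor,
            "threshold": self.threshold,
            "n_perm": int(self.n_perm),
            "seed": self.seed,
            "clusters": [
                {
                    "start_s": float(self.window_starts[c["start"]]),
                    "stop_s": float(self.window_starts[c["stop"] - 1]) + 0.1,
                    "mass": c["mass"],
                    "sign": c["sign"],
                    "p": c["p"],
                }
                for c in self.clusters
            ],
        }


def cluster_permutation_trials(
    values: np.ndarray,
    predictors: np.ndarray,
    subjects: np.ndarray,
    design: SlidingWindowDesign,
    predictor_names: list[str] | None = None,
    n_perm: int = 1000,
    cluster_alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> list[ClusterTestResult]:
    """Sliding mixed-model regression with cluster-mass permutation
    correction, one result per predictor.

    The null shuffles the trial order of the dependent variable within each
    subject (window order within a trial preserved, regressors fixed); a
    cluster is significant when its mass exceeds the 95th percentile of the
    permutation distribution of per-permutation maximum masses.
    """
    if n_perm < 100:
        import warnings

        warnings.warn(f"n_perm={n_perm} is low; permutation p-values are coarse")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seed_val = None if isinstance(seed, np.random.Generator) else int(seed)
    values = np.asarray(values, dtype=float)
    predictors = np.asarray(predictors, dtype=float)
    if predictors.ndim == 1:
        predictors = predictors[:, None]
    subjects = np.asarray(subjects)
    ok = np.isfinite(values).all(axis=1) & np.isfinite(predictors).all(axis=1)
    Y = values[ok]
    X = np.column_stack([np.ones(ok.sum()), predictors[ok]])
    groups = subjects[ok]
    k = X.shape[1] - 1
    if predictor_names is None:
        predictor_names = [f"x{i + 1}" for i in range(k)]

    lme = RandomInterceptDesign(X, groups)
    GY = lme.group_sums(Y)
    yty = (Y**2).sum(axis=0)
    t_obs_all, *_ = lme.fit_sums(X.T @ Y, GY, yty)
    singular = ~np.isfinite(t_obs_all).all(axis=0) | (np.std(Y, axis=0) <= 0)
    threshold = float(sps.t.ppf(1.0 - cluster_alpha / 2.0, df=lme.n - X.shape[1]))

    # permutation indices reorder trials within subject; within-group
    # response sums are invariant, so only X'Y changes per shuffle, and
    # shuffles are fit in batches to amortize the vectorized profiling
    order = np.arange(lme.n)
    blocks = [np.flatnonzero(lme.g == j) for j in range(lme.J)]
    W = Y.shape[1]
    null_max = np.zeros((n_perm, k))
    chunk = 25
    for b0 in range(0, n_perm, chunk):
        nb = min(chunk, n_perm - b0)
        XtY_all = np.empty((X.shape[1], nb * W))
        for b in range(nb):
            for rows in blocks:
                order[rows] = rows[rng.permutation(rows.size)]
            XtY_all[:, b * W : (b + 1) * W] = X.T @ Y[order]
        t_all, *_ = lme.fit_sums(XtY_all, np.tile(GY, (1, nb)), np.tile(yty, nb))
        for b in range(nb):
            t_perm = t_all[:, b * W : (b + 1) * W].copy()
            t_perm[:, singular] = np.nan
            for i in range(k):
                cl = find_clusters(t_perm[1 + i], threshold)
                null_max[b0 + b, i] = max((c["mass"] for c in cl), default=0.0)

    results = []
    for i in range(k):
        t_i = t_obs_all[1 + i].copy()
        t_i[singular] = np.nan
        clusters = find_clusters(t_i, threshold)
        for c in clusters:
            c["p"] = float((1 + np.sum(null_max[:, i] >= c["mass"])) / (n_perm + 1))
        results.append(
            ClusterTestResult(
                predictor=predictor_names[i],
                tvalues=t_i,
                threshold=threshold,
                clusters=clusters,
                null_max=null_max[:, i].copy(),
                n_perm=n_perm,
                window_starts=design.starts,
                seed=seed_val,
                singular=singular.copy(),
            )
        )
    return results


@dataclass
class GroupRegressionResult:
    slopes: np.ndarray  # per-subject regression slopes
    r: np.ndarray  # per-subject correlation coefficients
    fisher_z: np.ndarray
    tstat: float
    pvalue: float
    n_subjects: int
    excluded: list


def per_subject_regression(
    values: np.ndarray,
    predictor: np.ndarray,
    subjects: np.ndarray,
    min_trials: int = 5,
) -> GroupRegressionResult:
    """Ordinary regression per subject followed by a one-sample t-test on the
    Fisher r-to-z transformed correlation-scale slopes."""
    import warnings

    values = np.asarray(values, dtype=float)
    predictor = np.asarray(predictor, dtype=float)
    subjects = np.asarray(subjects)
    uniq = np.unique(subjects)
    slopes, rs, excluded = [], [], []
    for s in uniq:
        rows = (subjects == s) & np.isfinite(values) & np.isfinite(predictor)
        if rows.sum() < min_trials:
            excluded.append(s)
            warnings.warn(f"subject {s!r} has <{min_trials} trials; excluded")
            continue
        x, y = predictor[rows], values[rows]
        if np.std(x) == 0 or np.std(y) == 0:
            excluded.append(s)
            continue
        slope = np.polyfit(x, y, 1)[0]
        slopes.append(slope)
        rs.append(np.corrcoef(x, y)[0, 1])
    if len(slopes) < 3:
        raise ValueError("need at least 3 subjects with enough trials")
    rs = np.clip(np.asarray(rs), -0.999999, 0.999999)
    z = np.arctanh(rs)
    tstat, p = sps.ttest_1samp(z, 0.0)
    return GroupRegressionResult(
        slopes=np.asarray(slopes), r=rs, fisher_z=z,
        tstat=float(tstat), pvalue=float(p),
        n_subjects=len(slopes), excluded=excluded,
    )


def bic(loglik: float, n_params: int, nobs: int) -> float:
    """Schwarz criterion k*ln(n) - 2*lnL."""
    return n_params * np.log(nobs) - 2.0 * loglik


def evidence_label(delta: float) -> str:
    """Evidence for the lower-BIC model: >2 positive, >6 strong, >10 very
    strong, otherwise inconclusive."""
    d = abs(delta)
    if d > 10:
        return "very strong"
    if d > 6:
        return "strong"
    if d > 2:
        return "positive"
    return "inconclusive"


def compare_bic(models: dict[str, LmeFitResult]) -> "pd.DataFrame":
    """BIC table for mixed models fit by ML on identical observations.

    The parameter count is the number of fixed effects plus the two variance
    components.  Raises if the models saw different numbers of observations.
    """
    import pandas as pd

    nobs = {name: fit.nobs for name, fit in models.items()}
    if len(set(nobs.values())) > 1:
        raise ValueError(f"models fit on differing observation sets: {nobs}")
    rows = []
    for name, fit in models.items():
        k = fit.params.size + 2
        rows.append(dict(model=name, loglik=fit.loglik, k=k, n=fit.nobs,
                         bic=bic(fit.loglik, k, fit.nobs)))
    table = pd.DataFrame(rows).set_index("model").sort_values("bic")
    best = table["bic"].iloc[0]
    table["delta_bic"] = table["bic"] - best
    table["evidence"] = [evidence_label(d) for d in table["delta_bic"]]
    return table
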