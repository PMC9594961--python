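"""Time-activity-budget error under interval sampling of behaviour records.

The central question: if a tag records one behaviour code every 2 s, how much
worse do daily time-activity budgets get when the record is subsampled at
interval ``i`` (10 s … 60 min)?  The error statistic is the *error ratio*

    error_ratio_ij = sd_sampling_ij / p_j,

the across-day standard deviation of (continuous − sampled) daily proportion
differences for behaviour ``j`` at interval ``i``, scaled by the behaviour's
mean daily proportion.  Under independent epochs the binomial expectation is

    E_error_ratio_ij = sqrt(p_j (1 − p_j) / n_i) / p_j,

with ``n_i`` records per day.  Real records are serially dependent; the
*dependence* statistic (normalized total-variation distance between the
lag-conditional next-behaviour distribution q and the marginal p),

    dependence = Σ_i |q_i − p_i| / (2 (1 − p_min)) ∈ [0, 1],

quantifies how strongly that assumption is violated at each lag.  A log-log
multiple regression of the empirical error ratio on sampling interval
(minutes) and p (percent) summarizes the scaling.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .io_formats import (
    EPOCH_S,
    EPOCHS_PER_DAY,
    ETHOGRAM,
    LABEL_TO_INDEX,
    N_BEHAVIOURS,
    BehaviourSequence,
)

#: Sampling intervals evaluated by default, seconds.
DEFAULT_INTERVALS_S: tuple[int, ...] = (10, 30, 60, 180, 300, 600, 1200, 1800, 3600)

#: Proportion grid of the expected-error-ratio reference table.
DEFAULT_PROPORTIONS: tuple[float, ...] = (0.005, 0.01, 0.02, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5)


# --------------------------------------------------------------------------
# Day filtering and budgets
# --------------------------------------------------------------------------


def filter_complete_days(
    sequences: Sequence[BehaviourSequence],
    min_fraction: float = 0.995,
    drop_first_last: bool = True,
) -> list[BehaviourSequence]:
    """Keep days covering at least ``min_fraction`` of a full day of epochs,
    discarding each animal's first and last tracking day (tag deployment and
    retrieval days are partial and behaviourally atypical)."""
    by_animal: dict[str, list[BehaviourSequence]] = {}
    for seq in sequences:
        by_animal.setdefault(seq.animal_id, []).append(seq)
    kept = []
    threshold = min_fraction * EPOCHS_PER_DAY
    for animal in sorted(by_animal):
        days = sorted(by_animal[animal], key=lambda s: s.day)
        if drop_first_last:
            days = days[1:-1]
        kept.extend(s for s in days if s.n_epochs >= threshold)
    return kept


def compute_budget(sequence: BehaviourSequence) -> np.ndarray:
    """Daily time-activity budget: per-behaviour epoch fractions (sum 1)."""
    if sequence.n_epochs == 0:
        raise ValueError("cannot compute a budget of an empty sequence")
    return np.bincount(sequence.codes, minlength=N_BEHAVIOURS) / sequence.n_epochs


def _check_interval(interval_s: int) -> int:
    if interval_s <= 0 or interval_s % EPOCH_S != 0:
        raise ValueError(
            f"sampling interval {interval_s}s must be a positive multiple of the "
            f"{EPOCH_S}s epoch"
        )
    return interval_s // EPOCH_S


def downsample(sequence: BehaviourSequence, interval_s: int) -> BehaviourSequence:
    """Subsample a day, keeping the first epoch and then every interval-th
    record until the end of the day.  Deterministic; no randomness anywhere."""
    m = _check_interval(interval_s)
    return BehaviourSequence(
        sequence.animal_id, sequence.day, sequence.times[::m], sequence.codes[::m]
    )


def records_per_day(interval_s: int, day_epochs: int = EPOCHS_PER_DAY) -> int:
    """Number of retained records over a day at the given interval."""
    m = _check_interval(interval_s)
    return math.ceil(day_epochs / m)


# --------------------------------------------------------------------------
# Empirical sampling-error table (error ratio per interval x behaviour)
# --------------------------------------------------------------------------


def behaviour_proportions(
    days: Sequence[BehaviourSequence], mode: str = "daily_mean"
) -> np.ndarray:
    """Mean behaviour proportions p_j from the continuous records.

    ``daily_mean`` (default): mean over days of the daily proportions.
    ``pooled``: epoch counts pooled across all days.  The two coincide when
    all days are complete.
    """
    if mode == "daily_mean":
        return np.mean([compute_budget(s) for s in days], axis=0)
    if mode == "pooled":
        counts = np.zeros(N_BEHAVIOURS)
        total = 0
        for s in days:
            counts += np.bincount(s.codes, minlength=N_BEHAVIOURS)
            total += s.n_epochs
        return counts / total
    raise ValueError("mode must be 'daily_mean' or 'pooled'")


def sampling_differences(
    days: Sequence[BehaviourSequence],
    intervals_s: Sequence[int] = DEFAULT_INTERVALS_S,
    all_offsets: bool = False,
) -> np.ndarray:
    """(n_days, n_intervals, 8) array of continuous − sampled daily budget
    differences.

    With ``all_offsets`` the sampled budget for each day/interval is replaced
    by the average over every possible start offset — a robustness variant of
    the deterministic first-record start."""
    out = np.empty((len(days), len(intervals_s), N_BEHAVIOURS))
    for d, seq in enumerate(days):
        cont = compute_budget(seq)
        for i, interval in enumerate(intervals_s):
            m = _check_interval(interval)
            if all_offsets:
                sampled = np.zeros(N_BEHAVIOURS)
                for off in range(m):
                    codes = seq.codes[off::m]
                    sampled += np.bincount(codes, minlength=N_BEHAVIOURS) / codes.size
                sampled /= m
            else:
                codes = seq.codes[::m]
                sampled = np.bincount(codes, minlength=N_BEHAVIOURS) / codes.size
            out[d, i] = cont - sampled
    return out


def sampling_error_table(
    days: Sequence[BehaviourSequence],
    intervals_s: Sequence[int] = DEFAULT_INTERVALS_S,
    p_mode: str = "daily_mean",
    all_offsets: bool = False,
) -> pd.DataFrame:
    """Tidy table of sd_sampling, p, error ratio and n per (interval,
    behaviour).

    sd is the sample standard deviation (divisor n−1) across days of the
    daily (continuous − sampled) proportion differences.  Rows whose
    behaviour never occurs (p = 0) are flagged ``defined = False`` and are
    excluded from the log-log regression downstream.
    """
    if len(days) < 2:
        raise ValueError("need at least 2 filtered days")
    diffs = sampling_differences(days, intervals_s, all_offsets=all_offsets)
    p = behaviour_proportions(days, mode=p_mode)
    sd = diffs.std(axis=0, ddof=1)  # (n_intervals, 8)
    rows = []
    for i, interval in enumerate(intervals_s):
        n_i = records_per_day(interval)
        for j, b in enumerate(ETHOGRAM):
            defined = p[j] > 0
            rows.append(
                {
                    "interval_s": interval,
                    "behaviour": b,
                    "sd_sampling": sd[i, j],
                    "p": p[j],
                    "error_ratio": sd[i, j] / p[j] if defined else np.nan,
                    "n_records": n_i,
                    "defined": defined,
                }
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Analytic expectation under independence
# --------------------------------------------------------------------------


def expected_error_ratio(p, n, day_epochs: int | None = None):
    """Expected error ratio sqrt(p(1−p)/n)/p under independent records.

    ``day_epochs``, if given, applies the finite-overlap correction
    sqrt(1 − n/day_epochs): the sampled records are a subset of the
    continuous reference, so the continuous−sampled difference has variance
    p(1−p)(1/n − 1/N), not p(1−p)/n.  The uncorrected form is the one to
    quote when gauging a planned sampling schedule (n ≪ N)."""
    p = np.asarray(p, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("p must be strictly between 0 and 1")
    if np.any(n < 1):
        raise ValueError("n must be >= 1")
    var = p * (1.0 - p) / n
    if day_epochs is not None:
        var = var * (1.0 - n / day_epochs)
    out = np.sqrt(var) / p
    return float(out) if out.ndim == 0 else out


def expected_error_table(
    proportions: Sequence[float] = DEFAULT_PROPORTIONS,
    intervals_s: Sequence[int] = DEFAULT_INTERVALS_S,
) -> pd.DataFrame:
    """Reference grid of expected error ratios (rows: p, columns: interval),
    with boolean companion masks ``attrs['gt_half']`` / ``attrs['gt_one']``
    marking the 0.5 and 1.0 contours."""
    n = np.array([records_per_day(i) for i in intervals_s], dtype=float)
    p = np.asarray(proportions, dtype=float)
    grid = expected_error_ratio(p[:, None], n[None, :])
    df = pd.DataFrame(grid, index=list(proportions), columns=list(intervals_s))
    df.index.name = "p"
    df.columns.name = "interval_s"
    df.attrs["gt_half"] = df > 0.5
    df.attrs["gt_one"] = df > 1.0
    return df


# --------------------------------------------------------------------------
# Dependence between records at a given lag
# --------------------------------------------------------------------------


def dependence_from_qp(q: np.ndarray, p: np.ndarray) -> float:
    """Normalized total-variation distance Σ|q−p| / (2(1−p_min)) ∈ [0, 1]."""
    q = np.asarray(q, dtype=float)
    p = np.asarray(p, dtype=float)
    p_min = p.min()
    if p_min >= 1.0:
        raise ValueError("degenerate p (a single behaviour with proportion 1)")
    return float(np.abs(q - p).sum() / (2.0 * (1.0 - p_min)))


def transition_profile(
    days: Sequence[BehaviourSequence], interval_s: int, focal_behaviour: str
) -> np.ndarray:
    """Conditional next-behaviour distribution q at lag ``interval_s``.

    q pools, across days, all ordered epoch pairs (t, t + lag) within the
    same day where behaviour(t) is the focal behaviour; pairs never span a
    day boundary."""
    m = _check_interval(interval_s)
    focal = LABEL_TO_INDEX[focal_behaviour]
    counts = np.zeros(N_BEHAVIOURS)
    for seq in days:
        c = seq.codes
        if c.size <= m:
            continue
        idx = np.flatnonzero(c[:-m] == focal)
        if idx.size:
            counts += np.bincount(c[idx + m], minlength=N_BEHAVIOURS)
    total = counts.sum()
    if total == 0:
        raise ValueError(
            f"focal behaviour {focal_behaviour!r} never observed at lag-paired positions"
        )
    return counts / total


def dependence(
    days: Sequence[BehaviourSequence],
    interval_s: int,
    focal_behaviour: str,
    p: np.ndarray | None = None,
) -> float:
    """Dependence of the behaviour sequence on the focal behaviour at the
    given lag: 0 = records independent of the focal state, 1 = fully
    determined."""
    q = transition_profile(days, interval_s, focal_behaviour)
    if p is None:
        p = behaviour_proportions(days)
    return dependence_from_qp(q, p)


def dependence_table(
    days: Sequence[BehaviourSequence],
    intervals_s: Sequence[int] = DEFAULT_INTERVALS_S,
    behaviours: Sequence[str] = ETHOGRAM,
) -> pd.DataFrame:
    """Dependence per (behaviour, interval); NaN where the focal behaviour
    is never observed."""
    p = behaviour_proportions(days)
    rows = []
    for b in behaviours:
        for interval in intervals_s:
            try:
                val = dependence(days, interval, b, p=p)
            except ValueError:
                val = np.nan
            rows.append({"behaviour": b, "interval_s": interval, "dependence": val})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Log-log regression of the error ratio
# --------------------------------------------------------------------------


@dataclasses.dataclass
class RegressionFit:
    """OLS fit of ln(error ratio) ~ ln(interval, min) + ln(p, %)."""

    intercept: float
    coef_ln_interval: float
    coef_ln_p: float
    se_intercept: float
    se_ln_interval: float
    se_ln_p: float
    r_squared: float
    f_statistic: float
    df_model: int
    df_resid: int
    n_obs: int
    n_excluded: int

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def fit_loglog_regression(table: pd.DataFrame) -> RegressionFit:
    """Fit ln(error ratio) on ln(sampling interval in minutes) and ln(p in
    percent) by ordinary least squares.

    Undefined rows (p = 0) and rows with a zero error ratio (log undefined)
    are excluded; the latter with a warning.
    """
    t = table.copy()
    usable = t["defined"] & (t["error_ratio"] > 0)
    n_excluded = int((~usable).sum())
    if (t["defined"] & (t["error_ratio"] == 0)).any():
        warnings.warn(
            f"excluding {int((t['defined'] & (t['error_ratio'] == 0)).sum())} "
            "row(s) with error ratio 0 from the log-log regression",
            stacklevel=2,
        )
    t = t[usable]
    if len(t) < 4:
        raise ValueError("need at least 4 defined rows for the regression")
    y = np.log(t["error_ratio"].to_numpy())
    X = np.column_stack(
        [
            np.log(t["interval_s"].to_numpy() / 60.0),  # minutes
            np.log(t["p"].to_numpy() * 100.0),  # percent
        ]
    )
    model = sm.OLS(y, sm.add_constant(X)).fit()
    return RegressionFit(
        intercept=float(model.params[0]),
        coef_ln_interval=float(model.params[1]),
        coef_ln_p=float(model.params[2]),
        se_intercept=float(model.bse[0]),
        se_ln_interval=float(model.bse[1]),
        se_ln_p=float(model.bse[2]),
        r_squared=float(model.rsquared),
        f_statistic=float(model.fvalue),
        df_model=int(model.df_model),
        df_resid=int(model.df_resid),
        n_obs=int(model.nobs),
        n_excluded=n_excluded,
    )
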