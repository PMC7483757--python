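"""Attention metrics during meditation and group-level contrasts.

Per subject and mental state: *percentage time engaged* (event volumes over
all decodable volumes, so state percentages plus the excluded percentage sum
to exactly 100), *number of events*, *mean event duration*, and *variability*
(sample SD of event durations, undefined below two events). Group contrasts
are a one-way repeated-measures ANOVA over the three states per metric,
followed by planned paired t-tests of Breath vs. MW and Breath vs. Self.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .decoder import DecodedRun
from .design import MEDITATION_STATES


@dataclass(frozen=True)
class StateMetrics:
    pct_time: float
    n_events: int
    mean_duration: float  # seconds; NaN when no events
    sd_duration: float  # seconds; NaN below two events


@dataclass
class AttentionMetrics:
    """One subject's attention profile over a meditation run."""

    per_state: dict[str, StateMetrics]
    total_events: int
    pct_excluded: float
    subject: str | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for state, m in self.per_state.items():
            rows.append(
                {
                    "subject": self.subject,
                    "state": state,
                    "pct_time": m.pct_time,
                    "n_events": m.n_events,
                    "mean_duration": m.mean_duration,
                    "sd_duration": m.sd_duration,
                }
            )
        return pd.DataFrame(rows)


def compute_metrics(
    run: DecodedRun, states: tuple[str, ...] | None = None, subject: str | None = None
) -> AttentionMetrics:
    """Quantify a decoded run into per-state attention metrics.

    The percentage-time denominator is all decodable volumes; time in runs
    too short to be events is reported separately as ``pct_excluded``, making
    the conservation identity exact. States with no events get 0% time,
    0 events, and missing durations.
    """
    states = tuple(states or run.states)
    total = run.n_volumes
    per_state = {}
    for state in states:
        evs = [e for e in run.events if e.state == state]
        vols = sum(e.n_volumes for e in evs)
        durations = np.array([e.duration_seconds for e in evs])
        per_state[state] = StateMetrics(
            pct_time=100.0 * vols / total,
            n_events=len(evs),
            mean_duration=float(durations.mean()) if len(evs) else float("nan"),
            sd_duration=float(durations.std(ddof=1)) if len(evs) >= 2 else float("nan"),
        )
    return AttentionMetrics(per_state, len(run.events), run.pct_excluded, subject)


def metrics_frame(metrics: list[AttentionMetrics]) -> pd.DataFrame:
    """Long-format subject x state x metric table."""
    frames = []
    for i, m in enumerate(metrics):
        f = m.to_frame()
        if f["subject"].isna().all():
            f["subject"] = i
        frames.append(f)
    return pd.concat(frames, ignore_index=True)


def rm_anova(values: np.ndarray) -> tuple[float, float, int, int]:
    """One-way repeated-measures ANOVA on a subjects x conditions matrix.

    Subject is the blocking factor. Returns ``(F, p, df1, df2)``. Degenerate
    inputs are resolved explicitly: no between-condition variation gives
    F = 0 (p = 1) even when the residual is also zero; zero residual with
    real condition differences gives an infinite F (p = 0).
    """
    values = np.asarray(values, dtype=float)
    n, k = values.shape
    if n < 2 or k < 2:
        raise ValueError("repeated-measures ANOVA needs >= 2 subjects and conditions")
    grand = values.mean()
    ss_cond = n * ((values.mean(axis=0) - grand) ** 2).sum()
    ss_subj = k * ((values.mean(axis=1) - grand) ** 2).sum()
    ss_err = ((values - grand) ** 2).sum() - ss_cond - ss_subj
    df1, df2 = k - 1, (k - 1) * (n - 1)
    scale = max(np.abs(values).max() ** 2, 1.0)
    if ss_cond <= 1e-12 * scale:
        return 0.0, 1.0, df1, df2
    if ss_err <= 1e-12 * scale:
        return float("inf"), 0.0, df1, df2
    F = (ss_cond / df1) / (ss_err / df2)
    return float(F), float(stats.f.sf(F, df1, df2)), df1, df2


def _paired_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided paired t-test; identically-zero differences give t = 0."""
    diff = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    ok = np.isfinite(diff)
    diff = diff[ok]
    if diff.size < 2:
        return float("nan"), float("nan")
    if diff.std(ddof=1) == 0.0:
        if np.allclose(diff, 0.0):
            return 0.0, 1.0
        return float(np.sign(diff.mean())) * np.inf, 0.0
    t, p = stats.ttest_rel(np.asarray(a, dtype=float)[ok], np.asarray(b, dtype=float)[ok])
    return float(t), float(p)


@dataclass
class MetricContrast:
    F: float
    p: float
    df1: int
    df2: int
    n_subjects: int
    t_breath_mw: float
    p_breath_mw: float
    t_breath_self: float
    p_breath_self: float


@dataclass
class GroupMetricsResult:
    """Per-metric repeated-measures ANOVA plus planned Breath contrasts."""

    contrasts: dict[str, MetricContrast]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"metric": k, **vars(v)} for k, v in self.contrasts.items()]
        )


DEFAULT_METRICS = ("pct_time", "n_events", "mean_duration", "sd_duration")


def group_tests(
    metrics: list[AttentionMetrics],
    which: tuple[str, ...] = DEFAULT_METRICS,
    states: tuple[str, ...] = MEDITATION_STATES,
) -> GroupMetricsResult:
    """Group-level contrasts of attention metrics across the three states.

    Requires at least 3 subjects. For each metric, subjects with a missing
    value in any state (e.g., an undefined duration SD) are dropped from that
    metric's ANOVA, with a warning stating how many; the planned paired
    t-tests use pairwise-complete subjects.
    """
    if len(metrics) < 3:
        raise ValueError("group tests require at least 3 subjects")
    long = metrics_frame(metrics)
    contrasts = {}
    for metric in which:
        wide = long.pivot(index="subject", columns="state", values=metric)[list(states)]
        mat = wide.to_numpy(dtype=float)
        complete = np.isfinite(mat).all(axis=1)
        n_dropped = int((~complete).sum())
        if n_dropped:
            warnings.warn(
                f"{metric}: dropping {n_dropped} subject(s) with missing values"
            )
        if complete.sum() < 2:
            raise ValueError(f"{metric}: fewer than 2 complete subjects")
        F, p, df1, df2 = rm_anova(mat[complete])
        t_bm, p_bm = _paired_t(wide["Breath"].to_numpy(), wide["MW"].to_numpy())
        t_bs, p_bs = _paired_t(wide["Breath"].to_numpy(), wide["Self"].to_numpy())
        contrasts[metric] = MetricContrast(
            F, p, df1, df2, int(complete.sum()), t_bm, p_bm, t_bs, p_bs
        )
    return GroupMetricsResult(contrasts)
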