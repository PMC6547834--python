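"""Scoring of raw assessment data: task scores, pattern LIFs, wLIF, BBT.

A timed mSHAP task attempt is scaled to a dimensionless task score

    Ts(t) = 100 * (m - t) / (m - n)

where ``n`` is the normative ("normal function") time and ``m`` the
minimal-function bound (by convention eight times ``n``). Times at or below
``n`` score 100, times at or above ``m`` — and unsuccessful (DNF) attempts —
score 0. Task scores are averaged within each prehensile pattern to a linear
index of functionality (LIF), and the six LIFs combine with weights
3, 3, 6, 5, 5, 3 (divisor 25) into the weighted linear index of
functionality (wLIF). The Box and Blocks Test (BBT) score for a session is
the mean blocks-per-minute over its trials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .reference import DEFAULT_PATTERN_WEIGHTS, PATTERNS

__all__ = [
    "TaskRecord",
    "NormativeBounds",
    "SessionScore",
    "ScoringError",
    "ConfigurationError",
    "scale_task_score",
    "compute_lif",
    "compute_wlif",
    "score_bbt",
    "score_session",
    "score_sessions",
    "bounds_table_from_frame",
]


class ScoringError(ValueError):
    """Invalid raw input (negative time, unknown task, bad quadrant)."""


class ConfigurationError(ValueError):
    """Invalid bounds table, pattern mapping or weight configuration."""


@dataclass(frozen=True)
class TaskRecord:
    """One mSHAP task attempt.

    ``time_s`` is None when the attempt was a DNF; the terminal-device
    orientation quadrant is recorded even on failure.
    """

    task_id: str
    time_s: float | None
    dnf: bool
    quadrant: int

    def __post_init__(self) -> None:
        if self.dnf and self.time_s is not None:
            raise ScoringError(
                f"task {self.task_id!r}: DNF attempts carry no time"
            )
        if not self.dnf and (self.time_s is None or self.time_s < 0):
            raise ScoringError(
                f"task {self.task_id!r}: completed attempts need a time >= 0"
            )
        if self.quadrant not in (1, 2, 3, 4):
            raise ScoringError(
                f"task {self.task_id!r}: quadrant must be 1..4, "
                f"got {self.quadrant!r}"
            )


@dataclass(frozen=True)
class NormativeBounds:
    """Scaling boundaries for one task.

    ``n_lower`` is the normative time (scores 100), ``m_upper`` the
    minimal-function time (scores 0). ``patterns`` lists every prehensile
    pattern the task loads; most tasks load exactly one.
    """

    task_id: str
    n_lower: float
    m_upper: float
    patterns: tuple[str, ...]

    def __post_init__(self) -> None:
        if not (0 < self.n_lower < self.m_upper):
            raise ConfigurationError(
                f"task {self.task_id!r}: need 0 < n_lower < m_upper, "
                f"got n={self.n_lower}, m={self.m_upper}"
            )
        if not self.patterns:
            raise ConfigurationError(
                f"task {self.task_id!r}: at least one pattern required"
            )
        unknown = set(self.patterns) - set(PATTERNS)
        if unknown:
            raise ConfigurationError(
                f"task {self.task_id!r}: unknown pattern(s) {sorted(unknown)}"
            )


@dataclass(frozen=True)
class SessionScore:
    """Scores for one subject-session: 22 task scores, six LIFs, wLIF, BBT."""

    subject_id: str
    session: int
    task_scores: dict[str, float]
    lif: dict[str, float]
    wlif: float
    bbt_mean: float | None = None
    weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PATTERN_WEIGHTS)
    )


def scale_task_score(
    time_s: float | None, bounds: NormativeBounds
) -> float:
    """Scale one task time to the [0, 100] task score.

    ``time_s=None`` denotes a DNF and scores 0. Times faster than the
    normative bound clamp to 100; slower than the minimal-function bound
    clamp to 0.
    """
    if time_s is None:
        return 0.0
    if not math.isfinite(time_s) or time_s < 0:
        raise ScoringError(
            f"task {bounds.task_id!r}: time must be finite and >= 0, "
            f"got {time_s!r}"
        )
    n, m = bounds.n_lower, bounds.m_upper
    ts = 100.0 * (m - time_s) / (m - n)
    return float(min(100.0, max(0.0, ts)))


def compute_lif(
    task_scores: Mapping[str, float],
    pattern: str,
    bounds_table: Mapping[str, NormativeBounds],
) -> float:
    """Linear index of functionality: mean task score within one pattern."""
    if pattern not in PATTERNS:
        raise ConfigurationError(f"unknown pattern {pattern!r}")
    members = [
        score
        for task_id, score in task_scores.items()
        if pattern in _bounds_for(task_id, bounds_table).patterns
    ]
    if not members:
        raise ConfigurationError(
            f"no scored task maps to pattern {pattern!r}"
        )
    return float(np.mean(members))


def compute_wlif(
    lifs: Mapping[str, float],
    weights: Mapping[str, float] | None = None,
) -> float:
    """Weighted linear index of functionality over the six pattern LIFs."""
    w = dict(DEFAULT_PATTERN_WEIGHTS if weights is None else weights)
    missing = [p for p in PATTERNS if p not in lifs]
    if missing:
        raise ConfigurationError(f"missing pattern LIF(s): {missing}")
    if set(w) != set(PATTERNS) or any(v <= 0 for v in w.values()):
        raise ConfigurationError(
            "weights must cover exactly the six patterns with positive values"
        )
    divisor = sum(w.values())
    return float(sum(w[p] * lifs[p] for p in PATTERNS) / divisor)


def score_bbt(trials: Sequence[float]) -> float:
    """Session BBT score: mean blocks transported per minute over trials.

    Averages however many trials are recorded (normally three) so a missed
    trial does not break the pipeline.
    """
    if len(trials) == 0:
        raise ScoringError("BBT needs at least one trial")
    arr = np.asarray(trials, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr < 0):
        raise ScoringError(f"BBT trial counts must be finite and >= 0: {trials}")
    return float(arr.mean())


def _bounds_for(
    task_id: str, bounds_table: Mapping[str, NormativeBounds]
) -> NormativeBounds:
    try:
        return bounds_table[task_id]
    except KeyError:
        raise ConfigurationError(
            f"task {task_id!r} has no entry in the normative-bounds table"
        ) from None


def score_session(
    records: Iterable[TaskRecord],
    bounds_table: Mapping[str, NormativeBounds],
    *,
    subject_id: str = "",
    session: int = 0,
    bbt_trials: Sequence[float] | None = None,
    weights: Mapping[str, float] | None = None,
) -> SessionScore:
    """Score one mSHAP administration (and optionally its BBT trials)."""
    task_scores: dict[str, float] = {}
    for rec in records:
        if rec.task_id in task_scores:
            raise ScoringError(
                f"duplicate attempt for task {rec.task_id!r} in one session"
            )
        b = _bounds_for(rec.task_id, bounds_table)
        task_scores[rec.task_id] = scale_task_score(
            None if rec.dnf else rec.time_s, b
        )
    lifs = {
        p: compute_lif(task_scores, p, bounds_table) for p in PATTERNS
    }
    wlif = compute_wlif(lifs, weights)
    bbt = score_bbt(bbt_trials) if bbt_trials is not None else None
    w = dict(DEFAULT_PATTERN_WEIGHTS if weights is None else weights)
    return SessionScore(
        subject_id=subject_id,
        session=session,
        task_scores=task_scores,
        lif=lifs,
        wlif=wlif,
        bbt_mean=bbt,
        weights=w,
    )


def bounds_table_from_frame(
    bounds: pd.DataFrame,
) -> dict[str, NormativeBounds]:
    """Build the task_id -> NormativeBounds mapping from a bounds table.

    Expects columns ``task_id, n_lower_s, m_upper_s, pattern``; the pattern
    cell may hold several pipe-separated labels.
    """
    required = {"task_id", "n_lower_s", "m_upper_s", "pattern"}
    missing = required - set(bounds.columns)
    if missing:
        raise ConfigurationError(
            f"bounds table missing column(s): {sorted(missing)}"
        )
    if bounds["task_id"].duplicated().any():
        dupes = bounds.loc[bounds["task_id"].duplicated(), "task_id"]
        raise ConfigurationError(
            f"duplicate bounds for task(s): {sorted(set(dupes))}"
        )
    table: dict[str, NormativeBounds] = {}
    for row in bounds.itertuples(index=False):
        table[row.task_id] = NormativeBounds(
            task_id=row.task_id,
            n_lower=float(row.n_lower_s),
            m_upper=float(row.m_upper_s),
            patterns=tuple(str(row.pattern).split("|")),
        )
    return table


def score_sessions(
    session_log: pd.DataFrame,
    bounds: pd.DataFrame,
    bbt: pd.DataFrame | None = None,
    *,
    weights: Mapping[str, float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score every subject-session in a session log.

    Parameters
    ----------
    session_log
        Long table with columns ``subject_id, session, task_id, time_s,
        dnf, quadrant`` (one row per task attempt; ``time_s`` NaN on DNF).
    bounds
        Normative-bounds table (``task_id, n_lower_s, m_upper_s, pattern``).
    bbt
        Optional trial table ``subject_id, session, trial, blocks``.

    Returns
    -------
    (session_scores, task_scores)
        ``session_scores`` has one row per subject-session with ``wlif``,
        the six ``lif_<pattern>`` columns and ``bbt_mean`` (NaN where no
        trials exist, e.g. session 1). ``task_scores`` is long:
        ``subject_id, session, task_id, ts``.
    """
    table = bounds_table_from_frame(bounds)
    n_arr = session_log["task_id"].map(
        {t: b.n_lower for t, b in table.items()}
    )
    if n_arr.isna().any():
        unknown = sorted(
            set(session_log.loc[n_arr.isna(), "task_id"])
        )
        raise ConfigurationError(
            f"task(s) missing from the bounds table: {unknown}"
        )
    m_arr = session_log["task_id"].map(
        {t: b.m_upper for t, b in table.items()}
    )

    t = session_log["time_s"].to_numpy(dtype=float)
    dnf = session_log["dnf"].to_numpy().astype(bool)
    quad = session_log["quadrant"].to_numpy()
    if not np.isin(quad, (1, 2, 3, 4)).all():
        bad = session_log.loc[~np.isin(quad, (1, 2, 3, 4))]
        raise ScoringError(
            f"quadrant values outside 1..4 at rows {list(bad.index)[:5]}"
        )
    if np.any(t[~dnf] < 0) or np.any(~np.isfinite(t[~dnf])):
        raise ScoringError("completed attempts must have finite time_s >= 0")

    ts = 100.0 * (m_arr.to_numpy() - t) / (m_arr.to_numpy() - n_arr.to_numpy())
    ts = np.clip(ts, 0.0, 100.0)
    ts[dnf] = 0.0

    task_scores = session_log[["subject_id", "session", "task_id"]].copy()
    task_scores["ts"] = ts

    # Pattern membership (a task may load several patterns).
    pattern_rows = []
    for p in PATTERNS:
        member = task_scores["task_id"].map(
            {tid: p in b.patterns for tid, b in table.items()}
        )
        sub = task_scores[member.astype(bool)]
        lif = (
            sub.groupby(["subject_id", "session"])["ts"].mean().rename(f"lif_{p}")
        )
        pattern_rows.append(lif)
    lif_frame = pd.concat(pattern_rows, axis=1)
    if lif_frame.isna().any().any():
        empty = lif_frame.columns[lif_frame.isna().any()].tolist()
        raise ConfigurationError(
            f"some sessions have no scored task for pattern column(s) {empty}"
        )

    w = dict(DEFAULT_PATTERN_WEIGHTS if weights is None else weights)
    divisor = sum(w.values())
    wlif = sum(w[p] * lif_frame[f"lif_{p}"] for p in PATTERNS) / divisor
    session_scores = lif_frame.copy()
    session_scores.insert(0, "wlif", wlif)

    if bbt is not None and len(bbt):
        bbt_mean = (
            bbt.groupby(["subject_id", "session"])["blocks"]
            .apply(lambda s: score_bbt(s.to_numpy()))
            .rename("bbt_mean")
        )
        session_scores = session_scores.join(bbt_mean)
    else:
        session_scores["bbt_mean"] = np.nan

    session_scores = session_scores.reset_index()
    return session_scores, task_scores
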