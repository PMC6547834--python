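"""Prepositioning analysis: quadrant-change counts vs session-normalized wLIF.

Prepositioning — manually rotating the terminal device into an advantageous
orientation before a task — is quantified indirectly: the orientation
quadrant (1..4) recorded for each of the 22 mSHAP tasks gives, per
administration, the count ``q`` of between-task quadrant changes (0..21).

Performance is session-normalized: each subject's wLIF has the session mean
subtracted, removing the shared learning trend so scores are comparable
across sessions. Normalized scores sharing the same ``q`` are grouped and
averaged, and an ordinary least-squares line through the (q, group mean)
points tests for an association between prepositioning use and
above-average performance. The regression is unweighted by default (one
point per q group); a count-weighted variant is available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RegressionResult",
    "count_quadrant_changes",
    "normalize_scores",
    "group_by_q",
    "regress_q_vs_score",
    "prepositioning_records",
]


@dataclass(frozen=True)
class RegressionResult:
    """OLS line through grouped (q, mean normalized score) points.

    ``r`` is the Pearson correlation of the fitted points (NaN when the
    response has zero variance); ``r2 = r**2`` on the same points.
    """

    slope: float
    intercept: float
    r: float
    r2: float
    n_groups: int


def count_quadrant_changes(quadrants: Sequence[int]) -> int:
    """Number of adjacent task pairs with differing orientation quadrants."""
    q = np.asarray(quadrants)
    if q.size == 0:
        raise ValueError("empty quadrant sequence")
    if not np.isin(q, (1, 2, 3, 4)).all():
        bad = sorted(set(q[~np.isin(q, (1, 2, 3, 4))].tolist()))
        raise ValueError(f"quadrant values outside 1..4: {bad}")
    return int(np.count_nonzero(q[1:] != q[:-1]))


def normalize_scores(wlif: pd.DataFrame) -> pd.DataFrame:
    """Centre a subjects x sessions score table on its session (column) means.

    Every output column sums to zero over the subjects observed in that
    session; within-session rank order is unchanged.
    """
    if wlif.empty:
        raise ValueError("empty score table")
    counts = wlif.notna().sum(axis=0)
    if (counts == 0).any():
        empty = counts.index[counts == 0].tolist()
        raise ValueError(f"session column(s) with no subjects: {empty}")
    return wlif - wlif.mean(axis=0)


def prepositioning_records(
    session_log: pd.DataFrame, session_scores: pd.DataFrame
) -> pd.DataFrame:
    """Per subject-session quadrant-change counts joined to normalized wLIF.

    ``session_log`` rows must be in administration order within each
    subject-session. Returns columns ``subject_id, session, q, wlif_norm``.
    """
    q = (
        session_log.groupby(["subject_id", "session"], sort=True)["quadrant"]
        .apply(lambda s: count_quadrant_changes(s.to_numpy()))
        .rename("q")
    )
    wide = session_scores.pivot(
        index="subject_id", columns="session", values="wlif"
    )
    norm = normalize_scores(wide).stack().rename("wlif_norm")
    out = pd.concat([q, norm], axis=1).dropna().reset_index()
    out["q"] = out["q"].astype(int)
    return out


def group_by_q(records: pd.DataFrame) -> pd.DataFrame:
    """Group normalized scores by quadrant-change count.

    ``records`` needs columns ``q`` and ``wlif_norm``. Returns one row per
    distinct q with ``mean``, standard error ``se`` (NaN for singleton
    groups) and count ``n``.
    """
    if records.empty:
        raise ValueError("no prepositioning records to group")
    g = records.groupby("q")["wlif_norm"]
    out = g.agg(mean="mean", n="count")
    sd = g.std(ddof=1)
    out["se"] = sd / np.sqrt(out["n"])
    return out.reset_index()[["q", "mean", "se", "n"]]


def regress_q_vs_score(
    grouped: pd.DataFrame, *, weighted: bool = False
) -> RegressionResult:
    """OLS of group-mean normalized wLIF on quadrant-change count.

    Closed-form normal equations on the (q, mean) points; ``weighted=True``
    weights each point by its group count ``n`` instead of treating groups
    equally. A zero-variance response gives slope 0 with ``r`` undefined
    (NaN).
    """
    if len(grouped) < 2 or grouped["q"].nunique() < 2:
        raise ValueError("regression needs >= 2 distinct q groups")
    x = grouped["q"].to_numpy(dtype=float)
    y = grouped["mean"].to_numpy(dtype=float)
    w = (
        grouped["n"].to_numpy(dtype=float)
        if weighted
        else np.ones_like(x)
    )
    w = w / w.sum()
    xbar = float(w @ x)
    ybar = float(w @ y)
    sxx = float(w @ ((x - xbar) ** 2))
    syy = float(w @ ((y - ybar) ** 2))
    sxy = float(w @ ((x - xbar) * (y - ybar)))
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    if syy == 0.0:
        r = math.nan
        r2 = math.nan
    else:
        r = sxy / math.sqrt(sxx * syy)
        r2 = r * r
    return RegressionResult(
        slope=slope, intercept=intercept, r=r, r2=r2, n_groups=len(grouped)
    )
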