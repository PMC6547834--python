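"""Inverse learning-curve fitting, training endpoints, session effect sizes.

The learning-curve model for a score series Y over administrations X = 1..K is

    Y = a - b / X

with plateau ``a`` (asymptotic performance) and rate ``b`` (magnitude of
early gains). Because the model is linear in the basis {1, 1/X}, the
least-squares fit is solved exactly rather than by iterative optimisation —
mathematically identical for this model and fully deterministic.

The training endpoint is the first session whose fitted value reaches a set
fraction (default 90%) of the plateau:

    X* = ceil( b / ((1 - f) * a) ),   f = 0.9

reported on the session scale via ``session = X + offset`` (offset 0 for the
mSHAP, which starts in session 1; offset 1 for the BBT, whose administrations
1..9 fall in sessions 2..10).

Session-to-session effect size is the mean paired difference divided by the
sample standard deviation (n-1 denominator) of those differences, classified
against the conventional 0.20 / 0.50 / 0.80 thresholds.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ScoreSeries",
    "LearningCurveFit",
    "EffectSizeResult",
    "FitError",
    "fit_inverse_curve",
    "fit_inverse_curve_xy",
    "training_endpoint",
    "effect_size",
    "classify_effect",
    "effect_sizes_by_session",
    "summarize_table",
]

logger = logging.getLogger(__name__)

EFFECT_THRESHOLDS = {"small": 0.20, "medium": 0.50, "large": 0.80}


class FitError(ValueError):
    """Series unsuitable for fitting (too short, constant x, bad plateau)."""


@dataclass(frozen=True)
class ScoreSeries:
    """An ordered outcome series with its administration index.

    ``session_offset`` maps administration index to session number
    (session = x + offset): 0 for mSHAP-derived scores, 1 for the BBT.
    """

    values: tuple[float, ...]
    x_index: tuple[int, ...]
    session_offset: int = 0

    def __post_init__(self) -> None:
        if len(self.values) != len(self.x_index):
            raise FitError("values and x_index must have equal length")
        if any(b <= a for a, b in zip(self.x_index, self.x_index[1:])):
            raise FitError("x_index must be strictly increasing")
        if any(x < 1 for x in self.x_index):
            raise FitError("x_index entries must be positive integers")
        if self.session_offset < 0:
            raise FitError("session_offset must be >= 0")

    @classmethod
    def from_values(
        cls, values: Sequence[float], session_offset: int = 0
    ) -> "ScoreSeries":
        return cls(
            values=tuple(float(v) for v in values),
            x_index=tuple(range(1, len(values) + 1)),
            session_offset=session_offset,
        )


@dataclass(frozen=True)
class LearningCurveFit:
    """Fitted plateau/rate with goodness of fit and training endpoint.

    ``r2`` is NaN for a constant series (zero total sum of squares makes
    R² meaningless); ``endpoint_session`` is on the session scale, i.e.
    already includes ``session_offset``.
    """

    a: float
    b: float
    r2: float
    endpoint_session: int
    session_offset: int = 0
    n_obs: int = 0


@dataclass(frozen=True)
class EffectSizeResult:
    """Paired effect size for one session transition."""

    session: int
    es: float  # NaN when the difference SD is zero
    magnitude: str  # negative/negligible/small/medium/large/undefined
    n_pairs: int = 0

    @property
    def defined(self) -> bool:
        return not math.isnan(self.es)


def fit_inverse_curve(
    series: ScoreSeries | Sequence[float],
    *,
    endpoint_fraction: float = 0.9,
) -> LearningCurveFit:
    """Least-squares fit of Y = a - b/X to a score series.

    Exact linear least squares on the {1, 1/X} basis. Requires at least
    three points over at least two distinct x values. A constant series
    returns ``a = Y, b = 0`` with ``r2 = NaN``.
    """
    if not isinstance(series, ScoreSeries):
        series = ScoreSeries.from_values(series)
    return fit_inverse_curve_xy(
        series.x_index,
        series.values,
        session_offset=series.session_offset,
        endpoint_fraction=endpoint_fraction,
    )


def fit_inverse_curve_xy(
    x: Sequence[float],
    y: Sequence[float],
    *,
    session_offset: int = 0,
    endpoint_fraction: float = 0.9,
) -> LearningCurveFit:
    """Fit Y = a - b/X to (x, y) points; x values may repeat.

    This is the pooled-points entry: several subjects may contribute a
    point at the same administration index.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if len(y) != len(x):
        raise FitError("x and y must have equal length")
    if len(y) < 3:
        raise FitError(f"need >= 3 points to fit, got {len(y)}")
    if len(np.unique(x)) < 2:
        raise FitError("need >= 2 distinct x values")
    if np.any(x < 1):
        raise FitError("administration indexes must be >= 1")
    if np.any(~np.isfinite(y)):
        raise FitError("series contains non-finite values")

    design = np.column_stack([np.ones_like(x), -1.0 / x])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    a, b = float(coef[0]), float(coef[1])

    resid = y - design @ coef
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0.0:
        a, b, r2 = float(y[0]), 0.0, math.nan
    else:
        r2 = 1.0 - ss_res / ss_tot

    endpoint = training_endpoint(
        a,
        b,
        session_offset=session_offset,
        endpoint_fraction=endpoint_fraction,
    )
    return LearningCurveFit(
        a=a,
        b=b,
        r2=r2,
        endpoint_session=endpoint,
        session_offset=session_offset,
        n_obs=len(y),
    )


def training_endpoint(
    a: float,
    b: float,
    session_offset: int = 0,
    *,
    endpoint_fraction: float = 0.9,
) -> int:
    """First session whose fitted value reaches ``endpoint_fraction * a``.

    Smallest integer X >= 1 with a - b/X >= f*a, i.e. ceil(b / ((1-f)*a)),
    returned as X + session_offset. A non-positive rate means the plateau is
    met immediately (X = 1).
    """
    if not (0 < endpoint_fraction < 1):
        raise ValueError("endpoint_fraction must lie in (0, 1)")
    if not math.isfinite(a) or a <= 0:
        raise FitError(
            f"training endpoint undefined for non-positive plateau a={a!r}"
        )
    if b <= 0:
        return 1 + session_offset
    ratio = b / ((1.0 - endpoint_fraction) * a)
    # guard against 3.0000000000000004-style float noise at integer ratios
    x = max(1, math.ceil(ratio - 1e-9))
    return x + session_offset


def effect_size(
    scores_prev: Sequence[float] | Mapping[str, float],
    scores_curr: Sequence[float] | Mapping[str, float],
    *,
    session: int = 0,
    ddof: int = 1,
) -> EffectSizeResult:
    """Paired session effect size: mean difference / SD of differences.

    Mapping inputs are paired by subject key; subjects present in only one
    session are dropped with a warning. Sequence inputs are assumed aligned.
    A zero difference SD yields ``es = NaN`` with magnitude ``undefined``.
    """
    if isinstance(scores_prev, Mapping) != isinstance(scores_curr, Mapping):
        raise ValueError("pass two mappings or two sequences, not a mix")
    if isinstance(scores_prev, Mapping):
        common = sorted(set(scores_prev) & set(scores_curr))
        dropped = (set(scores_prev) | set(scores_curr)) - set(common)
        if dropped:
            logger.warning(
                "effect size session %s: dropping unpaired subject(s) %s",
                session,
                sorted(dropped),
            )
        prev = np.array([scores_prev[k] for k in common], dtype=float)
        curr = np.array([scores_curr[k] for k in common], dtype=float)
    else:
        if len(scores_prev) != len(scores_curr):
            raise ValueError("paired sequences must have equal length")
        prev = np.asarray(scores_prev, dtype=float)
        curr = np.asarray(scores_curr, dtype=float)
    if len(prev) < 2:
        raise ValueError("effect size needs at least 2 paired subjects")

    diffs = curr - prev
    sd = float(diffs.std(ddof=ddof))
    # a difference SD of zero to within float roundoff (e.g. identical
    # diffs whose mean does not reconstruct exactly) is still zero variance
    scale = max(1.0, float(np.abs(diffs).max()))
    if sd <= 1e-9 * scale:
        return EffectSizeResult(
            session=session, es=math.nan, magnitude="undefined",
            n_pairs=len(diffs),
        )
    es = float(diffs.mean() / sd)
    return EffectSizeResult(
        session=session, es=es, magnitude=classify_effect(es),
        n_pairs=len(diffs),
    )


def classify_effect(es: float) -> str:
    """Magnitude class for an effect size (0.20/0.50/0.80 thresholds)."""
    if not math.isfinite(es):
        raise ValueError(f"effect size must be finite, got {es!r}")
    if es < 0:
        return "negative"
    if es < EFFECT_THRESHOLDS["small"]:
        return "negligible"
    if es < EFFECT_THRESHOLDS["medium"]:
        return "small"
    if es < EFFECT_THRESHOLDS["large"]:
        return "medium"
    return "large"


def effect_sizes_by_session(
    scores: pd.DataFrame, *, ddof: int = 1
) -> pd.DataFrame:
    """Effect sizes for every consecutive session pair.

    ``scores`` is a subjects x sessions table (rows indexed by subject,
    columns by session number). Returns a frame with columns
    ``session, es, magnitude, n_pairs`` — one row per transition into each
    session from the second onward.
    """
    sessions = sorted(scores.columns)
    rows = []
    for prev_s, curr_s in zip(sessions, sessions[1:]):
        pair = scores[[prev_s, curr_s]].dropna()
        res = effect_size(
            pair[prev_s].to_dict(), pair[curr_s].to_dict(),
            session=int(curr_s), ddof=ddof,
        )
        rows.append(
            {
                "session": res.session,
                "es": res.es,
                "magnitude": res.magnitude,
                "n_pairs": res.n_pairs,
            }
        )
    return pd.DataFrame(rows)


def summarize_table(
    fits: pd.DataFrame, r2_threshold: float = 0.4
) -> dict[str, float]:
    """Summary statistics over a table of fits (columns ``r2, endpoint``).

    Reports the count of fits whose R² exceeds the threshold, mean ± SD of
    R² over all fits, and mean ± SD of the training endpoint over the fits
    above threshold. SDs use the n-1 denominator; they are NaN for a single
    fit.
    """
    if fits.empty:
        raise ValueError("need at least one fit to summarize")
    r2 = fits["r2"].astype(float)
    above = fits[r2 > r2_threshold]
    ep = above["endpoint"].astype(float)
    return {
        "n_fits": int(len(fits)),
        "n_above_threshold": int(len(above)),
        "r2_mean": float(r2.mean()),
        "r2_sd": float(r2.std(ddof=1)) if len(r2) > 1 else math.nan,
        "endpoint_mean_above": float(ep.mean()) if len(ep) else math.nan,
        "endpoint_sd_above": (
            float(ep.std(ddof=1)) if len(ep) > 1 else math.nan
        ),
    }
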