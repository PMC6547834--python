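"""End-to-end analysis: score -> fit -> effect sizes -> prepositioning.

``run_pipeline`` reads the three input CSVs, scores every session, fits the
inverse learning curve per outcome category (whole-assessment wLIF, BBT, the
22 per-task scores and 6 pattern LIFs), computes session effect sizes for
wLIF and BBT, runs the prepositioning analysis, and writes a report bundle:
CSV tables plus a machine-readable JSON summary. Everything is deterministic
given the inputs and configuration.

Fits default to the group-mean pathway (one point per session, the mean over
subjects); ``fit_pathway="pooled"`` fits all subject-level points instead.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .learning_curve import (
    LearningCurveFit,
    effect_sizes_by_session,
    fit_inverse_curve_xy,
    summarize_table,
)
from .prepositioning import (
    group_by_q,
    prepositioning_records,
    regress_q_vs_score,
)
from .reference import PATTERNS
from .scoring import score_sessions

__all__ = ["RunConfig", "run_pipeline", "analyze"]

logger = logging.getLogger(__name__)

#: BBT administrations 1..K fall in sessions 2..K+1.
BBT_SESSION_OFFSET = 1


@dataclass
class RunConfig:
    """Paths and analysis options for one pipeline run."""

    session_log: str | Path
    bounds: str | Path
    bbt: str | Path | None = None
    out_dir: str | Path = "mshap_out"
    r2_threshold: float = 0.4
    endpoint_fraction: float = 0.9
    es_ddof: int = 1  # n-1 sample SD in the effect-size denominator
    weighted_regression: bool = False
    fit_pathway: str = "mean"  # "mean" | "pooled"
    log_level: str = "INFO"

    def validate(self) -> None:
        if not (0 < self.endpoint_fraction < 1):
            raise ValueError("endpoint_fraction must lie in (0, 1)")
        if not (0 <= self.r2_threshold <= 1):
            raise ValueError("r2_threshold must lie in [0, 1]")
        if self.fit_pathway not in ("mean", "pooled"):
            raise ValueError("fit_pathway must be 'mean' or 'pooled'")
        if self.es_ddof not in (0, 1):
            raise ValueError("es_ddof must be 0 or 1")


def _fit_category(
    values: pd.DataFrame,
    value_col: str,
    session_offset: int,
    pathway: str,
    endpoint_fraction: float,
) -> LearningCurveFit:
    """Fit one category from a long (subject_id, session, value) frame."""
    sub = values.dropna(subset=[value_col])
    if pathway == "mean":
        per_session = sub.groupby("session")[value_col].mean()
        x = per_session.index.to_numpy(dtype=float) - session_offset
        y = per_session.to_numpy(dtype=float)
    else:
        x = sub["session"].to_numpy(dtype=float) - session_offset
        y = sub[value_col].to_numpy(dtype=float)
    return fit_inverse_curve_xy(
        x, y, session_offset=session_offset,
        endpoint_fraction=endpoint_fraction,
    )


def analyze(
    session_log: pd.DataFrame,
    bounds: pd.DataFrame,
    bbt: pd.DataFrame | None = None,
    *,
    r2_threshold: float = 0.4,
    endpoint_fraction: float = 0.9,
    es_ddof: int = 1,
    weighted_regression: bool = False,
    fit_pathway: str = "mean",
) -> dict:
    """Run the full analysis on in-memory tables; returns the report bundle.

    The bundle maps names to DataFrames (``session_scores``, ``task_scores``,
    ``fits``, ``effect_sizes``, ``preposition_groups``,
    ``preposition_regression``) plus a JSON-ready ``summary`` dict.
    """
    session_scores, task_scores = score_sessions(session_log, bounds, bbt)

    fit_rows = []

    def add_fit(category: str, frame: pd.DataFrame, col: str, offset: int):
        try:
            fit = _fit_category(
                frame, col, offset, fit_pathway, endpoint_fraction
            )
        except Exception as exc:  # partial series: log, keep going
            logger.warning("category %s not fitted: %s", category, exc)
            return
        fit_rows.append(
            {
                "category": category,
                "a": fit.a,
                "b": fit.b,
                "r2": fit.r2,
                "endpoint": fit.endpoint_session,
                "session_offset": offset,
                "n_obs": fit.n_obs,
            }
        )

    add_fit("wLIF", session_scores, "wlif", 0)
    if session_scores["bbt_mean"].notna().any():
        add_fit("BBT", session_scores, "bbt_mean", BBT_SESSION_OFFSET)
    for task in sorted(task_scores["task_id"].unique()):
        add_fit(
            f"Ts_{task}",
            task_scores[task_scores["task_id"] == task],
            "ts",
            0,
        )
    for p in PATTERNS:
        add_fit(f"LIF_{p}", session_scores, f"lif_{p}", 0)
    fits = pd.DataFrame(fit_rows)

    # Effect sizes on per-subject wLIF and BBT trajectories.
    es_frames = []
    wlif_wide = session_scores.pivot(
        index="subject_id", columns="session", values="wlif"
    )
    es_w = effect_sizes_by_session(wlif_wide, ddof=es_ddof)
    es_w.insert(0, "measure", "wlif")
    es_frames.append(es_w)
    bbt_wide = session_scores.pivot(
        index="subject_id", columns="session", values="bbt_mean"
    ).dropna(axis=1, how="all")
    if bbt_wide.shape[1] >= 2:
        es_b = effect_sizes_by_session(bbt_wide, ddof=es_ddof)
        es_b.insert(0, "measure", "bbt")
        es_frames.append(es_b)
    effect_sizes = pd.concat(es_frames, ignore_index=True)

    records = prepositioning_records(session_log, session_scores)
    groups = group_by_q(records)
    reg = regress_q_vs_score(groups, weighted=weighted_regression)
    reg_frame = pd.DataFrame([asdict(reg)])

    ts_fits = fits[fits["category"].str.startswith("Ts_")]
    lif_fits = fits[fits["category"].str.startswith("LIF_")]
    summary: dict = {
        "n_subjects": int(session_log["subject_id"].nunique()),
        "n_sessions": int(session_log["session"].nunique()),
        "fits": {
            row["category"]: {
                "a": row["a"], "b": row["b"], "r2": row["r2"],
                "endpoint": int(row["endpoint"]),
            }
            for _, row in fits.iterrows()
            if row["category"] in ("wLIF", "BBT")
        },
        "task_score_summary": (
            summarize_table(ts_fits, r2_threshold) if len(ts_fits) else None
        ),
        "lif_summary": (
            summarize_table(lif_fits, r2_threshold) if len(lif_fits) else None
        ),
        "prepositioning": asdict(reg),
        "options": {
            "r2_threshold": r2_threshold,
            "endpoint_fraction": endpoint_fraction,
            "es_ddof": es_ddof,
            "weighted_regression": weighted_regression,
            "fit_pathway": fit_pathway,
        },
    }

    return {
        "session_scores": session_scores,
        "task_scores": task_scores,
        "fits": fits,
        "effect_sizes": effect_sizes,
        "preposition_groups": groups,
        "preposition_regression": reg_frame,
        "summary": summary,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Read inputs, run :func:`analyze`, write the report bundle to disk."""
    config.validate()
    logging.basicConfig(level=config.log_level)

    session_log = mio.read_session_log(config.session_log)
    bounds = mio.read_bounds(config.bounds)
    bbt = mio.read_bbt(config.bbt) if config.bbt is not None else None

    bundle = analyze(
        session_log,
        bounds,
        bbt,
        r2_threshold=config.r2_threshold,
        endpoint_fraction=config.endpoint_fraction,
        es_ddof=config.es_ddof,
        weighted_regression=config.weighted_regression,
        fit_pathway=config.fit_pathway,
    )

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name in (
        "session_scores",
        "task_scores",
        "fits",
        "effect_sizes",
        "preposition_groups",
        "preposition_regression",
    ):
        mio.write_csv(bundle[name], out / f"{name}.csv")
    with open(out / "summary.json", "w") as fh:
        json.dump(_jsonable(bundle["summary"]), fh, indent=2)
    return bundle


def _jsonable(obj):
    """Recursively cast numpy scalars and map NaN to null for strict JSON."""
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, int)) and not isinstance(obj, bool):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if math.isnan(f) else f
    return obj
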