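"""CSV readers/writers and input validation.

All interchange is plain CSV (UTF-8, header row). Three dialects:

* session log — ``subject_id, session, task_id, time_s, dnf, quadrant``,
  one row per task attempt, ``time_s`` blank on DNF;
* BBT trials — ``subject_id, session, trial, blocks``;
* normative bounds — ``task_id, n_lower_s, m_upper_s, pattern`` (pattern
  cells may hold pipe-separated labels for multi-pattern tasks).

Numeric fields are written at full precision so write -> read round-trips
are exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .reference import PATTERNS

__all__ = [
    "SESSION_LOG_COLUMNS",
    "BBT_COLUMNS",
    "BOUNDS_COLUMNS",
    "ValidationReport",
    "read_session_log",
    "read_bbt",
    "read_bounds",
    "write_csv",
    "validate_inputs",
]

SESSION_LOG_COLUMNS = ["subject_id", "session", "task_id", "time_s", "dnf",
                       "quadrant"]
BBT_COLUMNS = ["subject_id", "session", "trial", "blocks"]
BOUNDS_COLUMNS = ["task_id", "n_lower_s", "m_upper_s", "pattern"]


@dataclass
class ValidationReport:
    """Outcome of schema/content validation with itemized findings."""

    passed: bool
    findings: list[str] = field(default_factory=list)

    def __str__(self) -> str:
        head = "PASS" if self.passed else "FAIL"
        lines = [f"{head}: {len(self.findings)} finding(s)"]
        lines += [f"  - {f}" for f in self.findings]
        return "\n".join(lines)


def read_session_log(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"subject_id": str, "task_id": str})
    _require_columns(df, SESSION_LOG_COLUMNS, path)
    df["session"] = df["session"].astype(int)
    df["time_s"] = pd.to_numeric(df["time_s"], errors="coerce")
    df["dnf"] = df["dnf"].astype(int)
    df["quadrant"] = df["quadrant"].astype(int)
    return df[SESSION_LOG_COLUMNS]


def read_bbt(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"subject_id": str})
    _require_columns(df, BBT_COLUMNS, path)
    df["session"] = df["session"].astype(int)
    df["trial"] = df["trial"].astype(int)
    df["blocks"] = pd.to_numeric(df["blocks"])
    return df[BBT_COLUMNS]


def read_bounds(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"task_id": str, "pattern": str})
    _require_columns(df, BOUNDS_COLUMNS, path)
    df["n_lower_s"] = pd.to_numeric(df["n_lower_s"])
    df["m_upper_s"] = pd.to_numeric(df["m_upper_s"])
    return df[BOUNDS_COLUMNS]


def write_csv(df: pd.DataFrame, path: str | Path) -> None:
    """Write a CSV with floats serialized at full round-trip precision."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.17g")


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")


def validate_inputs(
    session_log_path: str | Path,
    bounds_path: str | Path,
    bbt_path: str | Path | None = None,
) -> ValidationReport:
    """Validate input files: schemas, value ranges, task coverage, contiguity.

    Returns a pass/fail report with one finding per problem; unreadable
    files raise I/O errors as usual.
    """
    findings: list[str] = []

    try:
        log = read_session_log(session_log_path)
    except ValueError as exc:
        return ValidationReport(False, [str(exc)])
    try:
        bounds = read_bounds(bounds_path)
    except ValueError as exc:
        return ValidationReport(False, [str(exc)])

    bad_q = log[~log["quadrant"].isin((1, 2, 3, 4))]
    for idx, row in bad_q.iterrows():
        findings.append(
            f"session log row {idx}: quadrant {row['quadrant']} outside 1..4"
        )
    bad_dnf = log[~log["dnf"].isin((0, 1))]
    for idx, row in bad_dnf.iterrows():
        findings.append(f"session log row {idx}: dnf must be 0 or 1")
    dnf_with_time = log[(log["dnf"] == 1) & log["time_s"].notna()]
    for idx in dnf_with_time.index:
        findings.append(f"session log row {idx}: DNF rows must leave time_s blank")
    done_no_time = log[(log["dnf"] == 0) & log["time_s"].isna()]
    for idx in done_no_time.index:
        findings.append(f"session log row {idx}: completed attempt lacks time_s")
    neg_time = log[log["time_s"] < 0]
    for idx, row in neg_time.iterrows():
        findings.append(f"session log row {idx}: negative time {row['time_s']}")

    bad_bounds = bounds[~(
        (bounds["n_lower_s"] > 0)
        & (bounds["n_lower_s"] < bounds["m_upper_s"])
    )]
    for idx, row in bad_bounds.iterrows():
        findings.append(
            f"bounds row {idx} ({row['task_id']}): need 0 < n_lower_s < m_upper_s"
        )
    for idx, row in bounds.iterrows():
        unknown = set(str(row["pattern"]).split("|")) - set(PATTERNS)
        if unknown:
            findings.append(
                f"bounds row {idx} ({row['task_id']}): unknown pattern(s) "
                f"{sorted(unknown)}"
            )
    dup = bounds.loc[bounds["task_id"].duplicated(), "task_id"]
    for t in sorted(set(dup)):
        findings.append(f"bounds table: duplicate entry for task {t!r}")

    uncovered = sorted(set(log["task_id"]) - set(bounds["task_id"]))
    for t in uncovered:
        findings.append(f"task {t!r} missing from the bounds table")

    for subj, grp in log.groupby("subject_id"):
        sess = np.sort(grp["session"].unique())
        expected = np.arange(sess.min(), sess.max() + 1)
        gaps = sorted(set(expected) - set(sess))
        if gaps:
            findings.append(f"subject {subj}: missing session(s) {gaps}")

    if bbt_path is not None:
        try:
            bbt = read_bbt(bbt_path)
        except ValueError as exc:
            findings.append(str(exc))
        else:
            neg = bbt[bbt["blocks"] < 0]
            for idx, row in neg.iterrows():
                findings.append(
                    f"BBT row {idx}: negative block count {row['blocks']}"
                )

    return ValidationReport(passed=not findings, findings=findings)
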