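"""Synthetic training cohorts with the statistical structure the analysis assumes.

No public raw data exists for this kind of bypass-prosthesis training study,
so the generator emulates the study design end to end: a cohort of subjects
(default six) trains over repeated sessions (default ten); each subject's
underlying weighted index of functionality follows an inverse learning curve

    wLIF_i(X) = a_i - b_i / X + session noise

with subject-level plateaus ``a_i`` and rates ``b_i`` drawn around
population values. Task times are back-solved through the inverse of the
task-score scaling so that re-scoring the generated log reproduces the
target wLIF (exactly when all noise terms are zero, in expectation
otherwise). DNF events occur with a probability that decays geometrically
over sessions — early failures vanish with training. BBT trials (three per
session, sessions 2..n) follow their own inverse curve on the
administration index. Orientation quadrants follow a Markov switch process
with a per-subject switching propensity, independent of performance.

Default population parameters are the plateau/rate values reported by the
original study (wLIF 79.75/22.09; BBT 37.21/15.91); dispersion, noise and
event-rate defaults are package choices documented in the methods note.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import reference
from .reference import PATTERNS

__all__ = [
    "CohortConfig",
    "SyntheticCohort",
    "WorkedFixture",
    "generate_cohort",
    "generate_worked_fixture",
]


@dataclass(frozen=True)
class CohortConfig:
    """Simulation parameters for one synthetic cohort.

    Score units are wLIF points (0-100) unless noted; BBT units are
    blocks/minute.
    """

    n_subjects: int = 6
    n_sessions: int = 10
    pop_plateau: float = 79.75
    pop_rate: float = 22.09
    subject_sd_plateau: float = 8.0
    subject_sd_rate: float = 5.0
    noise_sd: float = 3.0
    task_jitter_sd: float = 0.08  # lognormal sigma on task times
    dnf_base_prob: float = 0.10
    dnf_decay: float = 0.5  # per-session geometric decay of DNF probability
    bbt_plateau: float = 37.21
    bbt_rate: float = 15.91
    bbt_noise_sd: float = 2.0
    preposition_propensity: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.n_sessions < 3:
            raise ValueError("n_sessions must be >= 3 (fits need 3 points)")
        for name in (
            "subject_sd_plateau",
            "subject_sd_rate",
            "noise_sd",
            "task_jitter_sd",
            "bbt_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("dnf_base_prob", "dnf_decay", "preposition_propensity"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not (0 < self.pop_plateau <= 100):
            raise ValueError("pop_plateau must lie in (0, 100]")
        if self.bbt_plateau <= 0:
            raise ValueError("bbt_plateau must be > 0")


@dataclass(frozen=True)
class SyntheticCohort:
    """Generated cohort: session log, BBT trials, bounds, and a manifest."""

    session_log: pd.DataFrame
    bbt: pd.DataFrame
    bounds: pd.DataFrame
    manifest: dict = field(default_factory=dict)


def generate_cohort(
    config: CohortConfig | None = None,
    bounds: pd.DataFrame | None = None,
) -> SyntheticCohort:
    """Generate one synthetic cohort, fully reproducible given the seed.

    Returns the session log (one row per task attempt: ``subject_id,
    session, task_id, time_s, dnf, quadrant``), the BBT trial table
    (``subject_id, session, trial, blocks``), the bounds table used, and a
    manifest recording the configuration.
    """
    config = config or CohortConfig()
    config.validate()
    if bounds is None:
        bounds = reference.default_bounds()
    rng = np.random.default_rng(config.seed)

    tasks = bounds["task_id"].to_numpy()
    n_lower = bounds["n_lower_s"].to_numpy(dtype=float)
    m_upper = bounds["m_upper_s"].to_numpy(dtype=float)
    n_tasks = len(tasks)
    subjects = [f"S{i + 1}" for i in range(config.n_subjects)]
    sessions = np.arange(1, config.n_sessions + 1)

    # Subject-level curve parameters around the population values.
    a_i = rng.normal(config.pop_plateau, config.subject_sd_plateau,
                     config.n_subjects)
    a_i = np.clip(a_i, 1.0, 100.0)
    b_i = rng.normal(config.pop_rate, config.subject_sd_rate,
                     config.n_subjects)
    b_i = np.clip(b_i, 0.0, None)

    rows: list[pd.DataFrame] = []
    for si, subj in enumerate(subjects):
        # Target wLIF trajectory with session noise, clamped to the score range.
        target = a_i[si] - b_i[si] / sessions
        target = target + rng.normal(0.0, config.noise_sd, config.n_sessions)
        target = np.clip(target, 0.0, 100.0)

        # Back-solve times: every task aims at the session's target score,
        # then gets mean-one lognormal jitter (keeps times positive).
        ts = np.repeat(target, n_tasks)  # (n_sessions*n_tasks,)
        n_rep = np.tile(n_lower, config.n_sessions)
        m_rep = np.tile(m_upper, config.n_sessions)
        time_clean = m_rep - ts * (m_rep - n_rep) / 100.0
        if config.task_jitter_sd > 0:
            sigma = config.task_jitter_sd
            jitter = np.exp(
                rng.normal(-0.5 * sigma**2, sigma, ts.size)
            )
        else:
            jitter = np.ones(ts.size)
        time_s = time_clean * jitter

        p_dnf = config.dnf_base_prob * config.dnf_decay ** (sessions - 1)
        dnf = rng.random((config.n_sessions, n_tasks)) < p_dnf[:, None]
        dnf = dnf.ravel()
        time_s[dnf] = np.nan

        quad = _quadrant_sequences(
            rng, config.n_sessions, n_tasks, config.preposition_propensity
        )

        rows.append(
            pd.DataFrame(
                {
                    "subject_id": subj,
                    "session": np.repeat(sessions, n_tasks),
                    "task_id": np.tile(tasks, config.n_sessions),
                    "time_s": time_s,
                    "dnf": dnf.astype(int),
                    "quadrant": quad.ravel(),
                }
            )
        )
    session_log = pd.concat(rows, ignore_index=True)

    # BBT: administrations k = 1..n_sessions-1 land in sessions 2..n_sessions.
    k = np.arange(1, config.n_sessions)
    bbt_rows: list[pd.DataFrame] = []
    for subj in subjects:
        mean_k = config.bbt_plateau - config.bbt_rate / k
        trials = rng.normal(
            np.repeat(mean_k, 3), config.bbt_noise_sd
        )
        blocks = np.clip(np.rint(trials), 0, None).astype(int)
        bbt_rows.append(
            pd.DataFrame(
                {
                    "subject_id": subj,
                    "session": np.repeat(k + 1, 3),
                    "trial": np.tile([1, 2, 3], len(k)),
                    "blocks": blocks,
                }
            )
        )
    bbt = pd.concat(bbt_rows, ignore_index=True)

    manifest = {"generator": "mshap.synthetic.generate_cohort",
                "config": asdict(config)}
    return SyntheticCohort(
        session_log=session_log, bbt=bbt, bounds=bounds.copy(),
        manifest=manifest,
    )


def _quadrant_sequences(
    rng: np.random.Generator, n_sessions: int, n_tasks: int, propensity: float
) -> np.ndarray:
    """Markov orientation sequences: switch to a uniformly chosen other
    quadrant with the subject's propensity, else stay."""
    quad = np.empty((n_sessions, n_tasks), dtype=int)
    quad[:, 0] = rng.integers(1, 5, n_sessions)
    switch = rng.random((n_sessions, n_tasks - 1)) < propensity
    # draw of the replacement quadrant: uniform over the 3 others
    step = rng.integers(1, 4, (n_sessions, n_tasks - 1))
    for j in range(1, n_tasks):
        prev = quad[:, j - 1]
        moved = (prev - 1 + step[:, j - 1]) % 4 + 1
        quad[:, j] = np.where(switch[:, j - 1], moved, prev)
    return quad


@dataclass(frozen=True)
class WorkedFixture:
    """Tiny deterministic dataset with hand-verifiable expected outputs."""

    session_log: pd.DataFrame
    bbt: pd.DataFrame
    bounds: pd.DataFrame
    expected: dict


def generate_worked_fixture() -> WorkedFixture:
    """Deterministic 2-subject x 3-session x 4-task dataset.

    The four tasks jointly load all six prehensile patterns (two tasks load
    two patterns each), which is what lets a four-task administration
    produce a complete wLIF. Times are chosen so that task scores are round
    numbers; one DNF exercises the zero-scoring path.

    Expected values (all hand arithmetic):

    * Subject S1 scores every task at 40, 60, 70 across sessions 1-3, so
      all LIFs equal the common task score and wLIF = 40, 60, 70.
    * Subject S2 scores 50, 65, 75, except the tip task in session 1 is a
      DNF: tip LIF = 0, the others 50, and
      wLIF = (3*50 + 3*50 + 6*50 + 5*50 + 5*0 + 3*50)/25 = 40.
    * Session-2 wLIF effect size: paired diffs (20, 25), mean 22.5,
      SD sqrt(12.5), ES = 22.5/sqrt(12.5) ~= 6.3640 (large).
    * Session-3 diffs are (10, 10): zero SD, effect size undefined.
    """
    bounds = pd.DataFrame(
        [
            ("light_spherical", 5.0, 40.0, "spherical"),
            ("light_power", 4.0, 32.0, "power|tripod"),
            ("light_lateral", 3.0, 24.0, "lateral|extension"),
            ("light_tip", 6.0, 48.0, "tip"),
        ],
        columns=["task_id", "n_lower_s", "m_upper_s", "pattern"],
    )
    tasks = bounds["task_id"].tolist()
    n = bounds["n_lower_s"].to_numpy()
    m = bounds["m_upper_s"].to_numpy()

    def times_for(score: float) -> np.ndarray:
        return m - score * (m - n) / 100.0

    target = {
        ("S1", 1): 40.0, ("S1", 2): 60.0, ("S1", 3): 70.0,
        ("S2", 1): 50.0, ("S2", 2): 65.0, ("S2", 3): 75.0,
    }
    quadrants = {
        ("S1", 1): [1, 1, 2, 2], ("S1", 2): [1, 1, 2, 2],
        ("S1", 3): [1, 1, 2, 2],
        ("S2", 1): [1, 2, 3, 4], ("S2", 2): [2, 2, 2, 2],
        ("S2", 3): [3, 3, 1, 1],
    }
    dnf_at = {("S2", 1): "light_tip"}

    rows = []
    for (subj, sess), score in target.items():
        tvec = times_for(score)
        for j, task in enumerate(tasks):
            is_dnf = dnf_at.get((subj, sess)) == task
            rows.append(
                {
                    "subject_id": subj,
                    "session": sess,
                    "task_id": task,
                    "time_s": np.nan if is_dnf else round(float(tvec[j]), 6),
                    "dnf": int(is_dnf),
                    "quadrant": quadrants[(subj, sess)][j],
                }
            )
    session_log = pd.DataFrame(rows)

    bbt = pd.DataFrame(
        [
            ("S1", 2, 1, 28), ("S1", 2, 2, 31), ("S1", 2, 3, 34),
            ("S1", 3, 1, 33), ("S1", 3, 2, 33), ("S1", 3, 3, 33),
            ("S2", 2, 1, 20), ("S2", 2, 2, 22), ("S2", 2, 3, 24),
            ("S2", 3, 1, 25), ("S2", 3, 2, 26), ("S2", 3, 3, 27),
        ],
        columns=["subject_id", "session", "trial", "blocks"],
    )

    s2s1_lif = {p: 50.0 for p in PATTERNS}
    s2s1_lif["tip"] = 0.0
    expected = {
        "wlif": {
            ("S1", 1): 40.0, ("S1", 2): 60.0, ("S1", 3): 70.0,
            ("S2", 1): 40.0, ("S2", 2): 65.0, ("S2", 3): 75.0,
        },
        "lif_S2_session1": s2s1_lif,
        "bbt_mean": {
            ("S1", 2): 31.0, ("S1", 3): 33.0,
            ("S2", 2): 22.0, ("S2", 3): 26.0,
        },
        "effect_size_session2": 22.5 / math.sqrt(12.5),
        "effect_size_session3_defined": False,
        "quadrant_changes": {
            ("S1", 1): 1, ("S1", 2): 1, ("S1", 3): 1,
            ("S2", 1): 3, ("S2", 2): 0, ("S2", 3): 1,
        },
    }
    return WorkedFixture(
        session_log=session_log, bbt=bbt, bounds=bounds, expected=expected
    )
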