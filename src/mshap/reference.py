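"""Reference tables: task inventory, default normative bounds, pattern weights,
and the published learning-curve fits used as benchmark inputs.

The 22-task inventory follows the modified Southampton Hand Assessment
Procedure (mSHAP): twelve abstract-object tasks (a light and a heavy variant
for each of the six prehensile patterns) and ten activities of daily living.
Four original SHAP tasks (remove jar lid, food cutting, pick up coins,
lifting a tray) are not part of the inventory.

``PUBLISHED_FITS`` carries the per-category learning-curve parameters
(plateau *a*, rate *b*, goodness of fit R², training endpoint in sessions)
reported by the original six-subject, ten-session bypass-prosthesis training
study. They are benchmark inputs for the endpoint rule and summary
statistics, not values this package estimates.

The normative lower bounds ``n`` in ``DEFAULT_BOUNDS`` are illustrative
plausible task times (the normative data set behind the published study is
not public); the upper bound is ``m = 8 n`` by the scoring convention
(minimal function at eight times the normative time). Replace them with a
real normative table via the bounds CSV for any substantive use.
"""

from __future__ import annotations

import pandas as pd

#: Prehensile patterns, in the canonical reporting order.
PATTERNS: tuple[str, ...] = (
    "spherical",
    "tripod",
    "power",
    "lateral",
    "tip",
    "extension",
)

#: wLIF weights per pattern; the divisor is their sum (25).
DEFAULT_PATTERN_WEIGHTS: dict[str, float] = {
    "spherical": 3,
    "tripod": 3,
    "power": 6,
    "lateral": 5,
    "tip": 5,
    "extension": 3,
}

# task_id -> (n_lower seconds, patterns loaded)
# Abstract tasks map to their named pattern; ADL tasks map by grasp demand.
_TASK_TABLE: list[tuple[str, float, tuple[str, ...]]] = [
    ("light_spherical", 1.6, ("spherical",)),
    ("heavy_spherical", 1.9, ("spherical",)),
    ("light_tripod", 1.5, ("tripod",)),
    ("heavy_tripod", 1.8, ("tripod",)),
    ("light_power", 1.7, ("power",)),
    ("heavy_power", 2.0, ("power",)),
    ("light_lateral", 1.5, ("lateral",)),
    ("heavy_lateral", 1.8, ("lateral",)),
    ("light_tip", 1.6, ("tip",)),
    ("heavy_tip", 1.9, ("tip",)),
    ("light_extension", 1.4, ("extension",)),
    ("heavy_extension", 1.7, ("extension",)),
    ("lifting_a_light_object", 2.1, ("tip",)),
    ("rotate_key", 2.4, ("lateral",)),
    ("rotate_a_screw", 3.2, ("lateral",)),
    ("door_handle", 2.6, ("power",)),
    ("open_close_zip", 3.5, ("lateral",)),
    ("heavy_object", 2.8, ("power",)),
    ("glass_jug_pouring", 4.5, ("power",)),
    ("page_turning", 2.2, ("tip",)),
    ("carton_pouring", 4.8, ("power",)),
    ("button_board", 5.0, ("tip",)),
]

#: The 22 mSHAP task identifiers, in administration order.
TASKS: tuple[str, ...] = tuple(t for t, _, _ in _TASK_TABLE)

#: Multiplier from normative time n to the minimal-function bound m.
MINIMAL_FUNCTION_MULTIPLIER = 8.0


def default_bounds() -> pd.DataFrame:
    """Illustrative normative-bounds table (task_id, n_lower_s, m_upper_s, pattern).

    The ``pattern`` column holds pipe-separated pattern labels when a task
    loads more than one pattern.
    """
    rows = [
        {
            "task_id": task,
            "n_lower_s": n,
            "m_upper_s": n * MINIMAL_FUNCTION_MULTIPLIER,
            "pattern": "|".join(pats),
        }
        for task, n, pats in _TASK_TABLE
    ]
    return pd.DataFrame(rows)


# Published learning-curve fits: (category, plateau a, rate b, R², endpoint).
# Categories "Ts_*" are single-task mean task scores; "LIF_*" are pattern
# indexes of functionality.
PUBLISHED_FITS: list[tuple[str, float, float, float, int]] = [
    ("Ts_lifting_a_light_object", 81.810, 8.036, 0.053, 1),
    ("Ts_rotate_key", 78.153, 7.658, 0.014, 1),
    ("Ts_heavy_power", 85.905, 17.054, 0.739, 2),
    ("Ts_heavy_lateral", 77.017, 13.366, 0.063, 2),
    ("Ts_heavy_extension", 73.555, 14.380, 0.313, 2),
    ("Ts_light_spherical", 85.515, 16.495, 0.407, 2),
    ("Ts_light_lateral", 80.019, 9.191, 0.073, 2),
    ("Ts_heavy_spherical", 77.226, 12.991, 0.005, 2),
    ("Ts_heavy_tripod", 68.066, 15.068, 0.144, 3),
    ("Ts_heavy_tip", 72.624, 20.719, 0.185, 3),
    ("Ts_rotate_a_screw", 68.910, 13.875, 0.040, 3),
    ("Ts_door_handle", 93.587, 22.090, 0.940, 3),
    ("Ts_open_close_zip", 81.115, 19.785, 0.307, 3),
    ("Ts_light_power", 89.998, 32.045, 0.934, 4),
    ("Ts_heavy_object", 91.678, 30.437, 0.906, 4),
    ("Ts_glass_jug_pouring", 74.551, 25.199, 0.589, 4),
    ("Ts_page_turning", 84.145, 28.916, 0.574, 4),
    ("Ts_light_tripod", 77.954, 31.493, 0.527, 5),
    ("Ts_light_extension", 78.645, 36.015, 0.681, 5),
    ("Ts_carton_pouring", 79.164, 34.153, 0.602, 5),
    ("Ts_button_board", 80.999, 38.876, 0.826, 5),
    ("Ts_light_tip", 72.735, 37.968, 0.621, 6),
    ("LIF_lateral", 78.171, 15.040, 0.691, 2),
    ("LIF_spherical", 80.635, 21.213, 0.493, 3),
    ("LIF_power", 85.315, 20.590, 0.823, 3),
    ("LIF_tripod", 75.673, 28.479, 0.818, 4),
    ("LIF_tip", 77.125, 25.001, 0.885, 4),
    ("LIF_extension", 78.782, 26.437, 0.806, 4),
]

#: Published whole-assessment fits: plateau, rate, R².
WLIF_FIT = {"a": 79.75, "b": 22.09, "r2": 0.94}
BBT_FIT = {"a": 37.21, "b": 15.91, "r2": 0.64}


def published_fits() -> pd.DataFrame:
    """The published per-category fits as a DataFrame."""
    return pd.DataFrame(
        PUBLISHED_FITS, columns=["category", "a", "b", "r2", "endpoint"]
    )
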