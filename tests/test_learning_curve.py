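"""Inverse-curve fitting, training endpoints, effect sizes, fit summaries."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import mshap
from mshap.learning_curve import (
    FitError,
    ScoreSeries,
    classify_effect,
    effect_size,
    fit_inverse_curve,
    fit_inverse_curve_xy,
    summarize_table,
    training_endpoint,
)


def brute_force_fit(x, y, a0, b0, span=200.0, iters=12, grid=41):
    """Grid-refinement least-squares oracle over (a, b)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    best = (a0, b0)
    for _ in range(iters):
        a_grid = np.linspace(best[0] - span, best[0] + span, grid)
        b_grid = np.linspace(best[1] - span, best[1] + span, grid)
        sse = (
            (y[None, None, :] - (a_grid[:, None, None]
             - b_grid[None, :, None] / x[None, None, :])) ** 2
        ).sum(axis=2)
        i, j = np.unravel_index(np.argmin(sse), sse.shape)
        best = (a_grid[i], b_grid[j])
        span *= 2.0 / (grid - 1)
    return best


class TestFitInverseCurve:
    def test_noiseless_recovery(self):
        x = np.arange(1, 11)
        fit = fit_inverse_curve(80 - 20 / x)
        assert fit.a == pytest.approx(80, abs=1e-9)
        assert fit.b == pytest.approx(20, abs=1e-9)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)
        assert fit.endpoint_session == 3

    def test_constant_series(self):
        fit = fit_inverse_curve([50.0, 50.0, 50.0, 50.0])
        assert fit.a == 50.0
        assert fit.b == 0.0
        assert math.isnan(fit.r2)  # R^2 is meaningless with zero SS_tot
        assert fit.endpoint_session == 1

    def test_too_few_points(self):
        with pytest.raises(FitError):
            fit_inverse_curve([1.0, 2.0])
        with pytest.raises(FitError):
            fit_inverse_curve_xy([2, 2, 2], [1.0, 2.0, 3.0])

    @given(
        a=st.floats(1, 100),
        b=st.floats(0, 60),
        k=st.integers(4, 15),
    )
    def test_noiseless_recovery_property(self, a, b, k):
        x = np.arange(1, k + 1, dtype=float)
        fit = fit_inverse_curve_xy(x, a - b / x)
        assert fit.a == pytest.approx(a, rel=1e-8, abs=1e-8)
        assert fit.b == pytest.approx(b, rel=1e-8, abs=1e-8)

    def test_matches_grid_refinement_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            x = np.arange(1, rng.integers(5, 11), dtype=float)
            y = rng.uniform(20, 90) - rng.uniform(5, 40) / x
            y = y + rng.normal(0, 2, len(x))
            fit = fit_inverse_curve_xy(x, y)
            a_o, b_o = brute_force_fit(x, y, fit.a + 11, fit.b - 7)
            assert fit.a == pytest.approx(a_o, abs=1e-5)
            assert fit.b == pytest.approx(b_o, abs=1e-5)

    def test_noisy_fixed_seed_recovery(self):
        # Tolerances established by Monte-Carlo over >=1000 replicates of
        # this noise model (sigma=3, 10 sessions).
        rng = np.random.default_rng(0)
        x = np.arange(1, 11, dtype=float)
        y = 79.75 - 22.09 / x + rng.normal(0, 3, 10)
        fit = fit_inverse_curve_xy(x, y)
        assert abs(fit.a - 79.75) < 5
        assert abs(fit.b - 22.09) < 8

    def test_pooled_points_allowed(self):
        x = np.repeat(np.arange(1, 6, dtype=float), 3)
        y = 70 - 15 / x
        fit = fit_inverse_curve_xy(x, y)
        assert fit.a == pytest.approx(70, abs=1e-9)


class TestTrainingEndpoint:
    @pytest.mark.parametrize(
        "a, b, offset, expected",
        [
            (79.75, 22.09, 0, 3),   # whole-assessment wLIF curve
            (93.587, 22.090, 0, 3),
            (72.735, 37.968, 0, 6),
            (37.21, 15.91, 1, 6),   # BBT: administrations 1..9 = sessions 2..10
            (80.0, 0.0, 0, 1),      # plateau met immediately
            (80.0, -5.0, 0, 1),
            (80.0, 8.0, 0, 1),      # ratio exactly 1.0
            (80.0, 16.0, 0, 2),     # ratio exactly 2.0: no float overshoot
        ],
    )
    def test_examples(self, a, b, offset, expected):
        assert training_endpoint(a, b, offset) == expected

    def test_published_fit_rows_all_reproduce(self):
        fits = mshap.published_fits()
        for row in fits.itertuples(index=False):
            assert training_endpoint(row.a, row.b) == row.endpoint, row.category

    def test_nonpositive_plateau_rejected(self):
        with pytest.raises(FitError):
            training_endpoint(0.0, 10.0)
        with pytest.raises(FitError):
            training_endpoint(-5.0, 10.0)

    def test_endpoint_fraction_configurable(self):
        # at 50% of plateau the endpoint comes much earlier
        assert training_endpoint(80, 32, endpoint_fraction=0.5) == 1
        assert training_endpoint(80, 32, endpoint_fraction=0.9) == 4

    @given(
        a=st.floats(1, 100),
        b1=st.floats(0.01, 60),
        b2=st.floats(0.01, 60),
    )
    def test_monotone_in_rate(self, a, b1, b2):
        if b1 <= b2:
            assert training_endpoint(a, b1) <= training_endpoint(a, b2)

    @given(
        a1=st.floats(1, 100),
        a2=st.floats(1, 100),
        b=st.floats(0.01, 60),
    )
    def test_antitone_in_plateau(self, a1, a2, b):
        if a1 <= a2:
            assert training_endpoint(a1, b) >= training_endpoint(a2, b)


class TestEffectSize:
    def test_hand_values(self):
        res = effect_size([0, 0, 0], [1, 2, 3], session=2)
        assert res.es == pytest.approx(2.0)
        assert res.magnitude == "large"
        neg = effect_size([0, 0, 0], [-1, -2, -3])
        assert neg.es == pytest.approx(-2.0)
        assert neg.magnitude == "negative"

    def test_zero_variance_flagged_undefined(self):
        res = effect_size([0, 0, 0], [5, 5, 5])
        assert not res.defined
        assert res.magnitude == "undefined"

    def test_unpaired_subjects_dropped(self, caplog):
        prev = {"S1": 10.0, "S2": 20.0, "S3": 30.0}
        curr = {"S1": 12.0, "S2": 24.0, "S4": 99.0}
        with caplog.at_level("WARNING"):
            res = effect_size(prev, curr)
        assert res.n_pairs == 2
        assert any("S3" in m or "S4" in m for m in caplog.messages)

    @given(
        diffs=st.lists(
            st.floats(-50, 50).map(lambda v: round(v, 3)),
            min_size=3,
            max_size=8,
        ),
        shift=st.floats(-100, 100),
    )
    def test_shift_invariance(self, diffs, shift):
        prev = np.zeros(len(diffs))
        curr = np.asarray(diffs)
        r1 = effect_size(prev, curr)
        r2 = effect_size(prev + shift, curr + shift)
        if r1.defined and r2.defined:
            assert r1.es == pytest.approx(r2.es, rel=1e-6, abs=1e-6)
        else:
            assert r1.defined == r2.defined

    @pytest.mark.parametrize(
        "es, expected",
        [
            (0.8679, "large"), (1.942, "large"),
            (0.20, "small"),   # boundary inclusive: "above 0.20"
            (0.50, "medium"), (0.80, "large"),
            (0.19, "negligible"), (-0.1, "negative"), (0.0, "negligible"),
        ],
    )
    def test_classification(self, es, expected):
        assert classify_effect(es) == expected


class TestSummarizeTable:
    def test_single_perfect_fit(self):
        import pandas as pd

        fits = pd.DataFrame({"r2": [1.0], "endpoint": [3]})
        s = summarize_table(fits, 0.4)
        assert s["n_above_threshold"] == 1
        assert s["r2_mean"] == 1.0

    def test_published_task_rows(self):
        fits = mshap.published_fits()
        ts = fits[fits["category"].str.startswith("Ts_")]
        s = summarize_table(ts, 0.4)
        assert s["n_fits"] == 22
        assert s["n_above_threshold"] == 12
        assert round(s["r2_mean"], 2) == 0.43
        assert round(s["endpoint_mean_above"], 2) == 4.08

    def test_published_lif_rows(self):
        fits = mshap.published_fits()
        lif = fits[fits["category"].str.startswith("LIF_")]
        s = summarize_table(lif, 0.4)
        assert s["n_fits"] == 6
        assert s["n_above_threshold"] == 6
        assert round(s["r2_mean"], 2) == 0.75
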