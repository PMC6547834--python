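"""Quadrant-change counting, session normalization, grouping and regression."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import mshap
from mshap.prepositioning import (
    count_quadrant_changes,
    group_by_q,
    normalize_scores,
    regress_q_vs_score,
)


class TestCountQuadrantChanges:
    @pytest.mark.parametrize(
        "seq, expected",
        [
            ([3] * 22, 0),
            ([1, 2, 2, 3], 2),
            ([1, 2] * 11, 21),  # strictly alternating 22-entry sequence
            ([4], 0),
        ],
    )
    def test_examples(self, seq, expected):
        assert count_quadrant_changes(seq) == expected

    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            count_quadrant_changes([1, 2, 5])
        with pytest.raises(ValueError):
            count_quadrant_changes([])

    @given(
        seq=st.lists(st.sampled_from([1, 2, 3, 4]), min_size=1, max_size=22),
        perm=st.permutations([1, 2, 3, 4]),
    )
    def test_invariant_under_quadrant_relabeling(self, seq, perm):
        relabeled = [perm[q - 1] for q in seq]
        assert count_quadrant_changes(relabeled) == count_quadrant_changes(seq)


class TestNormalizeScores:
    def test_hand_column(self):
        wlif = pd.DataFrame({1: [70.0, 80.0, 90.0]}, index=["a", "b", "c"])
        out = normalize_scores(wlif)
        assert out[1].tolist() == [-10.0, 0.0, 10.0]

    def test_single_subject_all_zero(self):
        wlif = pd.DataFrame({1: [55.0], 2: [60.0]}, index=["a"])
        assert (normalize_scores(wlif) == 0).all().all()

    @given(
        vals=st.lists(
            st.lists(
                st.floats(0, 100).map(lambda v: round(v, 3)),
                min_size=3,
                max_size=3,
            ),
            min_size=2,
            max_size=6,
        )
    )
    def test_columns_centred_and_rank_preserved(self, vals):
        wlif = pd.DataFrame(vals)
        out = normalize_scores(wlif)
        assert np.allclose(out.sum(axis=0), 0.0, atol=1e-9)
        for col in wlif.columns:
            assert (
                wlif[col].rank(method="average")
                == out[col].rank(method="average")
            ).all()

    def test_empty_column_rejected(self):
        wlif = pd.DataFrame({1: [70.0, 80.0], 2: [np.nan, np.nan]})
        with pytest.raises(ValueError):
            normalize_scores(wlif)


class TestGroupByQ:
    def test_hand_groups(self):
        rec = pd.DataFrame({"q": [1, 1, 3], "wlif_norm": [4.0, 6.0, -2.0]})
        out = group_by_q(rec).set_index("q")
        assert out.loc[1, "mean"] == 5.0
        assert out.loc[3, "mean"] == -2.0
        assert out.loc[1, "n"] == 2
        assert math.isnan(out.loc[3, "se"])  # singleton group

    def test_opposite_values_cancel(self):
        rec = pd.DataFrame({"q": [2, 2], "wlif_norm": [5.0, -5.0]})
        assert group_by_q(rec)["mean"].iloc[0] == 0.0

    @given(
        qs=st.lists(st.integers(0, 6), min_size=2, max_size=30),
        data=st.data(),
    )
    def test_count_weighted_means_conserve_grand_mean(self, qs, data):
        vals = data.draw(
            st.lists(
                st.floats(-30, 30),
                min_size=len(qs),
                max_size=len(qs),
            )
        )
        rec = pd.DataFrame({"q": qs, "wlif_norm": vals})
        out = group_by_q(rec)
        weighted = (out["mean"] * out["n"]).sum() / out["n"].sum()
        assert weighted == pytest.approx(rec["wlif_norm"].mean(), abs=1e-9)


class TestRegression:
    def test_exact_line(self):
        grouped = pd.DataFrame(
            {"q": [0, 1, 2, 3], "mean": [1.0, 3.0, 5.0, 7.0], "n": [2] * 4}
        )
        res = regress_q_vs_score(grouped)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)
        assert res.r2 == pytest.approx(1.0)

    def test_zero_variance_response(self):
        grouped = pd.DataFrame({"q": [0, 1, 2], "mean": [4.0] * 3, "n": [1] * 3})
        res = regress_q_vs_score(grouped)
        assert res.slope == 0.0
        assert math.isnan(res.r)

    def test_matches_scipy_linregress(self):
        # independent route: scipy's closed-form OLS on the same points
        from scipy.stats import linregress

        rng = np.random.default_rng(5)
        for _ in range(20):
            k = rng.integers(3, 9)
            grouped = pd.DataFrame(
                {
                    "q": np.arange(k),
                    "mean": rng.normal(0, 5, k),
                    "n": rng.integers(1, 6, k),
                }
            )
            res = regress_q_vs_score(grouped)
            ref = linregress(grouped["q"], grouped["mean"])
            assert res.slope == pytest.approx(ref.slope, abs=1e-10)
            assert res.intercept == pytest.approx(ref.intercept, abs=1e-10)
            assert res.r == pytest.approx(ref.rvalue, abs=1e-10)

    def test_weighted_matches_replication(self):
        # weighting by n must equal replicating each point n times
        from scipy.stats import linregress

        grouped = pd.DataFrame(
            {"q": [0, 1, 2], "mean": [1.0, 4.0, 2.0], "n": [1, 3, 2]}
        )
        res = regress_q_vs_score(grouped, weighted=True)
        x = np.repeat(grouped["q"], grouped["n"])
        y = np.repeat(grouped["mean"], grouped["n"])
        ref = linregress(x, y)
        assert res.slope == pytest.approx(ref.slope, abs=1e-10)
        assert res.intercept == pytest.approx(ref.intercept, abs=1e-10)

    def test_too_few_groups(self):
        grouped = pd.DataFrame({"q": [2], "mean": [1.0], "n": [4]})
        with pytest.raises(ValueError):
            regress_q_vs_score(grouped)


class TestEndToEnd:
    def test_fixture_quadrant_counts(self, worked_fixture):
        fx = worked_fixture
        scores, _ = mshap.score_sessions(fx.session_log, fx.bounds)
        rec = mshap.prepositioning_records(fx.session_log, scores)
        by_key = rec.set_index(["subject_id", "session"])["q"]
        for key, expected in fx.expected["quadrant_changes"].items():
            assert by_key.loc[key] == expected

    def test_null_simulation_slope_centred_on_zero(self):
        # q and performance are generated independently, so the regression
        # slope over many cohorts should be centred on 0
        slopes = []
        for seed in range(40):
            c = mshap.generate_cohort(mshap.CohortConfig(seed=seed))
            sc, _ = mshap.score_sessions(c.session_log, c.bounds, c.bbt)
            rec = mshap.prepositioning_records(c.session_log, sc)
            slopes.append(mshap.regress_q_vs_score(group_by_q(rec)).slope)
        slopes = np.asarray(slopes)
        se = slopes.std(ddof=1) / np.sqrt(len(slopes))
        assert abs(slopes.mean()) < 4 * se
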