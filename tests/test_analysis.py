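import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from metapred import (
    aggregate_to_scale,
    bottom_up_effect,
    build_transitions,
    colonization_rate,
    field_metrics,
    interaction_estimates,
    occupancy,
    top_down_effect,
)


def make_ts(counts_h, counts_p, run_id=0):
    """Long-format frame from (T, N) count arrays."""
    h = np.asarray(counts_h)
    p = np.asarray(counts_p)
    t, n = h.shape
    return pd.DataFrame(
        {
            "run_id": run_id,
            "patch_id": np.tile(np.arange(n), t),
            "time": np.repeat(np.arange(t), n),
            "H": h.ravel(),
            "P": p.ravel(),
        }
    )


def ols_slope(x, y):
    """Closed-form OLS oracle: sum (x-xbar)(y-ybar) / sum (x-xbar)^2."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    xc = x - x.mean()
    return float((xc * (y - y.mean())).sum() / (xc**2).sum())


class TestAggregation:
    def test_scale1_identity(self, layout9, rng):
        ts = make_ts(rng.integers(0, 10, (4, 9)), rng.integers(0, 3, (4, 9)))
        agg = aggregate_to_scale(ts, layout9, 1)
        pd.testing.assert_frame_equal(
            agg, ts.sort_values(["run_id", "time", "patch_id"], ignore_index=True),
            check_dtype=False,
        )

    def test_hand_sum(self, layout9):
        h = np.zeros((1, 9), dtype=int)
        h[0, :3] = [2, 3, 0]
        ts = make_ts(h, np.zeros_like(h))
        agg = aggregate_to_scale(ts, layout9, 3)
        assert agg.loc[agg.patch_id == 0, "H"].item() == 5

    def test_totals_conserved_across_scales(self, layout81, rng):
        ts = make_ts(rng.integers(0, 20, (5, 81)), rng.integers(0, 4, (5, 81)))
        for scale in (1, 3, 9, 27, 81):
            agg = aggregate_to_scale(ts, layout81, scale)
            for col in ("H", "P"):
                got = agg.groupby("time")[col].sum()
                want = ts.groupby("time")[col].sum()
                assert got.to_numpy().tolist() == want.to_numpy().tolist()

    def test_unknown_patches_rejected(self, layout9):
        ts = make_ts(np.zeros((1, 9), int), np.zeros((1, 9), int))
        ts.loc[0, "patch_id"] = 77
        with pytest.raises(ValueError):
            aggregate_to_scale(ts, layout9, 3)


class TestTransitions:
    def test_row_count_without_zero_pairs(self, rng):
        h = rng.integers(1, 10, (5, 4))  # strictly positive: nothing filtered
        ts = make_ts(h, rng.integers(0, 3, (5, 4)))
        tt = build_transitions(ts)
        assert len(tt) == 4 * 4

    def test_all_zero_pair_removed(self):
        h = np.array([[0, 5], [0, 6], [1, 7]])
        p = np.zeros_like(h)
        tt = build_transitions(make_ts(h, p))
        # patch 0's first transition (0,0,0,0) is dropped, second kept
        assert len(tt) == 3
        assert not ((tt[["H_t", "H_t1", "P_t", "P_t1"]] == 0).all(axis=1)).any()

    def test_log_ratio_formula(self):
        h = np.array([[2], [0]])
        p = np.array([[1], [3]])
        tt = build_transitions(make_ts(h, p))
        assert tt.y_td.item() == pytest.approx(np.log(3) - np.log(1))
        assert tt.x_td.item() == pytest.approx(2.0)
        assert tt.y_bu.item() == pytest.approx(np.log(4) - np.log(2))
        assert tt.x_bu.item() == pytest.approx(1.0)

    def test_transitions_do_not_span_rounds(self, rng):
        a = make_ts(rng.integers(1, 5, (3, 2)), rng.integers(1, 3, (3, 2)), run_id=0)
        b = make_ts(rng.integers(1, 5, (3, 2)), rng.integers(1, 3, (3, 2)), run_id=1)
        b["time"] += 3
        tt = build_transitions(pd.concat([a, b], ignore_index=True))
        assert len(tt) == 2 * 2 * 2  # (T-1) per round, never across the boundary
        assert not ((tt.run_id == 0) & (tt.t >= 2)).any()

    def test_adding_all_zero_pair_changes_nothing(self, rng):
        h = rng.integers(1, 9, (4, 3))
        p = rng.integers(0, 3, (4, 3))
        base = make_ts(h, p)
        extra = make_ts(np.zeros((4, 1), int), np.zeros((4, 1), int))
        extra["patch_id"] = 3
        both = pd.concat([base, extra], ignore_index=True)
        est_a = top_down_effect(build_transitions(base))
        est_b = top_down_effect(build_transitions(both))
        assert est_a.slope == pytest.approx(est_b.slope, abs=1e-14)


class TestRegression:
    def test_exact_recovery_of_planted_slope(self):
        x = np.arange(10, dtype=float)
        tt = pd.DataFrame({"x_td": x, "y_td": 0.5 * x, "x_bu": x, "y_bu": -0.2 * x + 1})
        td = top_down_effect(tt)
        bu = bottom_up_effect(tt)
        assert td.slope == pytest.approx(0.5, abs=1e-12)
        assert td.pearson_r == pytest.approx(1.0)
        assert bu.slope == pytest.approx(-0.2, abs=1e-12)

    def test_constant_response_gives_zero_slope(self, rng):
        x = rng.normal(size=30)
        tt = pd.DataFrame({"x_td": x, "y_td": np.zeros(30), "x_bu": x, "y_bu": np.zeros(30)})
        assert top_down_effect(tt).slope == pytest.approx(0.0, abs=1e-14)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_matches_closed_form_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 60))
        x = rng.normal(size=n)
        if np.ptp(x) == 0:
            return
        y = rng.normal(size=n)
        tt = pd.DataFrame({"x_td": x, "y_td": y, "x_bu": x, "y_bu": y})
        assert top_down_effect(tt).slope == pytest.approx(ols_slope(x, y), abs=1e-10)

    def test_degenerate_cases_flagged_not_thrown(self):
        tiny = pd.DataFrame({"x_td": [1.0, 2.0], "y_td": [0.1, 0.2],
                             "x_bu": [1.0, 2.0], "y_bu": [0.1, 0.2]})
        est = top_down_effect(tiny)
        assert not est.defined and np.isnan(est.slope)
        flat = pd.DataFrame({"x_td": np.ones(10), "y_td": np.arange(10.0),
                             "x_bu": np.ones(10), "y_bu": np.arange(10.0)})
        assert not top_down_effect(flat).defined

    def test_estimates_table_shape(self, layout81, rng):
        ts = make_ts(rng.integers(0, 15, (4, 81)), rng.integers(0, 3, (4, 81)))
        est = interaction_estimates(ts, layout81)
        assert len(est) == 8  # 2 metrics x scales (1, 3, 9, 27); top excluded
        assert sorted(est.scale.unique()) == [1, 3, 9, 27]
        est_all = interaction_estimates(ts, layout81, include_top_scale=True)
        assert len(est_all) == 10


class TestFieldMetrics:
    def test_occupancy_degenerate_full_and_empty(self):
        full = make_ts(np.ones((3, 4), int), np.zeros((3, 4), int))
        occ = occupancy(full, "H")
        assert occ.mean == 1.0 and occ.se == 0.0
        assert occupancy(full, "P").mean == 0.0

    def test_occupancy_two_dates_hand_value(self):
        h = np.array([[1, 1, 0, 0], [1, 1, 1, 1]])
        occ = occupancy(make_ts(h, np.zeros_like(h)), "H")
        assert occ.mean == pytest.approx(0.75)
        assert occ.se == pytest.approx(0.25)  # sd(0.5, 1.0)/sqrt(2)

    def test_colonization_hand_example(self):
        h = np.array([[0, 0, 5], [2, 0, 1]])
        col = colonization_rate(make_ts(h, np.zeros_like(h)), "H")
        assert col.values.tolist() == [0.5]  # 1 colonization / 2 empty

    def test_colonization_skips_full_intervals(self):
        h = np.array([[1, 1], [1, 1], [0, 1], [1, 1]])
        col = colonization_rate(make_ts(h, np.zeros_like(h)), "H")
        # first interval has no empty patch (skipped); second has 1/1
        assert col.values.tolist() == [1.0]

    def test_colonization_undefined_when_never_empty(self):
        h = np.ones((3, 2), int)
        col = colonization_rate(make_ts(h, np.zeros_like(h)), "H")
        assert not col.defined

    def test_all_empty_none_colonized_is_zero(self):
        h = np.zeros((2, 3), int)
        col = colonization_rate(make_ts(h, np.zeros_like(h)), "H")
        assert col.values.tolist() == [0.0]

    def test_report_covers_both_species(self, rng):
        ts = make_ts(rng.integers(0, 5, (6, 10)), rng.integers(0, 2, (6, 10)))
        report = field_metrics(ts)
        assert list(report.species) == ["herbivore", "predator"]
        assert ((report.filter(like="_mean") >= 0) & (report.filter(like="_mean") <= 1)).all().all()
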