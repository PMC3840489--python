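"""Quantile normalization, the replicate-consistency screen and its t-bound."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from mirpain.screen import (
    ExpressionMatrix,
    ScreenConfig,
    group_stats,
    implied_t_bound,
    quantile_normalize,
    screen,
    screen_report,
)

from conftest import make_matrix


def brute_quantile_normalize(arr: np.ndarray) -> np.ndarray:
    """Independent sort/average/remap oracle (no ties expected)."""
    reference = np.mean(np.sort(arr, axis=0), axis=1)
    out = np.empty_like(arr, dtype=float)
    for j in range(arr.shape[1]):
        order = np.argsort(arr[:, j])
        for rank, row in enumerate(order):
            out[row, j] = reference[rank]
    return out


class TestQuantileNormalize:
    def test_hand_worked_two_arrays(self):
        frame = pd.DataFrame({"A": [2.0, 4.0, 6.0], "B": [9.0, 5.0, 1.0]})
        result = quantile_normalize(frame)
        expected = pd.DataFrame({"A": [1.5, 4.5, 7.5], "B": [7.5, 4.5, 1.5]})
        pd.testing.assert_frame_equal(result, expected)

    def test_single_array_identity(self):
        frame = pd.DataFrame({"A": [3.0, 1.0, 2.0]})
        pd.testing.assert_frame_equal(quantile_normalize(frame), frame)

    def test_idempotent_and_sum_preserving(self, rng):
        frame = pd.DataFrame(rng.gamma(2.0, 100.0, (40, 5)))
        once = quantile_normalize(frame)
        twice = quantile_normalize(once)
        pd.testing.assert_frame_equal(once, twice)
        assert once.to_numpy().sum() == pytest.approx(frame.to_numpy().sum())

    def test_all_columns_share_sorted_vector(self, rng):
        frame = pd.DataFrame(rng.uniform(0, 1000, (30, 4)))
        norm = quantile_normalize(frame).to_numpy()
        ref = np.sort(norm[:, 0])
        for j in range(norm.shape[1]):
            np.testing.assert_allclose(np.sort(norm[:, j]), ref)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        arr = rng.uniform(1, 1e4, (50, 6))
        result = quantile_normalize(pd.DataFrame(arr)).to_numpy()
        np.testing.assert_allclose(result, brute_quantile_normalize(arr), rtol=1e-12)

    def test_rank_order_preserved_within_array(self, rng):
        arr = rng.uniform(0, 100, (25, 3))
        norm = quantile_normalize(pd.DataFrame(arr)).to_numpy()
        for j in range(arr.shape[1]):
            assert np.array_equal(np.argsort(arr[:, j]), np.argsort(norm[:, j]))

    def test_ties_get_mean_of_spanned_reference(self):
        # column A has a tied pair occupying reference slots 0 and 1
        frame = pd.DataFrame({"A": [5.0, 5.0, 9.0], "B": [1.0, 2.0, 3.0]})
        norm = quantile_normalize(frame)
        ref = np.sort(frame.to_numpy(), axis=0).mean(axis=1)
        assert norm["A"].iloc[0] == norm["A"].iloc[1] == pytest.approx(ref[:2].mean())

    def test_non_finite_rejected_with_cell(self):
        frame = pd.DataFrame({"A": [1.0, np.nan], "B": [2.0, 3.0]})
        with pytest.raises(ValueError, match="non-finite"):
            quantile_normalize(frame)


class TestGroupStats:
    def test_hand_arithmetic_sample_sd(self):
        m = make_matrix(
            {"s1": [90.0], "s2": [100.0], "s3": [110.0],
             "t1": [200.0], "t2": [200.0], "t3": [200.0]},
            {"s1": "sham", "s2": "sham", "s3": "sham",
             "t1": "tumour", "t2": "tumour", "t3": "tumour"},
        )
        stats = group_stats(m, "PID-8")
        assert stats["mean_sham"].iloc[0] == pytest.approx(100.0)
        assert stats["sd_sham"].iloc[0] == pytest.approx(10.0)
        assert stats["sd_tumour"].iloc[0] == pytest.approx(0.0)

    def test_array_order_irrelevant(self, small_matrix):
        stats = group_stats(small_matrix, "PID-8")
        shuffled = ExpressionMatrix(
            values=small_matrix.values[["t2", "s1", "t1", "s2"]],
            design=small_matrix.design.iloc[::-1].reset_index(drop=True),
        )
        pd.testing.assert_frame_equal(stats, group_stats(shuffled, "PID-8"))

    def test_missing_group_raises(self):
        m = make_matrix({"s1": [1.0], "s2": [2.0]}, {"s1": "sham", "s2": "sham"})
        with pytest.raises(ValueError, match="tumour"):
            group_stats(m, "PID-8")

    def test_population_sd_mode(self):
        m = make_matrix(
            {"s1": [90.0], "s2": [110.0], "t1": [90.0], "t2": [110.0]},
            {"s1": "sham", "s2": "sham", "t1": "tumour", "t2": "tumour"},
        )
        pop = group_stats(m, "PID-8", ScreenConfig(sd_mode="population"))
        assert pop["sd_sham"].iloc[0] == pytest.approx(10.0)  # ddof=0
        samp = group_stats(m, "PID-8")
        assert samp["sd_sham"].iloc[0] == pytest.approx(10.0 * np.sqrt(2))


def brute_screen(m_s, s_s, m_t, s_t, k=5.0, fc=2.5):
    """Independent reimplementation of the two selection inequalities."""
    if m_s <= 0 or m_t <= 0:
        return None
    consistent = abs(m_t - m_s) >= k * (s_t + s_s)
    ratio = m_t / m_s
    passes_fc = ratio >= fc or ratio <= 1.0 / fc
    selected = consistent and passes_fc
    direction = "none"
    if selected:
        direction = "up" if m_t > m_s else "down"
    return selected, direction


class TestScreen:
    @pytest.mark.parametrize(
        "m_s,s_s,m_t,s_t,selected,direction",
        [
            (100.0, 10.0, 300.0, 20.0, True, "up"),     # |200| >= 5*30, FC 3
            (100.0, 2.0, 220.0, 2.0, False, "none"),    # FC 2.2 < 2.5
            (100.0, 0.0, 100.0, 0.0, False, "none"),    # FC 1
            (300.0, 20.0, 100.0, 10.0, True, "down"),   # mirror of first
        ],
    )
    def test_worked_examples(self, m_s, s_s, m_t, s_t, selected, direction):
        stats = pd.DataFrame(
            {"mean_sham": [m_s], "sd_sham": [s_s],
             "mean_tumour": [m_t], "sd_tumour": [s_t]}, index=["mir"]
        )
        res = screen(stats)
        assert bool(res["selected"].iloc[0]) is selected
        assert res["direction"].iloc[0] == direction

    def test_secondary_threshold_tracked_separately(self):
        stats = pd.DataFrame(
            {"mean_sham": [100.0], "sd_sham": [2.0],
             "mean_tumour": [220.0], "sd_tumour": [2.0]}, index=["mir"]
        )
        res = screen(stats)
        assert bool(res["passes_consistency"].iloc[0])
        assert not bool(res["passes_fc_primary"].iloc[0])
        assert bool(res["passes_fc_secondary"].iloc[0])

    def test_boundaries_inclusive(self):
        stats = pd.DataFrame(
            {"mean_sham": [100.0, 100.0], "sd_sham": [10.0, 0.0],
             "mean_tumour": [250.0, 250.0], "sd_tumour": [20.0, 0.0]},
            index=["at_consistency_bound", "at_fc_bound"],
        )
        res = screen(stats)  # |150| == 5*(10+20); FC == 2.5 exactly
        assert res["selected"].all()

    def test_nonpositive_mean_unevaluable_not_crash(self):
        stats = pd.DataFrame(
            {"mean_sham": [0.0, 100.0], "sd_sham": [0.0, 1.0],
             "mean_tumour": [50.0, 400.0], "sd_tumour": [1.0, 1.0]},
            index=["bad", "good"],
        )
        res = screen(stats)
        assert not bool(res.loc["bad", "evaluable"])
        assert not bool(res.loc["bad", "selected"])
        assert bool(res.loc["good", "selected"])

    def test_matches_brute_force_on_exhaustive_grid(self):
        means = [10.0, 50.0, 100.0, 240.0, 260.0, 500.0]
        sds = [0.0, 1.0, 5.0, 30.0]
        rows, expected = [], []
        for m_s in means:
            for m_t in means:
                for s_s in sds:
                    for s_t in sds:
                        rows.append((m_s, s_s, m_t, s_t))
                        expected.append(brute_screen(m_s, s_s, m_t, s_t))
        stats = pd.DataFrame(rows, columns=["mean_sham", "sd_sham", "mean_tumour", "sd_tumour"])
        res = screen(stats)
        for i, exp in enumerate(expected):
            assert (bool(res["selected"].iloc[i]), res["direction"].iloc[i]) == exp

    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_scale_invariance(self, scale):
        stats = pd.DataFrame(
            {"mean_sham": [100.0, 80.0, 10.0], "sd_sham": [5.0, 1.0, 0.5],
             "mean_tumour": [300.0, 90.0, 3.0], "sd_tumour": [8.0, 1.0, 0.2]},
        )
        base = screen(stats)
        scaled = screen(stats * scale)
        pd.testing.assert_series_equal(base["selected"], scaled["selected"])
        pd.testing.assert_series_equal(base["direction"], scaled["direction"])


class TestImpliedTBound:
    def test_default_screen_implies_p_below_paper_bound(self):
        p = implied_t_bound(5, 3)
        assert p == pytest.approx(2 * sps.t.sf(5 * np.sqrt(3), 4))
        assert p <= 0.001

    def test_supremum_over_sd_grid(self):
        """Every SD configuration on the criterion boundary has p <= the bound."""
        k, n = 5.0, 3
        bound = implied_t_bound(k, n)
        grid = np.linspace(0.0, 10.0, 100)
        worst = 0.0
        for s_s in grid:
            for s_t in grid:
                if s_s == 0 and s_t == 0:
                    continue
                diff = k * (s_s + s_t)
                t = diff / np.sqrt((s_s**2 + s_t**2) / n)
                worst = max(worst, 2 * sps.t.sf(t, 2 * n - 2))
        assert worst <= bound + 1e-12
        assert worst == pytest.approx(bound, rel=1e-3)  # attained as one SD -> 0

    def test_monotone_decreasing_in_k(self):
        ps = [implied_t_bound(k, 3) for k in (1, 2, 5, 10)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_equal_sds_give_smaller_p(self):
        k, n = 5.0, 3
        t_equal = k * np.sqrt(2 * n)
        p_equal = 2 * sps.t.sf(t_equal, 2 * n - 2)
        assert p_equal < implied_t_bound(k, n)

    def test_rejects_single_replicate(self):
        with pytest.raises(ValueError):
            implied_t_bound(5, 1)


class TestScreenReport:
    def test_empty_selection(self):
        stats = pd.DataFrame(
            {"mean_sham": [100.0], "sd_sham": [50.0],
             "mean_tumour": [110.0], "sd_tumour": [50.0]}, index=["m"]
        )
        report = screen_report(screen(stats))
        assert report["summary"]["n_selected"] == 0
        assert report["heatmap"] is None

    def test_secondary_count_nests_primary(self, rng):
        stats = pd.DataFrame(
            {"mean_sham": rng.uniform(50, 150, 100),
             "sd_sham": rng.uniform(0, 10, 100),
             "mean_tumour": rng.uniform(50, 400, 100),
             "sd_tumour": rng.uniform(0, 10, 100)},
        )
        res = screen(stats)
        s = screen_report(res)["summary"]
        assert s["n_fc_secondary"] >= int(res["passes_fc_primary"].sum())

    def test_heatmap_rows_ordered_up_first(self):
        stats = pd.DataFrame(
            {"mean_sham": [100.0, 100.0], "sd_sham": [1.0, 1.0],
             "mean_tumour": [300.0, 25.0], "sd_tumour": [1.0, 1.0]},
            index=["up_mir", "down_mir"],
        )
        norm = pd.DataFrame(np.ones((2, 4)), index=["down_mir", "up_mir"])
        report = screen_report(screen(stats), normalized=norm)
        assert list(report["heatmap"].index) == ["up_mir", "down_mir"]
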