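import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from scipy.spatial.transform import Rotation

from dnadistort import trajectory_stats as ts
from dnadistort.io_formats import HelicalSeries, ScalarSeries


def _series(n_frames=11, n_levels=11, dt=2.0, name="buckle", seed=0):
    rng = np.random.default_rng(seed)
    return HelicalSeries(
        name, np.arange(n_frames) * dt, rng.standard_normal((n_frames, n_levels))
    )


class TestDiscardEquilibration:
    def test_full_protocol_retains_4851_frames(self):
        series = _series(n_frames=5001, dt=2.0)
        kept = ts.discard_equilibration(series, 300.0)
        assert kept.n_frames == 4851
        assert kept.times[0] == 300.0 and kept.times[-1] == 10000.0

    def test_t_start_zero_is_identity(self):
        series = _series()
        kept = ts.discard_equilibration(series, 0.0)
        np.testing.assert_array_equal(kept.values, series.values)

    def test_t_start_beyond_series_rejected(self):
        with pytest.raises(ValueError, match="no frames"):
            ts.discard_equilibration(_series(), 1e9)

    def test_works_on_scalar_series(self):
        series = ScalarSeries(np.arange(10) * 2.0, np.arange(10.0))
        kept = ts.discard_equilibration(series, 10.0)
        assert kept.times[0] == 10.0 and kept.values[0] == 5.0


class TestTrimTerminalLevels:
    def test_eleven_levels_trim_to_nine_keeping_indices(self):
        trimmed = ts.trim_terminal_levels(_series(n_levels=11), 1)
        assert trimmed.n_levels == 9
        assert trimmed.levels == tuple(range(2, 11))

    def test_ten_step_levels_trim_to_eight(self):
        trimmed = ts.trim_terminal_levels(_series(n_levels=10, name="twist"), 1)
        assert trimmed.n_levels == 8

    def test_k_zero_is_identity(self):
        series = _series()
        assert ts.trim_terminal_levels(series, 0) is series

    def test_too_few_levels_rejected(self):
        with pytest.raises(ValueError, match="cannot trim"):
            ts.trim_terminal_levels(_series(n_levels=4), 2)


class TestLevelSummaries:
    def test_simple_column(self):
        series = HelicalSeries("shear", [0, 2, 4], [[1.0], [2.0], [3.0]])
        (summ,) = ts.level_summaries(series)
        assert summ.median == 2.0
        assert summ.iqr == pytest.approx(1.0)  # type-7 quartiles: 1.5 to 2.5
        assert summ.n_frames == 3

    def test_constant_column_has_zero_iqr(self):
        series = HelicalSeries("shear", [0, 2, 4], np.full((3, 2), 7.0))
        for summ in ts.level_summaries(series):
            assert summ.median == 7.0 and summ.iqr == 0.0

    def test_agrees_with_sorted_order_statistic_oracle(self, rng):
        # type-7: quantile q sits at index (n-1)q, linearly interpolated
        def oracle(col, q):
            srt = np.sort(col)
            pos = (len(col) - 1) * q
            lo = int(np.floor(pos))
            hi = int(np.ceil(pos))
            return srt[lo] + (pos - lo) * (srt[hi] - srt[lo])

        values = rng.standard_normal((40, 200))
        series = HelicalSeries("roll", np.arange(40) * 2.0, values)
        for j, summ in enumerate(ts.level_summaries(series)):
            col = values[:, j]
            assert summ.median == pytest.approx(oracle(col, 0.5), abs=1e-12)
            assert summ.q1 == pytest.approx(oracle(col, 0.25), abs=1e-12)
            assert summ.q3 == pytest.approx(oracle(col, 0.75), abs=1e-12)

    def test_summary_invariant_to_adding_then_trimming_a_level(self, rng):
        values = rng.standard_normal((20, 9))
        inner = HelicalSeries("shear", np.arange(20) * 2.0, values,
                              levels=tuple(range(2, 11)))
        padded = HelicalSeries(
            "shear", np.arange(20) * 2.0,
            np.column_stack([rng.standard_normal(20), values, rng.standard_normal(20)]),
        )
        trimmed = ts.trim_terminal_levels(padded, 1)
        for a, b in zip(ts.level_summaries(inner), ts.level_summaries(trimmed)):
            assert a.median == b.median and a.q1 == b.q1 and a.q3 == b.q3


class TestMannWhitney:
    def test_textbook_exact_case(self):
        res = ts.mann_whitney_u([1, 2], [3, 4])
        assert res.U == 0.0
        assert res.p_value == pytest.approx(2 / 6)
        assert res.method == "exact"

    def test_identical_multisets_give_p_one(self):
        res = ts.mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == 1.0

    def test_degenerate_constant_input_flagged(self):
        res = ts.mann_whitney_u([5.0] * 4, [5.0] * 6)
        assert res.degenerate and res.p_value == 1.0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        x=st.lists(st.integers(-50, 50), min_size=1, max_size=7),
        y=st.lists(st.integers(-50, 50), min_size=1, max_size=7),
    )
    def test_u_statistics_sum_to_nx_times_ny(self, x, y):
        ux = ts.mann_whitney_u(x, y).U
        uy = ts.mann_whitney_u(y, x).U
        assert ux + uy == pytest.approx(len(x) * len(y))

    def test_two_sided_p_symmetric_in_arguments(self, rng):
        for n in (5, 12):
            x, y = rng.standard_normal(n), rng.standard_normal(n) + 0.4
            assert ts.mann_whitney_u(x, y).p_value == pytest.approx(
                ts.mann_whitney_u(y, x).p_value, abs=1e-12
            )

    def test_exact_branch_matches_scipy(self, rng):
        for _ in range(10):
            x, y = rng.standard_normal(6), rng.standard_normal(7)
            ours = ts.mann_whitney_u(x, y)
            ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert ours.U == ref.statistic
            assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_asymptotic_branch_matches_scipy(self, rng):
        for _ in range(10):
            x = np.round(rng.standard_normal(25), 1)  # induce ties
            y = np.round(rng.standard_normal(30) + 0.3, 1)
            ours = ts.mann_whitney_u(x, y)
            ref = stats.mannwhitneyu(x, y, alternative="two-sided",
                                     method="asymptotic", use_continuity=True)
            assert ours.method == "asymptotic"
            assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ts.mann_whitney_u([], [1.0])


class TestAndersonDarling:
    def test_matches_direct_sum_oracle_on_fixed_sample(self):
        rng = np.random.default_rng(42)
        x = rng.standard_normal(20)
        res = ts.anderson_darling_normality(x)
        z = np.sort((x - x.mean()) / x.std(ddof=1))
        n = len(z)
        phi = stats.norm.cdf(z)
        total = sum(
            (2 * i - 1) * (np.log(phi[i - 1]) + np.log(1 - phi[n - i]))
            for i in range(1, n + 1)
        )
        a2_oracle = -n - total / n
        assert res.a2 == pytest.approx(a2_oracle, abs=1e-10)
        assert res.a2_star == pytest.approx(a2_oracle * (1 + 0.75 / n + 2.25 / n**2))

    def test_matches_scipy_statistic(self, rng):
        x = rng.standard_normal(100)
        res = ts.anderson_darling_normality(x)
        ref = stats.anderson(x, "norm", method="interpolate")
        assert res.a2 == pytest.approx(ref.statistic, abs=1e-10)

    def test_bimodal_sample_rejected_as_non_normal(self, rng):
        x = np.concatenate([rng.standard_normal(250) - 5, rng.standard_normal(250) + 5])
        assert ts.anderson_darling_normality(x).reject_normality

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            ts.anderson_darling_normality(np.ones(20))

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError, match="at least 8"):
            ts.anderson_darling_normality(np.arange(5.0))


class TestKabschRmsd:
    def _frame(self, rng, n=6):
        return ts.CoordinateFrame(rng.standard_normal((n, 3)))

    def test_identical_frames_give_zero(self, rng):
        f = self._frame(rng)
        assert ts.kabsch_rmsd(f, f) == pytest.approx(0.0, abs=1e-12)

    def test_invariance_under_rigid_motion(self, rng):
        f = self._frame(rng)
        rot = Rotation.random(random_state=3).as_matrix()
        moved = ts.CoordinateFrame(f.points @ rot.T + np.array([1.0, -2.0, 3.0]))
        assert ts.kabsch_rmsd(f, moved) == pytest.approx(0.0, abs=1e-10)

    def test_single_displaced_point_matches_reference_superposition(self, rng):
        base = rng.standard_normal((4, 3))
        displaced = base.copy()
        displaced[0] += np.array([1.0, 0.0, 0.0])
        ours = ts.kabsch_rmsd(ts.CoordinateFrame(base), ts.CoordinateFrame(displaced))
        # independent oracle: scipy's rotational alignment on centered sets
        p = base - base.mean(axis=0)
        q = displaced - displaced.mean(axis=0)
        _, rssd = Rotation.align_vectors(q, p)
        assert ours == pytest.approx(rssd / np.sqrt(4), abs=1e-6)

    def test_reflection_is_not_allowed(self, rng):
        f = self._frame(rng)
        mirrored = ts.CoordinateFrame(f.points * np.array([-1.0, 1.0, 1.0]))
        assert ts.kabsch_rmsd(f, mirrored) > 1e-6

    def test_mismatched_inputs_rejected(self, rng):
        a = self._frame(rng, 5)
        b = self._frame(rng, 6)
        with pytest.raises(ValueError, match="point counts"):
            ts.kabsch_rmsd(a, b)
        c = ts.CoordinateFrame(a.points, unit="angstrom")
        with pytest.raises(ValueError, match="unit"):
            ts.kabsch_rmsd(a, c)

    def test_collinear_points_rejected(self):
        with pytest.raises(ValueError, match="collinear"):
            ts.CoordinateFrame(np.outer(np.arange(4.0), [1.0, 0.0, 0.0]))


class TestWindowedStats:
    def test_constant_series_has_zero_sd(self):
        series = ScalarSeries(np.arange(10) * 2.0, np.full(10, 0.2))
        (w,) = ts.windowed_stats(series, [(0.0, 18.0)])
        assert w.mean == 0.2 and w.sd == 0.0 and w.n == 10

    def test_two_windows_reproduce_global_mean_as_weighted_average(self, rng):
        values = rng.standard_normal(50)
        series = ScalarSeries(np.arange(50) * 2.0, values)
        a, b = ts.windowed_stats(series, [(0.0, 40.0), (40.0, 98.0)])
        combined = (a.mean * a.n + b.mean * b.n) / (a.n + b.n)
        assert a.n + b.n == 50
        assert combined == pytest.approx(values.mean(), abs=1e-12)

    def test_empty_window_rejected(self):
        series = ScalarSeries(np.arange(10) * 2.0, np.zeros(10))
        with pytest.raises(ValueError, match="no frames"):
            ts.windowed_stats(series, [(100.0, 200.0)])
        with pytest.raises(ValueError, match="empty or reversed"):
            ts.windowed_stats(series, [(4.0, 4.0)])
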