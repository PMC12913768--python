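"""Trajectory-statistics tests: crossings, events, classification,
envelopes, scaling and group comparisons."""

import itertools

import numpy as np
import pytest

from imcoal.im_model import EpochedHistory, ScalingConfig, TimeGrid, cumulative_migration
from imcoal.im_fit import IMTrajectory
from imcoal.coalsim import scenario
from imcoal.traj_stats import (
    PeriodCatalog,
    adjust_bh,
    classify_pattern,
    compare_groups,
    envelope,
    generations_to_years,
    initial_divergence_times,
    isolation_events,
    isolation_frequency_histogram,
    scale_times,
    scaled_lambda_to_size,
    scaled_time_to_generations,
    split_time,
)


def make_traj(boundaries, m, N1=None, N2=None):
    grid = TimeGrid(np.asarray(boundaries, float))
    m = np.asarray(m, float)
    if N1 is None:
        N1 = np.full(m.size, 20_000.0)
    if N2 is None:
        N2 = np.asarray(N1, float).copy()
    M = cumulative_migration(m, grid)
    return IMTrajectory(grid=grid, m=m, M=M, im_N1=np.asarray(N1, float),
                        im_N2=np.asarray(N2, float))


def traj_from_history(history: EpochedHistory, grid: TimeGrid) -> IMTrajectory:
    """Ground-truth trajectory: history parameters read off at midpoints."""
    idx = history.epoch_index(grid.midpoints)
    m = history.m[idx]
    return IMTrajectory(grid=grid, m=m, M=cumulative_migration(m, grid),
                        im_N1=history.N1[idx], im_N2=history.N2[idx])


@pytest.fixture(scope="module")
def sc():
    return ScalingConfig()


class TestSplitTime:
    def test_log_interpolated_crossing(self, sc):
        # M = 0.4 at 30,000 gen and 0.6 at 40,000 gen -> ~34,641 gen
        grid = TimeGrid(np.array([30_000.0, 40_000.0]))
        traj = IMTrajectory(grid=grid, m=np.array([1e-5]),
                            M=np.array([0.4, 0.6]),
                            im_N1=np.array([1e4]), im_N2=np.array([1e4]))
        res = split_time(traj, sc)
        assert res.generations == pytest.approx(30_000 * (4 / 3) ** 0.5,
                                                rel=1e-6)
        assert res.years == pytest.approx(69_282, rel=1e-3)

    def test_never_merging_is_none(self, sc):
        traj = make_traj(np.geomspace(10, 1e5, 12), np.zeros(11))
        assert split_time(traj, sc) is None

    def test_constant_m_closed_form(self, sc):
        grid = TimeGrid(np.geomspace(10, 2e5, 60))
        traj = make_traj(grid.boundaries, np.full(grid.n_intervals, 1e-5))
        res = split_time(traj, sc)
        t_half = np.log(2) / 2e-5  # ~34,657 generations
        k = np.searchsorted(grid.boundaries, res.generations)
        assert grid.boundaries[k - 1] <= t_half <= grid.boundaries[k + 1]


class TestInitialDivergence:
    def test_resolution_limit_flag(self, sc):
        # M reaches 0.9995 only at the oldest boundary
        grid = TimeGrid(np.geomspace(100, 1e5, 10))
        M = np.linspace(0.5, 0.9995, 10)
        traj = IMTrajectory(grid=grid, m=np.full(9, 1e-5), M=M,
                            im_N1=np.full(9, 1e4), im_N2=np.full(9, 1e4))
        res = initial_divergence_times(traj, sc)
        assert res[0.999] is not None and res[0.999].at_resolution_limit
        assert res[0.99] is not None

    def test_capped_M_returns_none(self, sc):
        grid = TimeGrid(np.geomspace(100, 1e5, 10))
        M = np.linspace(0.1, 0.95, 10)
        traj = IMTrajectory(grid=grid, m=np.full(9, 1e-5), M=M,
                            im_N1=np.full(9, 1e4), im_N2=np.full(9, 1e4))
        res = initial_divergence_times(traj, sc)
        assert res[0.999] is None and res[0.99] is None

    def test_shutoff_history_crossing(self, sc):
        """Migration ends 175,000 generations ago: the 0.99 crossing sits
        within one grid interval of the shutoff."""
        hist = EpochedHistory(
            boundaries=np.array([0.0, 175_000.0]),
            N1=np.array([2e4, 2e4]), N2=np.array([2e4, 2e4]),
            m=np.array([1e-5, 1e-3]))
        grid = TimeGrid.log_spaced(50, 1000, 5e5)
        traj = traj_from_history(hist, grid)
        res = initial_divergence_times(traj, sc)
        t99 = res[0.99].generations
        k_true = np.searchsorted(grid.boundaries, 175_000.0)
        k_got = np.searchsorted(grid.boundaries, t99)
        assert abs(k_got - k_true) <= 1

    def test_ordering_invariant(self, sc):
        """split <= divergence(0.99) <= divergence(0.999) when defined."""
        rng = np.random.default_rng(0)
        for _ in range(20):
            grid = TimeGrid(np.geomspace(100, 5e5, 25))
            m = rng.choice([0.0, 1e-6, 1e-5, 1e-4], size=24)
            traj = make_traj(grid.boundaries, m)
            st = split_time(traj, sc)
            div = initial_divergence_times(traj, sc)
            values = [st] + [div[t] for t in (0.99, 0.999)]
            defined = [v.years for v in values if v is not None]
            assert defined == sorted(defined)


class TestIsolationEvents:
    def test_pgp_window_event(self, sc):
        b = np.array([1e3, 5e3, 65e3, 95e3, 2e5])  # generations
        traj = make_traj(b, np.array([1e-5, 1e-5, 1e-8, 1e-5]))
        events = isolation_events(traj, sc)
        assert len(events) == 1
        assert events[0].midpoint_years == pytest.approx(160_000.0)

    def test_no_events(self, sc):
        traj = make_traj(np.geomspace(10, 1e5, 10), np.full(9, 1e-5))
        assert isolation_events(traj, sc) == []

    def test_two_separated_runs_ordered(self, sc):
        b = np.geomspace(100, 1e5, 8)
        m = np.array([1e-5, 0.0, 1e-5, 1e-5, 1e-9, 1e-9, 1e-5])
        traj = make_traj(b, m)
        events = isolation_events(traj, sc)
        assert len(events) == 2
        assert events[0].midpoint_years < events[1].midpoint_years
        spans = sum(e.end_years - e.start_years for e in events)
        total = (b[-1] - b[0]) * sc.g
        assert spans <= total

    def test_events_disjoint(self, sc):
        rng = np.random.default_rng(8)
        for _ in range(20):
            b = np.geomspace(100, 1e6, 30)
            m = rng.choice([0.0, 1e-8, 1e-5], size=29)
            events = isolation_events(make_traj(b, m), sc)
            for a, c in zip(events[:-1], events[1:]):
                assert a.end_years <= c.start_years


class TestIsolationHistogram:
    def test_identical_trajectories(self, sc):
        b = np.array([1e3, 5e3, 65e3, 95e3, 2e5])
        traj = make_traj(b, np.array([1e-5, 1e-5, 1e-8, 1e-5]))
        counts, freqs, edges = isolation_frequency_histogram([traj] * 10, sc)
        k = np.searchsorted(edges, 160_000.0) - 1
        assert freqs[k] == 1.0
        assert freqs.sum() == 1.0

    def test_empty_collection_rejected(self, sc):
        with pytest.raises(ValueError):
            isolation_frequency_histogram([], sc)


class TestClassifyPattern:
    def test_core_preset(self, sc):
        grid = TimeGrid.log_spaced(40, 1000, 5e5)
        traj = traj_from_history(scenario("core").history, grid)
        assert classify_pattern(traj, sc).label == "CORE"

    def test_peripheral_pgp_preset(self, sc):
        grid = TimeGrid.log_spaced(40, 1000, 5e5)
        traj = traj_from_history(scenario("peripheral_pgp").history, grid)
        assert classify_pattern(traj, sc).label == "PERIPHERAL_STRONG_PGP"

    def test_peripheral_mis8_preset(self, sc):
        grid = TimeGrid.log_spaced(60, 1000, 5e5)
        traj = traj_from_history(scenario("peripheral_mis8").history, grid)
        assert classify_pattern(traj, sc).label == "PERIPHERAL_STRONG_MIS8"

    def test_flat_fifteen_thousand_unclassified(self, sc):
        grid = TimeGrid.log_spaced(40, 1000, 5e5)
        traj = make_traj(grid.boundaries, np.full(39, 1e-5),
                         N1=np.full(39, 15_000.0))
        assert classify_pattern(traj, sc).label == "UNCLASSIFIED"

    def test_insufficient_span_rejected(self, sc):
        traj = make_traj(np.geomspace(1e3, 5e4, 12), np.full(11, 1e-5))
        with pytest.raises(ValueError):
            classify_pattern(traj, sc)

    def test_grid_refinement_invariance(self, sc):
        """The label does not change when the same step functions are
        sampled on a finer grid."""
        hist = scenario("peripheral_pgp").history
        for nb in (40, 80, 160):
            grid = TimeGrid.log_spaced(nb, 1000, 5e5)
            traj = traj_from_history(hist, grid)
            assert classify_pattern(traj, sc).label == "PERIPHERAL_STRONG_PGP"


class TestEnvelope:
    def _const_traj(self, n_value):
        grid = TimeGrid(np.geomspace(100, 1e5, 30))
        return make_traj(grid.boundaries, np.full(29, 1e-5),
                         N1=np.full(29, float(n_value)))

    def test_identical_trajectories_collapse(self):
        trajs = [self._const_traj(2e4) for _ in range(3)]
        env = envelope(trajs)
        assert np.allclose(env.ne_median, 2e4, rtol=1e-9)
        for lo_band, hi_band in env.ne_bands.values():
            assert np.allclose(lo_band, env.ne_median)
            assert np.allclose(hi_band, env.ne_median)

    def test_constant_levels_quantiles(self):
        trajs = [self._const_traj(k * 1e3) for k in (1, 2, 3, 4, 5)]
        env = envelope(trajs)
        assert np.allclose(env.ne_median, 3e3, rtol=1e-9)
        lo, hi = env.ne_bands["inner"]
        # linear-interpolation quantile convention at 12.5/87.5%
        assert np.allclose(lo, np.percentile([1e3, 2e3, 3e3, 4e3, 5e3], 12.5))
        assert np.allclose(hi, np.percentile([1e3, 2e3, 3e3, 4e3, 5e3], 87.5))

    def test_nesting_property(self):
        rng = np.random.default_rng(12)
        grid = TimeGrid(np.geomspace(100, 1e5, 30))
        trajs = [make_traj(grid.boundaries,
                           rng.uniform(1e-8, 1e-4, 29),
                           N1=rng.uniform(1e3, 1e5, 29))
                 for _ in range(9)]
        env = envelope(trajs, n_points=80)
        assert env.times.size == 80
        for quantity in ("m", "ne"):
            med = getattr(env, f"{quantity}_median")
            inner = getattr(env, f"{quantity}_bands")["inner"]
            outer = getattr(env, f"{quantity}_bands")["outer"]
            assert np.all(outer[0] <= inner[0] + 1e-12)
            assert np.all(inner[0] <= med + 1e-12)
            assert np.all(med <= inner[1] + 1e-12)
            assert np.all(inner[1] <= outer[1] + 1e-12)

    def test_single_trajectory_rejected(self):
        with pytest.raises(ValueError):
            envelope([self._const_traj(1e4)])


class TestScaling:
    def test_scaled_time_chain(self, sc):
        gens = scaled_time_to_generations(7.1e-5, sc)
        assert gens == pytest.approx(10_000.0)
        assert generations_to_years(gens, sc) == pytest.approx(20_000.0)
        assert scale_times(7.1e-5, sc, units="scaled") == pytest.approx(20_000.0)

    def test_west_east_median_split_figure(self, sc):
        # 4,900 generations at a 2-year generation time -> 9.8 ka
        assert scale_times(4_900.0, sc) == pytest.approx(9_800.0)

    def test_scaled_lambda_to_size(self, sc):
        lam = 1.0 / 2.84e-4
        assert scaled_lambda_to_size(lam, sc) == pytest.approx(20_000.0,
                                                               rel=1e-6)


class TestCompareGroups:
    def test_identical_groups_p_one(self):
        a = np.arange(1.0, 9.0)
        res = compare_groups(a, a.copy(), mode="wilcoxon")
        assert res.p_value == pytest.approx(1.0, abs=0.05)
        assert adjust_bh([res.p_value])[0] == pytest.approx(1.0, abs=0.05)

    def test_extreme_separation_exact_enumeration(self):
        """Fully separated groups: p equals the exact permutation value."""
        a = np.arange(1.0, 11.0)
        b = np.arange(101.0, 111.0)
        res = compare_groups(a, b, mode="wilcoxon")
        assert res.statistic in (0.0, 100.0)  # U at its extreme
        # oracle: enumerate all C(20,10) group assignments of the pooled
        # ranks and count those with a rank-sum at least as extreme
        pooled = np.concatenate([a, b])
        ranks = pooled.argsort().argsort() + 1
        obs = ranks[:10].sum()
        lo_sum = min(obs, 210 - obs)
        count = total = 0
        for combo in itertools.combinations(range(20), 10):
            s = ranks[list(combo)].sum()
            total += 1
            if s <= lo_sum or s >= 210 - lo_sum:
                count += 1
        assert res.p_value == pytest.approx(count / total, rel=1e-9)

    def test_shapiro_gate_selects_test(self):
        rng = np.random.default_rng(3)
        normal_a = rng.normal(0, 1, 40)
        normal_b = rng.normal(0.2, 1, 40)
        res = compare_groups(normal_a, normal_b)
        assert res.test == "t"
        skew_a = rng.lognormal(0, 2, 40)
        skew_b = rng.lognormal(0.2, 2, 40)
        res2 = compare_groups(skew_a, skew_b)
        assert res2.test == "wilcoxon"

    def test_bh_keeps_large_effect(self):
        """One true effect among many nulls survives BH at q = 0.05."""
        rng = np.random.default_rng(19)
        pvals = []
        for i in range(20):
            a = rng.normal(0, 1, 200)
            shift = 1.0 if i == 0 else 0.0
            b = rng.normal(shift, 1, 200)
            pvals.append(compare_groups(a, b, mode="wilcoxon").p_value)
        q = adjust_bh(pvals)
        assert q[0] < 0.05
        assert (q[1:] < 0.05).sum() <= 2  # false positives stay rare

    def test_too_small_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1.0, 2.0], [3.0, 4.0, 5.0])


class TestPeriodCatalog:
    def test_defaults(self):
        cat = PeriodCatalog()
        assert cat["LGM"] == (17_000.0, 22_000.0)
        assert cat["PGP"] == (130_000.0, 190_000.0)
        assert cat.classification_window == (17_000.0, 374_000.0)

    def test_invalid_interval(self):
        with pytest.raises(ValueError):
            PeriodCatalog({"X": (10.0, 5.0)})
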