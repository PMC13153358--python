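"""Permeation counting, occupancy and their invariants."""

import numpy as np
import pandas as pd
import pytest

from amparcore import (
    GateSlab,
    PermeationTracker,
    build_gate_slab,
    count_permeations,
    cumulative_average,
    make_water_trajectory,
    water_occupancy,
)


def static_slab(n_frames, lo=0.0, hi=10.0):
    return GateSlab(np.full(n_frames, lo), np.full(n_frames, hi))


def count_z(z, lo=0.0, hi=10.0, dt_ns=0.1, **kw):
    return count_permeations(z, static_slab(z.shape[0], lo, hi), dt_ns=dt_ns, **kw)


class TestGateSlab:
    def test_static_tetrads(self, default_map):
        fx = make_water_trajectory(4, 20, [], slab=(0.0, 10.0), seed=0)
        slab = build_gate_slab(fx.trajectory, default_map)
        np.testing.assert_allclose(slab.lower, 0.0)
        np.testing.assert_allclose(slab.upper, 10.0)

    def test_drifting_tetrads_tracked_exactly(self, default_map):
        fx = make_water_trajectory(2, 15, [], slab=(0.0, 10.0), seed=0)
        stack = fx.trajectory.stack
        drift = np.arange(15)[:, None] * 1.0
        gate = np.isin(stack.res_name, ["THR"])
        coords = stack.coord.copy()
        coords[:, gate, 2] += drift
        from amparcore import Trajectory
        import biotite.structure as struc

        drifted = Trajectory(
            struc.from_template(stack[0], coords), dt_ns=0.1
        )
        slab = build_gate_slab(drifted, default_map)
        np.testing.assert_allclose(slab.lower, drift[:, 0])
        np.testing.assert_allclose(slab.upper, 10.0 + drift[:, 0])

    def test_reversed_labels_swap_with_warning(self, default_map):
        fx = make_water_trajectory(2, 10, [], slab=(0.0, 10.0), seed=0)
        with pytest.warns(UserWarning, match="reversed order"):
            slab = build_gate_slab(
                fx.trajectory, default_map, lower_label="T625", upper_label="T617"
            )
        np.testing.assert_allclose(slab.lower, 0.0)
        np.testing.assert_allclose(slab.upper, 10.0)

    def test_lower_must_be_below_upper(self):
        with pytest.raises(ValueError, match="lower gate plane"):
            GateSlab(np.array([5.0]), np.array([1.0]))


class TestCounting:
    def test_static_outside_waters_give_zero(self):
        z = np.tile([-5.0, 15.0, -3.0], (30, 1))
        assert count_z(z).n_events == 0

    def test_single_down_crossing(self):
        z = np.linspace(15.0, -5.0, 21)[:, None]
        res = count_z(z)
        assert res.n_events == 1
        assert res.events.iloc[0]["direction"] == "down"
        assert res.rate == pytest.approx(1 / (21 * 0.1))

    def test_entry_then_retreat_cancels(self):
        z = np.array([-5.0, 5.0, -5.0])[:, None]
        assert count_z(z).n_events == 0

    def test_jump_straight_across_counts(self):
        z = np.array([-5.0, 15.0])[:, None]
        res = count_z(z)
        assert res.n_events == 1
        assert res.events.iloc[0]["direction"] == "up"

    def test_periodic_wrap_not_a_crossing(self):
        # water sits above the slab and wraps across the box boundary
        z = np.array([20.0, 22.0, -18.0, -16.0])[:, None]
        assert count_z(z, box_z=40.0).n_events == 0

    def test_dwell_inside_any_length(self):
        z = np.concatenate([[-5.0], np.full(50, 5.0), [15.0]])[:, None]
        res = count_z(z)
        assert res.n_events == 1
        # entry_frame = first frame inside, exit_frame = first frame beyond
        assert res.events.iloc[0]["entry_frame"] == 1
        assert res.events.iloc[0]["exit_frame"] == 51

    def test_requires_dt(self):
        with pytest.raises(ValueError, match="dt_ns"):
            count_permeations(np.zeros((5, 1)), static_slab(5))

    def test_trajectory_object_input(self):
        fx = make_water_trajectory(10, 50, [(0, 5, "down"), (3, 20, "up")], seed=2)
        slab = static_slab(50, *fx.slab)
        res = count_permeations(fx.trajectory, slab)
        assert res.n_events == 2
        assert res.total_ns == pytest.approx(50 * fx.dt_ns)


def random_script(rng, n_waters, n_frames, n_events, transit=8):
    starts = rng.choice(np.arange(0, n_frames - transit - 1), size=n_events, replace=False)
    waters = rng.choice(n_waters, size=n_events, replace=False)
    dirs = rng.choice(["up", "down"], size=n_events)
    return [(int(w), int(s), str(d)) for w, s, d in zip(waters, starts, dirs)]


class TestGroundTruthAgreement:
    @pytest.mark.parametrize("seed", range(20))
    def test_counts_equal_fixture_ground_truth(self, seed):
        rng = np.random.default_rng(seed)
        n_events = int(rng.integers(0, 7))
        script = random_script(rng, n_waters=30, n_frames=80, n_events=n_events)
        fx = make_water_trajectory(
            30, 80, script, seed=seed + 1000, transit_frames=8
        )
        res = count_z(fx.z, *fx.slab)
        assert res.n_events == len(fx.events)
        got = res.events.sort_values(["water_id"]).reset_index(drop=True)
        want = fx.events.sort_values(["water_id"]).reset_index(drop=True)
        pd.testing.assert_series_equal(got["water_id"], want["water_id"])
        pd.testing.assert_series_equal(got["direction"], want["direction"])


class TestInvariants:
    def test_frame_reversal_preserves_count_and_flips_direction(self):
        fx = make_water_trajectory(
            25, 70, [(0, 5, "down"), (1, 10, "up"), (2, 40, "down")], seed=5
        )
        fwd = count_z(fx.z, *fx.slab)
        rev = count_z(fx.z[::-1], *fx.slab)
        assert fwd.n_events == rev.n_events
        assert sorted(fwd.events["direction"]) == sorted(
            {"up": "down", "down": "up"}[d] for d in rev.events["direction"]
        )

    def test_chunked_tracking_equals_single_pass(self):
        fx = make_water_trajectory(
            20, 90, [(0, 5, "down"), (1, 30, "up"), (2, 60, "down")], seed=6
        )
        single = count_z(fx.z, *fx.slab)
        tracker = PermeationTracker(fx.z.shape[1])
        lo, hi = fx.slab
        for chunk in np.array_split(fx.z, 5, axis=0):
            for frame in chunk:
                tracker.update(frame, lo, hi)
        assert len(tracker.events) == single.n_events
        chunked = tracker.events_frame().sort_values("water_id").reset_index(drop=True)
        pd.testing.assert_frame_equal(
            chunked, single.events.sort_values("water_id").reset_index(drop=True)
        )

    def test_occupancy_covers_event_transits(self):
        fx = make_water_trajectory(10, 60, [(0, 10, "down"), (1, 30, "up")], seed=7)
        res = count_z(fx.z, *fx.slab)
        transit_frames = sum(
            ev["exit_frame"] - ev["entry_frame"] for _, ev in res.events.iterrows()
        )
        assert res.occupancy.sum() >= transit_frames


class TestRatesAndOccupancy:
    def test_cumulative_average_prefix_sum_oracle(self):
        rng = np.random.default_rng(8)
        rates = rng.exponential(2.0, size=25)
        got = cumulative_average(rates)
        oracle = np.array(
            [rates[: k + 1].sum() / (k + 1) for k in range(rates.size)]
        )
        np.testing.assert_allclose(got, oracle, rtol=1e-12)

    def test_cumulative_average_trivial_cases(self):
        np.testing.assert_allclose(cumulative_average([3.0, 3.0, 3.0]), 3.0)
        np.testing.assert_allclose(cumulative_average([0.0, 2.0]), [0.0, 1.0])
        with pytest.raises(ValueError, match="empty"):
            cumulative_average([])

    def test_per_window_rates_sum_to_total(self):
        fx = make_water_trajectory(
            20, 100, [(0, 5, "down"), (1, 40, "up"), (2, 70, "down")], seed=9
        )
        res = count_z(fx.z, *fx.slab, window_ns=2.0)
        frames_per = int(round(2.0 / 0.1))
        total_from_windows = np.sum(res.per_window_rates * frames_per * 0.1)
        assert total_from_windows == pytest.approx(res.n_events)
        np.testing.assert_allclose(
            res.cumulative_avg, cumulative_average(res.per_window_rates)
        )

    def test_parked_waters_occupancy(self):
        z = np.tile([5.0, 5.0, 5.0, -7.0], (12, 1))
        df = water_occupancy(z, static_slab(12))
        np.testing.assert_array_equal(df["slab"], 3)

    def test_transit_occupancy_window(self):
        fx = make_water_trajectory(1, 40, [(0, 10, "down")], seed=3, transit_frames=10)
        df = water_occupancy(fx.z, static_slab(40, *fx.slab))
        inside = np.flatnonzero(df["slab"].to_numpy() > 0)
        assert inside.min() >= 10 and inside.max() <= 20

    def test_empty_water_selection(self):
        df = water_occupancy(np.empty((10, 0)), static_slab(10))
        np.testing.assert_array_equal(df["slab"], 0)

    def test_per_level_counts(self):
        z = np.tile([0.5, 4.0, 9.9], (6, 1))
        df = water_occupancy(
            z, static_slab(6), per_level={"T617": np.zeros(6), "T625": np.full(6, 10.0)}
        )
        np.testing.assert_array_equal(df["T617"], 1)
        np.testing.assert_array_equal(df["T625"], 1)
        np.testing.assert_array_equal(df["slab"], 3)
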