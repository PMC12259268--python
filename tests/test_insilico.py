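"""Unit and property tests for the contact-dynamics simulator."""

import numpy as np
import pytest

from graftquant import insilico as ins


def make_config(**kw):
    base = dict(
        n_cells=50,
        speed_range=(1.0, 3.0),
        contact_duration={"red": 10, "blue": 10},
        n_ticks=50,
        snapshot_ticks=(25, 50),
        seeds=(1, 2, 3),
    )
    base.update(kw)
    return ins.SimulationConfig(**base)


class TestLayout:
    def test_requested_areas_realized(self):
        layout = ins.make_layout((200, 200), 900, 400, seed=0)
        assert layout.areas["red"] == pytest.approx(900)
        assert layout.areas["blue"] == pytest.approx(400)

    def test_deterministic_in_seed(self):
        a = ins.make_layout((200, 200), 900, 400, seed=5)
        b = ins.make_layout((200, 200), 900, 400, seed=5)
        assert a == b

    def test_different_seed_moves_compartments(self):
        a = ins.make_layout((200, 200), 900, 400, seed=5)
        b = ins.make_layout((200, 200), 900, 400, seed=6)
        assert a != b

    def test_oversized_areas_raise(self):
        with pytest.raises(ins.PlacementError):
            ins.make_layout((10, 10), 60, 60, seed=0)

    def test_compartments_disjoint_and_inside(self):
        for seed in range(10):
            layout = ins.make_layout((100, 100), 1500, 1500, seed=seed)
            a, b = layout.compartments
            assert not ins._rects_overlap(a, b)

    def test_overlapping_layout_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            ins.CompartmentLayout(
                100,
                100,
                (ins.Rect("red", 10, 10, 20, 20), ins.Rect("blue", 15, 15, 20, 20)),
            )


class TestStep:
    def test_stationary_cell_frozen_exactly_duration_ticks(self, small_layout):
        """A cell sitting inside red freezes for exactly 5 ticks, then moves."""
        config = make_config(
            n_cells=1, speed_range=(0.0, 0.0), contact_duration={"red": 5, "blue": 5}
        )
        state = ins.SimulationState(
            x=np.array([20.0]),
            y=np.array([20.0]),
            heading=np.array([0.0]),
            speed=np.array([0.0]),
            frozen_in=np.array([-1]),
            freeze_left=np.array([0]),
        )
        rng = np.random.default_rng(0)
        frozen_history = []
        for _ in range(8):
            ins.step(state, small_layout, config, rng)
            frozen_history.append(int(state.frozen_in[0] >= 0))
        # freezes on the entry tick, stays frozen 5 ticks total, then free
        assert frozen_history == [1, 1, 1, 1, 1, 0, 0, 0]

    def test_zero_duration_never_freezes(self, small_layout):
        config = make_config(contact_duration={"red": 0, "blue": 0})
        rng = np.random.default_rng(1)
        state = ins.init_state(config, small_layout, rng)
        for _ in range(50):
            ins.step(state, small_layout, config, rng)
            assert (state.frozen_in == -1).all()

    def test_cell_count_conserved_and_in_bounds(self, small_layout):
        config = make_config(n_cells=40)
        rng = np.random.default_rng(2)
        state = ins.init_state(config, small_layout, rng)
        for _ in range(100):
            ins.step(state, small_layout, config, rng)
            assert state.n_cells == 40
            assert (state.x >= 0).all() and (state.x <= 100).all()
            assert (state.y >= 0).all() and (state.y <= 100).all()

    def test_released_cell_placed_outside_compartment(self, small_layout):
        config = make_config(
            n_cells=1, speed_range=(0.0, 0.0), contact_duration={"red": 2, "blue": 2}
        )
        state = ins.SimulationState(
            x=np.array([20.0]),
            y=np.array([20.0]),
            heading=np.array([0.0]),
            speed=np.array([0.0]),
            frozen_in=np.array([-1]),
            freeze_left=np.array([0]),
        )
        rng = np.random.default_rng(3)
        for _ in range(3):
            ins.step(state, small_layout, config, rng)
        red = small_layout.compartments[0]
        assert not red.contains(state.x, state.y)[0]


class TestRunSimulation:
    def test_no_cells_no_density(self, small_layout):
        records = ins.run_simulation(make_config(n_cells=0), small_layout)
        assert all(r.densities["red"] == 0 and r.densities["blue"] == 0 for r in records)

    def test_deterministic(self, small_layout):
        config = make_config()
        a = ins.run_simulation(config, small_layout)
        b = ins.run_simulation(config, small_layout)
        assert a == b

    def test_one_record_per_snapshot_per_seed(self, small_layout):
        records = ins.run_simulation(make_config(), small_layout)
        assert len(records) == 2 * 3
        assert {(r.seed, r.tick) for r in records} == {
            (s, t) for s in (1, 2, 3) for t in (25, 50)
        }

    def test_empty_snapshots_rejected(self, small_layout):
        with pytest.raises(ValueError):
            ins.run_simulation(make_config(snapshot_ticks=()), small_layout)

    def test_physical_area_scaling(self):
        # 8 um cell diameter: 2 sim units -> 1 unit = 4 um
        assert ins.physical_area_mm2(1.0, 2.0) == pytest.approx((4e-3) ** 2)
        # at cell_diameter_sim = 8, sim units are micrometres
        assert ins.physical_area_mm2(1e6, 8.0) == pytest.approx(1.0)

    def test_frozen_occupancy_scales_with_duration(self):
        """Renewal argument: at equal encounter rates, frozen occupancy is
        proportional to the freeze duration."""
        layout = ins.make_layout(ins.CANVAS, 8000, 8000, seed=11)
        config = ins.SimulationConfig(
            n_cells=400,
            speed_range=ins.SPEED_RANGE,
            contact_duration={"red": 40, "blue": 20},
            n_ticks=300,
            snapshot_ticks=(200, 250, 300),
            seeds=(4, 5, 6),
        )
        records = ins.run_simulation(config, layout)
        red = np.mean([r.counts["red"] for r in records])
        blue = np.mean([r.counts["blue"] for r in records])
        assert red / blue > 1.5  # expected ~2 at equal encounter rates


class TestCompareConditions:
    def test_needs_two_conditions(self, small_layout):
        records = ins.run_simulation(make_config(), small_layout)
        with pytest.raises(ValueError):
            ins.compare_conditions({"only": records})

    def test_identical_conditions_flagged_degenerate(self, small_layout):
        records = ins.run_simulation(make_config(), small_layout)
        res = ins.compare_conditions({"a": records, "b": records})
        assert res["degenerate"]
        assert res["mean_diff"]["a"] == res["mean_diff"]["b"]

    def test_duration_asymmetry_dominates_other_variables(self):
        """Only contact-duration asymmetry shifts the area-normalized
        density difference; cell number and compartment area do not."""
        dur = ins.reference_experiment("duration", master_seed=100)
        area = ins.reference_experiment("area", master_seed=100)
        effect = lambda res: max(abs(v) for v in res["mean_diff"].values())
        assert effect(dur) > effect(area)
        assert dur["anova_p"] < 0.05


class TestInvariants:
    def test_symmetry_two_sided(self):
        """Equal areas and durations: red and blue densities statistically
        indistinguishable over 20 seeds (alpha = 0.01)."""
        from scipy import stats

        layout = ins.make_layout(ins.CANVAS, 8000, 8000, seed=21)
        diffs = []
        for seed in range(20):
            config = ins.SimulationConfig(
                n_cells=300,
                speed_range=ins.SPEED_RANGE,
                contact_duration={"red": 30, "blue": 30},
                n_ticks=250,
                snapshot_ticks=(250,),
                seeds=(seed * 3 + 1, seed * 3 + 2, seed * 3 + 3),
            )
            for r in ins.run_simulation(config, layout):
                diffs.append(r.densities["red"] - r.densities["blue"])
        _, p = stats.ttest_1samp(diffs, 0.0)
        assert p > 0.01

    def test_normalization_invariance_under_system_rescale(self):
        """Density in cells/mm^2 is intensive: scaling the whole system
        (canvas and compartment areas, cell count, speeds) by a common
        factor leaves the expected physical density unchanged within
        Monte-Carlo error."""

        def mean_density(k, seeds):
            side = 400.0 * np.sqrt(k)
            layout = ins.make_layout((side, side), 6000 * k, 6000 * k, seed=31)
            lo, hi = ins.SPEED_RANGE
            config = ins.SimulationConfig(
                n_cells=int(500 * k),
                speed_range=(lo * np.sqrt(k), hi * np.sqrt(k)),
                contact_duration={"red": 30, "blue": 30},
                n_ticks=300,
                snapshot_ticks=(200, 250, 300),
                seeds=seeds,
            )
            records = ins.run_simulation(config, layout)
            return np.mean(
                [r.densities["red"] + r.densities["blue"] for r in records]
            )

        base = mean_density(1, (7, 8, 9))
        scaled = mean_density(2, (10, 11, 12))
        assert scaled == pytest.approx(base, rel=0.10)

    def test_duration_monotonicity(self):
        layout = ins.make_layout(ins.CANVAS, 8000, 8000, seed=41)
        occupancies = []
        for dur in (10, 30, 90):
            config = ins.SimulationConfig(
                n_cells=400,
                speed_range=ins.SPEED_RANGE,
                contact_duration={"red": dur, "blue": 30},
                n_ticks=300,
                snapshot_ticks=(250, 300),
                seeds=(13, 14, 15),
            )
            records = ins.run_simulation(config, layout)
            occupancies.append(np.mean([r.densities["red"] for r in records]))
        assert occupancies[0] < occupancies[1] < occupancies[2]
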