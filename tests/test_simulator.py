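import numpy as np
import pandas as pd
import pytest

from mtalign.geometry import build_cell_domain
from mtalign.simulator import (
    SimParams,
    SimState,
    collision_angle_summary,
    detect_convergence,
    dimensionalize,
    gillespie_step,
    resolve_collision,
    run_simulation,
    sweep_eccentricity,
)


class TestDimensionalize:
    def test_reference_rates(self):
        d = dimensionalize(SimParams())
        assert round(d.R, 5) == 0.01829
        assert d.alpha_dim == pytest.approx(18.29, abs=0.005)
        assert d.beta_dim == pytest.approx(64.02, abs=0.02)
        assert d.alpha_prime_dim == pytest.approx(0.07316, abs=5e-6)
        assert d.beta_prime_dim == pytest.approx(0.01829, abs=5e-6)

    def test_time_conversion(self):
        d = dimensionalize(SimParams())
        t10 = float(d.seconds(10.0))
        # 550 s at two significant figures
        assert round(t10, -1) == 550

    def test_r_scales_with_growth_speed(self):
        d = dimensionalize(SimParams(), growth_speed_um_s=0.30)
        assert d.R_exact == pytest.approx(2 * 0.15e3 / (1000 * 8.2) , rel=1e-12)
        with pytest.raises(ValueError):
            dimensionalize(SimParams(), growth_speed_um_s=0.0)


class TestResolveCollision:
    def test_steep_boundary_always_catastrophe(self):
        for u in (0.0, 0.5, 0.999):
            assert resolve_collision(45, "boundary", "angle_dependent", u) == "catastrophe"

    def test_shallow_law_point_value(self):
        # P(cat) = 15/30 * 0.01 = 0.005 at 15 degrees
        assert resolve_collision(15, "microtubule", "angle_dependent", 0.0049) == "catastrophe"
        assert resolve_collision(15, "microtubule", "angle_dependent", 0.0051) == "zip"

    def test_threshold_angle_goes_to_steep_branch(self):
        assert resolve_collision(30, "boundary", "angle_dependent", 0.99) == "catastrophe"
        assert resolve_collision(30, "microtubule", "angle_dependent", 0.5) == "cross"

    @pytest.mark.parametrize(
        "rule, target, expected",
        [
            ("stabilize_no_cross", "microtubule", "catastrophe"),
            ("stabilize_no_cross", "boundary", "stabilize"),
            ("cross_stabilize", "microtubule", "cross"),
            ("cross_stabilize", "boundary", "stabilize"),
            ("cross_boundary_cat", "microtubule", "cross"),
            ("cross_boundary_cat", "boundary", "catastrophe"),
        ],
    )
    def test_simple_rule_sets(self, rule, target, expected):
        assert resolve_collision(50, target, rule, 0.5) == expected

    def test_monte_carlo_matches_law(self, rng):
        n = 100_000
        for angle in (5.0, 15.0, 25.0, 45.0, 75.0):
            u = rng.uniform(size=n)
            out = np.array([
                resolve_collision(angle, "microtubule", "angle_dependent", ui) for ui in u[:20_000]
            ])
            n_eff = len(out)
            if angle < 30:
                p_cat = angle / 30 * 0.01
                cat = np.mean(out == "catastrophe")
                se = np.sqrt(p_cat * (1 - p_cat) / n_eff)
                assert abs(cat - p_cat) <= 3 * se + 1e-12
                assert np.mean(out == "zip") == pytest.approx(1 - p_cat, abs=3 * se + 1e-12)
            else:
                cat = np.mean(out == "catastrophe")
                se = np.sqrt(0.01 * 0.99 / n_eff)
                assert abs(cat - 0.01) <= 3 * se
                assert np.mean(out == "cross") == pytest.approx(0.99, abs=3 * se)

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            resolve_collision(0.0, "boundary", "angle_dependent", 0.5)
        with pytest.raises(ValueError):
            resolve_collision(91.0, "boundary", "angle_dependent", 0.5)


class TestGillespie:
    def test_single_mt_dwell_time(self):
        dom = build_cell_domain(10_000, 0.0)  # large: no collisions early
        sim = SimState(dom, SimParams(n_seeds=1, rng_seed=3))
        dts = []
        for _ in range(4000):
            if sim.state[0] == 0:  # growing
                dts.append(gillespie_step(sim, 1))
            else:
                gillespie_step(sim, 1)
        mean = np.mean(dts)
        expect = 1.0 / (1000 + 1)
        se = expect / np.sqrt(len(dts))
        assert abs(mean - expect) <= 4 * se

    def test_growth_fraction_unconfined(self):
        dom = build_cell_domain(100_000, 0.0)
        sim = SimState(dom, SimParams(n_seeds=1, rng_seed=5))
        grow_events = 0
        grow_state_events = 0
        for _ in range(30_000):
            pre_state = sim.state[0]
            pre_n = sim.ndim[0]
            gillespie_step(sim, 1)
            if pre_state == 0:
                grow_state_events += 1
                if sim.ndim[0] == pre_n + 1:
                    grow_events += 1
        p = 1000 / 1001
        se = np.sqrt(p * (1 - p) / grow_state_events)
        assert abs(grow_events / grow_state_events - p) <= 3 * se

    def test_instant_renucleation_redraws_angle(self):
        dom = build_cell_domain(492, 0.5)
        sim = SimState(dom, SimParams(n_seeds=1, rng_seed=11, renucleation="instant"))
        first_dir = (sim.dirx[0], sim.diry[0])
        seen_new_dir = False
        for _ in range(50_000):
            gillespie_step(sim, 1)
            if sim.ndim[0] == 0 and (sim.dirx[0], sim.diry[0]) != first_dir:
                seen_new_dir = True
                break
        assert seen_new_dir
        assert sim.state[0] in (0, 1)  # never parks in the waiting state

    def test_rescue_wait_parks_at_zero(self):
        dom = build_cell_domain(492, 0.5)
        sim = SimState(dom, SimParams(n_seeds=1, rng_seed=11, renucleation="rescue_wait"))
        waited = False
        for _ in range(50_000):
            gillespie_step(sim, 1)
            if sim.state[0] == 4:
                assert sim.ndim[0] == 0
                waited = True
                break
        assert waited


class TestRunSimulation:
    def test_zero_duration(self):
        dom = build_cell_domain(492, 0.8)
        res = run_simulation(dom, SimParams(t_end=0.0, avg_window=0.0, n_seeds=10))
        assert res.mtsd == 90.0
        assert len(res.times) == 0

    def test_determinism(self):
        dom = build_cell_domain(492, 0.8)
        p = SimParams(n_seeds=30, t_end=1.5, rng_seed=99)
        a = run_simulation(dom, p)
        b = run_simulation(dom, p)
        pd.testing.assert_frame_equal(a.events, b.events)
        assert np.array_equal(a.histograms, b.histograms)

    def test_lengths_never_negative_and_inside(self, reference_run):
        res = reference_run
        for pts in res.polylines:
            seg = np.diff(pts, axis=0)
            assert (np.hypot(seg[:, 0], seg[:, 1]) >= 0).all()
        pts = np.vstack(res.polylines)
        assert res.domain.contains(pts).all()

    def test_histogram_mass_is_total_polymer(self, reference_run):
        res = reference_run
        total = sum(np.hypot(*np.diff(p, axis=0).T).sum() for p in res.polylines)
        assert res.histograms[-1].sum() == pytest.approx(total, rel=1e-9)

    def test_event_angles_in_range(self, small_run):
        ev = small_run.events
        assert len(ev) > 0
        assert ((ev.angle_deg > 0) & (ev.angle_deg <= 90)).all()
        assert set(ev.target.unique()) <= {"boundary", "microtubule"}

    def test_no_cross_rule_has_no_interior_intersections(self):
        from shapely.geometry import LineString

        dom = build_cell_domain(492, 0.8)
        res = run_simulation(dom, SimParams(
            n_seeds=30, t_end=2.0, rng_seed=13, rule_set="stabilize_no_cross"))
        lines = [LineString(p) for p in res.polylines if len(p) > 1 and np.ptp(p) > 0]
        crossings = 0
        for i in range(len(lines)):
            for j in range(i + 1, len(lines)):
                if lines[i].crosses(lines[j]):
                    crossings += 1
        assert crossings == 0


class TestConvergence:
    def test_constant_series(self):
        t = np.linspace(1, 100, 200)
        assert detect_convergence(t, np.full(200, 40.0), window_s=20) == 0.0

    def test_step_series(self):
        t = np.linspace(1, 100, 400)
        y = np.where(t < 37.0, 90.0, 40.0)
        got = detect_convergence(t, y, window_s=20)
        assert got == pytest.approx(t[t >= 37.0][0], abs=1e-9)

    def test_never_converges(self):
        t = np.linspace(1, 100, 300)
        y = 40 + 30 * np.sin(t)  # oscillates beyond any 10% band forever
        assert np.isnan(detect_convergence(t, y, window_s=20))


class TestSweepAndSummary:
    def test_sweep_shape_and_sem(self):
        res = sweep_eccentricity([492], [0.8, 0.9], SimParams(n_seeds=40, t_end=2.0, rng_seed=1),
                                 runs_per_point=3)
        assert len(res.runs) == 6
        assert res.comparison is None
        row = res.summary.iloc[0]
        sub = res.runs[(res.runs.width_nm == row.width_nm) & (res.runs.eccentricity == row.eccentricity)]
        assert row["sem"] == pytest.approx(sub.mtsd_deg.std(ddof=1) / np.sqrt(3))

    def test_collision_summary_properties(self, reference_run):
        summary = collision_angle_summary(reference_run.events)
        assert not summary.empty
        freq_sums = summary.groupby(["target", "category"], observed=True)["frequency"].sum()
        assert np.allclose(freq_sums, 1.0)
        # boundary collisions steeper than the critical angle always fail
        steep = summary[(summary.target == "boundary") & (summary.category == "61-90")]
        cat = steep[steep.outcome == "catastrophe"]["frequency"]
        assert len(cat) == 1 and cat.iloc[0] == pytest.approx(1.0)

    def test_empty_events(self):
        assert collision_angle_summary(pd.DataFrame(columns=["angle_deg", "target", "outcome"])).empty
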