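"""Runge-Kutta integration, crossing detection, and trace termination rules."""

import numpy as np
import pytest

from lvflow.field_model import OutOfDomainError
from lvflow.geometry import PlaneGeometry, build_lv_model, static_valve_plane
from lvflow.tracing import (
    TERMINATION_KINDS,
    TraceConfig,
    detect_plane_crossing,
    rk4_step,
    trace_all,
    trace_particle,
)

from conftest import exponential_field, rotation_field, uniform_field


def integrate(field, p0, h, n, t0=0.0):
    p = np.asarray(p0, float)
    t = t0
    for _ in range(n):
        p = rk4_step(field, p, t, h)
        t += h
    return p


class TestRK4:
    def test_zero_field_stationary(self):
        f = uniform_field()
        p = rk4_step(f, np.array([3.0, 3.0, 3.0]), 0.0, 10.0)
        assert np.allclose(p, [3.0, 3.0, 3.0])

    def test_exponential_field_fourth_order(self):
        # v_x = k x => x(t) = x0 exp(0.01 k t); error scales as h^4
        f = exponential_field(k=0.5)
        exact = 10.0 * np.exp(0.005 * 200.0)
        hs = np.array([20.0, 10.0, 5.0, 2.5])
        errs = [abs(integrate(f, [10.0, 2.0, 2.0], h, int(200 / h))[0] - exact) for h in hs]
        slope = np.polyfit(np.log(hs), np.log(errs), 1)[0]
        assert slope == pytest.approx(4.0, abs=0.3)

    def test_rotation_conserves_radius(self):
        f = rotation_field(omega=2 * np.pi / 3600.0)
        p = integrate(f, [10.0, 0.0, 1.0], 10.0, 360)
        assert np.hypot(p[0], p[1]) == pytest.approx(10.0, rel=1e-5)

    def test_backward_step_reverses_forward(self):
        f = rotation_field()
        p0 = np.array([8.0, 3.0, 1.0])
        p = integrate(f, p0, 10.0, 40)
        back = integrate(f, p, -10.0, 40)
        assert np.allclose(back, p0, atol=1e-3 * 40)

    def test_out_of_domain_substep_raises(self):
        f = uniform_field(v=(100.0, 0.0, 0.0), shape=(6, 6, 6))
        with pytest.raises(OutOfDomainError):
            rk4_step(f, np.array([4.9, 2.0, 2.0]), 0.0, 10.0)


class TestPlaneCrossing:
    PLANE = PlaneGeometry(np.zeros(3), np.array([0.0, 0.0, 1.0]), 10.0)

    def test_straight_crossing_at_origin(self):
        c = detect_plane_crossing(np.array([0.0, 0.0, -1.0]), np.array([0.0, 0.0, 1.0]), self.PLANE)
        assert c is not None
        assert np.allclose(c.position, [0.0, 0.0, 0.0])
        assert c.direction == 1
        assert c.parameter == pytest.approx(0.5)

    def test_outside_disc_radius_misses(self):
        plane = PlaneGeometry(np.zeros(3), np.array([0.0, 0.0, 1.0]), 0.5)
        c = detect_plane_crossing(np.array([2.0, 0.0, -1.0]), np.array([2.0, 0.0, 1.0]), plane)
        assert c is None

    def test_same_side_no_crossing(self):
        c = detect_plane_crossing(np.array([0.0, 0.0, 1.0]), np.array([0.0, 0.0, 3.0]), self.PLANE)
        assert c is None

    def test_reverse_direction_sign(self):
        c = detect_plane_crossing(np.array([1.0, 0.0, 2.0]), np.array([1.0, 0.0, -2.0]), self.PLANE)
        assert c.direction == -1

    def test_degenerate_segment(self):
        p = np.array([0.0, 0.0, -1.0])
        assert detect_plane_crossing(p, p.copy(), self.PLANE) is None


def simple_scene(v=(0.0, 0.0, 0.0), extent=70, limit=30.0):
    """Uniform field along x with a duct-like mask and valve discs."""
    f = uniform_field(v=v, shape=(extent, 13, 13), spacing=1.0,
                      origin=(-5.0, -6.0, -6.0), cycle=1000.0)
    mask = np.zeros((extent, 13, 13), bool)
    mask[5:45, 2:11, 2:11] = True  # x in [0, 40]
    model = build_lv_model(mask, mask, [1, 1, 1], [-5.0, -6.0, -6.0])
    times = np.array([0.0, 500.0])
    mitral = static_valve_plane("mitral", [0.0, 0.0, 0.0], [1, 0, 0], 12.0, times, 1000.0)
    aortic = static_valve_plane("aortic", [40.0, 0.0, 0.0], [1, 0, 0], 12.0, times, 1000.0)
    return f, model, mitral, aortic


class TestTraceParticle:
    def test_zero_field_reaches_end_in_place(self):
        f, model, mitral, aortic = simple_scene()
        seed = np.array([20.0, 0.0, 0.0])
        for direction in ("forward", "backward"):
            pl = trace_particle(f, seed, mitral, aortic, model,
                                direction=direction, es_time=350.0)
            assert pl.termination.kind == "reached_end"
            assert np.allclose(pl.termination.position, seed)
            assert np.allclose(pl.samples[0][1], seed)
            assert pl.samples[0][0] == 0.0

    def test_uniform_flow_crosses_aortic_at_predicted_time(self):
        # 20 cm/s = 0.2 mm/ms; seed 9.5 mm before the outlet disc -> 47.5 ms
        f, model, mitral, aortic = simple_scene(v=(20.0, 0.0, 0.0))
        pl = trace_particle(f, np.array([30.5, 0.0, 0.0]), mitral, aortic, model,
                            direction="forward", es_time=350.0)
        assert pl.termination.kind == "crossed_aortic"
        assert pl.termination.time == pytest.approx(47.5, abs=10.0)
        assert pl.termination.position[0] == pytest.approx(40.0, abs=1e-9)

    def test_backward_trace_crosses_mitral(self):
        f, model, mitral, aortic = simple_scene(v=(20.0, 0.0, 0.0))
        pl = trace_particle(f, np.array([5.0, 0.0, 0.0]), mitral, aortic, model,
                            direction="backward", es_time=350.0)
        assert pl.termination.kind == "crossed_mitral"
        # going back in time at +x flow moves toward -x; 5 mm at 0.2 mm/ms
        assert pl.termination.time == pytest.approx(-25.0, abs=10.0)

    def test_displacement_limit_stops_trace(self):
        # flow along +y: no valve plane in the way, duct surface at y = 4.5
        _, _, mitral, aortic = simple_scene()
        f2 = uniform_field(v=(0.0, 50.0, 0.0), shape=(50, 90, 13), spacing=1.0,
                           origin=(-5.0, -6.0, -6.0))
        mask = np.zeros((50, 90, 13), bool)
        mask[5:45, 2:11, 2:11] = True
        model = build_lv_model(mask, mask, [1, 1, 1], [-5.0, -6.0, -6.0])
        pl = trace_particle(f2, np.array([20.0, 0.0, 0.0]), mitral, aortic, model,
                            direction="forward", es_time=350.0)
        assert pl.termination.kind == "displacement_exceeded"
        # 0.5 mm/ms; limit 30 mm beyond the surface => stop near y=34.5 => ~70 ms
        assert pl.termination.time == pytest.approx(70.0, abs=10.0)

    def test_leaving_grid_is_left_domain(self):
        f, model, mitral, aortic = simple_scene(v=(0.0, 80.0, 0.0))
        cfg = TraceConfig(displacement_limit=500.0)
        pl = trace_particle(f, np.array([20.0, 0.0, 0.0]), mitral, aortic, model,
                            cfg=cfg, direction="forward", es_time=350.0)
        assert pl.termination.kind == "left_domain"


class TestTraceAll:
    def test_zero_field_all_reach_end(self):
        f, model, mitral, aortic = simple_scene()
        seeds = np.array([[10.0, 0.0, 0.0], [20.0, 1.0, 0.0], [30.0, -1.0, 2.0]])
        pset = trace_all(seeds, f, mitral, aortic, model, es_time=350.0)
        assert np.all(pset.fwd_kind == 0) and np.all(pset.bwd_kind == 0)
        assert np.allclose(pset.fwd_position, seeds)
        assert pset.fwd_time[0] == pytest.approx(350.0)
        assert pset.bwd_time[0] == pytest.approx(350.0 - 1000.0)

    def test_permutation_independence(self):
        f, model, mitral, aortic = simple_scene(v=(20.0, 5.0, 0.0))
        rng = np.random.default_rng(0)
        seeds = np.column_stack([rng.uniform(2, 38, 20), rng.uniform(-3, 3, 20),
                                 rng.uniform(-3, 3, 20)])
        perm = rng.permutation(20)
        a = trace_all(seeds, f, mitral, aortic, model, es_time=350.0)
        b = trace_all(seeds[perm], f, mitral, aortic, model, es_time=350.0)
        assert np.array_equal(a.fwd_kind[perm], b.fwd_kind)
        assert np.array_equal(a.fwd_position[perm], b.fwd_position)
        assert np.array_equal(a.bwd_time[perm], b.bwd_time)

    def test_bit_identical_reruns(self):
        f, model, mitral, aortic = simple_scene(v=(17.0, 3.0, -2.0))
        seeds = np.array([[10.0, 0.5, -0.5], [25.0, 2.0, 1.0]])
        a = trace_all(seeds, f, mitral, aortic, model, es_time=350.0)
        b = trace_all(seeds, f, mitral, aortic, model, es_time=350.0)
        assert np.array_equal(a.fwd_position, b.fwd_position)
        assert np.array_equal(a.bwd_position, b.bwd_position)
        assert np.array_equal(a.fwd_time, b.fwd_time)

    def test_partial_final_step_hits_es_exactly(self):
        f, model, mitral, aortic = simple_scene()
        pset = trace_all(np.array([[20.0, 0.0, 0.0]]), f, mitral, aortic, model,
                         TraceConfig(step=10.0), es_time=345.0)
        assert pset.fwd_time[0] == pytest.approx(345.0)

    def test_termination_kind_names(self):
        assert set(TERMINATION_KINDS.values()) == {
            "reached_end", "crossed_mitral", "crossed_aortic",
            "displacement_exceeded", "left_domain",
        }
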