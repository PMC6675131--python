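"""The fluids engine: kernel, densities, forces, damping, stickiness,
collisions, stepping and full runs."""

import numpy as np
import pytest
from scipy.integrate import quad

from intuifluids.fixtures import toy_scene
from intuifluids.geometry2d import Circle, Contact, Point2
from intuifluids.prediction import compute_judgment
from intuifluids.scenes import Divider, Scene
from intuifluids.sph_engine import (
    FluidParams,
    ParticleState,
    apply_damping,
    apply_stickiness,
    compute_density,
    compute_forces,
    initialize_particles,
    kernel_w,
    resolve_geometry,
    resolve_obstacle_collision,
    run_ife,
    step,
)

G = 9.81


def make_state(positions, velocities, params, liquid_radius=0.074):
    geo = resolve_geometry(params, liquid_radius)
    pos = np.asarray(positions, dtype=float)
    rho = compute_density(pos, geo.mass, geo.h)
    press = np.maximum(params.stiffness * (rho - params.rest_density), 0.0)
    return ParticleState(pos, np.asarray(velocities, dtype=float), rho, press,
                         np.zeros(len(pos), dtype=bool))


class TestKernel:
    def test_zero_at_and_beyond_cutoff(self):
        h = 0.05
        assert kernel_w(h, h) == 0.0
        assert kernel_w(2 * h, h) == 0.0

    def test_monotone_decrease(self):
        h = 0.05
        assert kernel_w(0.0, h) > kernel_w(h / 2, h) > 0.0
        rs = np.linspace(0, h, 50)
        ws = np.array([kernel_w(r, h) for r in rs])
        assert np.all(np.diff(ws) <= 1e-12)

    def test_2d_normalization_by_quadrature(self):
        h = 0.031
        integral, _ = quad(lambda r: kernel_w(r, h) * 2 * np.pi * r, 0, h, limit=200)
        assert integral == pytest.approx(1.0, abs=1e-4)

    def test_invalid_h(self):
        with pytest.raises(ValueError):
            kernel_w(0.1, 0.0)


class TestDensity:
    def test_isolated_particle(self):
        m, h = 0.3, 0.05
        rho = compute_density(np.array([[0.5, 0.5]]), m, h)
        assert rho[0] == pytest.approx(m * kernel_w(0.0, h))

    def test_two_particles_symmetric(self):
        m, h, d = 0.3, 0.05, 0.02
        rho = compute_density(np.array([[0.0, 0.0], [d, 0.0]]), m, h)
        expected = m * (kernel_w(0.0, h) + kernel_w(d, h))
        assert rho == pytest.approx([expected, expected])

    @pytest.mark.parametrize("n", [10, 50, 100])
    def test_matches_brute_force_oracle(self, n, rng):
        m, h = 0.2, 0.04
        pos = rng.uniform(0, 0.3, size=(n, 2))
        rho = compute_density(pos, m, h)
        oracle = np.zeros(n)
        for i in range(n):
            for j in range(n):
                r = float(np.hypot(*(pos[i] - pos[j])))
                oracle[i] += m * kernel_w(r, h)
        assert rho == pytest.approx(oracle, abs=1e-12)


class TestForces:
    def test_single_particle_gravity_only(self):
        params = FluidParams(N=1)
        st = make_state([[0.5, 1.0]], [[0.0, 0.0]], params)
        f = compute_forces(st, params)
        assert f[0] == pytest.approx([0.0, -G])

    def test_viscosity_slows_approaching_pair(self):
        """One step of a head-on pair: relative speed strictly smaller with
        artificial viscosity than without."""
        sc = Scene(obstacles=[], receptacle=Divider(0.5))
        rel = {}
        for alpha in (0.0, 2.0):
            params = FluidParams(N=2, alpha=alpha, zeta=0.0)
            geo = resolve_geometry(params)
            d = 0.5 * geo.h
            st = make_state([[0.5 - d / 2, 1.0], [0.5 + d / 2, 1.0]],
                            [[0.5, 0.0], [-0.5, 0.0]], params)
            out = step(st, sc, params)
            rel[alpha] = out.velocities[0, 0] - out.velocities[1, 0]
        assert rel[2.0] < rel[0.0]

    def test_lattice_at_rest_density_in_equilibrium(self):
        """Interior particles of a resting lattice feel pressure accelerations
        far below gravity (the mass normalization sets them at rest density)."""
        params = FluidParams(N=49, zeta=0.0)
        geo = resolve_geometry(params)
        s = geo.spacing
        xs = np.arange(7) * s
        gx, gy = np.meshgrid(xs, xs)
        pos = np.column_stack([gx.ravel(), gy.ravel()])
        st = make_state(pos, np.zeros_like(pos), params)
        f = compute_forces(st, params) - np.array([0.0, -G])
        interior = np.all((pos > s + 1e-9) & (pos < 5 * s + 1e-9), axis=1)
        assert np.abs(f[interior]).max() < 0.01 * G

    def test_pair_antisymmetry_conserves_momentum(self, rng):
        """Without gravity contribution, pair forces sum to ~zero."""
        params = FluidParams(N=20, zeta=0.0)
        geo = resolve_geometry(params)
        pos = rng.uniform(0, 4 * geo.h, size=(20, 2))
        vel = rng.normal(0, 0.5, size=(20, 2))
        st = make_state(pos, vel, params)
        f = compute_forces(st, params) - np.array([0.0, -G])
        assert np.abs(f.sum(axis=0)).max() < 1e-10 * max(1.0, np.abs(f).max())


class TestDamping:
    def test_zeta_zero_identity(self):
        f = np.array([[0.0, -G]])
        v = np.array([[1.0, 2.0]])
        assert apply_damping(f, v, 0.0) == pytest.approx(f)

    def test_zero_velocity_identity(self):
        f = np.array([[0.3, -G]])
        assert apply_damping(f, np.zeros((1, 2)), 5.0) == pytest.approx(f)

    def test_terminal_speed_closed_form(self, tall_scene):
        """dv/dt = -g - zeta*v has terminal speed g/zeta: 1.962 m/s at zeta=5."""
        params = FluidParams(N=1, zeta=5.0, t_max=3.0)
        res = run_ife(tall_scene, params, seed=0)
        speed = float(np.hypot(*res.final_state.velocities[0]))
        assert speed == pytest.approx(G / 5.0, rel=0.01)


class TestStickiness:
    def test_zero_coefficients_identity(self):
        ct = Contact(Point2(0, 0), (0.0, 1.0), 0.0)
        v = np.array([0.3, -0.2])
        assert apply_stickiness(v, ct, 0.0, 0.0) == pytest.approx(v)

    def test_full_coefficients_stop(self):
        ct = Contact(Point2(0, 0), (0.0, 1.0), 0.0)
        assert apply_stickiness(np.array([0.3, -0.2]), ct, 1.0, 1.0) == pytest.approx([0, 0])

    def test_matches_projection_matrix_oracle(self, rng):
        for _ in range(20):
            th = rng.uniform(0, 2 * np.pi)
            n = np.array([np.cos(th), np.sin(th)])
            v = rng.normal(size=2)
            kn, kt = rng.uniform(0, 1, 2)
            ct = Contact(Point2(0, 0), tuple(n), 0.0)
            got = apply_stickiness(v, ct, kn, kt)
            Pn = np.outer(n, n)
            Pt = np.eye(2) - Pn
            oracle = (1 - kn) * Pn @ v + (1 - kt) * Pt @ v
            assert got == pytest.approx(oracle, abs=1e-12)

    def test_non_unit_normal_rejected(self):
        from types import SimpleNamespace

        bad = SimpleNamespace(normal=(0.5, 0.5))
        with pytest.raises(ValueError):
            apply_stickiness(np.zeros(2), bad, 0.5, 0.5)


class TestObstacleCollision:
    def test_floor_contact_zeroes_vy_keeps_vx(self):
        sc = toy_scene("empty")
        params = FluidParams(N=1)
        geo = resolve_geometry(params)
        st = make_state([[0.5, geo.particle_radius * 0.5]], [[0.7, -1.0]], params)
        out = resolve_obstacle_collision(st, sc, params)
        assert out.velocities[0, 0] == pytest.approx(0.7)
        assert out.velocities[0, 1] == pytest.approx(0.0)
        assert out.positions[0, 1] == pytest.approx(geo.particle_radius)

    def test_no_contact_unchanged(self):
        sc = toy_scene("empty")
        params = FluidParams(N=1)
        st = make_state([[0.5, 1.0]], [[0.1, -0.5]], params)
        out = resolve_obstacle_collision(st, sc, params)
        assert out.positions == pytest.approx(st.positions)
        assert out.velocities == pytest.approx(st.velocities)

    def test_45_degree_slide_matches_projection(self):
        from intuifluids.geometry2d import Polygon

        ramp = Polygon([(0.0, 0.0), (1.0, 0.0), (1.0, 1.0)])  # hypotenuse at 45 deg
        sc = Scene(obstacles=[ramp], receptacle=Divider(0.5))
        params = FluidParams(N=1)
        geo = resolve_geometry(params)
        # particle just inside the hypotenuse y = x, moving straight down
        px, py = 0.5, 0.5 + geo.particle_radius * 0.5
        st = make_state([[px, py]], [[0.0, -1.0]], params)
        out = resolve_obstacle_collision(st, sc, params)
        n = np.array([-1.0, 1.0]) / np.sqrt(2)
        v0 = np.array([0.0, -1.0])
        expected = v0 - (v0 @ n) * n  # inelastic: remove inward normal part
        assert out.velocities[0] == pytest.approx(expected, abs=1e-9)


class TestStep:
    def test_one_step_hand_calculation(self):
        sc = toy_scene("empty")
        params = FluidParams(N=1, zeta=0.0)
        st = make_state([[0.5, 1.0]], [[0.0, 0.0]], params)
        out = step(st, sc, params)
        dt = params.dt
        assert out.velocities[0, 1] == pytest.approx(-G * dt)
        assert out.positions[0, 1] == pytest.approx(1.0 - G * dt * dt)
        assert out.time == pytest.approx(dt)

    def test_bitwise_determinism(self):
        sc = toy_scene("wedge_center")
        params = FluidParams(N=20)
        st = initialize_particles(sc, params, seed=3)
        a = step(st, sc, params)
        b = step(st, sc, params)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.velocities, b.velocities)


class TestFullRuns:
    def test_particles_stay_outside_obstacles(self):
        sc = toy_scene("wedge_center")
        params = FluidParams(N=30, zeta=5.0, t_max=2.0)
        res = run_ife(sc, params, seed=1)
        geo = resolve_geometry(params, sc.liquid_start.radius)
        wedge = sc.obstacles[0].shapely
        from shapely.geometry import Point as ShPoint

        for x, y in res.final_state.positions:
            assert not wedge.contains(ShPoint(x, y).buffer(-1e-9)) or \
                wedge.exterior.distance(ShPoint(x, y)) < geo.particle_radius + 1e-6

    def test_damping_monotone_slows_fluid(self):
        sc = toy_scene("wedge_center")
        means = {}
        for zeta in (0.0, 20.0):
            params = FluidParams(N=30, zeta=zeta, t_max=1.0)
            res = run_ife(sc, params, seed=0)
            means[zeta] = float(np.hypot(*res.final_state.velocities.T).mean())
        assert means[20.0] < means[0.0]

    def test_empty_scene_symmetry(self):
        sc = toy_scene("empty")
        js = []
        for seed in range(5):
            res = run_ife(sc, FluidParams(N=50, zeta=5.0, t_max=4.0), seed=seed)
            js.append(compute_judgment(res, sc).J)
        assert abs(float(np.mean(js)) - 0.5) <= 0.1

    def test_sticky_honey_leaves_particles_on_ledge(self, ledge_scene):
        from intuifluids.presets import FLUID_PRESETS

        _, params = FLUID_PRESETS["honey1-ife"]
        res = run_ife(ledge_scene, params, seed=0)
        st = res.final_state
        on_ledge = (st.positions[:, 1] > 0.8) & st.stuck_flags
        assert on_ledge.sum() > 0

    def test_particle_count_conserved(self):
        sc = toy_scene("wedge_center")
        params = FluidParams(N=25, t_max=1.0)
        res = run_ife(sc, params, seed=0)
        assert res.final_state.positions.shape == (25, 2)
        assert np.all(np.isfinite(res.final_state.positions))

    def test_trajectory_timestamps_increase(self):
        sc = toy_scene("empty")
        res = run_ife(sc, FluidParams(N=5, t_max=0.5), seed=0, record_every=500)
        assert np.all(np.diff(res.trajectory_times) > 0)
        assert res.trajectory.shape[0] == len(res.trajectory_times)
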