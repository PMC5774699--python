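"""Propagation: advection schemes, random walk, boundaries, reversibility."""

from datetime import datetime

import numpy as np
import pytest

import seadrift as sd
from seadrift.core import BoundaryPolicy, SimClock
from seadrift.geometry import M_PER_DEG_LAT, horizontal_distance_m, m_per_deg_lon
from seadrift.kinematics import (StepConfig, enforce_boundaries,
                                 integrate_step, random_walk_increment,
                                 step_ensemble)

START = datetime(2004, 1, 1)


def _run(ens, prov, bio, cfg, n_steps):
    return sd.run_simulation(ens, prov, bio, cfg, START, n_steps)


class TestDeterministicAdvection:
    def test_uniform_flow_closed_form_one_day(self, uniform_basin):
        """0.1 m/s east for a day: dlon = 8640 m / metres-per-degree."""
        for scheme in ("euler", "rk2", "rk4"):
            ens = sd.Ensemble([0.0], [0.0], [5.0])
            cfg = StepConfig(dt=300.0, scheme=scheme, seed=1)
            _run(ens, uniform_basin, None, cfg, 288)
            expect = 0.1 * 86400 / m_per_deg_lon(0.0)
            assert ens.lon[0] == pytest.approx(expect, abs=1e-12)
            assert ens.lat[0] == 0.0

    def test_rk2_orbit_closure_second_order(self, rotation_basin):
        """Solid-body orbit closure error decays as dt^2 (ratio in [3, 5])."""
        r_deg = 10000.0 / M_PER_DEG_LAT

        def closure(dt):
            ens = sd.Ensemble([0.0], [r_deg], [5.0])
            cfg = StepConfig(dt=dt, scheme="rk2", seed=1)
            _run(ens, rotation_basin, None, cfg, int(round(86400 / dt)))
            return float(horizontal_distance_m(0.0, r_deg,
                                               ens.lon[0], ens.lat[0]))

        e600, e300 = closure(600.0), closure(300.0)
        assert e300 < 10.0  # metres after a 63 km orbit
        assert 3.0 <= e600 / e300 <= 5.0

    def test_backward_direction_reverses_current(self, uniform_basin):
        ens = sd.Ensemble([0.1], [0.0], [5.0])
        cfg = StepConfig(dt=300.0, scheme="euler", direction="backward", seed=1)
        sd.run_simulation(ens, uniform_basin, None, cfg, START, 10)
        assert ens.lon[0] < 0.1  # moved west under eastward current


class TestRandomWalk:
    def test_zero_diffusivity_means_zero_displacement(self, uniform_basin):
        cfg = StepConfig(dt=60.0, seed=3)
        dx, dy, dz = random_walk_increment(np.zeros(100), np.zeros(100),
                                           np.full(100, 10.0),
                                           uniform_basin, cfg)
        assert not dx.any() and not dy.any() and not dz.any()

    def test_variance_grows_as_2kt(self):
        """Constant Kv: Var(z) after time t is 2 Kv t within Monte-Carlo error."""
        prov = sd.UniformFlow(Kv=1e-3, bounds=(-1, 1, -1, 1),
                              water_depth=1000.0)
        n = 20000
        ens = sd.Ensemble(np.zeros(n), np.zeros(n), np.full(n, 500.0))
        cfg = StepConfig(dt=10.0, scheme="euler", seed=5)
        _run(ens, prov, None, cfg, 360)
        var = np.var(ens.depth - 500.0)
        expect = 2.0 * 1e-3 * 3600.0
        se = expect * np.sqrt(2.0 / (n - 1))
        assert abs(var - expect) < 3.0 * se

    def test_well_mixed_condition_reduced(self, parabolic_basin):
        """Uniform tracers stay uniform under parabolic Kv (12 h, reduced n);
        without the gradient correction they pile up at the K minima."""
        from scipy.stats import kstest
        n = 3000
        for correction, bound, comparator in ((True, 0.035, np.less),
                                              (False, 0.05, np.greater)):
            rng = np.random.default_rng(8)
            ens = sd.Ensemble(np.zeros(n), np.zeros(n), rng.uniform(0, 50, n))
            cfg = StepConfig(dt=60.0, scheme="euler", seed=9,
                             gradient_correction=correction)
            _run(ens, parabolic_basin, None, cfg, 720)
            ks = kstest(ens.depth / 50.0, "uniform").statistic
            assert comparator(ks, bound), (correction, ks)

    def test_negative_diffusivity_rejected(self):
        class Broken(sd.UniformFlow):
            def turbulence(self, lon, lat, z):
                kh, kv = super().turbulence(lon, lat, z)
                return kh, kv - 1.0
        prov = Broken(bounds=(-1, 1, -1, 1))
        cfg = StepConfig(dt=60.0, seed=1)
        with pytest.raises(ValueError, match="negative"):
            random_walk_increment(np.zeros(2), np.zeros(2), np.full(2, 5.0),
                                  prov, cfg)


class TestBoundaries:
    def test_vertical_mirror_at_surface_and_bottom(self, uniform_basin):
        old = (np.array([0.0]), np.array([0.0]), np.array([5.0]))
        for z_cand, z_expect in ((-2.0, 2.0), (105.0, 95.0)):
            lon, lat, z, deact, _ = enforce_boundaries(
                *old, np.array([0.0]), np.array([0.0]), np.array([z_cand]),
                uniform_basin, BoundaryPolicy())
            assert z[0] == pytest.approx(z_expect)
            assert not deact.any()

    def test_coast_candidate_resolves_to_specular_mirror(self, toy_coast):
        lon, lat, z, deact, _ = enforce_boundaries(
            np.array([0.5]), np.array([0.5]), np.array([5.0]),
            np.array([1.5]), np.array([0.5]), np.array([5.0]),
            toy_coast, BoundaryPolicy())
        assert (lon[0], lat[0]) == (0.5, 0.5)

    def test_absorbing_policy_deactivates(self, uniform_basin):
        lon, lat, z, deact, _ = enforce_boundaries(
            np.array([0.9]), np.array([0.0]), np.array([5.0]),
            np.array([1.5]), np.array([0.0]), np.array([5.0]),
            uniform_basin, BoundaryPolicy(horizontal="absorb"))
        assert deact.all()

    def test_no_dry_positions_on_stair_coast(self):
        """Onshore flow + strong horizontal diffusion against a stair coast:
        every post-step position stays wet (boundary robustness sweep)."""
        edges = np.linspace(0.0, 1.0, 11)
        mask = np.zeros((10, 10), bool)
        for j in range(10):
            for i in range(10):
                if i + j >= 12:
                    mask[j, i] = True
        basin = sd.ToyCoastBasin(edges, edges, mask, u=1.0, v=1.0, Kh=100.0,
                                 Kv=1e-4, water_depth=20.0)
        n = 500
        rng = np.random.default_rng(3)
        ens = sd.Ensemble(rng.uniform(0.05, 0.4, n),
                          rng.uniform(0.05, 0.4, n), np.full(n, 5.0))
        cfg = StepConfig(dt=120.0, scheme="euler", seed=4)
        clk = SimClock(START)
        ev = {}
        for _ in range(200):
            basin.update(clk.time)
            clk = step_ensemble(ens, basin, None, cfg, clk, events=ev)
            assert np.all(basin.is_wet(ens.lon, ens.lat, ens.depth))
        assert ev["coast_reflection"] > 0  # the coast was actually exercised


class TestStepEnsemble:
    def test_passive_ensemble_translates_uniformly(self, uniform_basin):
        n = 50
        ens = sd.Ensemble(np.linspace(-0.4, 0.0, n), np.zeros(n),
                          np.full(n, 5.0))
        lon0 = ens.lon.copy()
        cfg = StepConfig(dt=300.0, scheme="rk2", seed=1)
        _run(ens, uniform_basin, None, cfg, 10)
        dlon = ens.lon - lon0
        assert np.allclose(dlon, dlon[0], atol=1e-15)

    def test_forward_then_backward_recovers_start(self, rotation_basin):
        """Adjoint backtracking in a steady rotational flow with K=0: the
        composition error is far below 1e-3 of the path length."""
        r_deg = 10000.0 / M_PER_DEG_LAT
        ens = sd.Ensemble([0.0], [r_deg], [5.0])
        fwd = StepConfig(dt=300.0, scheme="rk2", seed=2)
        sd.run_simulation(ens, rotation_basin, None, fwd, START, 100)
        bwd = StepConfig(dt=300.0, scheme="rk2", seed=2, direction="backward")
        sd.run_simulation(ens, rotation_basin, None, bwd,
                          START.replace(hour=8, minute=20), 100)
        err = float(horizontal_distance_m(0.0, r_deg, ens.lon[0], ens.lat[0]))
        path = 2.0 * (2 * np.pi * 10000.0) * (100 * 300.0 / 86400.0)
        assert err / path < 1e-3

    def test_fixed_seed_trajectories_bit_identical(self, parabolic_basin):
        def one():
            ens = sd.Ensemble(np.zeros(64), np.zeros(64),
                              np.linspace(1, 49, 64))
            cfg = StepConfig(dt=60.0, scheme="rk2", seed=77)
            _run(ens, parabolic_basin, None, cfg, 50)
            return ens.lon.copy(), ens.lat.copy(), ens.depth.copy()
        a, b = one(), one()
        for x, y in zip(a, b):
            assert np.array_equal(x, y)

    def test_rk_midpoint_fallback_counted(self):
        """RK2 midpoint stepping over the domain edge falls back to Euler."""
        prov = sd.UniformFlow(u=5.0, bounds=(-0.01, 0.01, -0.01, 0.01),
                              water_depth=100.0)
        ens = sd.Ensemble([0.009], [0.0], [5.0])
        cfg = StepConfig(dt=300.0, scheme="rk2", seed=1)
        ev = {}
        step_ensemble(ens, prov, None, cfg, SimClock(START), events=ev)
        assert ev["rk_fallback"] >= 1
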