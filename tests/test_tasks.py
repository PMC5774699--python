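"""Task drivers: connectivity, averaging, and the Eulerian ADR solver."""

from datetime import datetime

import numpy as np
import pytest

import seadrift as sd
from seadrift.kinematics import StepConfig
from seadrift.tasks import (EulerianField, Habitat, HabitatSet,
                            ReactionOperator, compute_connectivity,
                            eulerian_step, extract_average, run_eulerian)

START = datetime(2004, 1, 1)


@pytest.fixture
def two_habitat_setup():
    """Source A, sink B downstream; eastward current carries particles over."""
    prov = sd.UniformFlow(u=0.5, bounds=(-1, 1, -1, 1), water_depth=100.0)
    A = Habitat.from_box("A", 0.0, 0.1, -0.3, 0.3, role="source")
    B = Habitat.from_box("B", 0.5, 0.6, -0.3, 0.0, role="sink")
    return prov, HabitatSet([A, B])


class TestHabitats:
    def test_duplicate_ids_rejected(self):
        a = Habitat.from_box("X", 0, 1, 0, 1)
        with pytest.raises(ValueError):
            HabitatSet([a, Habitat.from_box("X", 2, 3, 0, 1)])

    def test_roles_and_lookup(self, two_habitat_setup):
        _, habs = two_habitat_setup
        assert [h.id for h in habs.sources] == ["A"]
        assert [h.id for h in habs.sinks] == ["B"]
        assert habs["B"].suitability == 1.0

    def test_geojson_round_trip(self, tmp_path):
        gj = {"type": "FeatureCollection", "features": [
            {"type": "Feature",
             "properties": {"id": "P", "role": "sink", "suitability": 0.5},
             "geometry": {"type": "Polygon", "coordinates":
                          [[[0, 0], [1, 0], [1, 1], [0, 1], [0, 0]]]}}]}
        import json
        path = tmp_path / "habs.geojson"
        path.write_text(json.dumps(gj))
        habs = HabitatSet.from_geojson(path)
        assert habs["P"].role == "sink"
        assert habs["P"].contains(0.5, 0.5)
        assert not habs["P"].contains(1.5, 0.5)


class TestConnectivity:
    def test_deterministic_toy_transport_probability(self, two_habitat_setup):
        """Four propagules, two on latitudes that pass through B: T = 2/4."""
        prov, habs = two_habitat_setup
        pos = {"A": ([0.05] * 4, [-0.2, -0.1, 0.1, 0.2], [5.0] * 4)}
        cfg = StepConfig(dt=600.0, scheme="euler", seed=1)
        M = compute_connectivity(habs, prov, sd.PassiveParticle(), cfg,
                                 START, 300, release_positions=pos)
        assert M.T.loc["B", "A"] == 0.5
        assert M.R["A"] == 4
        assert M.N.loc["B", "A"] == 2.0

    def test_survival_weighted_tally(self, two_habitat_setup):
        """Same toy with survival weight 0.5 per propagule: T = 0.25."""
        prov, habs = two_habitat_setup
        pos = {"A": ([0.05] * 4, [-0.2, -0.1, 0.1, 0.2], [5.0] * 4)}
        bio = sd.StagedLarva(egg_duration=0.0, yolk_duration=0.0,
                             competency_age=0.0, dvm_onset=1e9,
                             swim_speed=0.0, initial_survival=0.5)
        cfg = StepConfig(dt=600.0, scheme="euler", seed=1)
        M = compute_connectivity(habs, prov, bio, cfg, START, 300,
                                 release_positions=pos)
        assert M.T.loc["B", "A"] == 0.25

    def test_no_settlers_gives_zero_row(self, two_habitat_setup):
        prov, habs = two_habitat_setup
        # all latitudes miss B
        pos = {"A": ([0.05] * 3, [0.1, 0.2, 0.25], [5.0] * 3)}
        cfg = StepConfig(dt=600.0, scheme="euler", seed=1)
        M = compute_connectivity(habs, prov, sd.PassiveParticle(), cfg,
                                 START, 300, release_positions=pos)
        assert M.T.loc["B", "A"] == 0.0
        assert M.T["A"].sum() == 0.0

    def test_accounting_conserves_particles(self, two_habitat_setup):
        prov, habs = two_habitat_setup
        cfg = StepConfig(dt=600.0, scheme="euler", seed=5)
        M = compute_connectivity(habs, prov, sd.PassiveParticle(), cfg,
                                 START, 150, releases_per_source=200)
        row = M.accounting.loc["A"]
        assert row.settled + row.active + row.deactivated_other == row.released

    def test_suitability_thins_settlement(self, two_habitat_setup):
        prov, habs = two_habitat_setup
        habs["B"].suitability = 0.5
        cfg = StepConfig(dt=600.0, scheme="euler", seed=11)
        M = compute_connectivity(habs, prov, sd.PassiveParticle(), cfg,
                                 START, 300, releases_per_source=600)
        # full-suitability value is ~0.5 (half the released latitudes)
        assert 0.15 < M.T.loc["B", "A"] < 0.35

    def test_binomial_error_scaling(self):
        """std(T-hat) across repetitions scales as 1/sqrt(R)."""
        prov = sd.UniformFlow(u=0.5, Kh=50.0, bounds=(-1, 1, -1, 1),
                              water_depth=100.0)
        A = Habitat.from_box("A", 0.0, 0.05, -0.02, 0.02, role="source")
        B = Habitat.from_box("B", 0.5, 0.7, -0.1, 0.02, role="sink")
        habs = HabitatSet([A, B])

        def reps(R, nrep, seed0):
            out = []
            for k in range(nrep):
                cfg = StepConfig(dt=600.0, scheme="euler", seed=seed0 + k)
                M = compute_connectivity(habs, prov, sd.PassiveParticle(),
                                         cfg, START, 250,
                                         releases_per_source=R)
                out.append(M.T.loc["B", "A"])
            return np.asarray(out)

        T_small = reps(50, 24, 100)
        T_big = reps(200, 24, 400)
        s_small = T_small.std(ddof=1)
        s_big = T_big.std(ddof=1)
        assert 1.4 < s_small / s_big < 2.8  # ~2 with sampling noise
        p = T_big.mean()
        binom = np.sqrt(p * (1 - p) / 200)
        assert abs(s_big - binom) < 3.0 * binom / np.sqrt(2 * 23)


class TestExtractAverage:
    def test_constant_field_statistics(self):
        prov = sd.UniformFlow(bounds=(-1, 1, -1, 1), water_depth=100.0,
                              scalars={"temperature": 13.0})
        out = extract_average(prov, [("R", -0.5, 0.5, -0.5, 0.5)], [START],
                              ["temperature"], depth_range=(0.0, 50.0))
        row = out.iloc[0]
        assert row["mean"] == row["min"] == row["max"] == 13.0
        assert row["count"] > 0 and not row["flagged"]

    def test_linear_profile_slab_average(self):
        prov = sd.UniformFlow(bounds=(-1, 1, -1, 1), water_depth=100.0,
                              scalars={"temperature":
                                       lambda lon, lat, z: 15.0 - 0.1 * z})
        out = extract_average(prov, [("R", -0.5, 0.5, -0.5, 0.5)], [START],
                              ["temperature"], depth_range=(0.0, 10.0),
                              n_depth=11)
        assert out.iloc[0]["mean"] == pytest.approx(14.5, abs=1e-9)

    def test_fully_dry_region_flagged_not_raised(self, toy_coast):
        toy_coast._scalars = {"temperature": (lambda lon, lat, z: 10.0)}
        toy_coast.fields = frozenset({"temperature"})
        out = extract_average(toy_coast, [("land", 1.1, 1.9, 0.1, 2.9)],
                              [START], ["temperature"],
                              depth_range=(0.0, 10.0))
        row = out.iloc[0]
        assert row["flagged"] and row["count"] == 0 and row["n_dry"] > 0


class TestEulerianSolver:
    def test_mass_conserved_in_closed_box(self):
        C0 = np.zeros(101)
        C0[50] = 1.0
        f = EulerianField(C0, (100.0,), K=1.0)
        m0 = f.mass
        drift = 0.0
        for _ in range(200):
            m_prev = f.mass
            eulerian_step(f, 1000.0)
            drift = max(drift, abs(f.mass - m_prev) / m0)
        assert drift < 1e-12

    def test_logistic_growth_matches_closed_form(self):
        f = EulerianField(np.full(3, 0.1), (100.0,), K=0.0,
                          reaction=ReactionOperator("logistic", r=0.1,
                                                    Ccap=1.0))
        dt = 0.01 * 86400.0
        for _ in range(int(60 / 0.01)):
            eulerian_step(f, dt)
        t = 60.0
        exact = 1.0 / (1.0 + (0.9 / 0.1) * np.exp(-0.1 * t))
        assert abs(f.C[0] - exact) / exact < 1e-3

    def test_diffusive_plume_variance_grows_as_2kt(self):
        C0 = np.zeros(101)
        C0[50] = 1.0
        f = EulerianField(C0, (100.0,), K=1.0)
        n, dt = 500, 1000.0
        for _ in range(n):
            eulerian_step(f, dt)
        x = (np.arange(101) - 50) * 100.0
        w = f.C / f.C.sum()
        var = float((w * x ** 2).sum() - (w * x).sum() ** 2)
        assert abs(var - 2.0 * n * dt) / (2.0 * n * dt) < 0.02

    def test_divergence_free_flow_preserves_constants(self):
        """Wall-tangent streamfunction vortex: uniform C stays uniform."""
        n, dx = 20, 100.0
        xn = np.arange(n + 1)
        psi = (np.sin(np.pi * xn[None, :] / n)
               * np.sin(np.pi * xn[:, None] / n) * 5e3)
        v_face = -(psi[1:-1, 1:] - psi[1:-1, :-1]) / dx
        u_face = (psi[1:, 1:-1] - psi[:-1, 1:-1]) / dx
        f = EulerianField(np.ones((n, n)), (dx, dx), K=0.0,
                          face_velocity=(v_face, u_face))
        m0 = f.mass
        for _ in range(300):
            eulerian_step(f, 10.0)
        assert np.abs(f.C - 1.0).max() < 1e-12
        assert f.mass == pytest.approx(m0, rel=1e-14)

    def test_no_new_extrema_in_pure_transport(self):
        """Maximum principle for advection-diffusion with a wall-tangent
        (divergence-free) flow: no step creates a new extremum."""
        n, dx = 24, 100.0
        xn = np.arange(n + 1)
        psi = (np.sin(np.pi * xn[None, :] / n)
               * np.sin(np.pi * xn[:, None] / n) * 4e3)
        v_face = -(psi[1:-1, 1:] - psi[1:-1, :-1]) / dx
        u_face = (psi[1:, 1:-1] - psi[:-1, 1:-1]) / dx
        rng = np.random.default_rng(0)
        f = EulerianField(rng.uniform(0.0, 1.0, (n, n)), (dx, dx), K=0.5,
                          face_velocity=(v_face, u_face))
        for _ in range(200):
            prev_min, prev_max = f.C.min(), f.C.max()
            eulerian_step(f, 10.0)
            assert f.C.min() >= prev_min - 1e-13
            assert f.C.max() <= prev_max + 1e-13

    def test_cfl_violation_names_admissible_dt(self):
        f = EulerianField(np.ones(10), (100.0,),
                          velocity=(np.full(10, 1.0),), K=0.0)
        with pytest.raises(ValueError, match="admissible"):
            eulerian_step(f, 500.0)

    def test_grazing_box_depletes_against_ode_oracle(self):
        """Steady advective logistic flow with a localized grazing box:
        solver profile matches an independent ODE integration of the
        steady-state balance, and C -> Ccap upstream."""
        from scipy.integrate import solve_ivp
        nx, dx, u = 400, 100.0, 0.05
        r, Ccap, g = 0.5, 1.0, 2.0
        mask = np.zeros(nx)
        mask[200:250] = 1.0
        f = EulerianField(np.full(nx, Ccap), (dx,),
                          velocity=(np.full(nx, u),), K=0.0,
                          reaction=ReactionOperator(
                              "logistic_with_grazing", r=r, Ccap=Ccap,
                              grazing=g, grazing_mask=mask),
                          inflow={0: (Ccap, None)})
        for _ in range(3000):
            eulerian_step(f, 1000.0)
        assert f.C[100] == pytest.approx(Ccap, abs=1e-6)   # upstream
        assert f.C[200:250].min() < 0.5 * Ccap             # depleted in box
        r_s, g_s = r / 86400.0, g / 86400.0

        def rhs(x, y):
            m = 1.0 if 20000.0 <= x < 25000.0 else 0.0
            return (r_s * y * (1 - y / Ccap) - g_s * m * y) / u

        xs = np.arange(150, 300) * dx + dx / 2
        sol = solve_ivp(rhs, (xs[0], xs[-1]), [f.C[150]], t_eval=xs,
                        rtol=1e-9, atol=1e-12)
        assert np.abs(sol.y[0] - f.C[150:300]).max() < 0.05

    def test_zero_grazing_relaxes_to_capacity(self):
        f = EulerianField(np.full(50, 0.3), (100.0,), K=0.0,
                          reaction=ReactionOperator("logistic", r=0.5,
                                                    Ccap=1.0))
        for _ in range(2000):
            eulerian_step(f, 1000.0)
        assert np.all(np.abs(f.C - 1.0) < 1e-3)

    def test_run_eulerian_time_average_and_snapshots(self):
        f = EulerianField(np.full(20, 0.5), (100.0,), K=0.1)
        fld, snaps, avg = run_eulerian(f, 100.0, 50, snapshot_every=25)
        assert len(snaps) == 2
        assert avg == pytest.approx(np.full(20, 0.5))
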