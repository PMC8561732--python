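import numpy as np
import pytest
from scipy.stats import spearmanr

from microer import conditions
from microer.engine import (
    KB,
    EngineError,
    ERConfig,
    GeometryTerms,
    compute_rmsf,
    default_geometry,
    ensemble_b_equivalent,
    geometry_energy_gradient,
    run_ensemble_refinement,
)
from microer.model_io import AtomRecord, ReflectionRecord, ReflectionSet, StructureModel
from microer.xray import calc_structure_factors


def make_two_atoms(d=3.0):
    return StructureModel([
        AtomRecord(1, "CA", "C", "A", "S1", 1, np.array([8.0, 10.0, 10.0])),
        AtomRecord(2, "CA", "C", "A", "S1", 2, np.array([8.0 + d, 10.0, 10.0])),
    ], (20, 20, 20))


MINI_REFL = ReflectionSet([
    ReflectionRecord((1, 0, 0), 1.0, 1.0, False),
    ReflectionRecord((0, 1, 0), 1.0, 1.0, True),
])


class TestGeometry:
    def test_gradient_matches_finite_differences(self, toy_model, rng):
        geom = default_geometry(toy_model)
        pos = toy_model.positions + rng.normal(0, 0.15, toy_model.positions.shape)
        e, g = geometry_energy_gradient(geom, pos)
        eps = 1e-6
        fd = np.zeros_like(g)
        for j in range(0, toy_model.n_atoms, 7):
            for a in range(3):
                for s, sign in ((eps, 1), (-eps, -1)):
                    p = pos.copy()
                    p[j, a] += s
                    ee, _ = geometry_energy_gradient(geom, p)
                    fd[j, a] += sign * ee
        fd /= 2 * eps
        checked = np.arange(0, toy_model.n_atoms, 7)
        assert np.abs(g[checked] - fd[checked]).max() / np.abs(fd[checked]).max() < 1e-5

    def test_minimum_at_input_structure(self, toy_model):
        geom = default_geometry(toy_model)
        e, g = geometry_energy_gradient(geom, toy_model.positions)
        assert e == pytest.approx(0.0, abs=1e-18)
        np.testing.assert_allclose(g, 0.0, atol=1e-10)


class TestDynamics:
    def test_static_at_equilibrium_zero_temperature(self):
        model = make_two_atoms()
        cfg = ERConfig(wx=0.0, tx=1.0, steps_per_macrocycle=10, n_macrocycles=20,
                       temperature=0.0, friction=0.0, burn_in=2, rng_seed=0, den=None)
        res = run_ensemble_refinement(model, MINI_REFL, cfg)
        np.testing.assert_allclose(res.rmsf, 0.0, atol=1e-12)
        np.testing.assert_allclose(res.snapshots[-1].positions, model.positions)

    def test_bond_equipartition(self):
        """Thermal variance of one harmonic bond coordinate is kT/(2k)."""
        k_bond = 300.0
        T = 300.0
        model = make_two_atoms()
        geom = GeometryTerms(bond_pairs=np.array([[0, 1]]), bond_ideal=np.array([3.0]),
                             bond_k=k_bond, repulsion_k=0.0)
        cfg = ERConfig(wx=0.0, tx=1.0, steps_per_macrocycle=50, n_macrocycles=400,
                       temperature=T, friction=5.0, burn_in=50, rng_seed=1, den=None)
        res = run_ensemble_refinement(model, MINI_REFL, cfg, geometry=geom)
        d = np.array([np.linalg.norm(s.positions[1] - s.positions[0])
                      for s in res.snapshots])
        expected = KB * T / (2 * k_bond)
        # ~3 standard errors for the autocorrelated sample
        assert abs(d.var() / expected - 1.0) < 0.35

    def test_energy_conservation_microcanonical(self, toy_model):
        """wx=0, no DEN, zero friction and temperature: secular energy drift
        under velocity-Verlet integration stays below 1% over 10^4 steps."""
        rng = np.random.default_rng(3)
        start = toy_model.with_positions(
            toy_model.positions + rng.normal(0, 0.05, (toy_model.n_atoms, 3)))
        cfg = ERConfig(wx=0.0, tx=1.0, steps_per_macrocycle=50, n_macrocycles=200,
                       temperature=0.0, friction=0.0, burn_in=10, rng_seed=0, den=None)
        res = run_ensemble_refinement(start, MINI_REFL, cfg,
                                      geometry=default_geometry(toy_model))
        total = res.energy_history.sum(axis=1)
        # window means average out the aliased shadow-energy oscillation
        drift = abs(total[-50:].mean() - total[:50].mean()) / total[:50].mean()
        assert drift < 0.01

    def test_same_seed_bit_identical(self, standard_fixture):
        cfg = conditions.standard_er_config(n_macrocycles=20, rng_seed=7)
        r1 = run_ensemble_refinement(standard_fixture.mean_model,
                                     standard_fixture.reflections, cfg)
        r2 = run_ensemble_refinement(standard_fixture.mean_model,
                                     standard_fixture.reflections, cfg)
        np.testing.assert_array_equal(r1.r_free_history, r2.r_free_history)
        np.testing.assert_array_equal(r1.snapshots[-1].positions,
                                      r2.snapshots[-1].positions)

    def test_snapshot_count_contract(self, standard_fixture):
        cfg = conditions.standard_er_config(n_macrocycles=30, burn_in=10,
                                            snapshot_interval=4, rng_seed=0)
        res = run_ensemble_refinement(standard_fixture.mean_model,
                                      standard_fixture.reflections, cfg)
        assert len(res.snapshots) == (30 - 10) // 4

    def test_blowup_raises_named_macrocycle(self):
        model = make_two_atoms()
        geom = GeometryTerms(bond_pairs=np.array([[0, 1]]), bond_ideal=np.array([3.0]),
                             bond_k=300.0, repulsion_k=0.0)
        cfg = ERConfig(wx=0.0, tx=1.0, steps_per_macrocycle=50, n_macrocycles=20,
                       temperature=300.0, friction=1.0, timestep=0.5,
                       burn_in=2, rng_seed=0, den=None)
        with pytest.raises(EngineError, match="macrocycle"):
            run_ensemble_refinement(model, MINI_REFL, cfg, geometry=geom)


class TestRMSF:
    def _snapshots(self, positions_list):
        base = make_two_atoms()
        return [base.with_positions(p) for p in positions_list]

    def test_identical_snapshots_zero(self):
        p = make_two_atoms().positions
        assert compute_rmsf(self._snapshots([p, p, p])).max() == 0.0

    def test_two_point_displacement(self):
        p = make_two_atoms().positions
        q = p.copy()
        q[1, 0] += 0.8
        rmsf = compute_rmsf(self._snapshots([p, q]))
        assert rmsf[0] == pytest.approx(0.0)
        assert rmsf[1] == pytest.approx(0.4)  # +-delta/2 about the mean

    def test_isotropic_gaussian_closed_form(self, rng):
        sigma = 0.3
        p = make_two_atoms().positions
        snaps = self._snapshots([p + rng.normal(0, sigma, p.shape) for _ in range(4000)])
        rmsf = compute_rmsf(snaps)
        np.testing.assert_allclose(rmsf, sigma * np.sqrt(3), rtol=0.05)

    def test_insufficient_snapshots_raise(self):
        with pytest.raises(ValueError, match="snapshots"):
            compute_rmsf(self._snapshots([make_two_atoms().positions]))

    def test_b_equivalent_closed_form(self):
        np.testing.assert_allclose(ensemble_b_equivalent(np.array([0.0])), 0.0)
        rmsf = np.sqrt(3 * 0.01)
        assert ensemble_b_equivalent(np.array([rmsf]))[0] == pytest.approx(
            8 * np.pi**2 * 0.01)

    def test_b_equivalent_matches_gaussian_generator(self, rng):
        sigma = 0.25
        p = make_two_atoms().positions
        snaps = self._snapshots([p + rng.normal(0, sigma, p.shape) for _ in range(4000)])
        b = ensemble_b_equivalent(compute_rmsf(snaps))
        np.testing.assert_allclose(b, 8 * np.pi**2 * sigma**2, rtol=0.1)


class TestRestraintPhysics:
    def test_den_preserves_disorder_pattern(self, standard_fixture):
        """DEN restraints stabilize the run without reshaping which atoms
        are mobile: per-atom RMSF ranks agree between DEN-on and DEN-off
        when the simulation has to sample all of the disorder itself."""
        fx = standard_fixture
        results = {}
        for label, den in (("on", conditions.standard_er_config().den), ("off", None)):
            cfg = conditions.standard_er_config(n_macrocycles=100, rng_seed=3, den=den)
            results[label] = run_ensemble_refinement(fx.mean_model, fx.reflections, cfg)
        rho = spearmanr(results["on"].rmsf, results["off"].rmsf).statistic
        assert rho > 0.8

    def test_time_average_escapes_half_occupied_well(self):
        """A two-well coordinate encoded in the amplitudes is sampled on
        both sides under time-averaged restraints, while the memoryless
        target leaves the atom trapped in its starting well."""
        cell = (12.0, 8.0, 8.0)
        xa = np.array([3.0, 4.0, 4.0])
        x1 = np.array([6.5, 4.0, 4.0])
        x2 = np.array([9.5, 4.0, 4.0])

        def model_at(xb):
            return StructureModel([
                AtomRecord(1, "CA", "C", "A", "S1", 1, xa.copy()),
                AtomRecord(2, "CA", "C", "A", "S1", 2, np.array(xb, float)),
            ], cell)

        hkl = [
            (h, k, l)
            for h in range(7) for k in range(5) for l in range(5)
            if (h, k, l) != (0, 0, 0)
            and (h / 12.0) ** 2 + (k / 8.0) ** 2 + (l / 8.0) ** 2 <= 0.25
        ]
        probe = ReflectionSet([ReflectionRecord(h, 1.0, 1.0, False) for h in hkl])
        f_obs = np.abs(0.5 * calc_structure_factors(model_at(x1), probe)
                       + 0.5 * calc_structure_factors(model_at(x2), probe))
        refl = ReflectionSet([
            ReflectionRecord(h, float(f), 1.0, i % 10 == 9)
            for i, (h, f) in enumerate(zip(hkl, f_obs))])
        free_geom = GeometryTerms(bond_pairs=np.zeros((0, 2), dtype=int),
                                  bond_ideal=np.zeros(0), repulsion_k=0.0)

        def occupancy(tx):
            cfg = ERConfig(wx=1.0, tx=tx, steps_per_macrocycle=20, n_macrocycles=300,
                           temperature=40.0, friction=5.0, burn_in=60, rng_seed=0,
                           den=None, xray_energy_scale=100.0)
            res = run_ensemble_refinement(model_at(x1), refl, cfg, geometry=free_geom)
            rel = np.array([s.positions[1, 0] - s.positions[0, 0]
                            for s in res.snapshots])
            mid = 0.5 * ((x1[0] - xa[0]) + (x2[0] - xa[0]))
            return float((rel > mid).mean())

        occ_ta = occupancy(16.0)
        occ_memoryless = occupancy(0.0)
        assert min(occ_memoryless, 1 - occ_memoryless) < 0.2  # trapped
        assert min(occ_ta, 1 - occ_ta) >= 0.2                 # both wells sampled
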