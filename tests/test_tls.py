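import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from microer import conditions
from microer.fixtures import DisorderSpec, generate_fixture
from microer.tls import (
    B_PER_U,
    DisorderLevel,
    DisorderModel,
    TLSError,
    TLSGroup,
    b_iso_from_u,
    combine_levels,
    fit_echt,
    fit_ptls,
    level_contribution,
    u_from_tls,
)


def rigid_body_cov(T, L, S, r, n=200_000, seed=0):
    """Brute-force displacement covariance of u = t + w x r with S = E[w t^T]."""
    rng = np.random.default_rng(seed)
    sigma = np.block([[T, S.T], [S, L]])
    z = rng.multivariate_normal(np.zeros(6), sigma, size=n)
    u = z[:, :3] + np.cross(z[:, 3:], r)
    return (u.T @ u) / n


def random_tls(rng, amplitude=0.1):
    """Random joint-PSD rigid-body moments.

    Returns (T, L, S_raw): the raw screw matrix keeps the 6x6 sampling
    covariance PSD; the trace-free gauge copy for TLSGroup is
    ``S_raw - tr(S_raw)/3 * I`` (U is invariant under that shift).
    """
    joint = rng.normal(scale=amplitude, size=(6, 6))
    sigma = joint @ joint.T
    return sigma[:3, :3], sigma[3:, 3:], sigma[3:, :3]


def gauge_fixed(S):
    return S - np.trace(S) / 3.0 * np.eye(3)


class TestUFromTLS:
    def test_pure_translation_position_independent(self):
        g = TLSGroup(selection=(0,), origin=np.zeros(3), T=0.01 * np.eye(3),
                     L=np.zeros((3, 3)), S=np.zeros((3, 3)))
        for pos in ([0, 0, 0], [5, -3, 2]):
            np.testing.assert_allclose(u_from_tls(g, np.array(pos, float)), 0.01 * np.eye(3))

    def test_libration_matches_rigid_rotation_ensemble(self):
        lam = 0.01
        g = TLSGroup(selection=(0,), origin=np.zeros(3), T=np.zeros((3, 3)),
                     L=np.diag([0.0, 0.0, lam]), S=np.zeros((3, 3)))
        r = np.array([3.0, 0.0, 0.0])
        U = u_from_tls(g, r)
        Umc = rigid_body_cov(np.zeros((3, 3)), np.diag([0.0, 0.0, lam]),
                             np.zeros((3, 3)), r)
        assert np.linalg.norm(U - Umc) / np.linalg.norm(Umc) < 0.05

    @pytest.mark.parametrize("trial", range(5))
    def test_full_tls_matches_rigid_body_oracle(self, trial):
        rng = np.random.default_rng(100 + trial)
        T, L, S_raw = random_tls(rng)
        origin = rng.normal(size=3)
        pos = origin + rng.normal(scale=3.0, size=3)
        g = TLSGroup(selection=(0,), origin=origin, T=T, L=L, S=gauge_fixed(S_raw))
        U = u_from_tls(g, pos)
        Umc = rigid_body_cov(T, L, S_raw, pos - origin, seed=trial)
        assert np.linalg.norm(U - Umc) / np.linalg.norm(Umc) < 0.05

    def test_nonzero_trace_S_rejected(self):
        with pytest.raises(TLSError, match="gauge"):
            TLSGroup(selection=(0,), origin=np.zeros(3), T=np.eye(3) * 0.01,
                     L=np.zeros((3, 3)), S=np.eye(3) * 0.01)

    def test_non_psd_T_rejected(self):
        with pytest.raises(TLSError):
            TLSGroup(selection=(0,), origin=np.zeros(3), T=-0.01 * np.eye(3),
                     L=np.zeros((3, 3)), S=np.zeros((3, 3)))


class TestBIso:
    def test_closed_form(self):
        assert b_iso_from_u(0.01 * np.eye(3)) == pytest.approx(8 * np.pi**2 * 0.01)
        assert b_iso_from_u(np.zeros((3, 3))) == 0.0

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 10_000))
    def test_psd_gives_nonnegative_b(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.normal(size=(3, 3))
        assert b_iso_from_u(A @ A.T) >= 0.0


class TestLevelContribution:
    def test_flat_translation_profile(self, toy_model):
        g = TLSGroup(selection=tuple(range(toy_model.n_atoms)),
                     origin=toy_model.positions.mean(axis=0),
                     T=0.01 * np.eye(3), L=np.zeros((3, 3)), S=np.zeros((3, 3)))
        level = DisorderLevel(level_index=1, label="chain", groups=(g,))
        contrib = level_contribution(level, toy_model)
        np.testing.assert_allclose(contrib, 8 * np.pi**2 * 0.01, rtol=1e-12)

    def test_libration_grows_with_distance_squared(self, toy_model):
        origin = toy_model.positions.mean(axis=0)
        g = TLSGroup(selection=tuple(range(toy_model.n_atoms)), origin=origin,
                     T=np.zeros((3, 3)), L=0.001 * np.eye(3), S=np.zeros((3, 3)))
        level = DisorderLevel(level_index=1, label="chain", groups=(g,))
        contrib = level_contribution(level, toy_model)
        r2 = ((toy_model.positions - origin) ** 2).sum(axis=1)
        # isotropic L: B = (8 pi^2 / 3) * 2 * l * |r|^2 exactly
        np.testing.assert_allclose(contrib, (B_PER_U / 3.0) * 2 * 0.001 * r2, rtol=1e-9)

    def test_missing_coverage_raises(self, toy_model):
        g = TLSGroup(selection=(0, 1), origin=np.zeros(3), T=0.01 * np.eye(3),
                     L=np.zeros((3, 3)), S=np.zeros((3, 3)))
        level = DisorderLevel(level_index=1, label="chain", groups=(g,))
        with pytest.raises(TLSError, match="cover"):
            level_contribution(level, toy_model)


class TestCombineLevels:
    def _two_level_model(self, toy_model, b1, b2):
        sel = tuple(range(toy_model.n_atoms))
        origin = toy_model.positions.mean(axis=0)
        mk = lambda b: TLSGroup(selection=sel, origin=origin,
                                T=(b / B_PER_U) * np.eye(3),
                                L=np.zeros((3, 3)), S=np.zeros((3, 3)))
        return DisorderModel(levels=(
            DisorderLevel(1, "chain", (mk(b1),)),
            DisorderLevel(2, "secondary_structure", (mk(b2),)),
        ))

    def test_flat_levels_add(self, toy_model):
        dm = self._two_level_model(toy_model, 1.0, 0.5)
        np.testing.assert_allclose(combine_levels(dm, toy_model), 1.5)

    def test_exact_additivity_over_subsets(self, toy_model, echt_model, standard_fixture):
        m = standard_fixture.mean_model
        full = combine_levels(echt_model, m, {1, 2, 3})
        parts = sum(combine_levels(echt_model, m, {i}) for i in (1, 2, 3))
        np.testing.assert_array_equal(full, parts)

    def test_empty_subset_is_zero(self, toy_model, echt_model, standard_fixture):
        np.testing.assert_array_equal(
            combine_levels(echt_model, standard_fixture.mean_model, set()), 0.0)

    def test_adding_levels_never_decreases(self, echt_model, standard_fixture):
        m = standard_fixture.mean_model
        prev = combine_levels(echt_model, m, set())
        for subset in ({1}, {1, 2}, {1, 2, 3}):
            cur = combine_levels(echt_model, m, subset)
            assert (cur >= prev - 1e-12).all()
            prev = cur


class TestFitPTLS:
    def test_flat_translation_recovered_everywhere(self, toy_model):
        true_b = 2.0
        model = toy_model.with_b_iso(np.full(toy_model.n_atoms, true_b))
        dm = fit_ptls(model, ptls_fraction=0.9)
        contrib = combine_levels(dm, model)
        np.testing.assert_allclose(contrib, true_b, rtol=0.02)

    def test_overestimates_low_b_core_on_heterogeneous_fixture(
            self, standard_fixture, ptls_model):
        m = standard_fixture.mean_model
        contrib = combine_levels(ptls_model, m)
        b = m.b_iso
        decile = np.argsort(b)[: max(1, m.n_atoms // 10)]
        assert (contrib[decile] > b[decile]).any()

    def test_smaller_fraction_fits_its_subset_better(self, standard_fixture):
        m = standard_fixture.mean_model
        b = m.b_iso

        def subset_mse(frac):
            dm = fit_ptls(m, ptls_fraction=frac)
            contrib = combine_levels(dm, m)
            ca = m.select(lambda a: a.name == "CA")
            order = np.argsort(b[ca], kind="stable")
            keep = ca[order[: max(7, int(round(frac * len(ca))))]]
            return ((contrib[keep] - b[keep]) ** 2).mean()

        assert subset_mse(0.7) <= subset_mse(1.0) + 1e-9

    def test_too_few_marker_atoms_raises(self):
        from microer.fixtures import build_toy_structure
        tiny = build_toy_structure(1, 1, 3, 2, cell=(30, 30, 30))
        with pytest.raises(TLSError, match="marker"):
            fit_ptls(tiny, ptls_fraction=0.9)


class TestFitECHT:
    def test_zero_disorder_gives_zero_amplitudes(self, toy_model):
        dm = fit_echt(toy_model.with_b_iso(np.zeros(toy_model.n_atoms)))
        total = combine_levels(dm, toy_model)
        np.testing.assert_allclose(total, 0.0, atol=1e-12)

    def test_translation_only_lands_on_chain_level(self, toy_model):
        fx = generate_fixture(
            toy_model,
            DisorderSpec(sigma_chain_trans=0.15, n_conformers=500, rng_seed=3),
            d_min=conditions.D_MIN,
        )
        m = fx.mean_model
        dm = fit_echt(m)
        means = {lv.label: level_contribution(lv, m).mean() for lv in dm.levels}
        true_flat = B_PER_U * 0.15**2
        assert means["chain"] == pytest.approx(true_flat, rel=0.10)
        assert means["secondary_structure"] < 0.2
        assert means["residue"] < 0.2

    def test_bound_holds_at_every_atom(self, echt_model, standard_fixture):
        m = standard_fixture.mean_model
        total = combine_levels(echt_model, m)
        assert (total <= m.b_iso + 0.01 + 1e-9).all()

    def test_bound_on_randomized_fixture(self, toy_model):
        rng = np.random.default_rng(7)
        m = toy_model.with_b_iso(rng.uniform(1.0, 20.0, toy_model.n_atoms))
        dm = fit_echt(m)
        assert (combine_levels(dm, m) <= m.b_iso + 0.01 + 1e-9).all()
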