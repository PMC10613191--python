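import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from osteoadapt import defaults
from osteoadapt.constitutive import (
    InvariantSet,
    ModuliSet,
    energy_shares,
    energy_w1,
    energy_w2,
    hyperstress,
    invariants,
    orientation_curvature,
    orientation_torque,
    second_gradient_matrix,
    second_gradient_measures,
    stiffness_matrix,
    stress,
    stress_and_torque,
    structural_vectors,
)
from tests.conftest import random_hessian, random_strain


def total_energy(E, H, psi, p):
    w = energy_w1(invariants(E, psi), p)
    if H is not None:
        w = w + energy_w2(second_gradient_measures(H, psi), p)
    return w


class TestStructuralVectors:
    def test_identity_rotation(self):
        a1, a2 = structural_vectors(0.0)
        np.testing.assert_allclose(a1, [1.0, 0.0], atol=1e-15)
        np.testing.assert_allclose(a2, [0.0, 1.0], atol=1e-15)

    def test_quarter_turn(self):
        a1, a2 = structural_vectors(np.pi / 2)
        np.testing.assert_allclose(a1, [0.0, 1.0], atol=1e-15)
        np.testing.assert_allclose(a2, [-1.0, 0.0], atol=1e-15)

    def test_pi_periodic_energy(self, reference_moduli, rng):
        E = random_strain(rng)
        w0 = energy_w1(invariants(E, 0.3), reference_moduli)
        w_pi = energy_w1(invariants(E, 0.3 + np.pi), reference_moduli)
        assert w0 == pytest.approx(w_pi, rel=1e-12)

    def test_orthonormal(self, rng):
        psi = rng.uniform(-10, 10, size=50)
        a1, a2 = structural_vectors(psi)
        np.testing.assert_allclose(np.einsum("...i,...i->...", a1, a2), 0.0, atol=1e-14)
        np.testing.assert_allclose(np.linalg.norm(a1, axis=-1), 1.0)
        np.testing.assert_allclose(np.linalg.norm(a2, axis=-1), 1.0)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            structural_vectors(np.nan)


class TestInvariants:
    def test_zero_strain(self):
        inv = invariants(np.zeros((2, 2)), 0.4)
        for name in ("J1", "J2", "J4", "J5", "J6", "J7"):
            assert getattr(inv, name) == 0.0

    def test_uniaxial_aligned(self):
        eps = 1e-3
        inv = invariants(np.diag([eps, 0.0]), 0.0)
        assert inv.J1 == pytest.approx(eps)
        assert inv.J2 == pytest.approx(eps**2)
        assert inv.J4 == pytest.approx(eps)
        assert inv.J5 == pytest.approx(eps**2)
        assert inv.J6 == pytest.approx(0.0, abs=1e-18)
        assert inv.J7 == pytest.approx(0.0, abs=1e-18)

    def test_trace_identities_random(self, rng):
        # oracle: A1, A2 orthonormal => J4+J6 = tr E, J5+J7 = tr E^2
        E = random_strain(rng, shape=(200,))
        psi = rng.uniform(0, np.pi, size=200)
        inv = invariants(E, psi)
        np.testing.assert_allclose(inv.J4 + inv.J6, inv.J1, rtol=0, atol=1e-17)
        np.testing.assert_allclose(inv.J5 + inv.J7, inv.J2, rtol=1e-13, atol=1e-22)

    def test_nonsymmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            invariants(np.array([[0.0, 1e-3], [0.0, 0.0]]), 0.0)


class TestEnergyW1:
    def test_zero(self, reference_moduli):
        assert energy_w1(invariants(np.zeros((2, 2)), 0.1), reference_moduli) == 0.0

    def test_uniaxial_reference_value(self, reference_moduli):
        # hand substitution: (K/2 + mu/2 + a1 + 2 mu1 + b1/2) * 1e-6
        w = energy_w1(invariants(np.diag([1e-3, 0.0]), 0.0), reference_moduli)
        assert w == pytest.approx(7.775e3, rel=1e-12)

    def test_isotropic_hydrostatic(self, isotropic_moduli):
        eps = 2e-4
        w = energy_w1(invariants(eps * np.eye(2), 0.7), isotropic_moduli)
        assert w == pytest.approx(0.5 * 10e9 * (2 * eps) ** 2, rel=1e-12)

    def test_positivity_reference_set(self, reference_moduli, rng):
        E = random_strain(rng, shape=(10_000,))
        psi = rng.uniform(0, np.pi, size=10_000)
        w = energy_w1(invariants(E, psi), reference_moduli)
        assert np.all(w >= 0.0)

    def test_quarter_turn_breaks_symmetry(self, reference_moduli):
        # beta1 != beta2 so psi and psi + pi/2 are inequivalent
        E = np.diag([1e-3, 0.0])
        w0 = energy_w1(invariants(E, 0.0), reference_moduli)
        w90 = energy_w1(invariants(E, np.pi / 2), reference_moduli)
        assert abs(w0 - w90) > 1e-6 * w0


class TestEnergyW2:
    def test_affine_zero(self, reference_moduli):
        sg = second_gradient_measures(np.zeros((2, 2, 2)), 0.3)
        assert energy_w2(sg, reference_moduli) == 0.0

    def test_unit_stretch_gradient(self):
        p = ModuliSet(K=1e9, mu=1e9, alpha1=0, alpha2=0, mu1=0, mu2=0,
                      beta1=0, beta2=0, beta3=0, Ks1=1.5, Ks2=0, Kb1=0, Kb2=0)
        from osteoadapt.constitutive import SecondGradientMeasures

        sg = SecondGradientMeasures(s1=1.0, s2=0.0, b1=0.0, b2=0.0)
        assert energy_w2(sg, p) == pytest.approx(0.75)

    def test_switch_off_limit(self, rng):
        p = ModuliSet(**{**ModuliSet.from_gpa(defaults.REFERENCE_MODULI_GPA).as_dict()})
        E, H, psi = random_strain(rng), random_hessian(rng), 0.2
        assert total_energy(E, H, psi, p) == total_energy(E, None, psi, p)

    def test_positivity(self, reference_moduli, rng):
        H = random_hessian(rng, shape=(10_000,))
        psi = rng.uniform(0, np.pi, size=10_000)
        w = energy_w2(second_gradient_measures(H, psi), reference_moduli)
        assert np.all(w >= 0.0)


class TestSecondGradientMeasures:
    def test_quadratic_stretch(self):
        # u1 = x^2/2, u2 = 0: only u1,11 = 1 -> s1 = 1 at psi = 0
        H = np.zeros((2, 2, 2))
        H[0, 0, 0] = 1.0
        sg = second_gradient_measures(H, 0.0)
        assert sg.s1 == pytest.approx(1.0)
        assert sg.s2 == pytest.approx(0.0, abs=1e-15)
        assert sg.b1 == pytest.approx(0.0, abs=1e-15)
        assert sg.b2 == pytest.approx(0.0, abs=1e-15)

    def test_quadratic_bending(self):
        # u2 = x^2/2, u1 = 0: only u2,11 = 1 -> b1 = 1 (A1 fiber bends)
        H = np.zeros((2, 2, 2))
        H[1, 0, 0] = 1.0
        sg = second_gradient_measures(H, 0.0)
        assert sg.b1 == pytest.approx(1.0)
        assert sg.s1 == pytest.approx(0.0, abs=1e-15)

    def test_asymmetric_rejected(self):
        H = np.zeros((2, 2, 2))
        H[0, 0, 1] = 1.0  # H[0,1,0] left zero
        with pytest.raises(ValueError):
            second_gradient_measures(H, 0.0)


class TestDerivatives:
    def test_stress_fd(self, reference_moduli, rng):
        p = reference_moduli
        for _ in range(30):
            E, psi = random_strain(rng), rng.uniform(0, np.pi)
            s = stress(E, psi, p)
            eps = 1e-9
            for i in range(2):
                for j in range(2):
                    dE = np.zeros((2, 2))
                    dE[i, j] += eps / 2
                    dE[j, i] += eps / 2
                    fd = (
                        energy_w1(invariants(E + dE, psi), p)
                        - energy_w1(invariants(E - dE, psi), p)
                    ) / (2 * eps)
                    assert fd == pytest.approx(s[i, j], rel=1e-6, abs=1e-6 * np.abs(s).max())

    def test_hyperstress_fd(self, reference_moduli, rng):
        p = reference_moduli
        for _ in range(30):
            H, psi = random_hessian(rng, scale=1.0), rng.uniform(0, np.pi)
            hs = hyperstress(H, psi, p)
            eps = 1e-7
            scale = max(np.abs(hs).max(), 1e-12)
            for k in range(2):
                for i in range(2):
                    for j in range(2):
                        dH = np.zeros((2, 2, 2))
                        dH[k, i, j] += eps / 2
                        dH[k, j, i] += eps / 2
                        fd = (
                            energy_w2(second_gradient_measures(H + dH, psi), p)
                            - energy_w2(second_gradient_measures(H - dH, psi), p)
                        ) / (2 * eps)
                        assert fd == pytest.approx(hs[k, i, j], rel=1e-6, abs=1e-6 * scale)

    def test_torque_fd(self, reference_moduli, rng):
        p = reference_moduli
        for _ in range(50):
            E = random_strain(rng)
            H = random_hessian(rng)
            psi = rng.uniform(0, np.pi)
            tq = orientation_torque(E, psi, p, H)
            dpsi = 1e-6
            fd = (
                total_energy(E, H, psi + dpsi, p) - total_energy(E, H, psi - dpsi, p)
            ) / (2 * dpsi)
            scale = max(abs(tq), 1e-6 * total_energy(E, H, psi, p))
            assert abs(fd - tq) < 1e-6 * scale + 1e-4

    def test_curvature_fd(self, reference_moduli, rng):
        p = reference_moduli
        for _ in range(50):
            E, psi = random_strain(rng), rng.uniform(0, np.pi)
            c = orientation_curvature(E, psi, p)
            dpsi = 1e-5
            fd = (
                orientation_torque(E, psi + dpsi, p)
                - orientation_torque(E, psi - dpsi, p)
            ) / (2 * dpsi)
            w = energy_w1(invariants(E, psi), p)
            assert abs(fd - c) < 1e-6 * max(abs(c), w)

    def test_isotropic_torque_vanishes(self, isotropic_moduli, rng):
        E = random_strain(rng, shape=(20,))
        psi = rng.uniform(0, np.pi, size=20)
        _, _, tq = stress_and_torque(E, None, psi, isotropic_moduli)
        np.testing.assert_allclose(tq, 0.0, atol=1e-20)

    def test_dilatation_torque_vanishes(self, reference_moduli, rng):
        # w1 depends on psi only through deviatoric projections
        for _ in range(10):
            eps = rng.uniform(1e-4, 1e-3)
            psi = rng.uniform(0, np.pi)
            tq = orientation_torque(eps * np.eye(2), psi, reference_moduli)
            assert tq == pytest.approx(0.0, abs=1e-12)

    def test_eigen_aligned_stationary(self, reference_moduli):
        E = np.diag([1e-3, 0.0])
        for psi in (0.0, np.pi / 2):
            tq = orientation_torque(E, psi, reference_moduli)
            assert tq == pytest.approx(0.0, abs=1e-9)
        # brute-force: w1(psi) is stationary (symmetric) about 0 and pi/2
        delta = np.linspace(1e-4, 1e-2, 32)
        for center in (0.0, np.pi / 2):
            wp = energy_w1(invariants(np.broadcast_to(E, (32, 2, 2)), center + delta), reference_moduli)
            wm = energy_w1(invariants(np.broadcast_to(E, (32, 2, 2)), center - delta), reference_moduli)
            np.testing.assert_allclose(wp, wm, rtol=1e-11)


class TestObjectivity:
    def test_common_rotation_invariance(self, reference_moduli, rng):
        p = reference_moduli
        for _ in range(20):
            E, H = random_strain(rng), random_hessian(rng)
            psi = rng.uniform(0, np.pi)
            phi = rng.uniform(0, 2 * np.pi)
            c, s = np.cos(phi), np.sin(phi)
            R = np.array([[c, -s], [s, c]])
            E_r = R @ E @ R.T
            H_r = np.einsum("ka,pb,qc,abc->kpq", R, R, R, H)
            w = total_energy(E, H, psi, p)
            w_r = total_energy(E_r, H_r, psi + phi, p)
            assert w_r == pytest.approx(w, rel=1e-10)


class TestEnergyShares:
    def test_zero(self, reference_moduli):
        shares = energy_shares(np.zeros((2, 2)), 0.0, reference_moduli)
        assert all(v == 0.0 for v in shares.values())

    def test_dilatation_kills_mu_share(self, reference_moduli):
        shares = energy_shares(1e-3 * np.eye(2), 0.2, reference_moduli)
        assert shares["mu"] == pytest.approx(0.0, abs=1e-9)

    def test_uniaxial_beta_shares(self, reference_moduli):
        shares = energy_shares(np.diag([1e-3, 0.0]), 0.0, reference_moduli)
        assert shares["beta1"] == pytest.approx(1.485e3, rel=1e-12)
        assert shares["beta2"] == pytest.approx(0.0, abs=1e-18)

    def test_shares_nonnegative_and_consistent(self, reference_moduli, rng):
        p = reference_moduli
        E = random_strain(rng, shape=(500,))
        psi = rng.uniform(0, np.pi, size=500)
        shares = energy_shares(E, psi, p)
        assert all(np.all(v >= -1e-20) for v in shares.values())
        # the shares plus the remaining quadratic-form terms rebuild w1
        inv = invariants(E, psi)
        rest = (
            0.5 * p.K * inv.J1**2
            + (p.alpha1 * inv.J4 + p.alpha2 * inv.J6) * inv.J1
            + 2 * p.mu1 * inv.J5
            + 2 * p.mu2 * inv.J7
            + p.beta3 * inv.J4 * inv.J6
        )
        total = shares["mu"] + shares["beta1"] + shares["beta2"] + rest
        np.testing.assert_allclose(total, energy_w1(inv, p), rtol=1e-12)


class TestModuliSet:
    def test_diagonal_coefficients(self, reference_moduli):
        diag = reference_moduli.diagonal_coefficients() / 1e9
        np.testing.assert_allclose(diag, [7.775, 8.885, 9.04], rtol=1e-12)

    def test_positive_definite(self, reference_moduli):
        eigs = reference_moduli.check_positive_definite()
        assert np.all(eigs > 0)

    def test_inadmissible_rejected(self):
        bad = dict(defaults.REFERENCE_MODULI_GPA)
        bad["beta3"] = 50.0  # overwhelms the diagonal
        with pytest.raises(ValueError, match="positive definite"):
            ModuliSet.from_gpa(bad)

    def test_negative_base_moduli_rejected(self):
        with pytest.raises(ValueError):
            ModuliSet(K=-1.0, mu=1.0, alpha1=0, alpha2=0, mu1=0, mu2=0,
                      beta1=0, beta2=0, beta3=0)

    def test_evolving_subset(self, reference_moduli):
        assert reference_moduli.evolving == ("mu", "beta1", "beta2")

    def test_matrix_builders_match_energy(self, reference_moduli, rng):
        p = reference_moduli
        psi = rng.uniform(0, np.pi)
        Q = stiffness_matrix(psi, p)
        D = second_gradient_matrix(psi, p)
        E = random_strain(rng)
        H = random_hessian(rng)
        e = np.array([E[0, 0], E[1, 1], E[0, 1]])
        h = np.array([H[0, 0, 0], H[0, 1, 1], H[0, 0, 1],
                      H[1, 0, 0], H[1, 1, 1], H[1, 0, 1]])
        assert 0.5 * e @ Q @ e == pytest.approx(
            energy_w1(invariants(E, psi), p), rel=1e-12
        )
        assert 0.5 * h @ D @ h == pytest.approx(
            energy_w2(second_gradient_measures(H, psi), p), rel=1e-12
        )


@settings(max_examples=50, deadline=None)
@given(
    psi=st.floats(-6.0, 6.0),
    e11=st.floats(-1e-2, 1e-2),
    e22=st.floats(-1e-2, 1e-2),
    e12=st.floats(-1e-2, 1e-2),
)
def test_invariant_identities_property(psi, e11, e22, e12):
    E = np.array([[e11, e12], [e12, e22]])
    inv = invariants(E, psi)
    assert inv.J4 + inv.J6 == pytest.approx(inv.J1, abs=1e-15)
    assert inv.J5 + inv.J7 == pytest.approx(inv.J2, abs=1e-15)
    assert inv.J2 >= inv.J1**2 / 2 - 1e-15
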