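"""Orthotropic Fung constitutive law: energies, stresses, tangent."""

import numpy as np
import pytest

from cardiogrowth.errors import FrameError, InvertedElementError, ParameterError
from cardiogrowth.fibers import FiberFrame
from cardiogrowth.growth import longitudinal_growth_tensor, transverse_growth_tensor
from cardiogrowth.materials import (
    MaterialParameters,
    fung_energy,
    material_tangent,
    scale_weights,
    second_pk_from_C,
    stresses,
    volumetric_energy,
    volumetric_jacobian_from_pressure,
)

from .helpers import random_deformation, random_rotation, random_unit_vectors


class TestScaleWeights:
    def test_healthy_human_table(self):
        """The two-parameter scaling at B0 = 14.4 reproduces the published
        healthy-human weight table."""
        p = scale_weights(0.115, 14.4)
        assert p.Bff == pytest.approx(14.4)
        assert p.Bss == pytest.approx(5.76)
        assert p.Bnn == pytest.approx(5.76)
        assert p.Bfs == pytest.approx(5.04)
        assert p.Bfn == pytest.approx(5.04)
        assert p.Bsn == pytest.approx(2.88)
        assert p.C0 == pytest.approx(0.115)
        assert p.D0 == pytest.approx(0.001)

    @pytest.mark.parametrize(
        "B0, Bss, Bsn, Bfs",
        [(0.0, 0.0, 0.0, 0.0), (10.0, 4.0, 2.0, 3.5)],
    )
    def test_stated_ratios(self, B0, Bss, Bsn, Bfs):
        p = scale_weights(1.0, B0)
        assert p.Bss == pytest.approx(Bss)
        assert p.Bsn == pytest.approx(Bsn)
        assert p.Bfs == pytest.approx(Bfs)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ParameterError):
            scale_weights(-1.0, 14.4)
        with pytest.raises(ParameterError):
            MaterialParameters(C0=1.0, D0=0.001, Bff=-1, Bss=0, Bnn=0, Bfs=0, Bfn=0, Bsn=0)


class TestVolumetricEnergy:
    def test_stationary_at_unit_jacobian(self, cardiac_params):
        U, dU, d2U = volumetric_energy(1.0, cardiac_params)
        assert dU == pytest.approx(0.0, abs=1e-14)
        assert U == pytest.approx(0.5 / cardiac_params.D0)  # energy offset
        assert d2U > 0

    def test_formula_oracle(self):
        """Direct second-path evaluation at Je = 1.1, D0 = 0.001."""
        p = scale_weights(1.0, 1.0, D0=0.001)
        U, dU, d2U = volumetric_energy(1.1, p)
        assert U == pytest.approx((1.1**2 - 2 * np.log(1.1)) / (2 * 0.001))
        h = 1e-5
        Uf = lambda J: (J**2 - 2 * np.log(J)) / (2 * 0.001)
        assert dU == pytest.approx((Uf(1.1 + h) - Uf(1.1 - h)) / (2 * h), rel=1e-8)
        assert d2U == pytest.approx((Uf(1.1 + h) - 2 * Uf(1.1) + Uf(1.1 - h)) / h**2, rel=1e-4)

    def test_nonpositive_jacobian_rejected(self, cardiac_params):
        with pytest.raises(InvertedElementError):
            volumetric_energy(0.0, cardiac_params)

    def test_pressure_inversion_roundtrip(self, cardiac_params):
        J = np.array([0.9, 0.999, 1.0, 1.001, 1.2])
        _, p, _ = volumetric_energy(J, cardiac_params)
        J2, dJdp = volumetric_jacobian_from_pressure(p, cardiac_params)
        np.testing.assert_allclose(J2, J, rtol=1e-12)
        assert np.all(dJdp > 0)


class TestFungEnergy:
    def test_zero_strain_zero_energy(self, cardiac_params, axis_frame):
        assert fung_energy(np.zeros((3, 3)), axis_frame, cardiac_params) == 0.0

    def test_rank_one_fiber_strain_closed_form(self, cardiac_params, axis_frame):
        """A single fiber-fiber strain entry e gives
        psi = C0/2 [exp(Bff e^2) - 1] in scalar closed form."""
        e = 0.08
        E = np.zeros((3, 3))
        E[0, 0] = e
        psi = fung_energy(E, axis_frame, cardiac_params)
        expected = 0.5 * cardiac_params.C0 * np.expm1(cardiac_params.Bff * e**2)
        assert psi == pytest.approx(expected, rel=1e-12)

    def test_small_strain_quadratic_limit(self, cardiac_params, axis_frame, rng):
        """psi -> C0/2 (E:B:E) with relative error O(||E||^2) at ||E||=1e-4."""
        E = 1e-4 * rng.standard_normal((3, 3))
        E = 0.5 * (E + E.T)
        psi = fung_energy(E, axis_frame, cardiac_params)
        W = cardiac_params.weight_matrix()
        quad = 0.5 * cardiac_params.C0 * np.sum(W * E**2)
        assert psi == pytest.approx(quad, rel=1e-6)

    def test_non_orthonormal_frame_rejected(self, cardiac_params):
        bad = FiberFrame(
            f0=np.array([1.0, 0.0, 0.0]),
            s0=np.array([0.1, 1.0, 0.0]),
            n0=np.array([0.0, 0.0, 1.0]),
        )
        with pytest.raises(FrameError):
            fung_energy(np.zeros((3, 3)), bad, cardiac_params)

    def test_objectivity(self, cardiac_params, rng):
        """psi is invariant under simultaneous rotation of the strain state
        and the material frame."""
        f0 = random_unit_vectors(rng)
        s0 = np.cross(f0, random_unit_vectors(rng))
        s0 /= np.linalg.norm(s0)
        frame = FiberFrame.from_fiber_sheet(f0, s0)
        E = 0.1 * rng.standard_normal((3, 3))
        E = 0.5 * (E + E.T)
        psi0 = fung_energy(E, frame, cardiac_params)
        R = random_rotation(rng)
        framer = FiberFrame.from_fiber_sheet(R @ f0, R @ s0)
        psir = fung_energy(R @ E @ R.T, framer, cardiac_params)
        assert psir == pytest.approx(psi0, abs=1e-10 * max(1, abs(psi0)))


def _random_state(rng, scale=0.15):
    F = random_deformation(rng, scale=scale)
    f0 = random_unit_vectors(rng)
    s0 = np.cross(f0, random_unit_vectors(rng))
    s0 /= np.linalg.norm(s0)
    frame = FiberFrame.from_fiber_sheet(f0, s0)
    theta = rng.uniform(0.9, 1.3)
    mode = rng.choice(["transverse", "longitudinal"])
    if mode == "transverse":
        Fg = transverse_growth_tensor(np.array(theta), f0)
    else:
        Fg = longitudinal_growth_tensor(np.array(theta), f0)
    return F, Fg, frame


class TestStresses:
    def test_zero_stress_at_fully_grown_state(self, cardiac_params, rng):
        """F = Fg leaves no elastic strain: S vanishes identically."""
        for _ in range(10):
            _, Fg, frame = _random_state(rng)
            res = stresses(Fg, Fg, frame, cardiac_params)
            # the volumetric penalty amplifies Je roundoff by 1/D0 = 1000,
            # so "identically zero" means zero at the 1e-11 kPa level
            np.testing.assert_allclose(res.S, 0.0, atol=1e-11)
            np.testing.assert_allclose(res.sigma, 0.0, atol=1e-11)

    def test_symmetry(self, cardiac_params, rng):
        F, Fg, frame = _random_state(rng)
        res = stresses(F, Fg, frame, cardiac_params)
        for T in (res.S, res.Se, res.sigma):
            np.testing.assert_allclose(T, T.T, atol=1e-10 * max(1.0, np.abs(T).max()))

    def test_energy_consistency_fd(self, cardiac_params, rng):
        """S equals the central finite difference of the strain energy with
        respect to E, within 1e-6 relative, over 100 random states."""
        Qr = lambda fr: fr.rotation()
        for _ in range(100):
            F, Fg, frame = _random_state(rng)
            C = F.T @ F
            S = second_pk_from_C(C, Fg, Qr(frame), cardiac_params)
            d = rng.standard_normal((3, 3))
            d = 0.5 * (d + d.T)
            h = 1e-6
            _, _, pp = second_pk_from_C(C + 2 * h * d, Fg, Qr(frame), cardiac_params, with_energy=True)
            _, _, pm = second_pk_from_C(C - 2 * h * d, Fg, Qr(frame), cardiac_params, with_energy=True)
            num = (pp - pm) / (2 * h)
            ana = np.sum(S * d)
            assert num == pytest.approx(ana, rel=1e-6, abs=1e-12)

    def test_growth_pullback_identity(self, cardiac_params, rng):
        """S(F, Fg) == Fg^-1 Se Fg^-T with Se evaluated on Fe."""
        F, Fg, frame = _random_state(rng)
        res = stresses(F, Fg, frame, cardiac_params)
        pulled = np.linalg.inv(Fg) @ res.Se @ np.linalg.inv(Fg).T
        np.testing.assert_allclose(res.S, pulled, rtol=1e-10, atol=1e-13)

    def test_uniaxial_fiber_stress_monotone(self, cardiac_params, axis_frame):
        """Fiber-direction Cauchy stress grows strictly with fiber stretch."""
        lams = np.linspace(1.01, 1.3, 12)
        sig = [
            stresses(np.diag([lam, 1.0, 1.0]), np.eye(3), axis_frame, cardiac_params).sigma[0, 0]
            for lam in lams
        ]
        assert sig[0] > 0
        assert np.all(np.diff(sig) > 0)

    def test_objectivity_under_rotation(self, cardiac_params, rng):
        """psi(R F) = psi(F); sigma rotates as R sigma R^T."""
        F, Fg, frame = _random_state(rng)
        R = random_rotation(rng)
        a = stresses(F, Fg, frame, cardiac_params)
        b = stresses(R @ F, Fg, frame, cardiac_params)
        assert b.psi == pytest.approx(a.psi, rel=1e-10)
        np.testing.assert_allclose(b.sigma, R @ a.sigma @ R.T, atol=1e-10 * max(1, np.abs(a.sigma).max()))


class TestMaterialTangent:
    def test_directional_fd(self, cardiac_params, rng):
        """Tangent contraction with dE matches the directional finite
        difference of S within 1e-5 relative."""
        for _ in range(10):
            F, Fg, frame = _random_state(rng)
            C = F.T @ F
            Q = frame.rotation()
            CC = material_tangent(C, Fg, Q, cardiac_params)
            d = rng.standard_normal((3, 3))
            d = 0.5 * (d + d.T)
            h = 1e-6
            Sp = second_pk_from_C(C + 2 * h * d, Fg, Q, cardiac_params)
            Sm = second_pk_from_C(C - 2 * h * d, Fg, Q, cardiac_params)
            num = (Sp - Sm) / (2 * h)
            ana = np.einsum("ijkl,kl->ij", CC, d)
            np.testing.assert_allclose(ana, num, rtol=1e-5, atol=1e-7 * np.abs(num).max())

    def test_minor_symmetries(self, cardiac_params, rng):
        F, Fg, frame = _random_state(rng)
        CC = material_tangent(F.T @ F, Fg, frame.rotation(), cardiac_params)
        np.testing.assert_allclose(CC, np.swapaxes(CC, 0, 1), atol=1e-8 * np.abs(CC).max())
        np.testing.assert_allclose(CC, np.swapaxes(CC, 2, 3), atol=1e-8 * np.abs(CC).max())

    def test_linearity_in_C0(self, rng, axis_frame):
        """Doubling C0 doubles the isochoric tangent at fixed strain."""
        p1 = scale_weights(1.0, 5.0)
        p2 = scale_weights(2.0, 5.0)
        F = random_deformation(rng)
        C = F.T @ F
        Q = axis_frame.rotation()
        CC1 = material_tangent(C, np.eye(3), Q, p1, include_volumetric=False)
        CC2 = material_tangent(C, np.eye(3), Q, p2, include_volumetric=False)
        np.testing.assert_allclose(CC2, 2 * CC1, rtol=1e-9, atol=1e-10 * np.abs(CC1).max())

    def test_cubic_symmetry_at_identity_isotropic(self, isotropic_params, axis_frame):
        """With all weights equal and zero strain the tangent is isotropic:
        invariant under axis permutations."""
        CC = material_tangent(np.eye(3), np.eye(3), axis_frame.rotation(), isotropic_params)
        perm = [1, 2, 0]
        CCp = CC[perm][:, perm][:, :, perm][:, :, :, perm]
        np.testing.assert_allclose(CCp, CC, atol=1e-8 * np.abs(CC).max())
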