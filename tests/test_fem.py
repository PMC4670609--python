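"""Finite-element core: assembly, follower pressure, Newton, growth loop."""

import numpy as np
import pytest

from cardiogrowth.errors import ConfigError, SolverError
from cardiogrowth.fem import (
    MMHG_TO_KPA,
    DirichletBC,
    FEModel,
    SolverSettings,
    TangentCache,
    newton_solve,
    ramp_solve,
    staggered_growth_step,
)
from cardiogrowth.fibers import FiberFrame
from cardiogrowth.geometry import LVGeometryParams, make_box, make_ellipsoid_lv
from cardiogrowth.growth import GrowthState
from cardiogrowth.materials import second_pk_from_C, stresses

from .helpers import random_rotation


def uniform_frames(n):
    return FiberFrame.from_fiber_sheet(
        np.tile([1.0, 0.0, 0.0], (n, 1)), np.tile([0.0, 1.0, 0.0], (n, 1))
    )


@pytest.fixture(scope="module", params=[1, 2], ids=["linear", "quadratic"])
def box_model(request, soft_params):
    mesh = make_box((1.0, 1.0, 1.0), (2, 2, 2), order=request.param)
    return FEModel(mesh, soft_params, uniform_frames(mesh.n_elements))


class TestAssembly:
    def test_stress_free_reference(self, box_model):
        """Zero displacement, zero pressure: residual vanishes."""
        Fg = box_model.growth_tensors(None)
        R, c, _ = box_model.residual(np.zeros(box_model.ndof), Fg, {})
        assert np.abs(R).max() < 1e-12
        assert np.abs(c).max() < 1e-14

    def test_tangent_matches_fd_of_residual(self, box_model, rng):
        """Directional derivative of the residual (including follower
        pressure) matches the assembled tangent within 1e-4 relative."""
        Fg = box_model.growth_tensors(None)
        u = 0.02 * rng.standard_normal(box_model.ndof)
        press = {"xmin": 0.1}
        R0, K, free, fext, c0, aux = box_model.assemble(u, Fg, press, DirichletBC.empty())
        h = 1e-6
        for _ in range(3):
            d = rng.standard_normal(box_model.ndof)
            d /= np.linalg.norm(d)
            Rp, _, _ = box_model.residual(u + h * d, Fg, press)
            Rm, _, _ = box_model.residual(u - h * d, Fg, press)
            num = (Rp - Rm) / (2 * h)
            np.testing.assert_allclose(K @ d, num, atol=1e-4 * np.abs(num).max())

    def test_integration_point_stress_matches_material_point(self, box_model, soft_params):
        """Affine displacement: every quadrature point carries exactly the
        homogeneous material-point stress."""
        A = np.array([[0.04, 0.01, 0.0], [0.0, -0.02, 0.015], [0.0, 0.0, 0.03]])
        mesh = box_model.mesh
        u = (mesh.nodes @ A.T).ravel()
        F = np.eye(3) + A
        Fg = box_model.growth_tensors(None)
        frame = uniform_frames(1)[0]
        S_ref = stresses(F, np.eye(3), frame, soft_params).S
        Fq = box_model.deformation_gradients(u).reshape(-1, 3, 3)
        C = np.swapaxes(Fq, -1, -2) @ Fq
        Sq = second_pk_from_C(C, Fg, box_model.Qrot, soft_params)
        np.testing.assert_allclose(Sq, np.broadcast_to(S_ref, Sq.shape), rtol=1e-10, atol=1e-12)


class TestFollowerPressure:
    def test_zero_pressure_zero_force(self, box_model):
        f, _ = box_model.pressure_forces(np.zeros(box_model.ndof), "xmin", 0.0)
        assert np.abs(f).max() == 0.0

    def test_flat_face_total_force(self, box_model):
        """Unit pressure on the unit xmin face: total force = area x p,
        directed into the solid (+x)."""
        f, _ = box_model.pressure_forces(np.zeros(box_model.ndof), "xmin", 1.0, tangent=False)
        np.testing.assert_allclose(f.reshape(-1, 3).sum(axis=0), [1.0, 0.0, 0.0], atol=1e-12)

    def test_closed_surface_zero_resultant(self, isotropic_params):
        """Pressure on a closed deformed surface has zero net resultant.

        The hemispherical endocardium plus the flat cap over its (held)
        basal ring form a closed surface, so the endocardial follower-load
        resultant must equal exactly minus the analytic cap contribution
        ``p * A_ring * z`` even on a randomly deformed dome."""
        p = LVGeometryParams(a_endo=10.0, b_endo=10.0, t_equator=4.0, t_apex=4.0,
                             truncation=0.0, target_edge=3.0)
        mesh = make_ellipsoid_lv(p, order=2, resolution=(6, 12, 2))
        ring = np.asarray(mesh.node_sets["basal_ring_endo"])
        model = FEModel(mesh, isotropic_params, uniform_frames(mesh.n_elements))
        rngloc = np.random.default_rng(7)
        u = 0.05 * rngloc.standard_normal(model.ndof)
        for comp in range(3):
            u[3 * ring + comp] = 0.0  # hold the ring: the cap stays flat
        f_endo, _ = model.pressure_forces(u, "endocardium_lv", 1.0, tangent=False)
        resultant = f_endo.reshape(-1, 3).sum(axis=0)
        x = mesh.nodes[ring[::2]]  # polygon through the ring corners
        nxt = np.roll(x, -1, axis=0)
        area = 0.5 * np.abs((x[:, 0] * nxt[:, 1] - x[:, 1] * nxt[:, 0]).sum())
        scale = np.abs(f_endo).sum()
        np.testing.assert_allclose(resultant, [0.0, 0.0, -area], atol=1e-8 * scale)

    def test_missing_tag_raises(self, box_model):
        with pytest.raises(ConfigError):
            box_model.pressure_forces(np.zeros(box_model.ndof), "nope", 1.0)


class TestNewton:
    def test_zero_load_converges_immediately(self, box_model):
        Fg = box_model.growth_tensors(None)
        u, info = newton_solve(box_model, np.zeros(box_model.ndof), Fg, {}, DirichletBC.fix(
            box_model.mesh.node_sets["boundary"], [0, 1, 2]))
        assert info["iterations"] == 0
        assert np.abs(u).max() == 0.0

    def test_patch_affine_dirichlet(self, soft_params):
        """Affine Dirichlet data on the boundary reproduces the homogeneous
        solution at interior nodes to 1e-8 (quadratic elements)."""
        mesh = make_box((1.0, 1.0, 1.0), (2, 2, 2), order=2)
        model = FEModel(mesh, soft_params, uniform_frames(mesh.n_elements))
        A = np.array([[0.05, 0.02, 0.0], [0.0, -0.03, 0.01], [0.0, 0.0, 0.04]])
        bn = mesh.node_sets["boundary"]
        bc = DirichletBC.from_displacement(bn, mesh.nodes[bn] @ A.T)
        Fg = model.growth_tensors(None)
        u, info = newton_solve(model, np.zeros(model.ndof), Fg, {}, bc)
        assert np.abs(u - (mesh.nodes @ A.T).ravel()).max() < 1e-8

    def test_superlinear_terminal_convergence(self, soft_params):
        """Near the solution the full Newton iteration contracts faster
        than linearly: the last step reduces the residual by > 100x."""
        mesh = make_box((1.0, 1.0, 1.0), (2, 2, 2), order=2)
        model = FEModel(mesh, soft_params, uniform_frames(mesh.n_elements))
        bc = DirichletBC.fix(mesh.node_sets["boundary"][:8], [0, 1, 2])
        bc = DirichletBC.fix(np.unique(mesh.facets["xmax"]), [0, 1, 2])
        Fg = model.growth_tensors(None)
        u, info = newton_solve(model, np.zeros(model.ndof), Fg, {"xmin": 0.3}, bc,
                               SolverSettings(newton_max_iter=30))
        r = info["residuals"]
        assert r[-1] < 1e-2 * r[-2]

    def test_objectivity_of_the_discrete_solution(self, isotropic_params):
        """Rotating the mesh rotates the solution: solve a pressurized box
        in two orientations and compare rotated displacements to 1e-8."""
        mesh = make_box((1.0, 1.0, 1.0), (2, 2, 2), order=2)
        model = FEModel(mesh, isotropic_params, uniform_frames(mesh.n_elements))
        fixed = np.unique(mesh.facets["xmax"])
        bc = DirichletBC.fix(fixed, [0, 1, 2])
        Fg = model.growth_tensors(None)
        u1, _ = newton_solve(model, np.zeros(model.ndof), Fg, {"xmin": 0.4}, bc)

        R = random_rotation(np.random.default_rng(11))
        mesh2 = make_box((1.0, 1.0, 1.0), (2, 2, 2), order=2)
        mesh2.nodes = mesh2.nodes @ R.T
        fr = uniform_frames(mesh2.n_elements)
        fr2 = FiberFrame.from_fiber_sheet(fr.f0 @ R.T, fr.s0 @ R.T)
        model2 = FEModel(mesh2, isotropic_params, fr2)
        u2, _ = newton_solve(model2, np.zeros(model2.ndof), Fg, {"xmin": 0.4}, bc)
        np.testing.assert_allclose(
            u2.reshape(-1, 3), u1.reshape(-1, 3) @ R.T, atol=1e-8
        )

    def test_nonconvergence_raises_with_history(self, soft_params):
        mesh = make_box(order=1)
        model = FEModel(mesh, soft_params, uniform_frames(mesh.n_elements))
        bc = DirichletBC.fix(np.unique(mesh.facets["xmax"]), [0, 1, 2])
        Fg = model.growth_tensors(None)
        with pytest.raises((SolverError, Exception)):
            newton_solve(model, np.zeros(model.ndof), Fg, {"xmin": 500.0}, bc,
                         SolverSettings(newton_max_iter=3, ramp_steps=1))


class TestEnergyAndRamp:
    def test_energy_monotone_under_monotone_stretch(self, box_model, soft_params):
        """Total strain energy is non-decreasing under monotonically
        increasing displacement-controlled uniaxial stretch."""
        Fg = box_model.growth_tensors(None)
        mesh = box_model.mesh
        energies = []
        for lam in (1.0, 1.05, 1.1, 1.15):
            A = np.diag([lam - 1.0, 0.0, 0.0])
            u = (mesh.nodes @ A.T).ravel()
            energies.append(box_model.total_strain_energy(u, Fg))
        assert np.all(np.diff(energies) >= -1e-12)

    def test_ramp_reaches_target(self, isotropic_params):
        mesh = make_box((1.0, 1.0, 1.0), (2, 2, 2), order=2)
        model = FEModel(mesh, isotropic_params, uniform_frames(mesh.n_elements))
        bc = DirichletBC.fix(np.unique(mesh.facets["xmax"]), [0, 1, 2])
        Fg = model.growth_tensors(None)
        cache = TangentCache()
        u, info = ramp_solve(model, np.zeros(model.ndof), Fg, {}, {"xmin": 0.8}, bc,
                             SolverSettings(), cache=cache)
        R, c, _ = model.residual(u, Fg, {"xmin": 0.8})
        free = np.ones(model.ndof, bool)
        free[bc.dofs] = False
        assert np.linalg.norm(R[free]) < 1e-6


class TestStaggeredGrowth:
    @pytest.fixture()
    def loaded_box(self, soft_params):
        mesh = make_box((1.0, 1.0, 1.0), (1, 1, 1), order=2)
        model = FEModel(mesh, soft_params, uniform_frames(mesh.n_elements))
        bc = DirichletBC.fix(np.unique(mesh.facets["xmax"]), [0, 1, 2])
        return model, bc

    def test_fixed_point_below_threshold(self, loaded_box):
        """All stretches at or below threshold: the staggered step is the
        identity on the growth state."""
        model, bc = loaded_box
        gstate = model.initial_growth_state("transverse")
        gstate = gstate.calibrated(np.full(model.n_points, 2.0))  # huge threshold
        u = np.zeros(model.ndof)
        u2, g2, stats = staggered_growth_step(model, u, gstate, {"xmin": 0.2}, bc)
        assert stats["max_dtheta"] == 0.0
        np.testing.assert_array_equal(g2.theta, gstate.theta)

    def test_matches_scalar_recurrence_displacement_controlled(self, loaded_box):
        """Single element under constant affine overload stretch: the theta
        sequence equals the scalar recurrence computed independently."""
        model, bc = loaded_box
        mesh = model.mesh
        lam_hold = 1.12
        A = np.diag([lam_hold - 1.0, 0.0, 0.0])
        bn = np.unique(np.concatenate([f.ravel() for f in mesh.facets.values()]))
        bc_all = DirichletBC.from_displacement(bn, mesh.nodes[bn] @ A.T)
        crit = 1.05
        gstate = model.initial_growth_state("longitudinal", tau=2.0)
        gstate = gstate.calibrated(np.full(model.n_points, crit))
        dt = 0.1
        settings = SolverSettings(growth_dt=dt)
        # establish the overload equilibrium before the growth loop
        u, _ = newton_solve(model, np.zeros(model.ndof),
                            model.growth_tensors(gstate), {}, bc_all, settings)
        thetas = []
        for _ in range(5):
            u, gstate, stats = staggered_growth_step(model, u, gstate, {}, bc_all, settings)
            thetas.append(gstate.theta.copy())
        # independent scalar recurrence: lambda stays the total stretch of
        # the prescribed affine map, independent of growth
        theta_ref = 1.0
        for k in range(5):
            theta_ref = theta_ref + max(lam_hold - crit, 0.0) * dt / 2.0
            np.testing.assert_allclose(thetas[k], theta_ref, atol=1e-9)

    def test_step_increment_bound(self, loaded_box):
        """max dtheta per step never exceeds max<lam - crit> dt / tau."""
        model, bc = loaded_box
        gstate = model.initial_growth_state("transverse", tau=1.0)
        gstate = gstate.calibrated(np.full(model.n_points, 1.0))
        u = np.zeros(model.ndof)
        settings = SolverSettings(growth_dt=0.2)
        u, g2, stats = staggered_growth_step(model, u, gstate, {"xmin": 0.3}, bc, settings)
        assert stats["max_dtheta"] <= stats["max_excess"] * 0.2 / gstate.tau + 1e-15

    def test_idempotent_when_growth_disabled(self, loaded_box):
        """With the growth mask all False the staggered loop leaves both the
        growth field and the equilibrium untouched."""
        model, bc = loaded_box
        gstate = model.initial_growth_state("transverse")
        gstate.mask = np.zeros(model.n_points, dtype=bool)
        u = np.zeros(model.ndof)
        u1, g1, _ = staggered_growth_step(model, u, gstate, {"xmin": 0.2}, bc)
        u2, g2, _ = staggered_growth_step(model, u1, g1, {"xmin": 0.2}, bc)
        np.testing.assert_array_equal(g1.theta, g2.theta)
        np.testing.assert_allclose(u1, u2, atol=1e-12)
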