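"""Quasi-static nonlinear finite elements for growing myocardium.

Total-Lagrangian displacement formulation on linear or quadratic
tetrahedra.  Internal forces derive from the second Piola-Kirchhoff stress
of the grown Fung material; the consistent tangent combines the geometric
stiffness with the finite-difference material tangent
(:func:`cardiogrowth.materials.material_tangent`).  Cavity pressures are
follower loads: they act on the deformed endocardial facets along the
current normal, and their configuration dependence enters the tangent (the
load-stiffness term), which makes the Newton iteration converge
superlinearly even at large inflation.

Units: lengths mm, stresses/pressures kPa (inputs in mmHg are converted by
the scenario layer at 1 mmHg = 0.1333224 kPa), forces mN.

The staggered growth loop alternates global equilibrium at frozen growth
with a pointwise explicit update of the growth multiplier driven by the
converged fiber stretch — growth is so much slower than elasticity that
the tissue is always in quasi-static equilibrium.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .elements import tet_quadrature, tet_shape, tri_quadrature, tri_shape
from .errors import (
    ConfigError,
    GeometryError,
    InvertedElementError,
    SolverError,
    StepRejected,
)
from .fibers import FiberFrame
from .growth import GrowthState, fiber_stretch
from .materials import (
    MaterialParameters,
    material_tangent,
    second_pk_from_C,
    volumetric_energy,
    volumetric_jacobian_from_pressure,
)
from .mesh import VentricularMesh
from .tensors import _I3, det3, inv3

logger = logging.getLogger(__name__)

__all__ = [
    "SolverSettings",
    "DirichletBC",
    "FEModel",
    "TangentCache",
    "newton_solve",
    "ramp_solve",
    "staggered_growth_step",
    "MMHG_TO_KPA",
]

MMHG_TO_KPA = 0.1333224

_EPS = np.zeros((3, 3, 3))
for _i, _j, _k in ((0, 1, 2), (1, 2, 0), (2, 0, 1)):
    _EPS[_i, _j, _k] = 1.0
    _EPS[_i, _k, _j] = -1.0

# Voigt slots (N, L) with engineering shear ordering 11,22,33,12,13,23
_VOIGT = ((0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2))


@dataclass
class SolverSettings:
    """Newton / load-stepping controls.

    newton_tol : relative residual tolerance (w.r.t. the external/internal
        force scale).
    newton_abs_tol : absolute fallback (mN), used at zero load.
    ramp_steps : initial number of equal pressure increments; increments are
        halved automatically on Newton failure down to ``min_step_fraction``.
    """

    newton_tol: float = 1e-9
    newton_abs_tol: float = 1e-9
    newton_max_iter: int = 25
    #: optional relative-residual floor at which an iteration that ran out
    #: of iterations is still accepted (with a "stalled" flag) instead of
    #: failing; used by the organ-scale scenarios to ride through local
    #: wrinkling instabilities of the collapsing late growth phase.  None
    #: (the default) keeps strict behavior.
    stall_accept_tol: Optional[float] = None
    #: proximal stabilization factor: each load/growth step minimizes the
    #: potential plus ``mu/2 ||u - u_start||^2`` with ``mu`` equal to this
    #: factor times the median diagonal tangent stiffness.  Zero (default)
    #: is the unmodified quasi-static problem; small values (~1e-4) select
    #: the nearest equilibrium branch and suppress the flapping of
    #: mesh-scale wrinkling modes that coarse meshes cannot resolve.
    stabilization: float = 0.0
    ramp_steps: int = 4
    min_step_fraction: float = 1.0 / 64.0
    growth_dt: float = 0.2
    growth_steps: int = 40
    #: minimum per-iteration residual contraction before the reused LU is
    #: declared stale and the consistent tangent is refactored
    reuse_contraction: float = 0.2
    #: stagnation-driven refactorizations allowed per solve when an LU
    #: cache is reused; beyond this the (expensive) fresh tangent is known
    #: not to help and the old factorization is kept
    max_stagnant_refactors: int = 6
    #: backtracking halvings before a Newton step is declared unusable
    max_line_search: int = 8

    def __post_init__(self):
        if self.newton_tol <= 0 or self.newton_abs_tol <= 0:
            raise ConfigError("tolerances must be positive")


@dataclass
class DirichletBC:
    """Essential boundary conditions as global dof indices and values."""

    dofs: np.ndarray
    values: np.ndarray

    @classmethod
    def empty(cls) -> "DirichletBC":
        return cls(np.empty(0, dtype=np.int64), np.empty(0))

    @classmethod
    def fix(cls, node_ids: Sequence[int], components: Sequence[int], value: float = 0.0) -> "DirichletBC":
        node_ids = np.asarray(node_ids, dtype=np.int64)
        dofs = np.concatenate([3 * node_ids + c for c in components])
        return cls(dofs=dofs, values=np.full(dofs.shape, float(value)))

    @classmethod
    def from_displacement(cls, node_ids: Sequence[int], disp: np.ndarray) -> "DirichletBC":
        """Prescribe all three components of ``disp`` (n, 3) at ``node_ids``."""
        node_ids = np.asarray(node_ids, dtype=np.int64)
        disp = np.asarray(disp, dtype=float)
        dofs = (3 * node_ids[:, None] + np.arange(3)).ravel()
        return cls(dofs=dofs, values=disp.ravel().astype(float))

    def merged(self, other: "DirichletBC") -> "DirichletBC":
        dofs = np.concatenate([self.dofs, other.dofs])
        values = np.concatenate([self.values, other.values])
        uniq, idx = np.unique(dofs, return_index=True)
        return DirichletBC(uniq, values[idx])


def lv_basal_bc(mesh: VentricularMesh) -> DirichletBC:
    """Standard idealized-LV constraint: basal-plane nodes fixed along the
    long axis, epicardial basal ring additionally fixed in-plane.  Removes
    all rigid modes while leaving the endocardial ring free to dilate."""
    bc = DirichletBC.fix(mesh.node_sets["base"], [2])
    return bc.merged(DirichletBC.fix(mesh.node_sets["basal_ring_epi"], [0, 1]))


class FEModel:
    """Assembled view of mesh + material + fiber field.

    Precomputes reference shape-function gradients, quadrature weights, the
    per-quadrature-point fiber frames, and the sparse scatter pattern.  The
    model itself is stateless: displacement and growth state are passed in.
    """

    def __init__(
        self,
        mesh: VentricularMesh,
        params: MaterialParameters,
        frames: FiberFrame,
        growth_regions=("lv_wall", "rv_wall", "septum"),
    ):
        mesh.validate()
        self.mesh = mesh
        self.params = params
        order = mesh.order
        pts, w = tet_quadrature(order)
        _, dN = tet_shape(order, pts)  # (Q, nn, 3)
        X = mesh.nodes[mesh.tets]  # (E, nn, 3)
        Jac = np.einsum("eai,qaj->eqij", X, dN)  # (E,Q,3,3)
        detJ = np.linalg.det(Jac)
        if np.any(detJ <= 0):
            raise GeometryError("non-positive reference Jacobian")
        Jinv = np.linalg.inv(Jac)
        self.grads = np.einsum("qam,eqmj->eqaj", dN, Jinv)  # (E,Q,nn,3) d/dX
        self.wdet = detJ * w[None, :]  # (E,Q)
        self.V0 = self.wdet.sum(axis=1)  # reference element volumes
        self.n_qp_per_el = len(w)
        self.n_points = mesh.n_elements * self.n_qp_per_el

        if frames.f0.shape[0] == mesh.n_elements:
            rep = lambda a: np.repeat(a, self.n_qp_per_el, axis=0)
            frames = FiberFrame(rep(frames.f0), rep(frames.s0), rep(frames.n0))
        elif frames.f0.shape[0] != self.n_points:
            raise ConfigError("frame count matches neither elements nor points")
        self.frames = frames
        self.Qrot = frames.rotation()  # (P,3,3)
        self.f0 = frames.f0

        el_mask = mesh.growth_element_mask(growth_regions)
        self.growth_mask = np.repeat(el_mask, self.n_qp_per_el)
        self._kscale: Optional[float] = None

        # sparse scatter pattern for the volume elements
        nn = mesh.tets.shape[1]
        edofs = (3 * mesh.tets[:, :, None] + np.arange(3)).reshape(mesh.n_elements, 3 * nn)
        self._rows = np.repeat(edofs, 3 * nn, axis=1).ravel()
        self._cols = np.tile(edofs, (1, 3 * nn)).ravel()
        self._edofs = edofs
        self.ndof = mesh.n_dofs

        # facet data cache per pressure tag
        self._facet_cache: Dict[str, dict] = {}

    # -- kinematics -------------------------------------------------------
    def deformation_gradients(self, u: np.ndarray) -> np.ndarray:
        """F at every quadrature point, shape (E, Q, 3, 3)."""
        ue = u.reshape(-1, 3)[self.mesh.tets]  # (E, nn, 3)
        F = _I3 + np.einsum("eai,eqaj->eqij", ue, self.grads)
        return F

    def initial_growth_state(self, mode: str, tau: float = 1.0, theta_max=None) -> GrowthState:
        return GrowthState.initial(
            self.n_points, mode, tau=tau, theta_max=theta_max, mask=self.growth_mask
        )

    def growth_tensors(self, gstate: Optional[GrowthState]) -> np.ndarray:
        if gstate is None:
            return np.broadcast_to(_I3, (self.n_points, 3, 3))
        return gstate.growth_tensors(self.f0)

    def fiber_stretch_field(self, u: np.ndarray) -> np.ndarray:
        """Total fiber stretch per quadrature point (flat, length P)."""
        F = self.deformation_gradients(u).reshape(-1, 3, 3)
        return fiber_stretch(F, self.f0)

    # -- assembly ---------------------------------------------------------
    def _volumetric_state(self, F: np.ndarray, Fg: np.ndarray):
        """Mean-dilatation bookkeeping: per-point elastic Jacobian, its
        element average, and the variation vectors ``dJe/du``."""
        E, Q = self.wdet.shape
        J = det3(F)
        if np.any(J <= 0) or not np.all(np.isfinite(J)):
            raise InvertedElementError("non-positive total Jacobian")
        Jg = det3(Fg).reshape(E, Q)
        Je = J / Jg
        Je_bar = np.einsum("eq,eq->e", self.wdet, Je) / self.V0
        Finv = inv3(F.reshape(-1, 3, 3)).reshape(E, Q, 3, 3)
        # dJe/du_ai per point: Je * (F^-T)_iJ gradN_aJ
        qvec = Je[..., None, None] * np.einsum("eqji,eqaj->eqai", Finv, self.grads)
        return Je, Je_bar, qvec

    def closed_form_pressure(self, u: np.ndarray, Fg: np.ndarray) -> np.ndarray:
        """Element pressures slaved to the kinematics, ``pbar = U'(Je_bar)``.

        This is the consistent initialization of the mixed solver at any
        state and the exact converged value (where the constraint residual
        vanishes)."""
        F = self.deformation_gradients(u)
        _, Je_bar, _ = self._volumetric_state(F, Fg)
        _, dU, _ = volumetric_energy(Je_bar, self.params)
        return dU

    def internal_forces(
        self,
        u: np.ndarray,
        Fg: np.ndarray,
        tangent: bool = True,
        pbar: Optional[np.ndarray] = None,
    ):
        """Internal nodal forces, volumetric constraint residual, and
        (optionally) the condensed element tangent blocks.

        Mixed two-field formulation (Simo-Taylor mean dilatation with an
        independent element-constant pressure ``pbar``): the isochoric Fung
        response is integrated per quadrature point, the volumetric energy
        acts through the element-average elastic Jacobian ``Je_bar``, and
        the constraint ``c_e = V0 [Je_bar - J(pbar)]`` ties the pressure to
        the volumetric law ``pbar = U'(Je_bar)``.  Keeping ``pbar`` as an
        unknown (condensed element-wise inside each linear solve) removes
        the 1/D0 penalty scaling from the Newton remainder terms, which is
        what makes the iteration robust at bulk/shear ratios of 10^3-10^4.
        When ``pbar`` is None it is slaved to the displacement
        (``closed_form_pressure``), making the constraint residual zero and
        reproducing the pure mean-dilatation operator.

        Returns ``(fint, c, K_el, aux)``; ``K_el`` is None without tangent.
        ``aux`` carries ``Qhat = dJe_bar/du * V0`` and the constraint
        compliance ``Cdiag`` used for the pressure update.
        """
        E, Q = self.wdet.shape
        F = self.deformation_gradients(u)
        C = np.swapaxes(F, -1, -2) @ F
        Cf = C.reshape(-1, 3, 3)
        S = second_pk_from_C(
            Cf, Fg, self.Qrot, self.params, include_volumetric=False
        ).reshape(E, Q, 3, 3)
        Je, Je_bar, qvec = self._volumetric_state(F, Fg)
        if pbar is None:
            _, pbar, _ = volumetric_energy(Je_bar, self.params)
        J_of_p, dJdp = volumetric_jacobian_from_pressure(pbar, self.params)
        c = self.V0 * (Je_bar - J_of_p)
        Cdiag = self.V0 * dJdp

        fint_el = np.einsum("eqim,eqmj,eqaj,eq->eai", F, S, self.grads, self.wdet)
        Qhat = np.einsum("eq,eqai->eai", self.wdet, qvec)  # dJe_bar/du * V0
        fint_el += pbar[:, None, None] * Qhat
        fint = np.zeros(self.ndof)
        np.add.at(fint, self._edofs.reshape(E, -1), fint_el.reshape(E, -1))
        aux = {"Qhat": Qhat, "Cdiag": Cdiag, "pbar": pbar}
        if not tangent:
            return fint, c, None, aux

        CC = material_tangent(
            Cf, Fg, self.Qrot, self.params, include_volumetric=False
        ).reshape(E, Q, 3, 3, 3, 3)
        # Voigt condensation of the material tangent
        Dhat = np.empty((E, Q, 6, 6))
        for m, (i, j) in enumerate(_VOIGT):
            for n, (N, L) in enumerate(_VOIGT):
                Dhat[:, :, m, n] = CC[:, :, i, j, N, L]
        # strain-displacement operator (engineering shear)
        nn = self.grads.shape[2]
        B = np.empty((E, Q, nn, 3, 6))
        g = self.grads
        for m, (N, L) in enumerate(_VOIGT):
            if N == L:
                B[..., m] = F[:, :, None, :, N] * g[:, :, :, None, N]
            else:
                B[..., m] = (
                    F[:, :, None, :, N] * g[:, :, :, None, L]
                    + F[:, :, None, :, L] * g[:, :, :, None, N]
                )
        Kmat = np.einsum("eqaim,eqmn,eqbkn,eq->eaibk", B, Dhat, B, self.wdet, optimize=True)
        Kgeo = np.einsum("eqaj,eqjl,eqbl,eq->eab", g, S, g, self.wdet, optimize=True)
        K_el = Kmat + Kgeo[:, :, None, :, None] * _I3[None, None, :, None, :]

        # volumetric blocks: condensed pressure coupling and the geometric
        # second variation of Je weighted by the element pressure
        K_el += (1.0 / Cdiag)[:, None, None, None, None] * np.einsum(
            "eai,ebk->eaibk", Qhat, Qhat
        )
        w_over_je = self.wdet / Je
        K_el += pbar[:, None, None, None, None] * (
            np.einsum("eq,eqai,eqbk->eaibk", w_over_je, qvec, qvec, optimize=True)
            - np.einsum("eq,eqbi,eqak->eaibk", w_over_je, qvec, qvec, optimize=True)
        )
        return fint, c, K_el.reshape(E, 3 * nn, 3 * nn), aux

    def _facet_data(self, tag: str) -> dict:
        if tag not in self._facet_cache:
            if tag not in self.mesh.facets:
                raise ConfigError(f"pressure tag {tag!r} not present in mesh")
            fac = self.mesh.facets[tag]
            order = 1 if fac.shape[1] == 3 else 2
            pts, w = tri_quadrature(order)
            N, dN = tri_shape(order, pts)
            fdofs = (3 * fac[:, :, None] + np.arange(3)).reshape(fac.shape[0], -1)
            self._facet_cache[tag] = {
                "facets": fac,
                "N": N,
                "dN": dN,
                "w": w,
                "fdofs": fdofs,
                "rows": np.repeat(fdofs, fdofs.shape[1], axis=1).ravel(),
                "cols": np.tile(fdofs, (1, fdofs.shape[1])).ravel(),
            }
        return self._facet_cache[tag]

    def pressure_forces(self, u: np.ndarray, tag: str, p_kPa: float, tangent: bool = True):
        """Follower pressure load on the deformed tagged surface.

        Returns the external force vector (traction ``-p n dA`` integrated
        with the deformed facet normals) and, when requested, the element
        load-stiffness blocks ``d f_ext / d u``.
        """
        d = self._facet_data(tag)
        fac, N, dN, w = d["facets"], d["N"], d["dN"], d["w"]
        x = (self.mesh.nodes + u.reshape(-1, 3))[fac]  # (F, fn, 3)
        g1 = np.einsum("qa,fai->fqi", dN[:, :, 0], x)
        g2 = np.einsum("qa,fai->fqi", dN[:, :, 1], x)
        nda = np.cross(g1, g2)  # (F, Qf, 3), outward of solid
        fel = -p_kPa * np.einsum("q,qa,fqi->fai", w, N, nda)
        fext = np.zeros(self.ndof)
        np.add.at(fext, d["fdofs"].reshape(fac.shape[0], -1), fel.reshape(fac.shape[0], -1))
        if not tangent:
            return fext, None
        M1 = np.einsum("ikm,fqm->fqik", _EPS, g2)  # e_k x g2
        M2 = np.einsum("imk,fqm->fqik", _EPS, g1)  # g1 x e_k
        Kel = -p_kPa * np.einsum(
            "q,qa,fqik,qb->faibk", w, N, M1, dN[:, :, 0], optimize=True
        ) - p_kPa * np.einsum("q,qa,fqik,qb->faibk", w, N, M2, dN[:, :, 1], optimize=True)
        fn = fac.shape[1]
        return fext, Kel.reshape(fac.shape[0], 3 * fn, 3 * fn)

    def stiffness_scale(self) -> float:
        """Median diagonal entry of the reference-configuration *isochoric*
        tangent (kPa mm), used to scale the proximal stabilization.  The
        volumetric penalty is deliberately excluded: the stabilization must
        be sized against the soft deviatoric modes it regularizes, not the
        1/D0 constraint stiffness."""
        if self._kscale is None:
            E, Q = self.wdet.shape
            C = np.broadcast_to(_I3, (E * Q, 3, 3))
            Fg = self.growth_tensors(None)
            CC = material_tangent(
                C, Fg, self.Qrot, self.params, include_volumetric=False
            ).reshape(E, Q, 3, 3, 3, 3)
            g = self.grads
            # diagonal of the small-strain isochoric stiffness
            diag_el = np.einsum(
                "eqijkl,eqaj,eqal,eq->eaik", CC, g, g, self.wdet, optimize=True
            )
            vals = np.einsum("eaii->ea", diag_el) / 3.0
            d = np.zeros(self.mesh.n_nodes)
            np.add.at(d, self.mesh.tets, vals)
            self._kscale = float(np.median(d[d > 0]))
        return self._kscale

    def scatter_element_vector(self, vel: np.ndarray) -> np.ndarray:
        """Sum per-element nodal blocks ``(E, nn, 3)`` into a global vector."""
        E = self.mesh.n_elements
        out = np.zeros(self.ndof)
        np.add.at(out, self._edofs.reshape(E, -1), vel.reshape(E, -1))
        return out

    def residual(
        self,
        u: np.ndarray,
        Fg: np.ndarray,
        pressures: Dict[str, float],
        pbar: Optional[np.ndarray] = None,
    ):
        """Out-of-balance force ``R = f_int - f_ext`` and the volumetric
        constraint residual ``c`` (zero when ``pbar`` is slaved)."""
        fint, c, _, _ = self.internal_forces(u, Fg, tangent=False, pbar=pbar)
        fext = np.zeros(self.ndof)
        for tag, p in pressures.items():
            if p != 0.0:
                fe, _ = self.pressure_forces(u, tag, p, tangent=False)
                fext += fe
        return fint - fext, c, fext

    def assemble(
        self,
        u: np.ndarray,
        Fg: np.ndarray,
        pressures: Dict[str, float],
        bc: DirichletBC,
        tangent: bool = True,
        pbar: Optional[np.ndarray] = None,
    ):
        """Global residual ``R = f_int - f_ext``, condensed tangent operator,
        free-dof mask, external force, constraint residual and the
        volumetric coupling data."""
        fint, c, K_el, aux = self.internal_forces(u, Fg, tangent, pbar)
        fext = np.zeros(self.ndof)
        K_parts = []
        if tangent and K_el is not None:
            K_parts.append((self._rows, self._cols, K_el.ravel()))
        for tag, p in pressures.items():
            if p == 0.0:
                continue
            fe, Ke = self.pressure_forces(u, tag, p, tangent)
            fext += fe
            if tangent and Ke is not None:
                d = self._facet_data(tag)
                K_parts.append((d["rows"], d["cols"], -Ke.ravel()))
        R = fint - fext
        K = None
        if tangent:
            rows = np.concatenate([r for r, _, _ in K_parts])
            cols = np.concatenate([c_ for _, c_, _ in K_parts])
            vals = np.concatenate([v for _, _, v in K_parts])
            K = sp.coo_matrix((vals, (rows, cols)), shape=(self.ndof, self.ndof)).tocsr()
        free = np.ones(self.ndof, dtype=bool)
        free[bc.dofs] = False
        return R, K, free, fext, c, aux

    def total_strain_energy(self, u: np.ndarray, Fg: np.ndarray) -> float:
        """Total strain energy (kPa mm^3), mean-dilatation consistent:
        isochoric part per quadrature point plus ``V0 * U(Je_bar)`` per
        element.  Used for energy-monotonicity diagnostics."""
        E, Q = self.wdet.shape
        F = self.deformation_gradients(u)
        C = (np.swapaxes(F, -1, -2) @ F).reshape(-1, 3, 3)
        _, _, psi_iso = second_pk_from_C(
            C, Fg, self.Qrot, self.params, with_energy=True, include_volumetric=False
        )
        _, Je_bar, _ = self._volumetric_state(F, Fg)
        U, _, _ = volumetric_energy(Je_bar, self.params)
        return float(np.sum(psi_iso.reshape(E, Q) * self.wdet) + np.sum(U * self.V0))

    def cauchy_stress_field(self, u: np.ndarray, Fg: np.ndarray) -> np.ndarray:
        """Cauchy stress per quadrature point (P, 3, 3), with the volumetric
        part evaluated at the element-mean elastic Jacobian (consistent with
        the assembled equilibrium)."""
        E, Q = self.wdet.shape
        F = self.deformation_gradients(u)
        Ff = F.reshape(-1, 3, 3)
        C = np.swapaxes(Ff, -1, -2) @ Ff
        S = second_pk_from_C(C, Fg, self.Qrot, self.params, include_volumetric=False)
        Je, Je_bar, _ = self._volumetric_state(F, Fg)
        _, dU, _ = volumetric_energy(Je_bar, self.params)
        p_el = np.repeat(dU, Q) * Je.reshape(-1)
        S = S + p_el[:, None, None] * inv3(C)
        J = det3(Ff)
        return Ff @ S @ np.swapaxes(Ff, -1, -2) / J[:, None, None]


class TangentCache:
    """Reusable LU factorization of the consistent tangent.

    Factoring the sparse tangent dominates the solver cost, so the LU is
    kept across Newton iterations and across load/growth steps and only
    refreshed when the iteration contracts too slowly (modified Newton with
    automatic refactorization).  A fresh factorization restores the full
    Newton step, so the asymptotic convergence contract is preserved.
    """

    def __init__(self):
        self.lu = None
        self.Kff = None
        self.aux = None
        self.free_key = None
        #: element pressures of the last converged solve; kept across
        #: invalidations — a physically scaled initial guess for the next
        #: solve (re-slaving p to the kinematics after a growth update
        #: would re-introduce the penalty-pressure spike)
        self.pbar = None

    def invalidate(self):
        self.lu = None
        self.Kff = None
        self.aux = None
        self.free_key = None

    def refactor(self, model: "FEModel", u, Fg, pressures, bc, pbar=None, mu: float = 0.0):
        R, K, free, fext, c, aux = model.assemble(u, Fg, pressures, bc, tangent=True, pbar=pbar)
        self.Kff = K[free][:, free].tocsc()
        if mu > 0.0:
            self.Kff = (self.Kff + mu * sp.identity(int(free.sum()), format="csc")).tocsc()
        self.lu = spla.splu(self.Kff)
        self.aux = aux
        self.free_key = (len(bc.dofs), int(bc.dofs.sum()) if len(bc.dofs) else 0)
        return R, free, fext

    def regularized_lu(self, damping: float):
        """LU of the tangent with a Levenberg diagonal shift, used to force
        a usable descent direction near instability points."""
        d = np.abs(self.Kff.diagonal())
        shift = sp.diags(damping * np.maximum(d, d.max() * 1e-12))
        return spla.splu((self.Kff + shift).tocsc())

    def matches(self, bc: DirichletBC) -> bool:
        key = (len(bc.dofs), int(bc.dofs.sum()) if len(bc.dofs) else 0)
        return self.lu is not None and key == self.free_key


def newton_solve(
    model: FEModel,
    u0: np.ndarray,
    Fg: np.ndarray,
    pressures: Dict[str, float],
    bc: DirichletBC,
    settings: SolverSettings = SolverSettings(),
    bc_scale: float = 1.0,
    cache: Optional[TangentCache] = None,
    u_ref: Optional[np.ndarray] = None,
) -> Tuple[np.ndarray, dict]:
    """Newton iteration of the mixed displacement/pressure system at fixed
    loads and growth.

    When ``settings.stabilization`` is positive and a reference state
    ``u_ref`` (the step start) is supplied, the solve targets the
    proximally stabilized problem — potential plus
    ``mu/2 ||u - u_ref||^2`` — which regularizes snap-through of
    mesh-scale wrinkling modes while biasing the equilibrium only at order
    ``mu``.

    The element pressures are condensed out of every linear solve and
    updated alongside the displacements; a backtracking line search on the
    combined force/constraint merit globalizes the iteration.  Convergence
    requires the free-dof force residual to fall below ``newton_tol`` times
    the external force scale (or the absolute floor) *and* the volumetric
    constraint to be satisfied to near machine precision.  Raises
    :class:`StepRejected` for inadmissible or diverging trial states so the
    load stepping can bisect, and :class:`SolverError` on exhaustion of
    iterations.

    When a :class:`TangentCache` is supplied, the previous LU factorization
    is reused as long as the merit contracts by at least
    ``settings.reuse_contraction`` per iteration; otherwise (and always when
    ``cache`` is None) the consistent tangent is reassembled and refactored,
    recovering the full Newton step.
    """
    own_cache = cache is None
    if own_cache:
        cache = TangentCache()
    u = u0.copy()
    u[bc.dofs] = bc.values * bc_scale
    history: List[float] = []
    n_factor = 0
    free = np.ones(model.ndof, dtype=bool)
    free[bc.dofs] = False
    # constraint weight: fixed moderate scale (kPa * mm^2 per unit
    # volumetric strain), deliberately independent of the 1/D0 penalty
    kappa = model.params.C0 * max(1.0, model.params.Bff) * model.V0 ** (2.0 / 3.0)

    def free_norm(R):
        return float(np.linalg.norm(R[free]))

    def merit(R, c):
        return float(np.sqrt(free_norm(R) ** 2 + np.sum((kappa * c / model.V0) ** 2)))

    mu = 0.0
    if settings.stabilization > 0.0 and u_ref is not None:
        mu = settings.stabilization * model.stiffness_scale()

    def damp(Rv, uv):
        return Rv + mu * (uv - u_ref) if mu > 0.0 else Rv

    if cache.pbar is not None and cache.pbar.shape == (model.mesh.n_elements,):
        pbar = cache.pbar
    else:
        pbar = model.closed_form_pressure(u, Fg)
    R, c, fext = model.residual(u, Fg, pressures, pbar)
    R = damp(R, u)
    rnorm = free_norm(R)
    if not np.isfinite(rnorm):
        raise StepRejected("non-finite residual at the start state")
    for it in range(settings.newton_max_iter + 1):
        scale = max(free_norm(fext), 1.0)
        m = merit(R, c)
        cmax = float(np.max(np.abs(c) / model.V0))
        stagnant = bool(history) and m > settings.reuse_contraction * history[-1]
        history.append(m)
        ctol = max(1e-9, 0.01 * settings.newton_tol)
        if rnorm <= max(settings.newton_tol * scale, settings.newton_abs_tol) and cmax <= ctol:
            # certify convergence against the slaved-pressure (pure mean
            # dilatation) residual so that restarting from the returned
            # state reproduces it bitwise (exact fixed point for the
            # growth-threshold calibration)
            Rs, cs, fexts = model.residual(u, Fg, pressures, None)
            Rs = damp(Rs, u)
            rs = free_norm(Rs)
            ss = max(free_norm(fexts), 1.0)
            if rs <= max(settings.newton_tol * ss, settings.newton_abs_tol):
                cache.pbar = pbar.copy()
                return u, {
                    "iterations": it,
                    "residuals": history,
                    "converged": True,
                    "factorizations": n_factor,
                }
            pbar = model.closed_form_pressure(u, Fg)
            R, c, fext = Rs, cs, fexts
            rnorm = rs
        flat = it >= 12 and len(history) >= 7 and history[-1] > 0.9 * history[-7]
        if settings.stall_accept_tol is not None and (flat or it == settings.newton_max_iter):
            # a small flapping force remainder from local wrinkling modes is
            # tolerated in the organ-scale scenarios, provided the
            # volumetric constraint is essentially satisfied
            if rnorm <= settings.stall_accept_tol * scale and cmax <= 1e-4:
                logger.warning(
                    "accepting stalled Newton state at %.2e relative residual",
                    rnorm / scale,
                )
                cache.pbar = pbar.copy()
                return u, {
                    "iterations": it,
                    "residuals": history,
                    "converged": True,
                    "stalled": True,
                    "factorizations": n_factor,
                }
        if it == settings.newton_max_iter:
            break
        if own_cache or not cache.matches(bc) or (
            stagnant and n_factor < settings.max_stagnant_refactors
        ):
            cache.refactor(model, u, Fg, pressures, bc, pbar, mu=mu)
            n_factor += 1

        def try_direction(lu):
            """Solve for the coupled update with the given factorization and
            run the backtracking merit line search; None on failure."""
            Qhat, Cdiag = cache.aux["Qhat"], cache.aux["Cdiag"]
            Rhat = R + model.scatter_element_vector((c / Cdiag)[:, None, None] * Qhat)
            du = lu.solve(-Rhat[free])
            if not np.all(np.isfinite(du)):
                return None
            du_full = np.zeros(model.ndof)
            du_full[free] = du
            dpbar = (
                c + np.einsum("eai,eai->e", Qhat, du_full[model._edofs].reshape(Qhat.shape))
            ) / Cdiag
            alpha = 1.0
            for _ in range(settings.max_line_search):
                ut = u.copy()
                ut[free] += alpha * du
                pt = pbar + alpha * dpbar
                try:
                    Rt, ct, fextt = model.residual(ut, Fg, pressures, pt)
                    Rt = damp(Rt, ut)
                    mt = merit(Rt, ct)
                except (StepRejected, InvertedElementError):
                    mt = np.inf
                if np.isfinite(mt) and mt < (1.0 - 1e-4 * alpha) * m:
                    return (ut, pt, Rt, ct, fextt)
                alpha *= 0.5
            return None

        trial = try_direction(cache.lu)
        if trial is None and not own_cache:
            # a stale tangent can produce an unusable direction: refresh once
            cache.refactor(model, u, Fg, pressures, bc, pbar, mu=mu)
            n_factor += 1
            trial = try_direction(cache.lu)
        if trial is None:
            # indefinite tangent near an instability: Levenberg-damped steps
            for damping in (1e-6, 1e-4, 1e-2, 1.0):
                trial = try_direction(cache.regularized_lu(damping))
                n_factor += 1
                if trial is not None:
                    break
        if trial is None:
            cache.invalidate()
            raise StepRejected("line search failed: trial step rejected")
        u, pbar, R, c, fext = trial
        rnorm = free_norm(R)
    cache.invalidate()
    raise SolverError(
        f"Newton did not converge in {settings.newton_max_iter} iterations "
        f"(merit history {history})",
        diagnostics={"residuals": history},
    )


def _solve_with_fallback(model, u, Fg, pressures, bc, settings, cache):
    """Plain Newton first; on failure an escalating proximal-stabilization
    ladder (mu, then 100 mu) before giving up."""
    try:
        return newton_solve(model, u, Fg, pressures, bc, settings, cache=cache)
    except (StepRejected, SolverError) as exc:
        logger.info("equilibrium failed plainly (%s); stabilization fallback", exc)
        if cache is not None:
            cache.invalidate()
        if settings.stabilization <= 0.0:
            raise
        last = exc
        for factor in (1.0, 100.0):
            boosted = replace(settings, stabilization=settings.stabilization * factor)
            try:
                return newton_solve(model, u, Fg, pressures, bc, boosted, cache=cache, u_ref=u)
            except (StepRejected, SolverError) as exc2:
                if cache is not None:
                    cache.invalidate()
                last = exc2
        raise last


def ramp_solve(
    model: FEModel,
    u0: np.ndarray,
    Fg: np.ndarray,
    p_start: Dict[str, float],
    p_end: Dict[str, float],
    bc: DirichletBC,
    settings: SolverSettings = SolverSettings(),
    cache: Optional[TangentCache] = None,
) -> Tuple[np.ndarray, dict]:
    """Incremental load stepping from ``p_start`` to ``p_end`` with
    automatic halving of the increment on Newton failure."""
    tags = sorted(set(p_start) | set(p_end))
    a = {t: p_start.get(t, 0.0) for t in tags}
    b = {t: p_end.get(t, 0.0) for t in tags}
    u = u0.copy()
    frac = 0.0
    step = 1.0 / settings.ramp_steps
    total_iters = 0
    n_steps = 0
    while frac < 1.0 - 1e-12:
        trial = min(1.0, frac + step)
        p = {t: (1 - trial) * a[t] + trial * b[t] for t in tags}
        try:
            u_new, info = _solve_with_fallback(model, u, Fg, p, bc, settings, cache)
        except (StepRejected, SolverError, InvertedElementError):
            if cache is not None:
                cache.invalidate()
            step *= 0.5
            if step < settings.min_step_fraction / settings.ramp_steps:
                raise SolverError("load increment underflow during ramp")
            continue
        u = u_new
        frac = trial
        total_iters += info["iterations"]
        n_steps += 1
        step = min(step * 1.5, 0.5)
    return u, {"newton_iterations": total_iters, "load_steps": n_steps}


def staggered_growth_step(
    model: FEModel,
    u: np.ndarray,
    gstate: GrowthState,
    pressures: Dict[str, float],
    bc: DirichletBC,
    settings: SolverSettings = SolverSettings(),
    dt: Optional[float] = None,
    cache: Optional[TangentCache] = None,
    _depth: int = 0,
) -> Tuple[np.ndarray, GrowthState, dict]:
    """One pass of the staggered equilibrium/growth loop.

    Evaluates the fiber stretch of the current equilibrium, applies the
    explicit kinetic update to the growth field, and re-solves equilibrium
    at constant pressure for the updated field.  If the equilibrium solve
    rejects the grown state, the growth increment is sub-stepped (dt
    halved, recursively up to three levels) before giving up.  Returns the
    new displacement, the new growth state, and step statistics.
    """
    dt = settings.growth_dt if dt is None else dt
    lam = model.fiber_stretch_field(u)
    gnew = gstate.updated(lam, dt)
    Fg = model.growth_tensors(gnew)
    try:
        u_new, info = _solve_with_fallback(model, u, Fg, pressures, bc, settings, cache)
    except (StepRejected, SolverError):
        if cache is not None:
            cache.invalidate()
        if _depth >= 2:
            raise
        u_mid, g_mid, s1 = staggered_growth_step(
            model, u, gstate, pressures, bc, settings, 0.5 * dt, cache, _depth + 1
        )
        u_new, gnew, s2 = staggered_growth_step(
            model, u_mid, g_mid, pressures, bc, settings, 0.5 * dt, cache, _depth + 1
        )
        return u_new, gnew, {
            "max_dtheta": float(np.max(np.abs(gnew.theta - gstate.theta))),
            "max_excess": max(s1["max_excess"], s2["max_excess"]),
            "newton_iterations": s1["newton_iterations"] + s2["newton_iterations"],
            "substepped": True,
        }
    excess = np.maximum(lam - gstate.lambda_crit, 0.0)
    if gstate.mask is not None:
        excess = np.where(gstate.mask, excess, 0.0)
    stats = {
        "max_dtheta": float(np.max(np.abs(gnew.theta - gstate.theta))),
        "max_excess": float(np.max(excess)),
        "newton_iterations": info["iterations"],
        "substepped": False,
    }
    return u_new, gnew, stats
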