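"""Quasi-incompressible orthotropic Fung-type myocardium.

Strain energy per unit reference volume

.. code-block:: text

    psi = U(Je) + psi_bar(Ebar_e)
    U(Je)    = [Je^2 - 2 ln Je] / (2 D0)
    psi_bar  = C0/2 [exp(Ebar_e : B0 : Ebar_e) - 1]

where ``B0`` is the orthotropic weight tensor expressed in the local
fiber/sheet/normal frame.  In Voigt form its diagonal reads
``{Bff, Bss, Bnn, 2 Bfs, 2 Bfn, 2 Bsn}``; equivalently the quadratic form is

    E : B0 : E = sum_ab W_ab E_ab^2,   W = [[Bff, Bfs, Bfn],
                                            [Bfs, Bss, Bsn],
                                            [Bfn, Bsn, Bnn]]

with the strain expressed in fiber coordinates (off-diagonal entries appear
twice in the sum, which reproduces the Voigt shear factor of two).  Working
with the full quadratic form in the rotated frame eliminates Voigt
shear-factor bookkeeping entirely.

Stresses: the elastic second Piola-Kirchhoff stress ``Se = dpsi/dEe`` lives
in the intermediate (grown, stress-free) configuration and is pulled back to
the reference configuration through the growth tensor, ``S = Fg^-1 Se Fg^-T``.
The Cauchy stress is the usual push-forward ``sigma = F S F^T / det F``.

``D0`` carries reciprocal-stress units (kPa^-1) so that ``1/(2 D0)`` is a
volumetric stiffness; at the default 0.001 kPa^-1 that is 500 kPa, four
orders stiffer than the tissue scale ``C0`` — a numerical
quasi-incompressibility penalty, not a measured modulus.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Tuple

import numpy as np

from .errors import FrameError, InvertedElementError, ParameterError, StepRejected
from .fibers import FiberFrame
from .tensors import det3, inv3, _I3

__all__ = [
    "MaterialParameters",
    "StressResult",
    "scale_weights",
    "volumetric_energy",
    "volumetric_jacobian_from_pressure",
    "fung_energy",
    "stresses",
    "second_pk_from_C",
    "material_tangent",
]

#: exponent guard: beyond this the Fung exponential is treated as a diverged
#: trial state and the load step is rejected rather than overflowing
_Q_MAX = 80.0

#: default compressibility penalty (kPa^-1), healthy-human table value
DEFAULT_D0 = 0.001


@dataclass(frozen=True)
class MaterialParameters:
    """Fung stiffness/weight constants.

    C0 : stress scale (kPa).
    D0 : compressibility penalty parameter (kPa^-1).
    Bff..Bsn : dimensionless stiffness weights in the fiber (f), sheet (s),
        sheet-normal (n) frame.
    """

    C0: float
    D0: float
    Bff: float
    Bss: float
    Bnn: float
    Bfs: float
    Bfn: float
    Bsn: float

    def __post_init__(self):
        if not self.C0 > 0:
            raise ParameterError("C0 must be positive")
        if not self.D0 > 0:
            raise ParameterError("D0 must be positive")
        for name in ("Bff", "Bss", "Bnn", "Bfs", "Bfn", "Bsn"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")

    @classmethod
    def healthy_human(cls) -> "MaterialParameters":
        """Averaged in-vivo identified parameters of the healthy human heart
        (C0 = 0.115 kPa, B0 = 14.4, D0 = 0.001 kPa^-1)."""
        return scale_weights(0.115, 14.4)

    def weight_matrix(self) -> np.ndarray:
        """Symmetric 3x3 weight matrix ``W`` of the quadratic form (fiber frame)."""
        return np.array(
            [
                [self.Bff, self.Bfs, self.Bfn],
                [self.Bfs, self.Bss, self.Bsn],
                [self.Bfn, self.Bsn, self.Bnn],
            ]
        )

    def with_weights(self, **kw) -> "MaterialParameters":
        return replace(self, **kw)


def scale_weights(C0: float, B0: float, D0: float = DEFAULT_D0) -> MaterialParameters:
    """Two-parameter transversely isotropic reduction of the Fung weights.

    The fiber weight is ``Bff = B0``; transverse weights ``Bss = Bnn = 0.4 B0``;
    shear weights ``Bfs = Bfn = 0.35 B0`` and ``Bsn = 0.2 B0``.
    """
    if C0 <= 0 or B0 < 0:
        raise ParameterError("require C0 > 0 and B0 >= 0")
    return MaterialParameters(
        C0=C0,
        D0=D0,
        Bff=B0,
        Bss=0.4 * B0,
        Bnn=0.4 * B0,
        Bfs=0.35 * B0,
        Bfn=0.35 * B0,
        Bsn=0.2 * B0,
    )


def volumetric_energy(Je, params: MaterialParameters):
    """Volumetric energy ``U(Je)`` and its first two ``Je``-derivatives.

    ``U = [Je^2 - 2 ln Je]/(2 D0)`` is stationary at ``Je = 1`` (stress-free
    unit Jacobian) and blows up as ``Je -> 0`` or ``Je -> inf``.  Energy is
    defined up to a constant: ``U(1) = 1/(2 D0)``, not zero.
    """
    Je = np.asarray(Je, dtype=float)
    if np.any(Je <= 0):
        raise InvertedElementError("Je <= 0 in volumetric energy")
    inv_2d0 = 0.5 / params.D0
    U = inv_2d0 * (Je**2 - 2.0 * np.log(Je))
    dU = inv_2d0 * (2.0 * Je - 2.0 / Je)
    d2U = inv_2d0 * (2.0 + 2.0 / Je**2)
    return U, dU, d2U


def volumetric_jacobian_from_pressure(p, params: MaterialParameters):
    """Invert the volumetric law: the Jacobian ``J`` with ``U'(J) = p`` and
    its sensitivity ``dJ/dp``.

    ``U'(J) = (J - 1/J)/D0`` gives the closed form
    ``J = [D0 p + sqrt(D0^2 p^2 + 4)]/2`` (always positive), used by the
    mixed displacement/pressure solver.
    """
    p = np.asarray(p, dtype=float)
    x = params.D0 * p
    J = 0.5 * (x + np.sqrt(x * x + 4.0))
    dJdp = params.D0 / (1.0 + 1.0 / (J * J))
    return J, dJdp


def _quadratic_form(E_loc: np.ndarray, W: np.ndarray) -> np.ndarray:
    return np.einsum("...ab,ab->...", E_loc**2, W)


def fung_energy(Ebar_e: np.ndarray, frame: FiberFrame, params: MaterialParameters):
    """Isochoric Fung energy ``psi_bar = C0/2 [exp(E:B0:E) - 1]`` (kPa).

    ``Ebar_e`` is rotated into the ``(f0, s0, n0)`` frame and the quadratic
    form applied there.  Always non-negative.
    """
    frame.validate()
    Ebar_e = np.asarray(Ebar_e, dtype=float)
    Q = frame.rotation()
    E_loc = np.swapaxes(Q, -1, -2) @ Ebar_e @ Q
    q = _quadratic_form(E_loc, params.weight_matrix())
    return 0.5 * params.C0 * np.expm1(q)


@dataclass(frozen=True)
class StressResult:
    """Stress measures at a material point (all kPa).

    S : total second Piola-Kirchhoff stress (referential).
    Se : elastic second Piola-Kirchhoff stress (intermediate configuration).
    sigma : Cauchy stress (spatial).
    psi : strain energy density.
    """

    S: np.ndarray
    Se: np.ndarray
    sigma: np.ndarray
    psi: np.ndarray


def second_pk_from_C(
    C: np.ndarray,
    Fg: np.ndarray,
    Qrot: np.ndarray,
    params: MaterialParameters,
    with_energy: bool = False,
    include_volumetric: bool = True,
):
    """Batched total second Piola-Kirchhoff stress from the right
    Cauchy-Green tensor ``C = F^T F``.

    This is the single constitutive code path used by both the material-point
    API and the finite-element assembly; formulating it in ``C`` makes the
    finite-difference material tangent a six-column perturbation of this
    function.

    Parameters
    ----------
    C : (..., 3, 3) right Cauchy-Green tensor.
    Fg : (..., 3, 3) growth tensor.
    Qrot : (..., 3, 3) rotation with columns (f0, s0, n0).
    with_energy : also return ``(Se, psi)``.
    include_volumetric : when False, only the isochoric stress (and energy)
        is returned; the caller handles the volumetric response separately
        (mean-dilatation finite elements do this at the element level).

    Raises
    ------
    StepRejected
        if the Fung exponent exceeds the overflow guard (diverged trial state).
    InvertedElementError
        if the elastic Jacobian is non-positive.
    """
    Fg_inv = inv3(Fg)
    Fg_inv_T = np.swapaxes(Fg_inv, -1, -2)
    Ce = Fg_inv_T @ C @ Fg_inv
    Je2 = det3(Ce)
    if np.any(Je2 <= 0) or not np.all(np.isfinite(Je2)):
        raise InvertedElementError("non-positive elastic Jacobian")
    Je = np.sqrt(Je2)
    scale = Je[..., None, None] ** (-2.0 / 3.0)
    Ebar = 0.5 * (scale * Ce - _I3)
    Ebar = 0.5 * (Ebar + np.swapaxes(Ebar, -1, -2))

    E_loc = np.swapaxes(Qrot, -1, -2) @ Ebar @ Qrot
    W = params.weight_matrix()
    q = _quadratic_form(E_loc, W)
    if np.any(q > _Q_MAX) or not np.all(np.isfinite(q)):
        raise StepRejected("Fung exponent overflow: trial state rejected")
    Sbar_loc = params.C0 * np.exp(q)[..., None, None] * (W * E_loc)
    Sbar = Qrot @ Sbar_loc @ np.swapaxes(Qrot, -1, -2)

    Ce_inv = inv3(Ce)
    tr = np.einsum("...ij,...ij->...", Sbar, Ce)
    Se = scale * (Sbar - (tr / 3.0)[..., None, None] * Ce_inv)
    psi = 0.5 * params.C0 * np.expm1(q)
    if include_volumetric:
        U, dU, _ = volumetric_energy(Je, params)
        Se = Se + (dU * Je)[..., None, None] * Ce_inv
        psi = psi + U
    S = Fg_inv @ Se @ Fg_inv_T
    if not with_energy:
        return S
    return S, Se, psi


def stresses(
    F: np.ndarray,
    Fg: np.ndarray,
    frame: FiberFrame,
    params: MaterialParameters,
) -> StressResult:
    """Stress measures at a material point (batched).

    ``Se = dpsi/dEe`` through the volumetric/isochoric split, pulled back as
    ``S = Fg^-1 Se Fg^-T`` and pushed forward as ``sigma = F S F^T / det F``.
    """
    F = np.asarray(F, dtype=float)
    J = det3(F)
    if np.any(J <= 0):
        raise InvertedElementError("det(F) <= 0")
    frame.validate()
    C = np.swapaxes(F, -1, -2) @ F
    S, Se, psi = second_pk_from_C(C, np.asarray(Fg, float), frame.rotation(), params, with_energy=True)
    sigma = F @ S @ np.swapaxes(F, -1, -2) / J[..., None, None]
    return StressResult(S=S, Se=Se, sigma=sigma, psi=psi)


# symmetric perturbation basis for the six independent strain components
_SYM_BASIS = np.zeros((6, 3, 3))
_SLOTS = [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)]
for _m, (_i, _j) in enumerate(_SLOTS):
    _SYM_BASIS[_m, _i, _j] += 1.0
    _SYM_BASIS[_m, _j, _i] += 1.0
_SYM_BASIS[:3] *= 0.5  # diagonal slots: unit entry


def material_tangent(
    C: np.ndarray,
    Fg: np.ndarray,
    Qrot: np.ndarray,
    params: MaterialParameters,
    rel_step: float = 1e-7,
    include_volumetric: bool = True,
) -> np.ndarray:
    """Material tangent ``CC_MJNL = dS_MJ / dE_NL`` by forward differences.

    Perturbs each of the six symmetric strain components of ``E = (C - I)/2``
    with a relative step and differences the stress; the result has the minor
    symmetries by construction (``CC[..., N, L] == CC[..., L, N]`` and
    symmetry of the stress slots).  Accuracy is first order in the step,
    which is sufficient for the superlinear Newton contract of the solver.
    """
    C = np.asarray(C, dtype=float)
    S0 = second_pk_from_C(C, Fg, Qrot, params, include_volumetric=include_volumetric)
    h = rel_step * max(1.0, float(np.max(np.abs(C))))
    CC = np.empty(C.shape[:-2] + (3, 3, 3, 3))
    for m, (i, j) in enumerate(_SLOTS):
        dC = 2.0 * h * _SYM_BASIS[m]  # dC = 2 dE
        G = (
            second_pk_from_C(C + dC, Fg, Qrot, params, include_volumetric=include_volumetric)
            - S0
        ) / h
        if i == j:
            CC[..., i, j] = G
        else:
            CC[..., i, j] = 0.5 * G
            CC[..., j, i] = 0.5 * G
    return CC
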