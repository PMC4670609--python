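"""Second-order tensor kinematics of finite growth.

All tensors are stored as ``(..., 3, 3)`` NumPy arrays in one fixed global
Cartesian frame; routines are batched over leading axes so the finite-element
assembly can evaluate whole quadrature-point populations in one call.

The central object is the multiplicative split of the deformation gradient
into an elastic part and a growth part, ``F = Fe . Fg``.  Only the elastic
part generates stress; it is further decomposed into a volumetric part
(through the elastic Jacobian ``Je = det Fe``) and an isochoric part whose
Green-Lagrange strain ``Ebar_e = [Je^(-2/3) Fe^T Fe - I] / 2`` drives the
anisotropic strain energy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidGrowthStateError, InvertedElementError

__all__ = [
    "det3",
    "inv3",
    "multiplicative_split",
    "green_lagrange",
    "elastic_measures",
    "isochoric_part",
    "ElasticDecomposition",
]

#: determinant pivot below which a 3x3 inverse is refused
_SINGULAR_TOL = 1e-14

_I3 = np.eye(3)


def det3(a: np.ndarray) -> np.ndarray:
    """Closed-form determinant of ``(..., 3, 3)`` arrays."""
    a = np.asarray(a, dtype=float)
    return (
        a[..., 0, 0] * (a[..., 1, 1] * a[..., 2, 2] - a[..., 1, 2] * a[..., 2, 1])
        - a[..., 0, 1] * (a[..., 1, 0] * a[..., 2, 2] - a[..., 1, 2] * a[..., 2, 0])
        + a[..., 0, 2] * (a[..., 1, 0] * a[..., 2, 1] - a[..., 1, 1] * a[..., 2, 0])
    )


def inv3(a: np.ndarray, *, check: bool = True) -> np.ndarray:
    """Closed-form (adjugate) inverse of ``(..., 3, 3)`` arrays.

    Deterministic and much faster than ``np.linalg.inv`` at this size.
    Raises :class:`InvalidGrowthStateError` when any determinant magnitude
    falls below the pivot tolerance ``1e-14``.
    """
    a = np.asarray(a, dtype=float)
    d = det3(a)
    if check and np.any(np.abs(d) < _SINGULAR_TOL):
        raise InvalidGrowthStateError(
            "singular 3x3 tensor: |det| < 1e-14 (min |det| = %g)" % np.min(np.abs(d))
        )
    adj = np.empty_like(a)
    adj[..., 0, 0] = a[..., 1, 1] * a[..., 2, 2] - a[..., 1, 2] * a[..., 2, 1]
    adj[..., 0, 1] = a[..., 0, 2] * a[..., 2, 1] - a[..., 0, 1] * a[..., 2, 2]
    adj[..., 0, 2] = a[..., 0, 1] * a[..., 1, 2] - a[..., 0, 2] * a[..., 1, 1]
    adj[..., 1, 0] = a[..., 1, 2] * a[..., 2, 0] - a[..., 1, 0] * a[..., 2, 2]
    adj[..., 1, 1] = a[..., 0, 0] * a[..., 2, 2] - a[..., 0, 2] * a[..., 2, 0]
    adj[..., 1, 2] = a[..., 0, 2] * a[..., 1, 0] - a[..., 0, 0] * a[..., 1, 2]
    adj[..., 2, 0] = a[..., 1, 0] * a[..., 2, 1] - a[..., 1, 1] * a[..., 2, 0]
    adj[..., 2, 1] = a[..., 0, 1] * a[..., 2, 0] - a[..., 0, 0] * a[..., 2, 1]
    adj[..., 2, 2] = a[..., 0, 0] * a[..., 1, 1] - a[..., 0, 1] * a[..., 1, 0]
    return adj / d[..., None, None]


def multiplicative_split(F: np.ndarray, Fg: np.ndarray) -> np.ndarray:
    """Elastic part ``Fe = F . Fg^-1`` of the multiplicative decomposition.

    Parameters
    ----------
    F : (..., 3, 3)
        Total deformation gradient, ``det F > 0``.
    Fg : (..., 3, 3)
        Growth tensor, ``det Fg > 0``.

    Returns
    -------
    Fe : (..., 3, 3) such that ``Fe . Fg`` reproduces ``F``.
    """
    F = np.asarray(F, dtype=float)
    Fg = np.asarray(Fg, dtype=float)
    if np.any(det3(F) <= 0):
        raise InvertedElementError("det(F) <= 0 in multiplicative split")
    dg = det3(Fg)
    if np.any(dg <= 0):
        raise InvalidGrowthStateError("det(Fg) <= 0: inadmissible growth tensor")
    return F @ inv3(Fg)


def green_lagrange(F: np.ndarray) -> np.ndarray:
    """Total Green-Lagrange strain ``E = (F^T F - I) / 2``."""
    F = np.asarray(F, dtype=float)
    return 0.5 * (np.swapaxes(F, -1, -2) @ F - _I3)


def isochoric_part(Fe: np.ndarray) -> np.ndarray:
    """Volume-preserving part ``Fbar_e = Je^(-1/3) Fe`` (unit determinant)."""
    Fe = np.asarray(Fe, dtype=float)
    Je = det3(Fe)
    if np.any(Je <= 0):
        raise InvertedElementError("det(Fe) <= 0")
    return Je[..., None, None] ** (-1.0 / 3.0) * Fe


@dataclass(frozen=True)
class ElasticDecomposition:
    """Elastic deformation measures entering the strain energy.

    Attributes
    ----------
    Fe : (..., 3, 3) elastic deformation gradient
    Je : (...) elastic Jacobian, ``det Fe``
    Ebar_e : (..., 3, 3) isochoric elastic Green-Lagrange strain
    """

    Fe: np.ndarray
    Je: np.ndarray
    Ebar_e: np.ndarray


def elastic_measures(Fe: np.ndarray) -> ElasticDecomposition:
    """Elastic Jacobian and isochoric elastic Green-Lagrange strain.

    ``Je = det Fe`` and ``Ebar_e = [Je^(-2/3) Fe^T Fe - I] / 2``.  The
    isochoric strain is exactly symmetric by construction and vanishes for
    any rotation (objectivity).
    """
    Fe = np.asarray(Fe, dtype=float)
    Je = det3(Fe)
    if np.any(Je <= 0):
        raise InvertedElementError("det(Fe) <= 0: inverted elastic state")
    Ce = np.swapaxes(Fe, -1, -2) @ Fe
    Ebar = 0.5 * (Je[..., None, None] ** (-2.0 / 3.0) * Ce - _I3)
    # enforce exact symmetry against floating-point asymmetry
    Ebar = 0.5 * (Ebar + np.swapaxes(Ebar, -1, -2))
    return ElasticDecomposition(Fe=Fe, Je=Je, Ebar_e=Ebar)
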