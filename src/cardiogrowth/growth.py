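"""Stretch-driven finite-growth laws of cardiac hypertrophy.

Two sarcomere-deposition modes, each controlled by one scalar growth
multiplier ``theta`` per material point:

transverse (concentric remodeling, parallel sarcomere deposition)
    ``Fg = theta I + (1 - theta) f0 x f0`` — the cell cross-section grows
    isotropically perpendicular to the fiber; ``theta = sqrt(det Fg)`` is the
    cell thickening, grown volume ratio ``Jg = theta^2``.

longitudinal (eccentric remodeling, serial sarcomere deposition)
    ``Fg = I + (theta - 1) f0 x f0`` — the cell lengthens along the fiber;
    ``theta = det Fg = Jg``.

Both growth tensors are rank-one updates of the identity, so their inverses
are available in closed form via the Sherman-Morrison formula and the
elastic tensor ``Fe = F . Fg^-1`` never requires a numerical inverse.

Kinetics: ``dtheta/dt = <lambda - lambda_crit> / tau`` with the Macaulay
bracket ``<x> = max(x, 0)`` — growth is switched on only while the current
total fiber stretch ``lambda = |F . f0|`` exceeds the pointwise homeostatic
threshold ``lambda_crit`` recorded under baseline loading.  Growth is
irreversible: ``theta`` never decreases.  Time is normalized (the physical
counterpart is months to years); the explicit first-order update is
``theta = theta_n + <lambda - lambda_crit> dt / tau``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .errors import CalibrationError, FrameError, InvalidGrowthStateError
from .tensors import _I3

__all__ = [
    "GrowthState",
    "transverse_growth_tensor",
    "transverse_elastic_tensor",
    "longitudinal_growth_tensor",
    "longitudinal_elastic_tensor",
    "fiber_stretch",
    "growth_rate",
    "update_growth",
    "calibrate_lambda_crit",
    "GROWTH_MODES",
]

GROWTH_MODES = ("transverse", "longitudinal")

_UNIT_TOL = 1e-8


def _check_unit(f0: np.ndarray) -> np.ndarray:
    f0 = np.asarray(f0, dtype=float)
    if np.any(np.abs(np.linalg.norm(f0, axis=-1) - 1.0) > _UNIT_TOL):
        raise FrameError("fiber direction f0 must be a unit vector")
    return f0


def _check_theta(theta) -> np.ndarray:
    theta = np.asarray(theta, dtype=float)
    if np.any(theta <= 0):
        raise InvalidGrowthStateError("growth multiplier theta must be positive")
    return theta


def _outer(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return a[..., :, None] * b[..., None, :]


def transverse_growth_tensor(theta, f0) -> np.ndarray:
    """``Fg = theta I + (1 - theta) f0 x f0``: eigenvalue 1 along the fiber,
    eigenvalue ``theta`` (twice) transverse; ``det Fg = theta^2``."""
    theta = _check_theta(theta)
    f0 = _check_unit(f0)
    t = theta[..., None, None]
    return t * _I3 + (1.0 - t) * _outer(f0, f0)


def transverse_elastic_tensor(F, theta, f0) -> np.ndarray:
    """Closed-form ``Fe = F/theta + (theta-1)/theta f x f0`` with
    ``f = F . f0`` (Sherman-Morrison inverse of the transverse ``Fg``)."""
    theta = _check_theta(theta)
    f0 = _check_unit(f0)
    F = np.asarray(F, dtype=float)
    f = np.einsum("...ij,...j->...i", F, f0)
    t = theta[..., None, None]
    return F / t + (t - 1.0) / t * _outer(f, f0)


def longitudinal_growth_tensor(theta, f0) -> np.ndarray:
    """``Fg = I + (theta - 1) f0 x f0``: eigenvalue ``theta`` along the
    fiber, eigenvalue 1 transverse; ``det Fg = theta``."""
    theta = _check_theta(theta)
    f0 = _check_unit(f0)
    t = theta[..., None, None]
    return _I3 + (t - 1.0) * _outer(f0, f0)


def longitudinal_elastic_tensor(F, theta, f0) -> np.ndarray:
    """Closed-form ``Fe = F + (1-theta)/theta f x f0`` with ``f = F . f0``."""
    theta = _check_theta(theta)
    f0 = _check_unit(f0)
    F = np.asarray(F, dtype=float)
    f = np.einsum("...ij,...j->...i", F, f0)
    t = theta[..., None, None]
    return F + (1.0 - t) / t * _outer(f, f0)


def fiber_stretch(F, f0) -> np.ndarray:
    """Total fiber stretch ``lambda = [f0 . F^T F . f0]^(1/2) = |F . f0|``."""
    f0 = _check_unit(f0)
    F = np.asarray(F, dtype=float)
    return np.linalg.norm(np.einsum("...ij,...j->...i", F, f0), axis=-1)


def growth_rate(lam, lambda_crit, tau: float) -> np.ndarray:
    """``dtheta/dt = <lambda - lambda_crit> / tau`` (Macaulay bracket)."""
    return np.maximum(np.asarray(lam, float) - np.asarray(lambda_crit, float), 0.0) / tau


def update_growth(theta_n, lam, lambda_crit, tau: float, dt: float,
                  theta_max: Optional[float] = None) -> np.ndarray:
    """Explicit update ``theta = theta_n + <lambda - lambda_crit> dt / tau``,
    clamped to ``theta_max`` when configured.  Never decreases theta."""
    if dt <= 0:
        raise InvalidGrowthStateError("dt must be positive")
    theta = np.asarray(theta_n, float) + growth_rate(lam, lambda_crit, tau) * dt
    if theta_max is not None:
        theta = np.minimum(theta, theta_max)
        theta = np.maximum(theta, theta_n)  # cap never pulls theta below theta_n
    return theta


def calibrate_lambda_crit(baseline_stretch, converged: bool = True) -> np.ndarray:
    """Homeostatic thresholds as a pointwise copy of the converged baseline
    fiber-stretch field.  Immediately reloading the baseline then yields
    exactly zero growth rate (the bracket kills the zero excess)."""
    if not converged:
        raise CalibrationError("baseline solve did not converge; cannot calibrate")
    return np.array(baseline_stretch, dtype=float, copy=True)


@dataclass
class GrowthState:
    """Per-integration-point growth state of one simulation.

    theta : growth multipliers, one per integration point (>= 1 at init).
    mode : "transverse" or "longitudinal".
    lambda_crit : homeostatic fiber stretch per point (calibrated; 1.0 before
        calibration, i.e. a stress-free reference threshold).
    tau : growth time constant in normalized time.
    theta_max : optional cap emulating growth-limiting kinetics (off by default).
    mask : boolean growth-region mask per point (False = non-growing tissue).
    """

    theta: np.ndarray
    mode: str
    lambda_crit: np.ndarray
    tau: float = 1.0
    theta_max: Optional[float] = None
    mask: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.mode not in GROWTH_MODES:
            raise InvalidGrowthStateError(f"unknown growth mode {self.mode!r}")
        if self.tau <= 0:
            raise InvalidGrowthStateError("tau must be positive")
        self.theta = np.asarray(self.theta, dtype=float)
        self.lambda_crit = np.asarray(self.lambda_crit, dtype=float)
        if np.any(self.theta <= 0) or np.any(self.lambda_crit <= 0):
            raise InvalidGrowthStateError("theta and lambda_crit must be positive")

    @classmethod
    def initial(cls, n_points: int, mode: str, tau: float = 1.0,
                theta_max: Optional[float] = None,
                mask: Optional[np.ndarray] = None) -> "GrowthState":
        return cls(
            theta=np.ones(n_points),
            mode=mode,
            lambda_crit=np.ones(n_points),
            tau=tau,
            theta_max=theta_max,
            mask=mask,
        )

    def growth_tensors(self, f0: np.ndarray) -> np.ndarray:
        """Batched growth tensors for the current multipliers; identity on
        masked-out (non-growing) points."""
        if self.mode == "transverse":
            Fg = transverse_growth_tensor(self.theta, f0)
        else:
            Fg = longitudinal_growth_tensor(self.theta, f0)
        if self.mask is not None:
            Fg = np.where(self.mask[..., None, None], Fg, _I3)
        return Fg

    def jg(self) -> np.ndarray:
        """Grown volume ratio ``Jg = det Fg`` (theta^2 transverse, theta
        longitudinal)."""
        return self.theta**2 if self.mode == "transverse" else self.theta.copy()

    def updated(self, lam: np.ndarray, dt: float) -> "GrowthState":
        """New state after one explicit kinetic step driven by the fiber
        stretch field ``lam``; non-growing points keep their multiplier."""
        theta_new = update_growth(self.theta, lam, self.lambda_crit, self.tau, dt,
                                  self.theta_max)
        if self.mask is not None:
            theta_new = np.where(self.mask, theta_new, self.theta)
        return replace(self, theta=theta_new)

    def calibrated(self, baseline_stretch: np.ndarray, converged: bool = True) -> "GrowthState":
        return replace(self, lambda_crit=calibrate_lambda_crit(baseline_stretch, converged))
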