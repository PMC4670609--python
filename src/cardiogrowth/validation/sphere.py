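"""Semi-analytic thick-walled sphere under internal pressure.

Independent 1-D oracle for the FE solver: with an isotropic reduction of
the Fung weights (all entries of the weight matrix equal, so the exponent
becomes ``b * Ebar : Ebar``) the inflation of a spherical shell is a
spherically symmetric problem.  The radial equilibrium ODE

    d(sigma_rr)/dR = -2 (sigma_rr - sigma_tt) / r * dr/dR

is integrated in the reference radius ``R`` from the inner surface
(``sigma_rr = -p``) outward, with the radial stretch at every station
recovered by scalar root finding from the constitutive law, and the inner
deformed radius determined by shooting on the traction-free outer surface.

This module deliberately shares no code with the tensorial constitutive
routines: the energy is written in principal stretches and differentiated
by central finite differences, so agreement with the 3-D FE solution is a
genuine cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = ["SphereBenchmark", "solve_thick_sphere"]


def _energy(lam_r: float, lam_t: float, C0: float, b: float, D0: float) -> float:
    J = lam_r * lam_t * lam_t
    if J <= 0:
        return np.inf
    s = J ** (-2.0 / 3.0)
    Er = 0.5 * (s * lam_r**2 - 1.0)
    Et = 0.5 * (s * lam_t**2 - 1.0)
    U = (J * J - 2.0 * np.log(J)) / (2.0 * D0)
    Q = b * (Er * Er + 2.0 * Et * Et)
    return U + 0.5 * C0 * np.expm1(Q)


def _sigma(lam_r: float, lam_t: float, C0: float, b: float, D0: float):
    """Principal Cauchy stresses (radial, hoop) by central differences of
    the scalar energy: sigma_i = lam_i dpsi/dlam_i / J (hoop counted once)."""
    J = lam_r * lam_t * lam_t
    hr = 1e-6 * max(1.0, lam_r)
    ht = 1e-6 * max(1.0, lam_t)
    dpsi_dr = (_energy(lam_r + hr, lam_t, C0, b, D0) - _energy(lam_r - hr, lam_t, C0, b, D0)) / (2 * hr)
    dpsi_dt = (_energy(lam_r, lam_t + ht, C0, b, D0) - _energy(lam_r, lam_t - ht, C0, b, D0)) / (2 * ht)
    sig_r = lam_r * dpsi_dr / J
    sig_t = lam_t * dpsi_dt / (2.0 * J)
    return sig_r, sig_t


@dataclass(frozen=True)
class SphereBenchmark:
    """Solution of the inflated spherical shell.

    R : reference radii of the integration grid (mm).
    r : deformed radii (mm).
    sigma_rr : radial Cauchy stress along the grid (kPa).
    """

    R: np.ndarray
    r: np.ndarray
    sigma_rr: np.ndarray

    @property
    def inner_displacement(self) -> float:
        return float(self.r[0] - self.R[0])

    @property
    def outer_displacement(self) -> float:
        return float(self.r[-1] - self.R[-1])

    def radial_displacement(self, R: np.ndarray) -> np.ndarray:
        return np.interp(R, self.R, self.r - self.R)


def _lambda_r(sig_r: float, lam_t: float, C0: float, b: float, D0: float) -> float:
    """Invert the monotone map lam_r -> sigma_rr by bracketed root finding;
    the bracket grows outward from 1 and overflow of the Fung exponential at
    extreme trial stretches is treated as an infinite stress of the
    appropriate sign."""

    def f(lr: float) -> float:
        s = _sigma(lr, lam_t, C0, b, D0)[0]
        if not np.isfinite(s):
            return np.inf if lr > 1.0 else -np.inf
        return s - sig_r

    lo, hi = 0.8, 1.25
    while f(lo) > 0 and lo > 1e-3:
        lo *= 0.7
    while f(hi) < 0 and hi < 50.0:
        hi *= 1.3
    return brentq(f, lo, hi, xtol=1e-13, rtol=1e-14)


def solve_thick_sphere(
    Ri: float,
    Ro: float,
    p_kPa: float,
    C0: float,
    b: float,
    D0: float,
    n_steps: int = 400,
) -> SphereBenchmark:
    """Shoot on the inner deformed radius so that the outer surface is
    traction free; fixed-step RK4 in the reference radius (deterministic)."""
    Rs = np.linspace(Ri, Ro, n_steps + 1)
    h = Rs[1] - Rs[0]

    def integrate(ri: float):
        r, sig = ri, -p_kPa
        rr = np.empty(n_steps + 1)
        ss = np.empty(n_steps + 1)
        rr[0], ss[0] = r, sig

        def rhs(R, y):
            r_, s_ = y
            lt = r_ / R
            lr = _lambda_r(s_, lt, C0, b, D0)
            _, st = _sigma(lr, lt, C0, b, D0)
            return np.array([lr, -2.0 * (s_ - st) / r_ * lr])

        y = np.array([r, sig])
        for k in range(n_steps):
            R = Rs[k]
            k1 = rhs(R, y)
            k2 = rhs(R + h / 2, y + h / 2 * k1)
            k3 = rhs(R + h / 2, y + h / 2 * k2)
            k4 = rhs(R + h, y + h * k3)
            y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            rr[k + 1], ss[k + 1] = y
        return rr, ss

    def outer_traction(ri: float) -> float:
        return integrate(ri)[1][-1]

    ri = brentq(outer_traction, Ri * 1.000001, Ri * 1.8, xtol=1e-11)
    rr, ss = integrate(ri)
    return SphereBenchmark(R=Rs, r=rr, sigma_rr=ss)
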