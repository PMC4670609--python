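"""Local material frames of the myocardium.

Each material point carries a right-handed orthonormal triplet: the fiber
direction ``f0`` (myocyte long axis), the sheet direction ``s0`` (laminar
sheet, pointing transmurally outward in the rule-based architecture), and
the sheet normal ``n0 = f0 x s0``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import FrameError

__all__ = ["FiberFrame"]

_ORTHO_TOL = 1e-8


@dataclass(frozen=True)
class FiberFrame:
    """Batched orthonormal fiber/sheet/normal frames, shape ``(..., 3)`` each."""

    f0: np.ndarray
    s0: np.ndarray
    n0: np.ndarray

    @classmethod
    def from_fiber_sheet(cls, f0, s0) -> "FiberFrame":
        f0 = np.asarray(f0, dtype=float)
        s0 = np.asarray(s0, dtype=float)
        n0 = np.cross(f0, s0)
        frame = cls(f0=f0, s0=s0, n0=n0)
        frame.validate()
        return frame

    def validate(self, tol: float = _ORTHO_TOL) -> None:
        """Raise :class:`FrameError` unless unit, orthogonal and right-handed."""
        for name, v in (("f0", self.f0), ("s0", self.s0), ("n0", self.n0)):
            err = np.abs(np.linalg.norm(v, axis=-1) - 1.0)
            if np.any(err > tol):
                raise FrameError(f"{name} not unit length (max dev {err.max():g})")
        for a, b, name in (
            (self.f0, self.s0, "f0.s0"),
            (self.f0, self.n0, "f0.n0"),
            (self.s0, self.n0, "s0.n0"),
        ):
            dot = np.abs(np.sum(a * b, axis=-1))
            if np.any(dot > tol):
                raise FrameError(f"frame not orthogonal: |{name}| up to {dot.max():g}")
        hand = np.sum(np.cross(self.f0, self.s0) * self.n0, axis=-1)
        if np.any(hand < 1.0 - 1e-6):
            raise FrameError("frame not right-handed")

    def rotation(self) -> np.ndarray:
        """Rotation matrices ``(..., 3, 3)`` with columns ``(f0, s0, n0)``.

        ``Q.T @ A @ Q`` expresses a global-frame tensor ``A`` in fiber
        coordinates.
        """
        return np.stack([self.f0, self.s0, self.n0], axis=-1)

    def __getitem__(self, idx) -> "FiberFrame":
        return FiberFrame(self.f0[idx], self.s0[idx], self.n0[idx])

    @property
    def shape(self):
        return self.f0.shape[:-1]
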