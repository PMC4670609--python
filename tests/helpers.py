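"""Shared random-state generators for the test suite."""

import numpy as np


def random_rotation(rng: np.random.Generator, n=()) -> np.ndarray:
    """Random rotation matrices via sign-fixed QR of Gaussian matrices."""
    a = rng.standard_normal(n + (3, 3))
    q, r = np.linalg.qr(a)
    d = np.sign(np.diagonal(r, axis1=-2, axis2=-1))
    q = q * d[..., None, :]
    det = np.linalg.det(q)
    q[..., :, 0] *= det[..., None]
    return q


def random_deformation(rng: np.random.Generator, n=(), scale=0.2) -> np.ndarray:
    """Random deformation gradients with safely positive determinant."""
    F = np.eye(3) + scale * rng.standard_normal(n + (3, 3))
    d = np.linalg.det(F)
    bad = d <= 0.05
    while np.any(bad):
        F[bad] = np.eye(3) + scale * rng.standard_normal((int(bad.sum()), 3, 3))
        d = np.linalg.det(F)
        bad = d <= 0.05
    return F


def random_unit_vectors(rng: np.random.Generator, n=()) -> np.ndarray:
    v = rng.standard_normal(n + (3,))
    return v / np.linalg.norm(v, axis=-1, keepdims=True)
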