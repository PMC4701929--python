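"""Small 3D vector helpers used by the growth kernels and the generator."""

from __future__ import annotations

import numpy as np

_EPS = 1e-12


def unit(v: np.ndarray) -> np.ndarray:
    n = float(np.linalg.norm(v))
    if n < _EPS:
        raise ValueError("cannot normalize a zero vector")
    return v / n


def orthonormal_frame(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors spanning the plane perpendicular to ``axis`` (unit)."""
    # pick the coordinate axis least aligned with `axis` to avoid degeneracy
    helper = np.zeros(3)
    helper[int(np.argmin(np.abs(axis)))] = 1.0
    b1 = unit(np.cross(axis, helper))
    b2 = np.cross(axis, b1)
    return b1, b2


def perpendicular_unit(axis: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """A unit vector perpendicular to ``axis`` with uniformly random azimuth."""
    b1, b2 = orthonormal_frame(axis)
    phi = rng.uniform(0.0, 2.0 * np.pi)
    return np.cos(phi) * b1 + np.sin(phi) * b2


def sample_cone(
    axis: np.ndarray, half_angle_rad: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw a direction uniformly (by solid angle) within a cone around
    ``axis`` (unit vector) of the given half-angle."""
    cos_min = np.cos(half_angle_rad)
    cos_t = rng.uniform(cos_min, 1.0)
    sin_t = np.sqrt(max(0.0, 1.0 - cos_t * cos_t))
    b1, b2 = orthonormal_frame(axis)
    phi = rng.uniform(0.0, 2.0 * np.pi)
    return cos_t * axis + sin_t * (np.cos(phi) * b1 + np.sin(phi) * b2)


def rotate_towards(axis: np.ndarray, perp: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rotate unit vector ``axis`` by ``angle_rad`` towards the unit vector
    ``perp`` (which must be perpendicular to it)."""
    return np.cos(angle_rad) * axis + np.sin(angle_rad) * perp
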