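"""Beam/detector geometry and rotation-series bookkeeping.

Conventions (fixed throughout the package):

* incident beam along +z with wavevector k = (0, 0, 1/lambda) - the
  cycles-per-angstrom convention |k| = 1/lambda, so the wavelet phase
  2*pi*r.(k - k') is in radians with no hidden factors;
* flat detector perpendicular to the beam at ``distance`` mm, fast axis
  along lab x, slow axis along lab y, 0-based pixel indices, amplitudes
  evaluated at pixel centers;
* the crystal rotates about the lab x axis;
* momentum transfer q = k - k', and s = |q|/2 = sin(theta)/lambda is the
  form-factor argument.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DetectorGeometry",
    "RotationSeries",
    "as_orientation",
    "rotation_about_x",
    "axis_rotation",
    "pixel_to_kprime",
    "momentum_transfer",
    "detector_q_grid",
    "rotate_coordinates",
    "frame_plan",
]


@dataclass(frozen=True)
class DetectorGeometry:
    """Beam + detector parameters.

    wavelength in angstroms; distance and pixel pitch in mm; raster is
    (n_fast, n_slow); beam center in (fast, slow) pixel units.
    """

    wavelength: float
    distance: float
    pixel_size: float
    n_fast: int
    n_slow: int
    beam_center: tuple[float, float]

    def __post_init__(self) -> None:
        if self.wavelength <= 0 or self.distance <= 0 or self.pixel_size <= 0:
            raise ValueError("wavelength, distance and pixel size must be > 0")
        cf, cs = self.beam_center
        if not (0 <= cf < self.n_fast and 0 <= cs < self.n_slow):
            raise ValueError("beam center must lie inside the raster")

    @property
    def k_in(self) -> np.ndarray:
        return np.array([0.0, 0.0, 1.0 / self.wavelength])

    @property
    def shape(self) -> tuple[int, int]:
        """numpy raster shape (n_slow, n_fast): slow axis first."""
        return (self.n_slow, self.n_fast)


def _check_pixels(p: np.ndarray, geom: DetectorGeometry) -> None:
    if np.any(p[..., 0] < 0) or np.any(p[..., 0] > geom.n_fast - 1) or \
       np.any(p[..., 1] < 0) or np.any(p[..., 1] > geom.n_slow - 1):
        raise ValueError("pixel outside raster")


def pixel_to_kprime(p, geom: DetectorGeometry) -> np.ndarray:
    """Scattered wavevector k' (|k'| = 1/lambda) toward pixel p = (fast, slow)."""
    p = np.asarray(p, dtype=float)
    _check_pixels(p, geom)
    cf, cs = geom.beam_center
    lab = np.stack(
        [
            (p[..., 0] - cf) * geom.pixel_size,
            (p[..., 1] - cs) * geom.pixel_size,
            np.broadcast_to(geom.distance, p[..., 0].shape).copy(),
        ],
        axis=-1,
    )
    unit = lab / np.linalg.norm(lab, axis=-1, keepdims=True)
    return unit / geom.wavelength


def momentum_transfer(p, geom: DetectorGeometry) -> np.ndarray:
    """s = |k - k'| / 2 = sin(theta)/lambda at pixel p, in 1/A."""
    kprime = pixel_to_kprime(p, geom)
    q = geom.k_in - kprime
    return np.linalg.norm(q, axis=-1) / 2.0


def detector_q_grid(geom: DetectorGeometry):
    """q = k - k' and s for every pixel.

    Returns ``(q, s)`` with q of shape (n_slow, n_fast, 3) and s of shape
    (n_slow, n_fast), both indexed [slow, fast].
    """
    fast, slow = np.meshgrid(np.arange(geom.n_fast), np.arange(geom.n_slow))
    p = np.stack([fast, slow], axis=-1).astype(float)
    kprime = pixel_to_kprime(p, geom)
    q = geom.k_in - kprime
    s = np.linalg.norm(q, axis=-1) / 2.0
    return q, s


def axis_rotation(axis, angle_deg: float) -> np.ndarray:
    """Proper rotation matrix about an arbitrary (normalized) axis."""
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n < 1e-12:
        raise ValueError("zero rotation axis")
    u = axis / n
    t = math.radians(angle_deg)
    c, s = math.cos(t), math.sin(t)
    ux, uy, uz = u
    k = np.array([[0, -uz, uy], [uz, 0, -ux], [-uy, ux, 0]])
    return c * np.eye(3) + s * k + (1 - c) * np.outer(u, u)


def rotation_about_x(angle_deg: float) -> np.ndarray:
    return axis_rotation((1.0, 0.0, 0.0), angle_deg)


def rotate_coordinates(atoms, axis, angle_deg: float):
    """Rigid rotation of a LabeledAtomSet about the origin."""
    rot = axis_rotation(axis, angle_deg)
    return atoms.with_xyz(atoms.xyz @ rot.T)


def as_orientation(matrix) -> np.ndarray:
    """Validate a 3x3 proper rotation (orthogonal, det +1 within 1e-9)."""
    m = np.asarray(matrix, dtype=float)
    if m.shape != (3, 3):
        raise ValueError("orientation must be 3x3")
    if not np.allclose(m @ m.T, np.eye(3), atol=1e-9):
        raise ValueError("orientation matrix is not orthogonal")
    if abs(np.linalg.det(m) - 1.0) > 1e-9:
        raise ValueError("orientation matrix must have determinant +1")
    return m


@dataclass(frozen=True)
class RotationSeries:
    """Rotation protocol: total range tiled into frames built from substeps.

    All angles in degrees.  ``frame_width`` must be an integer multiple of
    the substep and ``total_range`` an integer multiple of the frame width.
    Substeps are placed at substep midpoints within each frame, giving
    unbiased angular coverage of the frame interval.
    """

    start: float = 0.0
    frame_width: float = 1.0
    substep: float = 0.1
    total_range: float = 180.0
    axis: tuple[float, float, float] = (1.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.frame_width <= 0 or self.substep <= 0 or self.total_range <= 0:
            raise ValueError("angles must be positive")
        for whole, part, what in (
            (self.frame_width, self.substep, "frame width / substep"),
            (self.total_range, self.frame_width, "total range / frame width"),
        ):
            ratio = whole / part
            if abs(ratio - round(ratio)) > 1e-9 * max(1.0, ratio):
                raise ValueError(f"{what} must be an integer ratio")

    @property
    def n_frames(self) -> int:
        return round(self.total_range / self.frame_width)

    @property
    def substeps_per_frame(self) -> int:
        return round(self.frame_width / self.substep)

    def frame_interval(self, frame_index: int) -> tuple[float, float]:
        lo = self.start + frame_index * self.frame_width
        return lo, lo + self.frame_width


def frame_plan(series: RotationSeries) -> list[tuple[int, np.ndarray]]:
    """One (frame index, substep midpoint angles) entry per frame.

    Frames tile [start, start + total_range) without overlap.
    """
    n_sub = series.substeps_per_frame
    plan = []
    for f in range(series.n_frames):
        lo, _ = series.frame_interval(f)
        angles = lo + (np.arange(n_sub) + 0.5) * series.substep
        plan.append((f, angles))
    return plan
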