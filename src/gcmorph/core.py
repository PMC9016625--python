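"""Shared domain types for growth-cone cytoskeleton morphometry.

Conventions used throughout the package:

* lengths are in nanometres; angles in degrees unless a function says radians;
* world coordinates are right-handed ``(x, y, z)`` with ``z`` the electron-beam
  direction (the axis along which the missing wedge elongates densities) and
  ``x`` the tilt axis;
* density volumes are numpy arrays indexed ``data[z, y, x]`` with zero-based,
  half-open voxel indexing, so world position ``(x, y, z)`` in nm maps to
  fractional index ``(z/v, y/v, x/v)`` for voxel size ``v``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "GcMorphError",
    "ValidationError",
    "OutOfBoundsError",
    "InsufficientDataError",
    "IndeterminateError",
    "MissingWedge",
    "Volume3D",
    "Centerline",
    "Constants",
    "CONSTANTS",
    "arc_position",
    "resample_centerline",
]


class GcMorphError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(GcMorphError, ValueError):
    """An input violated a documented precondition or invariant."""


class OutOfBoundsError(GcMorphError, ValueError):
    """A coordinate or arc-length parameter fell outside its valid range."""


class InsufficientDataError(GcMorphError, ValueError):
    """Too little data to compute the requested quantity."""


class IndeterminateError(GcMorphError, RuntimeError):
    """The measurement ran but no statistically determinate answer exists."""


@dataclass(frozen=True)
class MissingWedge:
    """Tilt geometry of a single-axis tomogram.

    The unsampled ("missing wedge") region of Fourier space is the set of
    spatial frequencies whose in-plane direction ``atan(kz/ky)`` lies outside
    ``[tilt_min, tilt_max]``; it is invariant along the tilt axis ``kx``.
    """

    tilt_min: float = -60.0
    tilt_max: float = 60.0
    tilt_axis: str = "x"
    increment: float = 3.0

    def __post_init__(self) -> None:
        if not (-90.0 <= self.tilt_min < self.tilt_max <= 90.0):
            raise ValidationError(
                f"require -90 <= tilt_min < tilt_max <= 90, got "
                f"[{self.tilt_min}, {self.tilt_max}]"
            )
        if self.tilt_axis != "x":
            raise ValidationError("only tilt_axis='x' is supported")
        if self.increment <= 0:
            raise ValidationError("tilt increment must be positive")


@dataclass
class Volume3D:
    """A 3D density volume with isotropic physical sampling.

    ``data`` is indexed ``[z, y, x]``; ``voxel_size`` is nm per voxel edge.
    ``wedge`` records the missing-wedge geometry *already applied* to the
    data (``None`` for an unfiltered volume).  ``origin_offset`` is the world
    position in nm of the centre of voxel ``(0, 0, 0)``, as ``(x, y, z)``.
    """

    data: np.ndarray
    voxel_size: float
    wedge: MissingWedge | None = None
    origin_offset: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValidationError("data must be a 3D grid with each axis >= 1")
        if not (self.voxel_size > 0):
            raise ValidationError("voxel_size must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # (nz, ny, nx)

    @property
    def extent_nm(self) -> tuple[float, float, float]:
        """Physical extent ``(x, y, z)`` of the grid in nm."""
        nz, ny, nx = self.data.shape
        return (nx * self.voxel_size, ny * self.voxel_size, nz * self.voxel_size)

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Map world ``(x, y, z)`` nm points to fractional ``(z, y, x)`` indices."""
        p = np.atleast_2d(np.asarray(points, dtype=float)) - np.asarray(self.origin_offset)
        return (p / self.voxel_size)[:, ::-1]

    def copy(self, **changes) -> "Volume3D":
        out = replace(self, **changes)
        if "data" not in changes:
            out.data = self.data.copy()
        return out


class Centerline:
    """Ordered 3D point path with arc-length parameterization.

    The backbone of every filament/microtubule measurement: piecewise-linear,
    points in nm, with strictly increasing cumulative arc length.
    """

    def __init__(self, points: np.ndarray, label: str = ""):
        pts = np.asarray(points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
            raise ValidationError("centerline needs >= 2 points of shape (n, 3)")
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.any(seg <= 0):
            raise ValidationError("consecutive centerline points must be distinct")
        self.points = pts
        self.label = label
        self.arc_length = np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def length(self) -> float:
        return float(self.arc_length[-1])

    def reversed(self) -> "Centerline":
        return Centerline(self.points[::-1].copy(), label=self.label)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Centerline({self.label!r}, n={len(self.points)}, L={self.length:.1f} nm)"


def arc_position(centerline: Centerline, s: float) -> tuple[np.ndarray, np.ndarray]:
    """Point and unit tangent at arc length ``s`` along a piecewise-linear path.

    Raises :class:`OutOfBoundsError` if ``s`` is outside ``[0, length]``.
    """
    al = centerline.arc_length
    if not (0.0 <= s <= al[-1] + 1e-9):
        raise OutOfBoundsError(f"s={s} outside [0, {al[-1]}]")
    s = min(s, al[-1])
    i = int(np.searchsorted(al, s, side="right") - 1)
    i = min(i, len(al) - 2)
    p0, p1 = centerline.points[i], centerline.points[i + 1]
    seg = al[i + 1] - al[i]
    t = (p1 - p0) / seg
    return p0 + (s - al[i]) * t, t


def resample_centerline(centerline: Centerline, spacing: float) -> Centerline:
    """Resample a path at (approximately) uniform arc-length ``spacing``."""
    if spacing <= 0:
        raise ValidationError("spacing must be positive")
    n = max(2, int(round(centerline.length / spacing)) + 1)
    ss = np.linspace(0.0, centerline.length, n)
    pts = np.array([arc_position(centerline, s)[0] for s in ss])
    return Centerline(pts, label=centerline.label)


def tangent_frame(tangent: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """In-plane-first orthonormal frame ``(e1, e2)`` perpendicular to ``tangent``.

    ``e1`` is chosen perpendicular to the beam axis ``z`` whenever possible, so
    profiles sampled along ``e1`` avoid the missing-wedge-degraded direction.
    ``(tangent, e1, e2)`` is right-handed.
    """
    t = np.asarray(tangent, dtype=float)
    t = t / np.linalg.norm(t)
    z = np.array([0.0, 0.0, 1.0])
    e1 = np.cross(z, t)
    n = np.linalg.norm(e1)
    if n < 1e-8:  # tangent along the beam: any transverse pair works
        e1 = np.array([1.0, 0.0, 0.0])
    else:
        e1 = e1 / n
    e2 = np.cross(t, e1)
    return e1, e2


@dataclass(frozen=True)
class Constants:
    """Physical constants of the growth-cone cytoskeleton, in nm unless noted.

    Values are stored at the precision at which they are commonly reported;
    tolerance handling belongs to callers.  The microtubule outer/inner
    diameters are the standard mammalian values (25/15 nm); the 15 nm lumen
    is also what the ~7% lumen-occupancy estimate presumes.
    """

    hex_spacing_short: float = 12.1
    hex_spacing_long: float = 20.9
    crosslink_period: float = 37.1
    half_repeat_long: float = 37.2
    half_repeat_short: float = 27.3
    subunit_shift: float = 5.5
    branch_angle: float = 70.1  # degrees
    pf_number: int = 13
    dimer_rise: float = 8.2
    defect_size_class_threshold: float = 16.0
    taper_threshold: float = 50.0
    particle_diam_mean: float = 7.8
    particle_diam_range: tuple[float, float] = (3.9, 14.7)
    ring_diam_range: tuple[float, float] = (7.0, 10.0)
    erickson_coeff: float = 0.066  # nm per Da^(1/3): R = c * M^(1/3) for a protein sphere
    mt_outer_diameter: float = 25.0
    mt_inner_diameter: float = 15.0

    def __post_init__(self) -> None:
        lengths = [
            self.hex_spacing_short, self.hex_spacing_long, self.crosslink_period,
            self.half_repeat_long, self.half_repeat_short, self.subunit_shift,
            self.dimer_rise, self.defect_size_class_threshold, self.taper_threshold,
            self.particle_diam_mean, self.erickson_coeff,
            self.mt_outer_diameter, self.mt_inner_diameter,
        ]
        if any(v <= 0 for v in lengths):
            raise ValidationError("all length constants must be positive")
        # hexagonal lattice identity: long axis = sqrt(3) * short axis
        if abs(math.sqrt(3.0) * self.hex_spacing_short - self.hex_spacing_long) \
                > 0.01 * self.hex_spacing_long:
            raise ValidationError("hex_spacing_long must be ~sqrt(3) * hex_spacing_short")


CONSTANTS = Constants()
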