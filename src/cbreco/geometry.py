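"""Circular cone-beam acquisition geometry and the voxel-to-detector mapping.

Coordinate conventions
----------------------
Right-handed volume frame with the rotation axis along +z.  A projection at
angle ``phi`` corresponds to the object rotated counter-clockwise by ``phi``
(viewed from +z).  In the rotated frame the X-ray source sits on the +y axis
at distance ``scd`` from the rotation centre and the flat detector lies in
the plane ``y = scd - sdd``, with columns along +x and rows along +z.

Detector pixel centres sit at integer 0-based indices.  The central ray
(source through the rotation axis) meets the detector at column
``(n_u - 1) / 2 + axis_offset_px`` and row ``(n_v - 1) / 2``; a horizontal
rotation-axis misalignment is therefore a pure shift of the detector column
origin.  ``d`` denotes the signed distance of a (rotated) voxel from the
plane through the rotation centre parallel to the detector, positive toward
the source, so the FDK distance weight is ``scd**2 / (scd - d)**2``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["ScanGeometry", "make_geometry", "voxel_to_detector", "distance_weight"]


@dataclass(frozen=True, eq=False)
class ScanGeometry:
    """Validated circular cone-beam scan geometry.

    Attributes
    ----------
    scd : float
        Source to rotation-centre distance (mm).
    sdd : float
        Source to detector distance (mm); ``scd < sdd``.
    pixel_size : float
        Detector pixel pitch (mm), square pixels.
    n_u, n_v : int
        Detector columns / rows.
    angles : numpy.ndarray
        Ordered projection angles in radians; a full scan covers [0, 2pi).
    axis_offset_px : float
        Horizontal rotation-axis offset in detector pixels (signed).
    axis_tilt : tuple of float
        ``(a, m)``: axis offset in pixels at slice 0 and slope in pixels per
        slice of the canonical volume grid (``n_z = n_v``).
    """

    scd: float
    sdd: float
    pixel_size: float
    n_u: int
    n_v: int
    angles: np.ndarray
    axis_offset_px: float = 0.0
    axis_tilt: tuple = (0.0, 0.0)

    @property
    def magnification(self) -> float:
        """Cone-beam magnification at the rotation centre, sdd/scd."""
        return self.sdd / self.scd

    @property
    def voxel_size(self) -> float:
        """Nyquist-matched isotropic voxel pitch: detector pitch demagnified
        to the rotation-centre plane."""
        return self.pixel_size * self.scd / self.sdd

    @property
    def n_proj(self) -> int:
        return len(self.angles)

    @property
    def u_center(self) -> float:
        """Detector column index of the rotation-axis image."""
        return (self.n_u - 1) / 2.0 + self.axis_offset_px

    @property
    def v_center(self) -> float:
        """Detector row index of the central ray."""
        return (self.n_v - 1) / 2.0

    def with_offset(self, axis_offset_px: float) -> "ScanGeometry":
        return replace(self, axis_offset_px=float(axis_offset_px))

    def with_tilt(self, a: float, m: float) -> "ScanGeometry":
        return replace(self, axis_tilt=(float(a), float(m)))

    def with_angles(self, angles) -> "ScanGeometry":
        return replace(self, angles=np.asarray(angles, dtype=float))


def make_geometry(
    scd: float,
    sdd: float,
    pixel_size: float,
    n_u: int,
    n_v: int,
    angles,
    axis_offset_px: float = 0.0,
    axis_tilt=(0.0, 0.0),
) -> ScanGeometry:
    """Build and validate a :class:`ScanGeometry`.

    Raises
    ------
    ValueError
        If ``scd >= sdd``, distances or pitch are non-positive, the detector
        is smaller than 2x2 pixels, or the angle list is empty/non-finite.
    """
    scd = float(scd)
    sdd = float(sdd)
    pixel_size = float(pixel_size)
    if not (0.0 < scd < sdd):
        raise ValueError(f"require 0 < scd < sdd, got scd={scd}, sdd={sdd}")
    if pixel_size <= 0.0:
        raise ValueError(f"pixel_size must be positive, got {pixel_size}")
    n_u = int(n_u)
    n_v = int(n_v)
    if n_u < 2 or n_v < 2:
        raise ValueError(f"detector must be at least 2x2 pixels, got {n_u}x{n_v}")
    angles = np.atleast_1d(np.asarray(angles, dtype=float))
    if angles.size == 0:
        raise ValueError("angle list is empty")
    if not np.all(np.isfinite(angles)):
        raise ValueError("angles must be finite")
    a, m = axis_tilt
    return ScanGeometry(
        scd=scd,
        sdd=sdd,
        pixel_size=pixel_size,
        n_u=n_u,
        n_v=n_v,
        angles=angles,
        axis_offset_px=float(axis_offset_px),
        axis_tilt=(float(a), float(m)),
    )


def voxel_to_detector(point, angle, geometry: ScanGeometry):
    """Map a voxel centre to detector coordinates at a projection angle.

    Parameters
    ----------
    point : tuple of float or array
        ``(x, y, z)`` voxel centre in volume mm coordinates (rotation centre
        at the origin).  Components may be arrays of a common shape.
    angle : float
        Projection angle in radians.
    geometry : ScanGeometry

    Returns
    -------
    Xp, Yp, d
        Detector horizontal/vertical coordinates in mm (origin on the
        central ray) and the signed voxel distance ``d`` in mm from the
        rotation-centre plane, positive toward the source.  The similar-
        triangle magnification is ``sdd / (scd - d)``.
    """
    x, y, z = point
    c = np.cos(angle)
    s = np.sin(angle)
    x_perp = x * c - y * s
    d = x * s + y * c
    scale = geometry.sdd / (geometry.scd - d)
    return x_perp * scale, np.asarray(z) * scale, d


def distance_weight(d, geometry: ScanGeometry):
    """FDK backprojection distance weight ``scd**2 / (scd - d)**2``.

    Equals 1 exactly for a voxel in the rotation-centre plane (``d = 0``) and
    exceeds 1 for voxels nearer the source (``d > 0``).
    """
    return geometry.scd**2 / (geometry.scd - d) ** 2
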