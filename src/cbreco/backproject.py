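"""Voxel-driven FDK backprojection with memory-budgeted chunking.

For every voxel the ray from the source through the voxel centre is
intersected with the detector; the weighted, ramp-filtered projection is
sampled there by full-precision bilinear interpolation and accumulated with
the distance weight ``scd^2/(scd - d)^2``.  The volume is processed in
z-slabs and the projection stack in batches so that arbitrarily large
problems fit a stated memory budget; because every voxel accumulates its
angle sum independently (and batches split that sum sequentially), the
result is independent of the chunking.

The accumulated sum is scaled by ``pi / n_proj * delta_s`` — the angular
step of a full-scan FDK integral (each ray direction is measured twice over
2*pi) times the Riemann factor of the discrete ramp convolution — so that
reconstructed values approximate attenuation per mm.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .geometry import ScanGeometry
from .preprocess import ProjectionStack

__all__ = ["Volume", "ChunkPlan", "bilinear_sample", "plan_chunks", "backproject",
           "reconstruct_slice"]


@dataclass
class Volume:
    """Reconstructed voxel grid.

    ``data`` has shape ``(n_x, n_y, n_z)``; ``voxel_size`` is the isotropic
    pitch in mm; ``origin`` is the mm offset of voxel (0, 0, 0)'s centre
    from the rotation centre.  The z index increases with the detector row
    coordinate.
    """

    data: np.ndarray
    voxel_size: float
    origin: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("volume data must be 3-D")
        self.origin = np.asarray(self.origin, dtype=float)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape

    def axis_coords(self, axis: int) -> np.ndarray:
        """Voxel-centre mm coordinates along one axis."""
        return self.origin[axis] + np.arange(self.data.shape[axis]) * self.voxel_size


@dataclass(frozen=True)
class ChunkPlan:
    """Partition of the reconstruction into volume z-slabs and projection
    batches, each fitting the memory budget.  Ranges are half-open."""

    slabs: Tuple[Tuple[int, int], ...]
    batches: Tuple[Tuple[int, int], ...]
    budget_bytes: int

    def validate(self, n_z: int, n_proj: int) -> None:
        for name, ranges, total in (("slabs", self.slabs, n_z),
                                    ("batches", self.batches, n_proj)):
            pos = 0
            for lo, hi in ranges:
                if lo != pos or hi <= lo:
                    raise ValueError(f"{name} must tile [0, {total}) exactly once")
                pos = hi
            if pos != total:
                raise ValueError(f"{name} must cover [0, {total}), got up to {pos}")


def _tile(total: int, size: int) -> Tuple[Tuple[int, int], ...]:
    return tuple((lo, min(lo + size, total)) for lo in range(0, total, size))


def plan_chunks(volume_shape, n_proj: int, detector_shape, budget_bytes: int,
                itemsize: int = 4) -> ChunkPlan:
    """Greedy maximal z-slab / projection-batch plan under a memory budget.

    The budget must hold one volume slab plus one projection batch at a
    time (``itemsize`` bytes per element, float32 by default).  Slabs are
    maximized first (fewest volume passes); the remaining budget sets the
    batch size.
    """
    nx, ny, nz = (int(s) for s in volume_shape)
    nv, nu = (int(s) for s in detector_shape)
    n_proj = int(n_proj)
    slice_bytes = nx * ny * itemsize
    proj_bytes = nv * nu * itemsize
    minimum = slice_bytes + proj_bytes
    if budget_bytes < minimum:
        raise ValueError(
            f"memory budget {budget_bytes} B too small; one volume slice plus one "
            f"projection needs at least {minimum} B"
        )
    slab = min(nz, (budget_bytes - proj_bytes) // slice_bytes)
    batch = min(n_proj, (budget_bytes - slab * slice_bytes) // proj_bytes)
    return ChunkPlan(slabs=_tile(nz, slab), batches=_tile(n_proj, batch),
                     budget_bytes=int(budget_bytes))


def bilinear_sample(image: np.ndarray, x, y):
    """Full-precision bilinear interpolation of a 2-D image.

    ``x`` is the fractional column and ``y`` the fractional row (scalars or
    arrays).  Coordinates outside ``[0, n-1]`` in either axis contribute 0.
    """
    image = np.asarray(image, dtype=float)
    n_rows, n_cols = image.shape
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    inside = (x >= 0) & (x <= n_cols - 1) & (y >= 0) & (y <= n_rows - 1)

    i0 = np.clip(np.floor(x).astype(int), 0, n_cols - 1)
    j0 = np.clip(np.floor(y).astype(int), 0, n_rows - 1)
    i1 = np.minimum(i0 + 1, n_cols - 1)
    j1 = np.minimum(j0 + 1, n_rows - 1)
    fx = np.clip(x - i0, 0.0, 1.0)
    fy = np.clip(y - j0, 0.0, 1.0)

    v00 = image[j0, i0]
    v01 = image[j0, i1]
    v10 = image[j1, i0]
    v11 = image[j1, i1]
    val = (v00 * (1 - fx) * (1 - fy) + v01 * fx * (1 - fy)
           + v10 * (1 - fx) * fy + v11 * fx * fy)
    result = np.where(inside, val, 0.0)
    if result.ndim == 0:
        return float(result)
    return result


def backproject(stack: ProjectionStack, geometry: ScanGeometry,
                plan: Optional[ChunkPlan] = None,
                shape: Optional[Sequence[int]] = None,
                origin: Optional[Sequence[float]] = None) -> Volume:
    """Voxel-driven FDK backprojection of a weighted, filtered stack.

    ``shape`` defaults to the canonical grid ``(n_u, n_u, n_v)`` with the
    Nyquist-matched voxel size and the rotation centre in the middle.  When
    the geometry carries an axis tilt ``(a, m)``, detector sampling is
    shifted horizontally by ``a + m * iz`` with ``iz`` the slice index on
    the canonical grid (sub-volumes convert through their z coordinate, so
    the correction is consistent for any slab).
    """
    if stack.stage != "filtered":
        raise ValueError(f"backproject expects a filtered stack, got stage {stack.stage!r}")
    if stack.data.shape[1:] != (geometry.n_v, geometry.n_u):
        raise ValueError("stack and geometry detector dimensions differ")

    vs = geometry.voxel_size
    if shape is None:
        shape = (geometry.n_u, geometry.n_u, geometry.n_v)
    nx, ny, nz = (int(s) for s in shape)
    if origin is None:
        origin = -(np.array([nx, ny, nz], dtype=float) - 1.0) / 2.0 * vs
    origin = np.asarray(origin, dtype=float)
    if plan is None:
        plan = ChunkPlan(slabs=((0, nz),), batches=((0, stack.n_proj),),
                         budget_bytes=0)
    plan.validate(nz, stack.n_proj)

    xs = origin[0] + np.arange(nx) * vs
    ys = origin[1] + np.arange(ny) * vs
    zs = origin[2] + np.arange(nz) * vs
    X, Y = np.meshgrid(xs, ys, indexing="ij")

    scd, sdd, pix = geometry.scd, geometry.sdd, geometry.pixel_size
    a_t, m_t = geometry.axis_tilt
    has_tilt = a_t != 0.0 or m_t != 0.0
    # per-slice horizontal shift in px, indexed on the canonical grid
    if has_tilt:
        iz_canonical = zs / vs + (geometry.n_v - 1) / 2.0
        tilt_shift = a_t + m_t * iz_canonical
    else:
        tilt_shift = np.zeros(nz)

    vol = np.zeros((nx, ny, nz))
    for b_lo, b_hi in plan.batches:
        for k in range(b_lo, b_hi):
            phi = stack.angles[k]
            proj = stack.data[k]
            c, s = np.cos(phi), np.sin(phi)
            x_perp = X * c - Y * s
            d = X * s + Y * c
            mag = sdd / (scd - d)
            w2 = (scd / (scd - d)) ** 2
            u_base = x_perp * mag / pix + geometry.u_center
            for z_lo, z_hi in plan.slabs:
                z_block = zs[z_lo:z_hi]
                v_px = z_block[:, None, None] * mag[None] / pix + geometry.v_center
                if has_tilt:
                    u_px = u_base[None] + tilt_shift[z_lo:z_hi, None, None]
                else:
                    u_px = np.broadcast_to(u_base, (z_hi - z_lo, nx, ny))
                vals = bilinear_sample(proj, u_px, v_px)
                vol[:, :, z_lo:z_hi] += np.transpose(vals * w2[None], (1, 2, 0))

    vol *= np.pi / stack.n_proj * vs
    return Volume(data=vol, voxel_size=vs, origin=origin)


def reconstruct_slice(stack: ProjectionStack, geometry: ScanGeometry, z_index: int,
                      n_xy: Optional[int] = None) -> np.ndarray:
    """Reconstruct a single z-slice of the canonical volume grid.

    ``z_index`` addresses the canonical ``n_z = n_v`` stack; returns an
    ``(n_xy, n_xy)`` image.  Used by the rotation-axis autofocus search,
    where many single-slice reconstructions are scored.
    """
    if n_xy is None:
        n_xy = geometry.n_u
    vs = geometry.voxel_size
    z_mm = (z_index - (geometry.n_v - 1) / 2.0) * vs
    origin = np.array([-(n_xy - 1) / 2.0 * vs, -(n_xy - 1) / 2.0 * vs, z_mm])
    volume = backproject(stack, geometry, shape=(n_xy, n_xy, 1), origin=origin)
    return volume.data[:, :, 0]
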