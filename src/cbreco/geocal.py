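"""Geometry auto-calibration: rotation-axis offset by autofocus and axis
tilt by linear least squares.

A mis-centred rotation axis blurs or doubles edges in reconstructed slices.
The offset is found like a camera autofocus: a single slice is reconstructed
for a sweep of candidate offsets, each candidate is scored by an
edge-sharpness functional (bilateral denoise, Sobel gradient, sum of
squares), and the sharpest candidate wins, refined to sub-grid precision by
a parabola through the best score triplet.  When the offset varies linearly
with slice height (tilted axis), offsets estimated at several heights are
fitted with an ordinary least-squares line ``f(z) = a + m*z`` whose
coefficients feed the per-slice correction in the backprojector.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skimage.filters import sobel
from skimage.restoration import denoise_bilateral

from .backproject import reconstruct_slice
from .filterbank import make_kernel, filter_rows, weight_projections
from .geometry import ScanGeometry
from .preprocess import ProjectionStack

logger = logging.getLogger(__name__)

__all__ = [
    "SharpnessConfig",
    "OffsetSearch",
    "TiltFit",
    "sharpness_score",
    "find_axis_offset",
    "fit_axis_tilt",
]


@dataclass(frozen=True)
class SharpnessConfig:
    """Sharpness-score settings: central processing-window fraction
    (window edge ``L = margin_factor * w / 2``) and bilateral-filter
    parameters (spatial sigma in px, range sigma as a fraction of the slice
    dynamic range).  The derivative operator is a fixed 3x3 Sobel."""

    margin_factor: float = 0.8
    sigma_spatial: float = 3.0
    sigma_range_frac: float = 0.1

    def __post_init__(self):
        if not 0.0 < self.margin_factor < 1.0:
            raise ValueError("margin_factor must be in (0, 1)")


@dataclass(frozen=True)
class OffsetSearch:
    """Axis-offset search grid: slice to focus on, offset range [lo, hi] in
    pixels, coarse step, and whether to refine below the grid step."""

    slice_index: int
    lo: float
    hi: float
    step: float = 1.0
    refine: bool = True

    def __post_init__(self):
        if not self.lo < self.hi:
            raise ValueError("require lo < hi")
        if self.step <= 0:
            raise ValueError("step must be positive")


@dataclass
class TiltFit:
    """Result of the tilt line fit: sampled slice positions and offsets,
    fitted intercept ``a`` (px at slice 0), slope ``m`` (px per slice) and
    the residual norm."""

    positions: np.ndarray
    offsets: np.ndarray
    a: float
    m: float
    residual_norm: float


def sharpness_score(slice_image: np.ndarray, cfg: SharpnessConfig = SharpnessConfig()) -> float:
    """Edge-sharpness score of a tomogram slice (autofocus functional).

    Crops the central ``L x L`` window with ``L = margin_factor * w / 2``,
    applies edge-preserving bilateral smoothing, takes the Sobel gradient
    magnitude and returns the sum of its squares.  Zero for a constant
    image; invariant to adding a constant; scales with the square of a
    global intensity factor (so score *rankings* are scale-free).
    """
    img = np.asarray(slice_image, dtype=float)
    w = min(img.shape)
    L = int(round(cfg.margin_factor * w / 2.0))
    if L < 8:
        raise ValueError(f"processing window {L} px too small (need >= 8)")
    r0 = (img.shape[0] - L) // 2
    c0 = (img.shape[1] - L) // 2
    crop = img[r0 : r0 + L, c0 : c0 + L]

    span = float(crop.max() - crop.min())
    if span == 0.0:
        return 0.0
    shifted = crop - crop.min()
    smooth = denoise_bilateral(shifted, sigma_color=cfg.sigma_range_frac * span,
                               sigma_spatial=cfg.sigma_spatial)
    grad = sobel(smooth)
    return float(np.sum(grad * grad))


def _score_offset(stack: ProjectionStack, geometry: ScanGeometry, offset: float,
                  slice_index: int, kernel_family: str, cfg: SharpnessConfig) -> float:
    geom = geometry.with_offset(offset)
    weighted = weight_projections(stack, geom)
    kernel = make_kernel(kernel_family, geom.n_u, geom.voxel_size)
    filtered = filter_rows(weighted, kernel)
    image = reconstruct_slice(filtered, geom, slice_index)
    return sharpness_score(image, cfg)


def find_axis_offset(stack: ProjectionStack, geometry: ScanGeometry, search: OffsetSearch,
                     cfg: SharpnessConfig = SharpnessConfig(),
                     kernel_family: str = "ram-lak") -> float:
    """Estimate the horizontal rotation-axis offset in detector pixels.

    Reconstructs the chosen slice (near-central recommended: cone-beam
    artifacts vanish there) for every candidate offset on the coarse grid,
    scores each reconstruction, picks the argmax (ties broken toward the
    smaller magnitude) and, when ``search.refine`` is set, interpolates a
    parabola through the best triplet for sub-grid precision.  The slice
    must contain object structure; featureless slices defeat any autofocus.
    """
    if stack.stage != "attenuation":
        raise ValueError(f"find_axis_offset expects attenuation, got {stack.stage!r}")
    n_steps = int(np.floor((search.hi - search.lo) / search.step + 0.5))
    candidates = search.lo + search.step * np.arange(n_steps + 1)
    scores = np.array([
        _score_offset(stack, geometry, o, search.slice_index, kernel_family, cfg)
        for o in candidates
    ])

    best_score = scores.max()
    ties = np.flatnonzero(scores == best_score)
    i_best = ties[np.argmin(np.abs(candidates[ties]))]

    if i_best == 0 or i_best == len(candidates) - 1:
        warnings.warn(
            f"sharpness maximum at search boundary {candidates[i_best]:+.3f} px; "
            "widen the offset range", stacklevel=2)
        return float(candidates[i_best])

    offset = float(candidates[i_best])
    if search.refine:
        s0, s1, s2 = scores[i_best - 1 : i_best + 2]
        denom = s0 - 2.0 * s1 + s2
        if denom < 0:  # proper maximum
            delta = 0.5 * (s0 - s2) / denom
            offset += float(np.clip(delta, -1.0, 1.0)) * search.step
    return offset


def fit_axis_tilt(positions: Sequence[float], offsets: Sequence[float]) -> TiltFit:
    """Ordinary least-squares line through per-slice axis offsets.

    Solves ``min_C || f - X C ||^2`` with design matrix ``X = [1, z]`` and
    returns intercept ``a`` (offset in px at slice 0) and slope ``m``
    (px per slice).  Requires at least two distinct slice positions.
    """
    x = np.asarray(positions, dtype=float).ravel()
    f = np.asarray(offsets, dtype=float).ravel()
    if x.shape != f.shape or x.size < 2:
        raise ValueError("need matching positions/offsets with >= 2 samples")
    if np.unique(x).size < 2:
        raise ValueError("all slice positions identical: tilt slope is unidentifiable")
    design = np.column_stack([np.ones_like(x), x])
    coef, _, _, _ = np.linalg.lstsq(design, f, rcond=None)
    resid = float(np.linalg.norm(design @ coef - f))
    return TiltFit(positions=x, offsets=f, a=float(coef[0]), m=float(coef[1]),
                   residual_norm=resid)
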