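"""Projection pre-processing: flat/dark normalization with fluence options,
beam-hardening linearization, log transform, defect-pixel detection/repair
and detector-line-ratio (DLR) ring-artifact correction.

The processing chain mirrors a standard laboratory micro-CT workflow: raw
counts are flat/dark corrected and fluence-scaled, defect pixels (which stay
on fixed detector coordinates while object structure moves from projection
to projection) are masked and median-repaired, residual per-pixel detector
gain is equalized by a sensitivity correction matrix (SCM) built from
detector line ratios, and only then is the logarithm taken to obtain
attenuation line integrals.  Beam hardening is linearized post-log with an
empirical polynomial ``f(x) = a*x + b*x**c``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

__all__ = [
    "ProjectionStack",
    "NormalizationConfig",
    "BHCParams",
    "OutlierConfig",
    "normalize",
    "to_attenuation",
    "bhc_correct",
    "calibrate_bhc",
    "find_outlier_mask",
    "repair_defects",
    "build_scm_dlr",
    "apply_scm",
    "ring_metric",
]

STAGES = ("raw", "normalized", "attenuation", "filtered")

#: transmission clamp applied before the logarithm
EPS_TRANSMISSION = 1e-6


@dataclass
class ProjectionStack:
    """Ordered stack of 2-D detector images with a processing-stage tag.

    ``data`` has shape ``(n_proj, n_v, n_u)``; ``stage`` is one of
    ``raw -> normalized -> attenuation -> filtered``; ``angles`` holds the
    projection angle (radians) of each image.
    """

    data: np.ndarray
    stage: str
    angles: np.ndarray = field(default=None)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"projection stack must be 3-D, got {self.data.ndim}-D")
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        if self.angles is None:
            self.angles = np.linspace(0.0, 2.0 * np.pi, self.data.shape[0], endpoint=False)
        self.angles = np.asarray(self.angles, dtype=float)
        if len(self.angles) != self.data.shape[0]:
            raise ValueError("angles length must match number of projections")

    @property
    def n_proj(self) -> int:
        return self.data.shape[0]

    @property
    def n_v(self) -> int:
        return self.data.shape[1]

    @property
    def n_u(self) -> int:
        return self.data.shape[2]

    def with_data(self, data, stage=None) -> "ProjectionStack":
        return ProjectionStack(data, stage or self.stage, self.angles)


@dataclass
class NormalizationConfig:
    """Flat/dark normalization settings.

    mode
        ``none``: input already fluence corrected, keep the up-scaled values;
        ``roi_fluence``: divide each projection by the mean of a background
        ROI; ``flat_mean``: divide by the mean open-beam level.
    dark, flat
        Detector-sized reference frames (beam off / beam on, no object).
    roi
        ``(u0, v0, width, height)`` in pixels, ``roi_fluence`` mode only.
    per_projection_fluence
        Optional per-projection fluence readings from a monitor device; when
        given, the up-scaling constant becomes ``fluence_i - mean(dark)``
        instead of ``mean(flat - dark)``.
    """

    mode: str
    dark: np.ndarray
    flat: np.ndarray
    roi: Optional[tuple] = None
    per_projection_fluence: Optional[Sequence[float]] = None

    def __post_init__(self):
        if self.mode not in ("none", "roi_fluence", "flat_mean"):
            raise ValueError(f"unknown normalization mode {self.mode!r}")
        self.dark = np.asarray(self.dark, dtype=float)
        self.flat = np.asarray(self.flat, dtype=float)
        if self.dark.shape != self.flat.shape:
            raise ValueError("dark and flat must share detector dimensions")
        if self.mode == "roi_fluence":
            if self.roi is None:
                raise ValueError("roi_fluence mode requires a background ROI")
            u0, v0, w, h = self.roi
            n_v, n_u = self.flat.shape
            if w < 1 or h < 1:
                raise ValueError("ROI has zero area")
            if u0 < 0 or v0 < 0 or u0 + w > n_u or v0 + h > n_v:
                raise ValueError("ROI must lie inside the detector")


def normalize(raw: ProjectionStack, cfg: NormalizationConfig) -> ProjectionStack:
    """Flat/dark correct and fluence-scale a raw projection stack.

    Computes ``I = (raw - dark) / (flat - dark) * C_fl`` with ``C_fl`` the
    mean open-beam level or the per-projection fluence monitor value, then
    applies the selected fluence-correction mode (background-ROI division,
    open-beam-mean division, or none).  Output is strictly positive.
    """
    if raw.stage != "raw":
        raise ValueError(f"normalize expects a raw stack, got stage {raw.stage!r}")
    if raw.data.shape[1:] != cfg.flat.shape:
        raise ValueError("projections and flat/dark must share detector dimensions")

    denom = cfg.flat - cfg.dark
    positive = denom > 0
    if not positive.any():
        raise ValueError("unusable flat field: flat <= dark everywhere")
    if not positive.all():
        n_bad = int((~positive).sum())
        logger.warning("flat - dark non-positive at %d pixels; substituting mean level", n_bad)
        denom = np.where(positive, denom, denom[positive].mean())

    if cfg.per_projection_fluence is not None:
        fl = np.asarray(cfg.per_projection_fluence, dtype=float)
        if len(fl) != raw.n_proj:
            raise ValueError("per-projection fluence length must match stack")
        c_fl = (fl - cfg.dark.mean())[:, None, None]
    else:
        c_fl = denom.mean()

    out = (raw.data - cfg.dark) / denom * c_fl

    if cfg.mode == "roi_fluence":
        u0, v0, w, h = cfg.roi
        roi_mean = out[:, v0 : v0 + h, u0 : u0 + w].mean(axis=(1, 2))
        if np.any(roi_mean <= 0):
            raise ValueError("background ROI mean is non-positive for some projection")
        out = out / roi_mean[:, None, None]
    elif cfg.mode == "flat_mean":
        out = out / denom.mean()
    # mode "none": keep the up-scaled values

    out = np.maximum(out, 1e-12)
    return ProjectionStack(out, "normalized", raw.angles)


def to_attenuation(stack: ProjectionStack) -> ProjectionStack:
    """Convert normalized transmission to attenuation line integrals,
    ``p = -ln(max(I, 1e-6))``."""
    if stack.stage != "normalized":
        raise ValueError(f"to_attenuation expects a normalized stack, got {stack.stage!r}")
    p = -np.log(np.maximum(stack.data, EPS_TRANSMISSION))
    return ProjectionStack(p, "attenuation", stack.angles)


@dataclass(frozen=True)
class BHCParams:
    """Empirical beam-hardening polynomial coefficients for
    ``f(x) = a*x + b*x**c``; the exponent ``c`` (typically in [2, 3]) is the
    most sensitive parameter."""

    a: float
    b: float
    c: float

    def __post_init__(self):
        if self.c <= 0:
            raise ValueError(f"exponent c must be positive, got {self.c}")


def bhc_correct(stack: ProjectionStack, params: BHCParams) -> ProjectionStack:
    """Linearize attenuation values with the polynomial ``a*x + b*x**c``.

    Negative attenuation values (log noise around zero) are clamped to 0
    before the fractional power is taken.
    """
    if stack.stage != "attenuation":
        raise ValueError(f"bhc_correct expects an attenuation stack, got {stack.stage!r}")
    x = stack.data
    if np.any(x < 0):
        logger.warning("clamping %d negative attenuation values to 0 before BHC", int((x < 0).sum()))
        x = np.maximum(x, 0.0)
    out = params.a * x + params.b * np.power(x, params.c)
    return stack.with_data(out, "attenuation")


def calibrate_bhc(measured, target, c_grid=None) -> BHCParams:
    """Fit beam-hardening coefficients mapping measured polychromatic
    attenuation onto a linear (monochromatic-equivalent) target.

    For each candidate exponent ``c`` the coefficients ``(a, b)`` are linear
    and solved by least squares; the exponent with the smallest residual
    wins.  ``measured`` and ``target`` are matching 1-D samples of the
    attenuation transfer curve (e.g. from a calibration wedge or a known
    beam model).
    """
    measured = np.asarray(measured, dtype=float).ravel()
    target = np.asarray(target, dtype=float).ravel()
    if measured.shape != target.shape or measured.size < 3:
        raise ValueError("measured and target must be matching 1-D samples (>= 3)")
    if c_grid is None:
        c_grid = np.linspace(2.0, 3.0, 21)
    best = None
    for c in np.atleast_1d(c_grid):
        design = np.column_stack([measured, np.power(np.maximum(measured, 0.0), c)])
        coef, _, _, _ = np.linalg.lstsq(design, target, rcond=None)
        resid = float(np.linalg.norm(design @ coef - target))
        if best is None or resid < best[0]:
            best = (resid, float(coef[0]), float(coef[1]), float(c))
    _, a, b, c = best
    return BHCParams(a=a, b=b, c=c)


@dataclass(frozen=True)
class OutlierConfig:
    """Defect-pixel detection settings: z-score threshold multiplier ``n``
    (sigma_th = n*sigma) and the median-blur window ``(w, h)``."""

    sigma_multiplier: float = 3.0
    window: tuple = (5, 5)

    def __post_init__(self):
        w, h = self.window
        if w < 3 or h < 3 or w % 2 == 0 or h % 2 == 0:
            raise ValueError(f"median window must be odd and >= 3, got {self.window}")
        if self.sigma_multiplier <= 0:
            raise ValueError("sigma multiplier must be positive")


def find_outlier_mask(stack: ProjectionStack, cfg: OutlierConfig = OutlierConfig()) -> np.ndarray:
    """Detect defect detector pixels from a projection stack.

    Object structure moves across projections while defects stay on fixed
    coordinates, so the pixel-wise stack mean suppresses real edges.  The
    mean image is median-blurred, the absolute difference z-scored, and
    pixels above the threshold flagged.  Returns a boolean detector-sized
    mask (True = defect).
    """
    if stack.n_proj < 2:
        raise ValueError("need at least 2 projections to separate defects from structure")
    w, h = cfg.window
    mean_img = stack.data.mean(axis=0)
    blurred = ndimage.median_filter(mean_img, size=(h, w), mode="reflect")
    diff = np.abs(mean_img - blurred)
    s = diff.std()
    if s == 0:
        return np.zeros(mean_img.shape, dtype=bool)
    z = (diff - diff.mean()) / s
    return z > cfg.sigma_multiplier


def repair_defects(stack: ProjectionStack, mask: np.ndarray, window: int = 5) -> ProjectionStack:
    """Replace masked pixels with the median of non-masked neighbours.

    Applied to each projection independently; non-masked pixels are returned
    unchanged.  If a window contains only masked pixels it grows by 2 until
    at least one valid neighbour is found.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != stack.data.shape[1:]:
        raise ValueError("mask dimensions must match the detector")
    if window < 3 or window % 2 == 0:
        raise ValueError(f"repair window must be odd and >= 3, got {window}")
    coords = np.argwhere(mask)
    if coords.size == 0:
        return stack.with_data(stack.data.copy())

    n_v, n_u = mask.shape
    out = stack.data.copy()
    grown = False
    for v, u in coords:
        win = window
        while True:
            half = win // 2
            v0, v1 = max(0, v - half), min(n_v, v + half + 1)
            u0, u1 = max(0, u - half), min(n_u, u + half + 1)
            valid = ~mask[v0:v1, u0:u1]
            if valid.any():
                break
            win += 2
            if not grown:
                logger.info("repair window grown beyond %d px around (%d, %d)", window, v, u)
                grown = True
        block = stack.data[:, v0:v1, u0:u1]
        out[:, v, u] = np.median(block[:, valid], axis=1)
    return stack.with_data(out)


def build_scm_dlr(stack: ProjectionStack, detrend_window: Optional[int] = None) -> np.ndarray:
    """Estimate the per-pixel sensitivity correction matrix (SCM) from
    detector line ratios (DLR).

    For each horizontally adjacent pixel pair the relative gain is the
    median over all projections of the value ratio: object structure moves
    from projection to projection while detector gain does not, so the
    median isolates the gain.  Per detector row the gains are accumulated as
    a cumulative product of ratios, high-pass detrended with a wide moving
    median (true smooth flat-field trends are preserved; isolated gain
    spikes are not pulled into the trend) and globally normalized to mean 1.

    Returns a strictly positive ``(n_v, n_u)`` multiplicative gain image.
    """
    if stack.stage != "normalized":
        raise ValueError(f"build_scm_dlr expects a normalized stack, got {stack.stage!r}")
    if stack.n_proj < 2:
        raise ValueError("need at least 2 projections for line ratios")
    if stack.n_proj < 50:
        logger.warning("DLR with %d projections; >= 50 recommended for stability", stack.n_proj)

    data = stack.data
    scale = np.median(data)
    eps = 1e-9 * max(scale, 1.0)
    num = data[:, :, 1:]
    den = data[:, :, :-1]
    usable = den > eps
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(usable, num / np.where(usable, den, 1.0), np.nan)
    frac = usable.mean(axis=0)
    with np.errstate(all="ignore"):
        r = np.nanmedian(ratio, axis=0)
    bad = (frac < 0.1) | ~np.isfinite(r) | (r <= 0)
    if bad.any():
        logger.info("DLR: %d pixel pairs with <10%% usable projections set to ratio 1", int(bad.sum()))
        r = np.where(bad, 1.0, r)

    gains = np.ones((stack.n_v, stack.n_u))
    gains[:, 1:] = np.cumprod(r, axis=1)

    if detrend_window is None:
        # narrow enough to track genuine smooth flat-field trends near steep
        # object silhouettes, wide enough to reject 1-2 column gain spikes
        detrend_window = max(5, stack.n_u // 16)
    if detrend_window % 2 == 0:
        detrend_window += 1
    trend = ndimage.median_filter(gains, size=(1, detrend_window), mode="nearest")
    scm = gains / np.maximum(trend, eps)
    scm = np.maximum(scm, 1e-6)
    scm = scm / scm.mean()
    return scm


def apply_scm(stack: ProjectionStack, scm: np.ndarray) -> ProjectionStack:
    """Divide every projection by the sensitivity correction matrix."""
    if stack.stage != "normalized":
        raise ValueError(f"apply_scm expects a normalized stack, got {stack.stage!r}")
    scm = np.asarray(scm, dtype=float)
    if scm.shape != stack.data.shape[1:]:
        raise ValueError("SCM dimensions must match the detector")
    return stack.with_data(stack.data / scm)


def ring_metric(slice_image: np.ndarray, center=None, r_min: float = 1.0,
                r_max: Optional[float] = None, n_theta: int = 360) -> float:
    """Ring-artifact severity of a tomogram slice: mean over radii of the
    standard deviation of values sampled along circles centred on the
    rotation axis.  Rings are constant along a circle's neighbours but step
    sharply across radii, so the std along the circles they cross rises with
    ring amplitude while a ring-free slice scores near the noise floor.
    ``r_min``/``r_max`` (pixels) select the radial band evaluated; genuine
    off-axis structure inside the band also raises the score, so comparisons
    should use a band dominated by the rings of interest.
    """
    img = np.asarray(slice_image, dtype=float)
    n0, n1 = img.shape
    if center is None:
        center = ((n0 - 1) / 2.0, (n1 - 1) / 2.0)
    if r_max is None:
        r_max = min(n0, n1) / 2.0 - 2.0
    radii = np.arange(r_min, r_max)
    theta = np.linspace(0.0, 2.0 * np.pi, n_theta, endpoint=False)
    rr, tt = np.meshgrid(radii, theta, indexing="ij")
    coords = np.stack([center[0] + rr * np.cos(tt), center[1] + rr * np.sin(tt)])
    samples = ndimage.map_coordinates(img, coords, order=1, mode="nearest")
    return float(samples.std(axis=1).mean())
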