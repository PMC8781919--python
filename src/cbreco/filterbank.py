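"""Cone-beam weighting and row-wise ramp filtering.

The discrete Ram-Lak and Shepp-Logan kernels are defined in the spatial
domain (band-limited sampling of the ramp), which avoids the DC-offset error
of sampling ``|w|`` in the frequency domain.  Convolution is evaluated
through the FFT with acyclic zero-padding to at least ``Nf + Np - 1``
samples, so it is exactly linear convolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from .geometry import ScanGeometry
from .preprocess import ProjectionStack

__all__ = [
    "FilterKernel",
    "ramlak_kernel",
    "shepplogan_kernel",
    "make_kernel",
    "cosine_weights",
    "weight_projections",
    "filter_rows",
]

FAMILIES = ("ram-lak", "shepp-logan")


@dataclass(frozen=True, eq=False)
class FilterKernel:
    """Symmetric spatial-domain ramp-filter taps.

    ``taps[k]`` holds ``H(n)`` for ``n = k - N`` with ``N = (len-1)//2``;
    ``delta_s`` is the sampling interval in mm (detector pitch, demagnified
    to the rotation-centre plane in the default pipeline).
    """

    taps: np.ndarray
    delta_s: float
    family: str

    @property
    def half_length(self) -> int:
        return (len(self.taps) - 1) // 2


def ramlak_kernel(N: int, delta_s: float) -> FilterKernel:
    """Discrete Ramachandran-Lakshminarayanan (ramp) kernel.

    ``H(0) = 1/(4 ds^2)``, ``H(n) = 0`` for even ``n != 0`` and
    ``H(n) = -1/(n pi ds)^2`` for odd ``n``.
    """
    if N < 1:
        raise ValueError("kernel half-length must be >= 1")
    n = np.arange(-N, N + 1)
    taps = np.zeros(2 * N + 1)
    taps[N] = 1.0 / (4.0 * delta_s**2)
    odd = n % 2 != 0
    taps[odd] = -1.0 / (n[odd] * np.pi * delta_s) ** 2
    return FilterKernel(taps=taps, delta_s=float(delta_s), family="ram-lak")


def shepplogan_kernel(N: int, delta_s: float) -> FilterKernel:
    """Discrete Shepp-Logan kernel, ``H(n) = -2/(pi^2 ds^2 (4 n^2 - 1))``;
    a smoothed ramp with lower high-frequency gain than Ram-Lak."""
    if N < 1:
        raise ValueError("kernel half-length must be >= 1")
    n = np.arange(-N, N + 1)
    taps = -2.0 / (np.pi**2 * delta_s**2 * (4.0 * n**2 - 1.0))
    return FilterKernel(taps=taps, delta_s=float(delta_s), family="shepp-logan")


def make_kernel(family: str, N: int, delta_s: float) -> FilterKernel:
    if family == "ram-lak":
        return ramlak_kernel(N, delta_s)
    if family == "shepp-logan":
        return shepplogan_kernel(N, delta_s)
    raise ValueError(f"unknown filter family {family!r}; expected one of {FAMILIES}")


def cosine_weights(geometry: ScanGeometry) -> np.ndarray:
    """Cone-beam cosine weights ``W = SDD / sqrt(Xp^2 + Yp^2 + SDD^2)``.

    Evaluated at pixel-centre mm coordinates with the horizontal origin on
    the central ray, i.e. shifted by the rotation-axis offset.  Returns an
    ``(n_v, n_u)`` image; 1.0 on the central ray and strictly decreasing
    with radial distance.
    """
    u = (np.arange(geometry.n_u) - geometry.u_center) * geometry.pixel_size
    v = (np.arange(geometry.n_v) - geometry.v_center) * geometry.pixel_size
    Xp, Yp = np.meshgrid(u, v)
    return geometry.sdd / np.sqrt(Xp**2 + Yp**2 + geometry.sdd**2)


def weight_projections(stack: ProjectionStack, geometry: ScanGeometry) -> ProjectionStack:
    """Apply the cosine weights to every projection (pre-filtering step)."""
    if stack.stage != "attenuation":
        raise ValueError(f"weighting expects an attenuation stack, got {stack.stage!r}")
    if stack.data.shape[1:] != (geometry.n_v, geometry.n_u):
        raise ValueError("stack and geometry detector dimensions differ")
    return stack.with_data(stack.data * cosine_weights(geometry)[None])


def filter_rows(stack: ProjectionStack, kernel: FilterKernel) -> ProjectionStack:
    """Convolve every detector row with the ramp kernel (linear, acyclic).

    Realized by FFT multiplication after zero-padding both operands to at
    least ``Nf + Np - 1`` samples (next fast transform length), then
    cropping the centred original row length — identical to direct spatial
    convolution up to floating-point rounding.
    """
    if stack.stage != "attenuation":
        raise ValueError(f"filter_rows expects an attenuation stack, got {stack.stage!r}")
    out = fftconvolve(stack.data, kernel.taps[None, None, :], mode="same", axes=-1)
    return ProjectionStack(out, "filtered", stack.angles)
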