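"""Gaussian low-pass and high-boost filtering of 8-bit images.

The two filters implemented here are the classic spatial-domain pair used
to degrade (blur) or enhance (sharpen) image regions:

* **GLPF** — Gaussian low-pass filter.  Convolution with a normalized
  sampled Gaussian ``w(x, y) ∝ exp(-(x² + y²) / (2σ²))``, where ``x, y``
  are integer offsets from the kernel center and ``σ`` the standard
  deviation in pixels.  Normalization to unit sum replaces the continuous
  ``1/(2πσ²)`` constant, which cancels.

* **HBF** — high-boost filter, ``f_HB = (A − 1)·f + f_hp``, with
  amplification factor ``A ≥ 1`` and high-pass component
  ``f_hp = f − GLPF(f)`` (unsharp mask).  Algebraically this equals
  ``A·f − GLPF(f)``; ``A = 1`` is the pure high-pass case, larger ``A``
  keeps more of the original signal while boosting edges.

All arithmetic is carried out in float64; outputs are rounded half-to-even
and clipped to [0, 255].  Boundary handling is mirror reflection without
repeating the edge pixel.  Channels are processed independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.ndimage import convolve1d

__all__ = [
    "FilterType",
    "GaussianKernel",
    "FilterSpec",
    "auto_sigma",
    "make_gaussian_kernel",
    "glpf",
    "glpf_real",
    "high_pass",
    "high_boost",
]

_BOUNDARY = "mirror"  # reflect without repeating the edge sample


class FilterType(str, Enum):
    """Which refinement filter to apply."""

    GLPF = "glpf"
    HBF = "hbf"
    GLPF_THEN_HBF = "glpf+hbf"
    IDENTITY = "identity"


def auto_sigma(size: int) -> float:
    """Default kernel-size→σ convention: ``0.3·((size−1)/2 − 1) + 0.8``."""
    return 0.3 * ((size - 1) / 2 - 1) + 0.8


def _check_size_sigma(size: int, sigma: float) -> None:
    if not isinstance(size, (int, np.integer)) or size < 1 or size % 2 == 0:
        raise ValueError(f"kernel size must be a positive odd integer, got {size!r}")
    if not sigma > 0:
        raise ValueError(f"sigma must be positive, got {sigma!r}")


@dataclass(frozen=True)
class GaussianKernel:
    """A normalized, sampled 2-D Gaussian.

    Attributes
    ----------
    size : odd int
        Side length in pixels.
    sigma : float
        Standard deviation in pixels.
    weights : (size, size) float64 array
        Non-negative, sums to 1, symmetric under transpose and 180° rotation,
        maximal at the center.
    """

    size: int
    sigma: float
    weights: np.ndarray = field(repr=False)

    @property
    def weights_1d(self) -> np.ndarray:
        """Normalized 1-D factor; the 2-D kernel is its outer product."""
        r = self.size // 2
        x = np.arange(-r, r + 1, dtype=np.float64)
        w = np.exp(-(x**2) / (2.0 * self.sigma**2))
        return w / w.sum()


def make_gaussian_kernel(size: int, sigma: float) -> GaussianKernel:
    """Build the normalized sampled Gaussian kernel.

    Weights are ``exp(−(x²+y²)/(2σ²))`` on the integer offset grid from the
    center, divided by their sum.

    Raises
    ------
    ValueError
        If ``size`` is even or non-positive, or ``sigma`` ≤ 0.
    """
    _check_size_sigma(size, sigma)
    r = size // 2
    x = np.arange(-r, r + 1, dtype=np.float64)
    w1 = np.exp(-(x**2) / (2.0 * sigma**2))
    w2 = np.outer(w1, w1)
    w2 /= w2.sum()
    return GaussianKernel(size=int(size), sigma=float(sigma), weights=w2)


@dataclass(frozen=True)
class FilterSpec:
    """Configuration of one refinement filter application.

    ``sigma=None`` means the ``auto_sigma`` convention per stage.  For the
    stacked ``GLPF_THEN_HBF`` filter, ``kernel_size`` is the GLPF stage and
    ``second_kernel_size`` the HBF stage.
    """

    filter_type: FilterType
    kernel_size: int = 3
    sigma: float | None = None
    amplification: float = 2.0
    second_kernel_size: int | None = None

    def __post_init__(self) -> None:
        if self.filter_type is FilterType.IDENTITY:
            return
        _check_size_sigma(self.kernel_size, 1.0 if self.sigma is None else self.sigma)
        if self.amplification < 1:
            raise ValueError(
                f"amplification must be >= 1, got {self.amplification!r}"
            )
        if self.filter_type is FilterType.GLPF_THEN_HBF:
            k2 = self.second_kernel_size
            if k2 is None:
                raise ValueError("GLPF_THEN_HBF requires second_kernel_size")
            _check_size_sigma(k2, 1.0)
        elif self.second_kernel_size is not None:
            raise ValueError("second_kernel_size is only valid for GLPF_THEN_HBF")

    def sigma_for(self, size: int) -> float:
        return auto_sigma(size) if self.sigma is None else self.sigma

    @property
    def pad_radius(self) -> int:
        """Halo width needed so local filtering matches global filtering."""
        if self.filter_type is FilterType.IDENTITY:
            return 0
        r = self.kernel_size // 2
        if self.filter_type is FilterType.GLPF_THEN_HBF:
            r = max(r, self.second_kernel_size // 2)
        return r


def _as_float_image(img: np.ndarray) -> np.ndarray:
    a = np.asarray(img)
    if a.ndim not in (2, 3) or a.ndim == 3 and a.shape[2] not in (1, 3):
        raise ValueError(f"expected HxW or HxWxC (C in {{1,3}}) image, got shape {a.shape}")
    if a.shape[0] < 1 or a.shape[1] < 1:
        raise ValueError("image must have H, W >= 1")
    return a.astype(np.float64)


def _quantize(a: np.ndarray) -> np.ndarray:
    """Round half-to-even and clip to the 8-bit range."""
    return np.clip(np.rint(a), 0, 255).astype(np.uint8)


def glpf_real(img: np.ndarray, size: int, sigma: float | None = None) -> np.ndarray:
    """Gaussian low-pass in real arithmetic (no rounding or clipping).

    Exploits separability: one 1-D pass per axis, mirror boundary.
    """
    if sigma is None:
        sigma = auto_sigma(size)
    k = make_gaussian_kernel(size, sigma)
    f = _as_float_image(img)
    w = k.weights_1d
    out = convolve1d(f, w, axis=0, mode=_BOUNDARY)
    out = convolve1d(out, w, axis=1, mode=_BOUNDARY)
    return out


def glpf(img: np.ndarray, size: int, sigma: float | None = None) -> np.ndarray:
    """Gaussian low-pass filter of an 8-bit image.

    Returns a uint8 image of the same shape: per-channel convolution with
    :func:`make_gaussian_kernel`, mirror boundary, rounded half-to-even and
    clipped to [0, 255].
    """
    return _quantize(glpf_real(img, size, sigma))


def high_pass(img: np.ndarray, size: int, sigma: float | None = None) -> np.ndarray:
    """Unsharp-mask high-pass component ``f − GLPF(f)``.

    Computed in real arithmetic; the result is a signed float64 grid (may
    be negative) of the same shape as the input.
    """
    f = _as_float_image(img)
    return f - glpf_real(f, size, sigma)


def high_boost(
    img: np.ndarray, size: int, sigma: float | None = None, A: float = 2.0
) -> np.ndarray:
    """High-boost sharpening ``(A−1)·f + (f − GLPF(f))``.

    Equivalent to ``A·f − GLPF(f)`` before quantization.  ``A = 1`` keeps
    only the high-pass component (mostly clipped to dark values); ``A = 2``
    is classic unsharp masking.

    Raises
    ------
    ValueError
        If ``A < 1``.
    """
    if A < 1:
        raise ValueError(f"amplification A must be >= 1, got {A!r}")
    f = _as_float_image(img)
    return _quantize((A - 1.0) * f + high_pass(f, size, sigma))


def apply_filter_spec(img: np.ndarray, spec: FilterSpec) -> np.ndarray:
    """Apply a full :class:`FilterSpec` to a whole image."""
    if spec.filter_type is FilterType.IDENTITY:
        return np.asarray(img).astype(np.uint8, copy=True)
    if spec.filter_type is FilterType.GLPF:
        return glpf(img, spec.kernel_size, spec.sigma_for(spec.kernel_size))
    if spec.filter_type is FilterType.HBF:
        return high_boost(
            img, spec.kernel_size, spec.sigma_for(spec.kernel_size), spec.amplification
        )
    # stacked: blur then sharpen, each stage quantized like its standalone op
    k2 = spec.second_kernel_size
    blurred = glpf(img, spec.kernel_size, spec.sigma_for(spec.kernel_size))
    return high_boost(blurred, k2, spec.sigma_for(k2), spec.amplification)


__all__.append("apply_filter_spec")
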