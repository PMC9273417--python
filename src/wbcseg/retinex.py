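"""Classic retinex machinery: SSR, MSR and constant-gain MSRCR.

Retinex theory models an observed image ``S`` as the product of an
illumination field ``L`` and a surface reflectance ``R``.  Taking logarithms
turns the product into a sum, ``s = r + l``, and the reflectance is recovered
by subtracting a Gaussian-surround estimate of the illumination:

    r_sigma(x, y) = log(S + eps) - log(G_sigma * S + eps)

Single-scale retinex (SSR) uses one surround scale; multi-scale retinex (MSR)
averages several; MSRCR additionally multiplies each channel by a colour
recovery gain c_i = alpha * log(beta * S_i / sum_i S_i) to undo the greying
that channel-wise MSR causes.

All functions operate on unit-interval floats.  ``log_eps`` arguments are on
the same unit scale as the plane they apply to; :class:`RetinexParams` stores
its default on the conventional byte scale (1.0 / 255 after conversion).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import convolve1d

from .image import RasterImage, ColourSpaceError, as_plane, as_rgb_unit, RGB, BYTE

__all__ = [
    "SurroundScaleSet",
    "ReflectanceStack",
    "RetinexParams",
    "gaussian_surround",
    "ssr",
    "reflectance_stack",
    "msr",
    "color_recovery_constant",
    "msrcr",
    "stretch_to_display",
]

#: Gaussian support is cut off at this many standard deviations.
DEFAULT_TRUNCATE = 4.0


@dataclass(frozen=True)
class SurroundScaleSet:
    """Gaussian surround scales and their weights for multi-scale retinex."""

    scales: tuple = (15.0, 80.0, 250.0)
    weights: tuple = (1.0 / 3.0, 1.0 / 3.0, 1.0 / 3.0)

    def __post_init__(self) -> None:
        scales = tuple(float(s) for s in self.scales)
        weights = tuple(float(w) for w in self.weights)
        object.__setattr__(self, "scales", scales)
        object.__setattr__(self, "weights", weights)
        if len(scales) != len(weights):
            raise ValueError("scales and weights must have the same length")
        if not scales:
            raise ValueError("at least one surround scale is required")
        if any(s <= 0 for s in scales):
            raise ValueError("surround scales must be strictly positive")
        if any(b <= a for a, b in zip(scales, scales[1:])):
            raise ValueError("surround scales must be strictly increasing")
        if any(w < 0 for w in weights):
            raise ValueError("surround weights must be nonnegative")
        if abs(sum(weights) - 1.0) > 1e-9:
            raise ValueError(f"surround weights must sum to 1, got {sum(weights)}")

    @classmethod
    def single(cls, sigma: float) -> "SurroundScaleSet":
        return cls(scales=(float(sigma),), weights=(1.0,))


@dataclass(frozen=True)
class ReflectanceStack:
    """Log-domain decomposition s = r + l of a plane or image."""

    r: np.ndarray
    l: np.ndarray
    s: np.ndarray

    def __post_init__(self) -> None:
        if not (self.r.shape == self.l.shape == self.s.shape):
            raise ValueError("r, l, s must share a shape")


@dataclass(frozen=True)
class RetinexParams:
    """All tunables of the retinex enhancement.

    ``alpha`` and ``beta_const`` are the colour-recovery gains of classic
    MSRCR (conventionally 46 and 125).  ``gamma`` is the base gain of the
    adaptive correction: each block's beta is gamma * exp(C_M), so at zero
    Michelson contrast the adaptive form reduces to constant-beta MSRCR with
    beta = gamma.  ``block_k`` is the block side in pixels.  ``log_eps`` is
    the offset added inside every logarithm, stated on the byte scale.
    """

    surround: SurroundScaleSet = field(default_factory=SurroundScaleSet)
    alpha: float = 46.0
    beta_const: float = 125.0
    gamma: float = 125.0
    block_k: int = 32
    log_eps: float = 1.0
    stretch: object = "minmax"
    smooth_beta: bool = False

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.beta_const <= 1:
            raise ValueError("beta_const must exceed 1")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.block_k < 1:
            raise ValueError("block_k must be at least 1")
        if self.log_eps <= 0:
            raise ValueError("log_eps must be positive")

    @property
    def log_eps_unit(self) -> float:
        """log_eps converted to the unit scale used internally."""
        return self.log_eps / 255.0


def gaussian_surround(sigma: float, truncate: float = DEFAULT_TRUNCATE) -> np.ndarray:
    """Normalised 2-D Gaussian surround kernel truncated at ``truncate * sigma``.

    The kernel is exp(-(x^2 + y^2) / (2 sigma^2)) sampled on an odd square
    grid and renormalised to sum to one, so convolving a constant plane
    leaves it unchanged.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    radius = max(1, int(truncate * float(sigma) + 0.5))
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    g1 = np.exp(-(x**2) / (2.0 * sigma**2))
    kernel = np.outer(g1, g1)
    return kernel / kernel.sum()


def _surround_blur(plane: np.ndarray, sigma: float, truncate: float = DEFAULT_TRUNCATE) -> np.ndarray:
    # Separable convolution with reflective padding; identical to convolving
    # with the full 2-D gaussian_surround kernel because the kernel factorises.
    radius = max(1, int(truncate * float(sigma) + 0.5))
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    g1 = np.exp(-(x**2) / (2.0 * sigma**2))
    g1 /= g1.sum()
    out = convolve1d(plane, g1, axis=0, mode="reflect")
    return convolve1d(out, g1, axis=1, mode="reflect")


def reflectance_stack(plane, sigma: float, log_eps: float = 1.0 / 255.0) -> ReflectanceStack:
    """Log-domain decomposition of a plane at one surround scale.

    Returns ``s = log(S + eps)``, ``l = log(G_sigma * S + eps)`` and
    ``r = s - l``; the identity ``s = r + l`` holds by construction.
    """
    arr = as_plane(plane)
    if log_eps < 0:
        raise ValueError("log_eps must be nonnegative")
    s = np.log(arr + log_eps)
    l = np.log(_surround_blur(arr, sigma) + log_eps)
    return ReflectanceStack(r=s - l, l=l, s=s)


def ssr(plane, sigma: float, log_eps: float = 1.0 / 255.0) -> np.ndarray:
    """Single-scale retinex reflectance of a single plane.

    ``log(S + eps) - log(G_sigma * S + eps)`` with reflective boundary
    padding.  A constant plane maps to zero everywhere, and multiplying the
    plane by a positive constant leaves the result unchanged when
    ``log_eps`` is zero (illumination invariance).
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    return reflectance_stack(plane, sigma, log_eps).r


def msr(plane, surround: SurroundScaleSet | None = None, log_eps: float = 1.0 / 255.0) -> np.ndarray:
    """Multi-scale retinex: weighted average of SSR over the surround set."""
    if surround is None:
        surround = SurroundScaleSet()
    arr = as_plane(plane)
    out = np.zeros_like(arr, dtype=np.float64)
    for sigma, w in zip(surround.scales, surround.weights):
        out += w * ssr(arr, sigma, log_eps)
    return out


def color_recovery_constant(channel_value, channel_sum, alpha: float = 46.0,
                            beta: float = 125.0, log_eps: float = 1e-8):
    """Constant-gain colour recovery c_i = alpha * log(beta * S_i / sum_i S_i).

    Accepts scalars or arrays.  When the channel value is zero the log
    argument is clamped to ``log_eps`` to keep the gain finite.
    """
    channel_sum = np.asarray(channel_sum, dtype=np.float64)
    channel_value = np.asarray(channel_value, dtype=np.float64)
    if np.any(channel_sum <= 0):
        raise ValueError("channel_sum must be strictly positive")
    if np.any(channel_value < 0):
        raise ValueError("channel_value must be nonnegative")
    arg = np.maximum(beta * channel_value / channel_sum, log_eps)
    out = alpha * np.log(arg)
    return float(out) if out.ndim == 0 else out


def stretch_to_display(r, rule="minmax") -> np.ndarray:
    """Map a log-domain plane linearly onto the display range [0, 255].

    ``rule`` is either ``"minmax"`` (plane minimum to 0, maximum to 255; a
    constant plane maps to mid-grey 128) or a tuple ``("percentile", lo, hi)``
    which clips at the given percentiles before the linear map.
    """
    arr = np.asarray(r, dtype=np.float64)
    if rule == "minmax":
        lo, hi = float(arr.min()), float(arr.max())
    elif isinstance(rule, (tuple, list)) and len(rule) == 3 and rule[0] == "percentile":
        lo, hi = (float(q) for q in np.percentile(arr, [rule[1], rule[2]]))
        arr = np.clip(arr, lo, hi)
    else:
        raise ValueError(f"unknown stretch rule {rule!r}")
    if hi - lo < 1e-300:
        return np.full_like(arr, 128.0)
    return (arr - lo) / (hi - lo) * 255.0


def msrcr(image, params: RetinexParams | None = None) -> RasterImage:
    """Constant-beta MSRCR enhancement of an RGB image.

    Per channel i: stretch(c_i(x, y) * MSR_i(x, y)) with
    c_i = alpha * log(beta * S_i / (S_R + S_G + S_B)).  Returns a byte-domain
    RGB image.
    """
    if params is None:
        params = RetinexParams()
    rgb = as_rgb_unit(image)
    eps = params.log_eps_unit
    channel_sum = np.maximum(rgb.sum(axis=2), eps)
    out = np.empty_like(rgb)
    for i in range(3):
        f = msr(rgb[:, :, i], params.surround, eps)
        c = color_recovery_constant(rgb[:, :, i], channel_sum,
                                    params.alpha, params.beta_const, eps)
        out[:, :, i] = stretch_to_display(c * f, params.stretch)
    return RasterImage(out, colour_space=RGB, domain=BYTE)
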