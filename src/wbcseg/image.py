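"""Pixel-array container with an explicit colour-space and value-domain tag.

All internal mathematics in this package runs on floats in the unit interval;
byte-scale values appear only at the I/O edges.  ``RasterImage`` makes the
current convention explicit so that conversions happen exactly once.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

RGB = "rgb"
HSV = "hsv"
PLANE = "plane"

UNIT = "unit"
BYTE = "byte"


class ColourSpaceError(ValueError):
    """Raised when an operation receives an image in the wrong colour space."""


@dataclass(frozen=True)
class RasterImage:
    """An H×W or H×W×C pixel array tagged with colour space and value domain.

    Parameters
    ----------
    pixels
        ``(H, W)`` array for a single plane or ``(H, W, 3)`` for RGB/HSV.
    colour_space
        One of ``"rgb"``, ``"hsv"``, ``"plane"``.
    domain
        ``"unit"`` for values in [0, 1] or ``"byte"`` for values in [0, 255].
        HSV images always use the unit domain (all three components in [0, 1]).
    """

    pixels: np.ndarray
    colour_space: str = RGB
    domain: str = UNIT

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        object.__setattr__(self, "pixels", px)
        if px.ndim == 2:
            if self.colour_space != PLANE:
                raise ColourSpaceError(
                    f"2-D pixel array requires colour_space='plane', got {self.colour_space!r}"
                )
        elif px.ndim == 3:
            if px.shape[2] not in (1, 3):
                raise ValueError(f"channel count must be 1 or 3, got {px.shape[2]}")
            if px.shape[2] == 3 and self.colour_space == PLANE:
                raise ColourSpaceError("3-channel image cannot be tagged 'plane'")
        else:
            raise ValueError(f"pixels must be 2-D or 3-D, got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError(f"image must be at least 1x1, got shape {px.shape}")
        if self.colour_space not in (RGB, HSV, PLANE):
            raise ColourSpaceError(f"unknown colour space {self.colour_space!r}")
        if self.domain not in (UNIT, BYTE):
            raise ValueError(f"unknown value domain {self.domain!r}")
        if self.colour_space == HSV and self.domain != UNIT:
            raise ValueError("HSV images must use the unit domain")
        lo, hi = (0.0, 1.0) if self.domain == UNIT else (0.0, 255.0)
        if px.size and (np.nanmin(px) < lo - 1e-9 or np.nanmax(px) > hi + 1e-9):
            raise ValueError(
                f"pixel values [{np.nanmin(px):.4g}, {np.nanmax(px):.4g}] outside "
                f"declared {self.domain} domain"
            )

    @property
    def shape(self) -> tuple:
        return self.pixels.shape

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def channels(self) -> int:
        return 1 if self.pixels.ndim == 2 else self.pixels.shape[2]

    def to_unit(self) -> "RasterImage":
        if self.domain == UNIT:
            return self
        return replace(self, pixels=self.pixels.astype(np.float64) / 255.0, domain=UNIT)

    def to_byte(self) -> "RasterImage":
        if self.domain == BYTE:
            return self
        return replace(self, pixels=self.pixels.astype(np.float64) * 255.0, domain=BYTE)

    def as_uint8(self) -> np.ndarray:
        """Pixels rounded and clipped to uint8 on the byte scale."""
        return np.clip(np.round(self.to_byte().pixels), 0, 255).astype(np.uint8)


def as_plane(plane) -> np.ndarray:
    """Coerce a single-plane image (RasterImage or 2-D array) to a float array."""
    if isinstance(plane, RasterImage):
        if plane.channels != 1:
            raise ColourSpaceError("expected a single-channel plane")
        arr = plane.to_unit().pixels
        return arr[..., 0] if arr.ndim == 3 else arr
    arr = np.asarray(plane, dtype=np.float64)
    if arr.ndim != 2:
        raise ColourSpaceError(f"expected a 2-D plane, got shape {arr.shape}")
    return arr


def as_rgb_unit(image) -> np.ndarray:
    """Coerce an RGB image (RasterImage or H×W×3 array) to unit-interval floats."""
    if isinstance(image, RasterImage):
        if image.colour_space != RGB:
            raise ColourSpaceError(f"expected an RGB image, got {image.colour_space!r}")
        return image.to_unit().pixels.astype(np.float64)
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ColourSpaceError(f"expected an H×W×3 RGB array, got shape {arr.shape}")
    if arr.max(initial=0.0) > 1.0 + 1e-9:
        arr = arr / 255.0
    return arr
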