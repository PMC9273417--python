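"""Image, mask and configuration I/O.

All internal mathematics runs on unit-interval floats; conversion to and
from the byte scale happens here, at the edges.  Masks on disk are 0/255
single-channel PNGs (unambiguous across image libraries).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml
from PIL import Image, UnidentifiedImageError

from .image import RasterImage, RGB, PLANE, BYTE, UNIT

__all__ = ["read_image", "write_image", "read_mask", "write_mask",
           "load_config", "save_config", "write_sidecar",
           "UnsupportedFormatError", "CorruptImageError"]

SUPPORTED = {".png", ".jpg", ".jpeg", ".tif", ".tiff", ".bmp"}


class UnsupportedFormatError(ValueError):
    """File extension is not a supported raster format."""


class CorruptImageError(IOError):
    """File exists but cannot be decoded as an image."""


def _check_path(path: Path, for_read: bool) -> Path:
    path = Path(path)
    if path.suffix.lower() not in SUPPORTED:
        raise UnsupportedFormatError(
            f"unsupported image format {path.suffix!r} (supported: {sorted(SUPPORTED)})"
        )
    if for_read and not path.exists():
        raise FileNotFoundError(f"no such image file: {path}")
    return path


def read_image(path) -> RasterImage:
    """Read an RGB image into a unit-domain :class:`RasterImage`."""
    path = _check_path(path, for_read=True)
    try:
        with Image.open(path) as im:
            arr = np.asarray(im.convert("RGB"), dtype=np.float64)
    except UnidentifiedImageError as exc:
        raise CorruptImageError(f"cannot decode {path}: {exc}") from exc
    return RasterImage(arr / 255.0, colour_space=RGB, domain=UNIT)


def write_image(image: RasterImage, path) -> None:
    """Write an RGB image (PNG/TIFF/BMP lossless; JPEG lossy)."""
    path = _check_path(path, for_read=False)
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(image.as_uint8()).save(path)


def read_mask(path) -> np.ndarray:
    """Read a 0/255 single-channel mask PNG as a boolean array."""
    path = _check_path(path, for_read=True)
    try:
        with Image.open(path) as im:
            arr = np.asarray(im.convert("L"))
    except UnidentifiedImageError as exc:
        raise CorruptImageError(f"cannot decode {path}: {exc}") from exc
    return arr >= 128


def write_mask(mask, path) -> None:
    """Write a boolean/int mask as a 0/255 single-channel PNG."""
    path = _check_path(path, for_read=False)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = np.asarray(mask)
    Image.fromarray(((arr != 0) * np.uint8(255))).save(path)


def load_config(path) -> dict:
    """Load a YAML configuration file as a dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def save_config(cfg: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def write_sidecar(params: dict, path) -> None:
    """Write the resolved processing parameters next to an output artifact."""
    from . import __version__
    payload = {"wbcseg_version": __version__, **params}
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(payload, indent=1, default=str))
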