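"""Synthetic blood-smear generator with exact ground truth.

Emulates the structure of Wright-stained peripheral-blood micrographs that
the correction and segmentation stages rely on: a bright, low-saturation
background; many pale, weakly saturated distractor cells (erythrocytes and
debris); a few darker, strongly saturated leukocytes; a smooth multiplicative
illumination field (linear gradient or radial vignette); and additive sensor
noise.  In HSV terms the mean saturation obeys

    leukocytes > distractors > background

and leukocyte value (brightness) lies strictly below the background value —
the separability the adaptive correction exploits.  Cells are smoothed
ellipses; photorealism (staining chemistry, cell typing, adherent clusters)
is out of scope.

Everything is deterministic given the seed, and the returned mask marks
exactly the placed leukocyte pixels, so segmentation and counting can be
scored against exact ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import binary_dilation, gaussian_filter
from skimage.color import hsv2rgb

from .image import RasterImage, RGB, UNIT

__all__ = ["SmearConfig", "GenerationError", "generate_smear", "generate_dataset",
           "rasterize_objects"]


class GenerationError(RuntimeError):
    """Raised when cells cannot be placed without overlap within the retry budget."""


@dataclass(frozen=True)
class SmearConfig:
    """Parameters of the synthetic smear.

    Ranges are (low, high) and sampled uniformly.  ``illumination`` is
    ``("none",)``, ``("linear", amplitude)`` or ``("vignette", amplitude)``;
    a linear gradient of amplitude ``a`` makes the ratio of brightest to
    darkest background value equal (1+a)/(1-a), with a random direction per
    image.  ``flare`` adds stray light proportional to the local
    illumination deficit (white of that strength where the field is
    darkest), which desaturates the dim side the way real stray light does;
    0 keeps the field purely multiplicative.  Defaults model a moderately
    uneven smear at desk scale.
    """

    size: tuple = (128, 128)
    n_leukocytes: int = 3
    n_distractors: int = 25
    illumination: tuple = ("linear", 0.25)
    leukocyte_hue: tuple = (0.72, 0.83)
    leukocyte_sat: tuple = (0.55, 0.75)
    leukocyte_val: tuple = (0.48, 0.62)
    distractor_hue: tuple = (0.04, 0.08)  # orange-red, clear of the hue wrap at 0
    distractor_sat: tuple = (0.15, 0.30)
    distractor_val: tuple = (0.72, 0.84)
    background_hue: tuple = (0.07, 0.11)
    background_sat: tuple = (0.04, 0.10)
    background_val: tuple = (0.84, 0.92)
    leukocyte_axes: tuple = (8.0, 14.0)
    distractor_axes: tuple = (4.0, 9.0)
    blur_sigma: float = 0.8
    noise_sd: float = 0.01
    flare: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_leukocytes < 0 or self.n_distractors < 0:
            raise ValueError("object counts must be nonnegative")
        if self.leukocyte_sat[0] <= self.distractor_sat[1]:
            raise ValueError(
                "leukocyte saturation range must lie strictly above the "
                "distractor saturation range"
            )
        if self.leukocyte_val[1] >= self.background_val[0]:
            raise ValueError(
                "leukocyte value range must lie strictly below the "
                "background value range"
            )
        if self.illumination[0] not in ("none", "linear", "vignette"):
            raise ValueError(f"unknown illumination model {self.illumination[0]!r}")


def _ellipse_stencil(shape, centre, axes, angle) -> np.ndarray:
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w]
    dr = rr - centre[0]
    dc = cc - centre[1]
    ca, sa = np.cos(angle), np.sin(angle)
    u = dr * ca + dc * sa
    v = -dr * sa + dc * ca
    return (u / axes[0]) ** 2 + (v / axes[1]) ** 2 <= 1.0


def _sample_range(rng, rng_pair) -> float:
    return float(rng.uniform(rng_pair[0], rng_pair[1]))


def rasterize_objects(shape, objects, cls: str) -> np.ndarray:
    """Rebuild the union stencil of all placed objects of one class from the
    metadata that :func:`generate_smear` records."""
    out = np.zeros(shape, dtype=bool)
    for obj in objects:
        if obj["class"] == cls:
            out |= _ellipse_stencil(shape, obj["centre"], obj["axes"], obj["angle"])
    return out


def generate_smear(config: SmearConfig | None = None, seed: int | None = None,
                   max_retries: int = 200):
    """Generate one smear image with its leukocyte mask and metadata.

    Returns ``(image, mask, metadata)``: a unit-domain RGB :class:`RasterImage`,
    a boolean H×W mask marking exactly the leukocyte pixels, and a metadata
    dict recording every placed object (class, centre, axes, angle), the
    illumination field parameters and the seed.  Deterministic given the seed.
    Leukocytes never overlap one another; placement is rejection-sampled and
    a :class:`GenerationError` is raised if the packing is infeasible.
    """
    if config is None:
        config = SmearConfig()
    if seed is not None:
        config = replace(config, seed=int(seed))
    rng = np.random.default_rng(config.seed)
    h, w = config.size

    hue = np.full((h, w), _sample_range(rng, config.background_hue))
    sat = np.full((h, w), _sample_range(rng, config.background_sat))
    val = np.full((h, w), _sample_range(rng, config.background_val))

    objects = []

    def place(n, axes_range, cls, forbid):
        placed = []
        for _ in range(n):
            for attempt in range(max_retries):
                ax = (rng.uniform(*axes_range), rng.uniform(*axes_range))
                margin = max(ax)
                centre = (rng.uniform(margin, h - margin), rng.uniform(margin, w - margin))
                angle = rng.uniform(0, np.pi)
                stencil = _ellipse_stencil((h, w), centre, ax, angle)
                if forbid is not None and np.any(stencil & forbid):
                    continue
                placed.append({"class": cls, "centre": centre, "axes": ax,
                               "angle": float(angle)})
                if forbid is not None:
                    # dilate so placed cells keep a >=1 px gap: component
                    # counts stay exact even under 8-connectivity
                    forbid |= binary_dilation(stencil,
                                              np.ones((3, 3), dtype=bool))
                break
            else:
                raise GenerationError(
                    f"could not place {cls} #{len(placed) + 1} after {max_retries} tries"
                )
        return placed

    # Distractors first (may overlap each other), leukocytes on top so no
    # distractor pixel survives inside the mask.
    objects += place(config.n_distractors, config.distractor_axes, "distractor", None)
    occupied = np.zeros((h, w), dtype=bool)
    objects += place(config.n_leukocytes, config.leukocyte_axes, "leukocyte", occupied)

    def paint(stencil, obj_hue, obj_sat, obj_val):
        alpha = gaussian_filter(stencil.astype(np.float64), config.blur_sigma)
        nonlocal hue, sat, val
        hue = hue * (1 - alpha) + (obj_hue % 1.0) * alpha
        sat = sat * (1 - alpha) + obj_sat * alpha
        val = val * (1 - alpha) + obj_val * alpha

    for obj in objects:
        if obj["class"] != "distractor":
            continue
        stencil = _ellipse_stencil((h, w), obj["centre"], obj["axes"], obj["angle"])
        paint(stencil, _sample_range(rng, config.distractor_hue),
              _sample_range(rng, config.distractor_sat),
              _sample_range(rng, config.distractor_val))

    mask = np.zeros((h, w), dtype=bool)
    for obj in objects:
        if obj["class"] != "leukocyte":
            continue
        stencil = _ellipse_stencil((h, w), obj["centre"], obj["axes"], obj["angle"])
        cyto_val = _sample_range(rng, config.leukocyte_val)
        cyto_sat = _sample_range(rng, config.leukocyte_sat)
        obj_hue = _sample_range(rng, config.leukocyte_hue)
        paint(stencil, obj_hue, cyto_sat, cyto_val)
        # darker, slightly more saturated nucleus inside the cell
        nucleus = _ellipse_stencil((h, w), obj["centre"],
                                   (obj["axes"][0] * 0.55, obj["axes"][1] * 0.55),
                                   obj["angle"])
        paint(nucleus, obj_hue, min(1.0, cyto_sat * 1.1), cyto_val * 0.65)
        mask |= stencil

    rgb = hsv2rgb(np.dstack([hue % 1.0, np.clip(sat, 0, 1), np.clip(val, 0, 1)]))

    kind = config.illumination[0]
    illum_meta = {"model": kind}
    if kind != "none":
        a = float(config.illumination[1])
        if not 0.0 <= a < 1.0:
            raise ValueError("illumination amplitude must lie in [0, 1)")
        rr, cc = np.mgrid[0:h, 0:w]
        if kind == "linear":
            theta = rng.uniform(0, 2 * np.pi)
            t = (rr - (h - 1) / 2) * np.cos(theta) + (cc - (w - 1) / 2) * np.sin(theta)
            t = t / np.abs(t).max() if np.abs(t).max() > 0 else t
            field_g = (1.0 + a * t) / (1.0 + a)
            illum_meta.update(amplitude=a, direction=float(theta))
        else:  # vignette
            r2 = ((rr - (h - 1) / 2) ** 2 + (cc - (w - 1) / 2) ** 2)
            field_g = 1.0 - a * r2 / r2.max()
            illum_meta.update(amplitude=a)
        rgb = rgb * field_g[:, :, None]
        if config.flare > 0:
            # stray light fills the dimly lit side, washing out saturation
            # there the way misaligned illumination does on a real microscope
            rgb = rgb + config.flare * (1.0 - field_g)[:, :, None]
        illum_meta["flare"] = float(config.flare)

    if config.noise_sd > 0:
        rgb = rgb + rng.normal(0.0, config.noise_sd, rgb.shape)
    rgb = np.clip(rgb, 0.0, 1.0)

    metadata = {
        "seed": int(config.seed),
        "size": [int(h), int(w)],
        "illumination": illum_meta,
        "objects": [
            {"class": o["class"],
             "centre": [float(o["centre"][0]), float(o["centre"][1])],
             "axes": [float(o["axes"][0]), float(o["axes"][1])],
             "angle": float(o["angle"])}
            for o in objects
        ],
    }
    return RasterImage(rgb, colour_space=RGB, domain=UNIT), mask, metadata


def generate_dataset(n_images: int, config: SmearConfig | None = None,
                     split: float = 0.5, out_dir=None):
    """Generate ``n_images`` smear/mask pairs and split them into train/test.

    The split is applied by a seeded shuffle; per-image seeds derive from the
    config seed, so regeneration is bit-identical.  Returns
    ``(train, test, manifest)`` where train/test are lists of
    (image, mask, metadata) and the manifest is a DataFrame with one row per
    image.  With ``out_dir`` set, images and masks are written as PNG
    (masks 0/255 single channel) alongside ``manifest.csv`` and
    ``metadata.json``.
    """
    if not 0.0 < split < 1.0:
        raise ValueError(f"split must lie in (0, 1), got {split}")
    if config is None:
        config = SmearConfig()
    master = np.random.default_rng(config.seed)
    seeds = master.integers(0, 2**31 - 1, size=n_images)
    order = master.permutation(n_images)
    n_train = int(round(n_images * split))
    split_tag = np.empty(n_images, dtype=object)
    split_tag[order[:n_train]] = "train"
    split_tag[order[n_train:]] = "test"

    samples = [generate_smear(config, seed=int(s)) for s in seeds]
    manifest = pd.DataFrame({
        "index": np.arange(n_images),
        "filename": [f"smear_{i:04d}.png" for i in range(n_images)],
        "mask": [f"smear_{i:04d}_mask.png" for i in range(n_images)],
        "split": split_tag,
        "seed": seeds,
        "n_leukocytes": [sum(1 for o in m["objects"] if o["class"] == "leukocyte")
                         for _, _, m in samples],
    })

    if out_dir is not None:
        from . import io as wio
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        all_meta = {}
        for row, (img, mask, meta) in zip(manifest.itertuples(), samples):
            wio.write_image(img, out_dir / row.filename)
            wio.write_mask(mask, out_dir / row.mask)
            all_meta[row.filename] = meta
        manifest.to_csv(out_dir / "manifest.csv", index=False)
        (out_dir / "metadata.json").write_text(json.dumps(all_meta, indent=1))

    train = [s for s, tag in zip(samples, split_tag) if tag == "train"]
    test = [s for s, tag in zip(samples, split_tag) if tag == "test"]
    return train, test, manifest
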