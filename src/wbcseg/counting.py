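"""Leukocyte counting by connected-component analysis of a binary mask.

The predicted segmentation is binarised, connected foreground domains are
extracted (8-connectivity by default; leukocyte blobs are compact and
8-connectivity avoids splitting thin diagonal bridges), and components are
numbered 1..count with background 0.  Touching or overlapping cells merge
into one component — counting adherent cells is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from PIL import Image, ImageDraw

from .image import RasterImage, as_rgb_unit, RGB, UNIT

__all__ = ["ComponentLabeling", "binarize", "count_components", "annotate_counts"]


@dataclass(frozen=True)
class ComponentLabeling:
    """Connected-component labelling: 0 = background, labels 1..count."""

    label_map: np.ndarray
    count: int
    centroids: tuple  # per-component (row, col)

    def __post_init__(self) -> None:
        if self.count != len(self.centroids):
            raise ValueError("one centroid per component is required")


def binarize(pred, threshold: float = 0.5) -> np.ndarray:
    """Binary foreground mask from a probability map or a label mask.

    Float input is thresholded at ``value > threshold``; integer/bool input
    is treated as labels with foreground = nonzero.
    """
    arr = np.asarray(pred)
    if arr.dtype == bool:
        return arr.copy()
    if np.issubdtype(arr.dtype, np.integer):
        return arr != 0
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    return arr > threshold


def count_components(mask, connectivity: int = 8, min_area: int = 0) -> ComponentLabeling:
    """Label connected foreground domains of a binary mask.

    ``connectivity`` is 4 (edge-adjacent) or 8 (edge- or corner-adjacent).
    Components smaller than ``min_area`` pixels are dropped and the labels
    renumbered consecutively.
    """
    arr = np.asarray(mask)
    if arr.dtype != bool:
        if not (np.issubdtype(arr.dtype, np.integer) and set(np.unique(arr)) <= {0, 1}):
            raise TypeError("count_components requires a binary mask")
        arr = arr.astype(bool)
    if connectivity not in (4, 8):
        raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")
    structure = ndimage.generate_binary_structure(2, 1 if connectivity == 4 else 2)
    label_map, count = ndimage.label(arr, structure=structure)
    if min_area > 0 and count:
        sizes = ndimage.sum_labels(arr, label_map, index=np.arange(1, count + 1))
        keep = np.flatnonzero(sizes >= min_area) + 1
        remap = np.zeros(count + 1, dtype=label_map.dtype)
        remap[keep] = np.arange(1, len(keep) + 1)
        label_map = remap[label_map]
        count = len(keep)
    centroids = tuple(
        (float(r), float(c))
        for r, c in ndimage.center_of_mass(arr, label_map, index=np.arange(1, count + 1))
    ) if count else ()
    return ComponentLabeling(label_map=label_map, count=int(count), centroids=centroids)


def annotate_counts(image, labeling: ComponentLabeling,
                    colour=(255, 0, 0)) -> RasterImage:
    """Draw each component's index at its centroid on a copy of the image.

    Background is component 0 and is not drawn.  The input is not modified.
    """
    rgb = as_rgb_unit(image)
    if rgb.shape[:2] != labeling.label_map.shape:
        raise ValueError(
            f"image shape {rgb.shape[:2]} does not match labeling {labeling.label_map.shape}"
        )
    canvas = Image.fromarray(np.clip(np.round(rgb * 255), 0, 255).astype(np.uint8))
    draw = ImageDraw.Draw(canvas)
    h, w = labeling.label_map.shape
    for idx, (r, c) in enumerate(labeling.centroids, start=1):
        pos = (min(max(int(c) - 3, 0), w - 7), min(max(int(r) - 5, 0), h - 11))
        draw.text(pos, str(idx), fill=tuple(colour))
    out = np.asarray(canvas, dtype=np.float64) / 255.0
    return RasterImage(out, colour_space=RGB, domain=UNIT)
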