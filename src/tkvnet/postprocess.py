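"""Mask inpainting: binarize, fill holes, despeckle, lateralize.

The network's raw output masks can carry defects — holes inside the kidney,
speckle outside it — so before volumetry every mask passes through a fixed
pipeline: threshold, hole-filling (4-connected background), despeckle
(8-connected small components removed), then a left/right split by
component centroid relative to the image vertical midline.  Radiological
convention: the left half of the image is the patient's right side.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .geometry_io import SeriesGeometry

logger = logging.getLogger("tkvnet")

#: 8-connectivity structuring element for component labelling.
_STRUCT8 = np.ones((3, 3), dtype=int)

#: default minimum component area (native-grid pixels) kept by despeckle —
#: far below any kidney cross-section, well above noise speckle
DEFAULT_MIN_SIZE_PX = 25


@dataclass
class LateralizedMaskStack:
    """Per-slice left/right kidney masks; disjoint by construction."""

    left: list[np.ndarray]
    right: list[np.ndarray]
    geometry: SeriesGeometry

    def __post_init__(self) -> None:
        if len(self.left) != len(self.right):
            raise ValueError("left and right stacks must have equal length")
        for l, r in zip(self.left, self.right):
            if l.shape != r.shape:
                raise ValueError("left/right slice shapes must match")
            if np.any(l & r):
                raise ValueError("left and right masks must be disjoint")


def binarize(mask: np.ndarray) -> np.ndarray:
    """Threshold a grayscale (0–255) or probability (0–1) map to {0, 1}.

    Grayscale values become 1 at >= 128; probabilities at >= 0.5.  The two
    conventions are equivalent (128/255 ≈ 0.5) and are auto-detected from
    the value range: any value > 1 selects the grayscale rule.
    """
    arr = np.asarray(mask, dtype=np.float64)
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("values outside both the 0–1 and 0–255 ranges")
    if arr.max() > 1.0:
        return (arr >= 128).astype(np.uint8)
    return (arr >= 0.5).astype(np.uint8)


def fill_holes(mask: np.ndarray) -> np.ndarray:
    """Set to foreground every background region not 4-connected to the border.

    Never removes foreground; idempotent.
    """
    m = np.asarray(mask).astype(bool)
    # default structure of binary_fill_holes is the 4-connected cross
    return ndimage.binary_fill_holes(m).astype(np.uint8)


def despeckle(mask: np.ndarray, min_size_px: int = DEFAULT_MIN_SIZE_PX) -> np.ndarray:
    """Remove 8-connected foreground components with area < ``min_size_px``.

    Never adds foreground; idempotent.
    """
    if min_size_px < 0:
        raise ValueError("min_size_px must be >= 0")
    m = np.asarray(mask).astype(bool)
    if min_size_px == 0:
        return m.astype(np.uint8)
    labels, n = ndimage.label(m, structure=_STRUCT8)
    if n == 0:
        return m.astype(np.uint8)
    sizes = np.bincount(labels.ravel())
    keep = sizes >= min_size_px
    keep[0] = False
    return keep[labels].astype(np.uint8)


def clean_mask(mask: np.ndarray, min_size_px: int = DEFAULT_MIN_SIZE_PX) -> np.ndarray:
    """The fixed inpainting order: binarize → fill holes → despeckle.

    Filling before despeckling matters: a thin ring (a kidney outline with
    a hollow centre) first becomes a solid disk and then survives the size
    filter it would otherwise fail.
    """
    return despeckle(fill_holes(binarize(mask)), min_size_px)


def split_left_right(masks: list[np.ndarray],
                     geometry: SeriesGeometry) -> LateralizedMaskStack:
    """Assign each 8-connected component to the patient's left or right side.

    A component whose centroid column is left of the image midline lies on
    the patient's right (radiological convention); at or right of the
    midline, the patient's left.  A component straddling the midline goes
    wholly to the side of its centroid.  A warning is logged when a
    component's side flips between adjacent slices.
    """
    midline = (geometry.n_cols - 1) / 2.0
    left_out, right_out = [], []
    prev_sides: set[str] | None = None
    for k, mask in enumerate(masks):
        m = np.asarray(mask).astype(bool)
        left = np.zeros_like(m, dtype=np.uint8)
        right = np.zeros_like(m, dtype=np.uint8)
        labels, n = ndimage.label(m, structure=_STRUCT8)
        sides: set[str] = set()
        for lab in range(1, n + 1):
            comp = labels == lab
            centroid_col = ndimage.center_of_mass(comp)[1]
            if centroid_col < midline:
                right |= comp
                sides.add("right")
            else:
                left |= comp
                sides.add("left")
        if prev_sides is not None and sides and prev_sides and sides != prev_sides \
                and (sides - prev_sides):
            logger.warning("slice %d: component side set changed %s -> %s",
                           k, sorted(prev_sides), sorted(sides))
        prev_sides = sides
        left_out.append(left)
        right_out.append(right)
    return LateralizedMaskStack(left=left_out, right=right_out, geometry=geometry)
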