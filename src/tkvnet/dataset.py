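"""Annotations, masks, data splitting and per-epoch augmentation.

Polygon annotations (Labelme-style JSON, one file per slice) are rasterized
to binary masks with a pixel-centre inclusion rule: a pixel is foreground
iff its centre lies inside or on the boundary of any kidney polygon.  Left
and right kidney polygons are merged into a single foreground class for
training; laterality is recovered downstream by the post-processing split.

Augmentation mirrors small-rotation / shift / zoom jitter commonly used for
scarce medical data: one random affine transform per pair per epoch, drawn
fresh each epoch, applied identically to image and mask.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import shapely
from scipy import ndimage
from shapely.geometry import Polygon

VALID_LABELS = ("left_kidney", "right_kidney")


class AnnotationError(ValueError):
    pass


@dataclass(frozen=True)
class PolygonAnnotation:
    """One polygon outline of a kidney on one slice.

    Vertices are (x, y) = (column, row) in pixel units, pixel centres at
    integer coordinates.
    """

    label: str
    vertices: tuple[tuple[float, float], ...]
    image_ref: str = ""

    def __post_init__(self) -> None:
        if self.label not in VALID_LABELS:
            raise AnnotationError(
                f"label must be one of {VALID_LABELS}, got {self.label!r}")
        if len(self.vertices) < 3:
            raise AnnotationError(
                f"polygon needs at least 3 vertices, got {len(self.vertices)}")


@dataclass(frozen=True)
class AugmentationParams:
    """Magnitudes of the random per-epoch transform.

    Defaults: rotation up to 5 degrees, shift and zoom up to 10%, no flips.
    """

    rotation_max_deg: float = 5.0
    shift_max_frac: float = 0.10
    zoom_max_frac: float = 0.10
    horizontal_flip: bool = False
    vertical_flip: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.rotation_max_deg, self.shift_max_frac, self.zoom_max_frac) < 0:
            raise ValueError("augmentation magnitudes must be >= 0")


@dataclass
class LabeledPair:
    """A model-grid image with its binary kidney mask."""

    image: np.ndarray
    mask: np.ndarray
    subject_id: str = ""
    slice_index: int = 0

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=np.float64)
        self.mask = np.asarray(self.mask)
        if self.image.shape != self.mask.shape:
            raise ValueError("image and mask shapes must match")
        if not np.all(np.isin(np.unique(self.mask), (0, 1))):
            raise ValueError("mask values must be in {0, 1}")
        self.mask = self.mask.astype(np.uint8)


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------

def polygons_to_mask(annotations: Sequence[PolygonAnnotation],
                     shape: tuple[int, int]) -> np.ndarray:
    """Rasterize polygons to a binary mask of the given (rows, cols) shape.

    A pixel is 1 iff its centre (integer (row, col) coordinate) lies inside
    or on the boundary of any polygon.  All kidney labels are merged into
    one foreground.
    """
    n_rows, n_cols = shape
    if n_rows < 1 or n_cols < 1:
        raise ValueError("mask shape must be positive")
    mask = np.zeros((n_rows, n_cols), dtype=np.uint8)
    for ann in annotations:
        poly = Polygon(ann.vertices)
        if not poly.is_valid:
            poly = poly.buffer(0)
        minx, miny, maxx, maxy = poly.bounds
        c0 = max(int(np.floor(minx)), 0)
        c1 = min(int(np.ceil(maxx)), n_cols - 1)
        r0 = max(int(np.floor(miny)), 0)
        r1 = min(int(np.ceil(maxy)), n_rows - 1)
        if c1 < c0 or r1 < r0:
            continue
        cols, rows = np.meshgrid(np.arange(c0, c1 + 1), np.arange(r0, r1 + 1))
        pts = shapely.points(cols.ravel().astype(float), rows.ravel().astype(float))
        inside = shapely.covers(poly, pts).reshape(rows.shape)
        mask[r0:r1 + 1, c0:c1 + 1] |= inside.astype(np.uint8)
    return mask


# ---------------------------------------------------------------------------
# Labelme-style JSON
# ---------------------------------------------------------------------------

def read_labelme(path: str | Path) -> tuple[list[PolygonAnnotation], tuple[int, int]]:
    """Read one Labelme-style JSON file: annotations plus (rows, cols)."""
    with open(path) as fh:
        doc = json.load(fh)
    shape = (int(doc["imageHeight"]), int(doc["imageWidth"]))
    anns = []
    for sh in doc.get("shapes", []):
        if sh.get("shape_type", "polygon") != "polygon":
            continue
        anns.append(PolygonAnnotation(
            label=sh["label"],
            vertices=tuple((float(x), float(y)) for x, y in sh["points"]),
            image_ref=str(doc.get("imagePath", Path(path).stem)),
        ))
    return anns, shape


def write_labelme(path: str | Path, annotations: Sequence[PolygonAnnotation],
                  shape: tuple[int, int], image_path: str = "") -> None:
    doc = {
        "version": "3.0",
        "shapes": [
            {
                "label": ann.label,
                "points": [[float(x), float(y)] for x, y in ann.vertices],
                "shape_type": "polygon",
            }
            for ann in annotations
        ],
        "imagePath": image_path,
        "imageHeight": int(shape[0]),
        "imageWidth": int(shape[1]),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def pairs_from_directory(series_dir: str | Path, annotations_dir: str | Path,
                         size: int = 256) -> list[LabeledPair]:
    """Build model-grid training pairs from a DICOM series + Labelme JSONs.

    Annotation files are matched to slices by index (``slice_NNNN.json``);
    slices without a JSON get an empty mask.  Images are resampled to the
    model grid and scaled to [0, 1]; masks are rasterized on the native
    grid then nearest-neighbour resampled.
    """
    from skimage.transform import resize as _resize

    from .geometry_io import prepare_for_model, read_series

    stack = read_series(series_dir)
    annotations_dir = Path(annotations_dir)
    pairs = []
    for k, sl in enumerate(stack.slices):
        img = prepare_for_model(sl, size)
        jpath = annotations_dir / f"slice_{k:04d}.json"
        if jpath.exists():
            anns, shape = read_labelme(jpath)
            mask = polygons_to_mask(anns, shape)
        else:
            mask = np.zeros(sl.shape, dtype=np.uint8)
        if mask.shape != (size, size):
            mask = (_resize(mask.astype(float), (size, size), order=0,
                            mode="edge", anti_aliasing=False,
                            preserve_range=True) > 0.5).astype(np.uint8)
        pairs.append(LabeledPair(img, mask, stack.subject_id, k))
    return pairs


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

def split_train_val(items: Sequence, train_frac: float = 0.8,
                    seed: int = 0) -> tuple[list, list]:
    """Random train/validation partition with ``floor(n * train_frac)`` in train.

    Deterministic given *seed*; the two parts are disjoint and together
    contain every item exactly once.
    """
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must be in (0, 1)")
    items = list(items)
    if not items:
        raise ValueError("cannot split an empty list")
    n_train = int(np.floor(len(items) * train_frac))
    order = np.random.default_rng(seed).permutation(len(items))
    train = [items[i] for i in order[:n_train]]
    val = [items[i] for i in order[n_train:]]
    return train, val


def split_by_patient(items: Sequence, subject_of, train_frac: float = 0.8,
                     seed: int = 0) -> tuple[list, list]:
    """Partition *items* so that no subject spans train and validation.

    ``subject_of`` maps an item to its subject id.  Subjects (not images)
    are randomly assigned with ``floor(n_subjects * train_frac)`` in train;
    this avoids the leakage an image-wise split permits.
    """
    items = list(items)
    if not items:
        raise ValueError("cannot split an empty list")
    subjects = sorted({subject_of(it) for it in items})
    train_subj, _ = split_train_val(subjects, train_frac, seed)
    train_set = set(train_subj)
    train = [it for it in items if subject_of(it) in train_set]
    val = [it for it in items if subject_of(it) not in train_set]
    return train, val


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------

def augment_pair(pair: LabeledPair, params: AugmentationParams,
                 draw: np.random.Generator) -> LabeledPair:
    """Apply one random rotation/shift/zoom (and optional flips) to a pair.

    The same geometric transform is applied to image (bilinear) and mask
    (nearest-neighbour, re-binarized); regions moved in from outside the
    canvas are filled with 0 (MRI background is dark).  With all magnitudes
    zero and flips off this is the identity.
    """
    img, msk = pair.image, pair.mask
    rows, cols = img.shape

    angle = np.deg2rad(draw.uniform(-params.rotation_max_deg, params.rotation_max_deg))
    shift_r = draw.uniform(-params.shift_max_frac, params.shift_max_frac) * rows
    shift_c = draw.uniform(-params.shift_max_frac, params.shift_max_frac) * cols
    zoom = draw.uniform(1.0 - params.zoom_max_frac, 1.0 + params.zoom_max_frac)
    flip_h = params.horizontal_flip and draw.random() < 0.5
    flip_v = params.vertical_flip and draw.random() < 0.5

    if angle == 0 and shift_r == 0 and shift_c == 0 and zoom == 1 and not (flip_h or flip_v):
        return LabeledPair(img.copy(), msk.copy(), pair.subject_id, pair.slice_index)

    # Output->input affine about the image centre (row, col convention).
    c, s = np.cos(angle), np.sin(angle)
    rot = np.array([[c, -s], [s, c]]) / zoom
    if flip_v:
        rot = rot @ np.diag([-1.0, 1.0])
    if flip_h:
        rot = rot @ np.diag([1.0, -1.0])
    centre = np.array([(rows - 1) / 2.0, (cols - 1) / 2.0])
    offset = centre - rot @ (centre + np.array([shift_r, shift_c]))

    out_img = ndimage.affine_transform(img, rot, offset=offset, order=1,
                                       mode="constant", cval=0.0)
    out_msk = ndimage.affine_transform(msk.astype(np.float64), rot, offset=offset,
                                       order=0, mode="constant", cval=0.0)
    return LabeledPair(np.clip(out_img, 0.0, 1.0), (out_msk > 0.5).astype(np.uint8),
                       pair.subject_id, pair.slice_index)
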