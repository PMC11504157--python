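"""Synthetic MRI-like phantom cases with known kidney masks and volumes.

Each phantom is a stack of grayscale slices containing two non-overlapping
ellipsoidal "kidneys" (optionally carrying brighter spherical "cysts", as
fluid appears bright on T2-weighted MRI), additive Gaussian noise, and full
geometry metadata.  The exact rendered ellipsoid cross-sections serve as
ground-truth masks, and both a voxel-counted and an analytic 4/3*pi*a*b*c
volume are recorded, so every downstream stage — DICOM I/O, annotation
rasterization, training, post-processing, volumetry — can be exercised and
checked without patient data.

Physical layout: columns map to x, rows to y, slices to z, all in mm via
the spec's pixel spacing and slice thickness.  Slices are contiguous
(spacing between slices equals slice thickness).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from skimage import measure

from .dataset import PolygonAnnotation, write_labelme
from .geometry_io import SeriesGeometry, SliceStack, write_series

SIDES = ("left", "right")


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic case.

    Defaults describe a small abdomen-like field of view (64 x 64 pixels at
    4 mm, 20 slices of 8 mm) with two ADPKD-scale kidneys of roughly 242 mL
    each, chosen so that CPU training on the resulting slices completes in
    minutes.  Intensities follow the T2 convention: dark background, bright
    parenchyma, brighter cysts.
    """

    n_slices: int = 20
    n_rows: int = 64
    n_cols: int = 64
    pixel_spacing: float = 4.0
    slice_thickness: float = 8.0
    orientation: str = "axial"
    # (a, b, c) semiaxes in mm along (x, y, z), per side
    kidney_semiaxes_mm: dict = field(default_factory=lambda: {
        "left": (30.0, 35.0, 55.0), "right": (30.0, 35.0, 55.0)})
    # (x, y, z) centres in mm, per side; patient-left is image-right
    kidney_centers_mm: dict = field(default_factory=lambda: {
        "left": (180.0, 128.0, 80.0), "right": (76.0, 128.0, 80.0)})
    n_cysts: int = 3
    cyst_radius_range_mm: tuple[float, float] = (5.0, 12.0)
    noise_sd: float = 8.0
    background_intensity: float = 30.0
    kidney_intensity: float = 140.0
    cyst_intensity: float = 220.0
    seed: int = 0

    def __post_init__(self) -> None:
        for side in SIDES:
            if min(self.kidney_semiaxes_mm[side]) <= 0:
                raise ValueError(f"{side} kidney semiaxes must be positive")
        for v in (self.background_intensity, self.kidney_intensity, self.cyst_intensity):
            if not 0 <= v <= 255:
                raise ValueError("intensities must lie in [0, 255]")

    @property
    def geometry(self) -> SeriesGeometry:
        return SeriesGeometry(
            pixel_spacing_row=self.pixel_spacing,
            pixel_spacing_col=self.pixel_spacing,
            slice_thickness=self.slice_thickness,
            spacing_between_slices=self.slice_thickness,
            n_rows=self.n_rows,
            n_cols=self.n_cols,
            orientation=self.orientation,  # type: ignore[arg-type]
        )


@dataclass
class PhantomCase:
    """A generated phantom: images, truth masks, and true volumes."""

    stack: SliceStack
    truth_masks: dict  # side -> list of (n_rows, n_cols) uint8 masks
    true_volume_ml: dict  # side -> mL from voxel counting; plus "total"
    analytic_volume_ml: dict  # side -> 4/3 pi a b c in mL; plus "total"
    spec: PhantomSpec

    @property
    def combined_masks(self) -> list[np.ndarray]:
        return [l | r for l, r in zip(self.truth_masks["left"],
                                      self.truth_masks["right"])]


def _ellipsoid_masks(spec: PhantomSpec, side: str) -> list[np.ndarray]:
    a, b, c = spec.kidney_semiaxes_mm[side]
    cx, cy, cz = spec.kidney_centers_mm[side]
    xs = np.arange(spec.n_cols) * spec.pixel_spacing
    ys = np.arange(spec.n_rows) * spec.pixel_spacing
    u = ((xs - cx) / a) ** 2  # (n_cols,)
    v = ((ys - cy) / b) ** 2  # (n_rows,)
    masks = []
    for k in range(spec.n_slices):
        z = k * spec.slice_thickness
        w = ((z - cz) / c) ** 2
        masks.append((v[:, None] + u[None, :] + w <= 1.0).astype(np.uint8))
    return masks


def generate_phantom(spec: PhantomSpec) -> PhantomCase:
    """Render one phantom case; deterministic given ``spec.seed``.

    Truth masks are the exact ellipsoid cross-sections evaluated at voxel
    centres (cysts lie inside the kidney and count as kidney, as they do
    clinically for TKV).  Noise is added to the image only and never alters
    the truth masks.
    """
    rng = np.random.default_rng(spec.seed)
    masks = {side: _ellipsoid_masks(spec, side) for side in SIDES}

    for ml, mr in zip(masks["left"], masks["right"]):
        if np.any(ml & mr):
            raise ValueError("kidneys overlap at the stated centres/semiaxes")

    voxel_ml = spec.pixel_spacing ** 2 * spec.slice_thickness / 1000.0
    true_vol = {side: float(sum(m.sum() for m in masks[side])) * voxel_ml
                for side in SIDES}
    true_vol["total"] = true_vol["left"] + true_vol["right"]
    analytic = {side: 4.0 / 3.0 * np.pi * np.prod(spec.kidney_semiaxes_mm[side]) / 1000.0
                for side in SIDES}
    analytic["total"] = analytic["left"] + analytic["right"]

    # Cyst centres sampled inside the inner half of each ellipsoid so the
    # whole cyst stays within the kidney boundary.
    cysts = []
    for side in SIDES:
        a, b, c = spec.kidney_semiaxes_mm[side]
        centre = np.array(spec.kidney_centers_mm[side])
        for _ in range(spec.n_cysts):
            r = rng.uniform(*spec.cyst_radius_range_mm)
            # rejection-free: scale a random unit direction into the ellipsoid
            # shrunk by the cyst radius on each axis
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            radial = rng.uniform(0, 1) ** (1 / 3)
            semis = np.maximum(np.array([a, b, c]) - r, 0.0)
            cysts.append((centre + direction * radial * semis * 0.9, r))

    xs = np.arange(spec.n_cols) * spec.pixel_spacing
    ys = np.arange(spec.n_rows) * spec.pixel_spacing
    slices = []
    for k in range(spec.n_slices):
        z = k * spec.slice_thickness
        img = np.full((spec.n_rows, spec.n_cols), spec.background_intensity)
        kidney = (masks["left"][k] | masks["right"][k]).astype(bool)
        img[kidney] = spec.kidney_intensity
        for (ccx, ccy, ccz), r in cysts:
            dz2 = (z - ccz) ** 2
            if dz2 >= r ** 2:
                continue
            d2 = ((ys - ccy) ** 2)[:, None] + ((xs - ccx) ** 2)[None, :] + dz2
            img[(d2 <= r ** 2) & kidney] = spec.cyst_intensity
        img = img + rng.normal(0.0, spec.noise_sd, img.shape)
        slices.append(np.clip(np.rint(img), 0, 255))

    stack = SliceStack(slices=slices, geometry=spec.geometry,
                       subject_id=f"phantom-{spec.seed}",
                       slice_positions=[k * spec.slice_thickness
                                        for k in range(spec.n_slices)])
    return PhantomCase(stack=stack, truth_masks=masks, true_volume_ml=true_vol,
                       analytic_volume_ml=analytic, spec=spec)


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def mask_to_polygons(mask: np.ndarray, label: str) -> list[PolygonAnnotation]:
    """Trace a binary mask's boundary into polygon annotations.

    Uses the 0.5-level contour of the zero-padded mask, so every foreground
    pixel centre lies strictly inside the polygon and rasterizing it back
    with the pixel-centre rule recovers the mask almost exactly.
    """
    padded = np.pad(np.asarray(mask, dtype=float), 1)
    anns = []
    for contour in measure.find_contours(padded, 0.5):
        # (row, col) in padded coords -> (x, y) in image coords
        pts = [(float(col - 1), float(row - 1)) for row, col in contour]
        if len(pts) < 3:
            continue
        anns.append(PolygonAnnotation(label=label, vertices=tuple(pts)))
    return anns


def export_case(case: PhantomCase, directory: str | Path) -> dict:
    """Export a phantom to disk: DICOM series, Labelme JSONs, truth CSV.

    One JSON is written per slice that contains kidney; slices without a
    JSON are kidney-free.  Returns a manifest of everything written.
    """
    if len(case.stack) == 0:
        raise ValueError("cannot export an empty case")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    dicom_dir = directory / "dicom"
    dicom_files = write_series(case.stack, dicom_dir)

    ann_dir = directory / "annotations"
    ann_dir.mkdir(exist_ok=True)
    shape = (case.spec.n_rows, case.spec.n_cols)
    side_label = {"left": "left_kidney", "right": "right_kidney"}
    json_files = []
    for k in range(case.spec.n_slices):
        anns = []
        for side in SIDES:
            if case.truth_masks[side][k].any():
                anns.extend(mask_to_polygons(case.truth_masks[side][k],
                                             side_label[side]))
        if not anns:
            continue
        path = ann_dir / f"slice_{k:04d}.json"
        write_labelme(path, anns, shape, image_path=f"slice_{k:04d}.dcm")
        json_files.append(path)

    csv_path = directory / "ground_truth.csv"
    with open(csv_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["subject_id", "left_ml", "right_ml", "total_ml"])
        writer.writerow([case.stack.subject_id,
                         f"{case.true_volume_ml['left']:.3f}",
                         f"{case.true_volume_ml['right']:.3f}",
                         f"{case.true_volume_ml['total']:.3f}"])

    return {"dicom": dicom_files, "annotations": json_files,
            "ground_truth": csv_path}


def coronal_spec(seed: int = 0) -> PhantomSpec:
    """A coronal-orientation default: long kidney axis in-plane (along y)."""
    return PhantomSpec(
        orientation="coronal",
        kidney_semiaxes_mm={"left": (30.0, 55.0, 35.0), "right": (30.0, 55.0, 35.0)},
        kidney_centers_mm={"left": (180.0, 128.0, 80.0), "right": (76.0, 128.0, 80.0)},
        seed=seed,
    )
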