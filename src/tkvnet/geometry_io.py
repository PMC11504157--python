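"""DICOM series I/O and model-grid resampling.

Reads a single-series directory of ``.dcm`` files into a :class:`SliceStack`
carrying the geometric metadata volumetry depends on (PixelSpacing,
SliceThickness, SpacingBetweenSlices, Rows, Columns, orientation), writes
stacks back out as a DICOM series, and converts slices to and from the
fixed square grid the segmentation network consumes.

Coordinate conventions used throughout the package: arrays are row-major
with origin at the top-left, indices are 0-based, and pixel boxes are
half-open.  ``x`` denotes column, ``y`` row.
"""

from __future__ import annotations

import logging
import uuid
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid
from skimage.transform import resize

logger = logging.getLogger("tkvnet")

Orientation = Literal["axial", "coronal"]

#: ImageOrientationPatient direction cosines for the two supported planes.
_ORIENT_COSINES = {
    "axial": [1.0, 0.0, 0.0, 0.0, 1.0, 0.0],
    "coronal": [1.0, 0.0, 0.0, 0.0, 0.0, -1.0],
}


class SeriesReadError(ValueError):
    """Raised when a DICOM directory cannot be read as one coherent series."""


@dataclass(frozen=True)
class SeriesGeometry:
    """Spatial metadata of one imaging series.

    Parameters
    ----------
    pixel_spacing_row, pixel_spacing_col
        Physical size of one pixel in mm along the row / column direction.
    slice_thickness
        Acquired slice thickness in mm.
    spacing_between_slices
        Centre-to-centre slice distance in mm, or ``None`` when the tag is
        absent from the source series (never silently defaulted).
    n_rows, n_cols
        In-plane grid size in pixels.
    orientation
        ``"axial"`` or ``"coronal"``.
    """

    pixel_spacing_row: float
    pixel_spacing_col: float
    slice_thickness: float
    spacing_between_slices: float | None
    n_rows: int
    n_cols: int
    orientation: Orientation

    def __post_init__(self) -> None:
        for name in ("pixel_spacing_row", "pixel_spacing_col", "slice_thickness"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.spacing_between_slices is not None and self.spacing_between_slices <= 0:
            raise ValueError("spacing_between_slices must be strictly positive when present")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid size must be at least 1x1")
        if self.orientation not in ("axial", "coronal"):
            raise ValueError(f"orientation must be 'axial' or 'coronal', got {self.orientation!r}")

    @property
    def pixel_area_mm2(self) -> float:
        return self.pixel_spacing_row * self.pixel_spacing_col

    def slice_spacing_mm(self, mode: str = "thickness") -> float:
        """Through-plane step in mm under the chosen convention."""
        if mode == "thickness":
            return self.slice_thickness
        if mode == "between_slices":
            if self.spacing_between_slices is None:
                raise KeyError(
                    "spacing_mode='between_slices' requested but the "
                    "SpacingBetweenSlices tag was absent from this series"
                )
            return self.spacing_between_slices
        raise ValueError(f"unknown spacing mode {mode!r}")


@dataclass
class SliceStack:
    """An ordered stack of grayscale slices forming one imaging series."""

    slices: list[np.ndarray]
    geometry: SeriesGeometry
    subject_id: str = ""
    slice_positions: list[float] | None = None

    def __post_init__(self) -> None:
        shape = (self.geometry.n_rows, self.geometry.n_cols)
        for i, s in enumerate(self.slices):
            if s.shape != shape:
                raise ValueError(
                    f"slice {i} has shape {s.shape}, geometry says {shape}"
                )
        if self.slice_positions is not None:
            pos = np.asarray(self.slice_positions, dtype=float)
            if len(pos) != len(self.slices):
                raise ValueError("slice_positions length must match number of slices")
            if len(pos) > 1 and not (np.all(np.diff(pos) >= 0) or np.all(np.diff(pos) <= 0)):
                raise ValueError("slice order is not monotone in position")

    def __len__(self) -> int:
        return len(self.slices)

    def as_array(self) -> np.ndarray:
        return np.stack(self.slices, axis=0)


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def _normal_axis(ds: Dataset) -> np.ndarray | None:
    iop = getattr(ds, "ImageOrientationPatient", None)
    if iop is None:
        return None
    iop = np.asarray([float(v) for v in iop])
    return np.cross(iop[:3], iop[3:])


def _orientation_label(ds: Dataset) -> Orientation:
    normal = _normal_axis(ds)
    if normal is None:
        logger.warning("ImageOrientationPatient absent; assuming axial orientation")
        return "axial"
    # Axial slices stack along z (patient head-foot); coronal along y.
    axis = int(np.argmax(np.abs(normal)))
    return "axial" if axis == 2 else "coronal"


def read_series(directory_path: str | Path) -> SliceStack:
    """Read a directory of DICOM files into a :class:`SliceStack`.

    Slices are sorted by the projection of ImagePositionPatient onto the
    slice normal, falling back to InstanceNumber when positions are absent.
    RescaleSlope/Intercept, if present, are applied so intensities are on
    the stored-value scale the annotators saw.

    Raises
    ------
    SeriesReadError
        On an empty directory, files from more than one series, or a
        missing PixelSpacing / SliceThickness tag.
    """
    directory_path = Path(directory_path)
    files = sorted(p for p in directory_path.glob("*.dcm"))
    if not files:
        files = sorted(p for p in directory_path.iterdir() if p.is_file())
    if not files:
        raise SeriesReadError(f"no DICOM files found in {directory_path}")

    datasets = [pydicom.dcmread(str(p)) for p in files]

    series_uids = {str(getattr(ds, "SeriesInstanceUID", "")) for ds in datasets}
    if len(series_uids) > 1:
        raise SeriesReadError(
            f"directory mixes {len(series_uids)} series: {sorted(series_uids)}"
        )

    first = datasets[0]
    for tag in ("PixelSpacing", "SliceThickness"):
        if getattr(first, tag, None) is None:
            raise SeriesReadError(f"required DICOM tag {tag} is missing")

    normal = _normal_axis(first)
    keyed = []
    for ds in datasets:
        ipp = getattr(ds, "ImagePositionPatient", None)
        if ipp is not None and normal is not None:
            key = float(np.dot(normal, [float(v) for v in ipp]))
            keyed.append((0, key, ds))
        else:
            keyed.append((1, float(getattr(ds, "InstanceNumber", 0)), ds))
    if any(k[0] == 1 for k in keyed):
        logger.info("sorting slices by InstanceNumber (position tags incomplete)")
        keyed = [(1, float(getattr(ds, "InstanceNumber", i)), ds) for i, (_, _, ds) in enumerate(keyed)]
    keyed.sort(key=lambda t: (t[0], t[1]))
    datasets = [t[2] for t in keyed]
    positions = [t[1] for t in keyed] if all(t[0] == 0 for t in keyed) else None

    ps = [float(v) for v in first.PixelSpacing]
    sbs = getattr(first, "SpacingBetweenSlices", None)
    if sbs is None:
        logger.info("SpacingBetweenSlices absent; recorded as absent (not defaulted)")
    geometry = SeriesGeometry(
        pixel_spacing_row=ps[0],
        pixel_spacing_col=ps[1],
        slice_thickness=float(first.SliceThickness),
        spacing_between_slices=float(sbs) if sbs is not None else None,
        n_rows=int(first.Rows),
        n_cols=int(first.Columns),
        orientation=_orientation_label(first),
    )

    slices = []
    for ds in datasets:
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        if slope != 1.0 or intercept != 0.0:
            arr = arr * slope + intercept
        slices.append(arr)

    subject = str(getattr(first, "PatientID", "")) or directory_path.name
    return SliceStack(slices=slices, geometry=geometry, subject_id=subject,
                      slice_positions=positions)


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def write_series(stack: SliceStack, directory_path: str | Path) -> list[Path]:
    """Write *stack* as one DICOM file per slice; returns the file manifest.

    ``read_series(write_series(stack))`` is the identity on geometry and on
    pixel data (stored as unsigned 16-bit).
    """
    if len(stack) == 0:
        raise ValueError("cannot write an empty stack")
    directory_path = Path(directory_path)
    directory_path.mkdir(parents=True, exist_ok=True)

    geom = stack.geometry
    series_uid = generate_uid(entropy_srcs=[stack.subject_id or str(uuid.uuid4())])
    study_uid = generate_uid(entropy_srcs=[(stack.subject_id or "study") + "/study"])
    cosines = _ORIENT_COSINES[geom.orientation]
    normal = np.cross(cosines[:3], cosines[3:])
    step = geom.spacing_between_slices or geom.slice_thickness

    manifest: list[Path] = []
    for i, sl in enumerate(stack.slices):
        arr = np.asarray(sl)
        if arr.min() < 0 or arr.max() > 65535:
            raise ValueError("pixel intensities must fit unsigned 16-bit storage")

        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = pydicom.uid.MRImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian

        ds = Dataset()
        ds.file_meta = meta
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.Modality = "MR"
        ds.PatientID = stack.subject_id or "anon"
        ds.PatientName = stack.subject_id or "anon"
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.InstanceNumber = i + 1
        ds.Rows = geom.n_rows
        ds.Columns = geom.n_cols
        ds.PixelSpacing = [geom.pixel_spacing_row, geom.pixel_spacing_col]
        ds.SliceThickness = geom.slice_thickness
        if geom.spacing_between_slices is not None:
            ds.SpacingBetweenSlices = geom.spacing_between_slices
        ds.ImageOrientationPatient = list(cosines)
        if stack.slice_positions is not None:
            pos_along = stack.slice_positions[i]
        else:
            pos_along = i * step
        ds.ImagePositionPatient = [float(v) for v in normal * pos_along]
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.PixelData = np.rint(arr).astype(np.uint16).tobytes()

        path = directory_path / f"slice_{i:04d}.dcm"
        pydicom.dcmwrite(str(path), ds, enforce_file_format=True)
        manifest.append(path)
    return manifest


# ---------------------------------------------------------------------------
# Model-grid resampling
# ---------------------------------------------------------------------------

def prepare_for_model(slice_2d: np.ndarray, size: int = 256) -> np.ndarray:
    """Resample one slice to ``size``x``size`` and scale intensities to [0, 1].

    Resampling is bilinear; non-square inputs are resized anisotropically
    (no letterboxing), so the inverse map back to the native grid is the
    plain inverse resize applied by :func:`restore_to_grid`.  Intensities
    are divided by 255 and clipped to [0, 1].
    """
    arr = np.asarray(slice_2d, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D slice, got ndim={arr.ndim}")
    if arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError("slice dimensions must be positive")
    if arr.shape != (size, size):
        arr = resize(arr, (size, size), order=1, mode="edge",
                     anti_aliasing=False, preserve_range=True)
    return np.clip(arr / 255.0, 0.0, 1.0)


def restore_to_grid(mask: np.ndarray, geometry: SeriesGeometry) -> np.ndarray:
    """Map a binary model-grid mask back to the native (n_rows, n_cols) grid.

    Nearest-neighbour resampling; output is uint8 over {0, 1}.
    """
    arr = np.asarray(mask)
    uniq = np.unique(arr)
    if not np.all(np.isin(uniq, (0, 1))):
        raise ValueError("restore_to_grid expects a binary mask")
    target = (geometry.n_rows, geometry.n_cols)
    if arr.shape == target:
        return arr.astype(np.uint8)
    out = resize(arr.astype(np.float64), target, order=0, mode="edge",
                 anti_aliasing=False, preserve_range=True)
    return (out > 0.5).astype(np.uint8)


def resample_probabilities(prob: np.ndarray, geometry: SeriesGeometry) -> np.ndarray:
    """Bilinearly resample a model-grid probability map to the native grid."""
    target = (geometry.n_rows, geometry.n_cols)
    arr = np.asarray(prob, dtype=np.float64)
    if arr.shape == target:
        return arr
    out = resize(arr, target, order=1, mode="edge",
                 anti_aliasing=False, preserve_range=True)
    return np.clip(out, 0.0, 1.0)
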