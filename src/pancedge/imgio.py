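"""Grayscale image and ROI handling.

Coordinate conventions used throughout the package:

* pixels are addressed ``(row, col)``, 0-based, with pixel centers at integer
  coordinates;
* ROI boxes are half-open: a box covers rows ``[top, top + height)`` and
  columns ``[left, left + width)``;
* all geometry is expressed in pixels; physical spacing (mm/px) is carried
  along when the source format provides it (DICOM ``PixelSpacing``) and is
  used for optional millimeter reporting only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import pydicom
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, generate_uid

from .errors import ImageIOError, ROIError

__all__ = [
    "GrayImage",
    "ROIBox",
    "ManifestEntry",
    "load_image",
    "save_image",
    "crop",
    "load_manifest",
]

_DICOM_SUFFIXES = {".dcm", ".dicom"}
_RASTER_SUFFIXES = {".png", ".tif", ".tiff"}


@dataclass(frozen=True)
class GrayImage:
    """A 2D grayscale image with optional physical pixel spacing.

    Parameters
    ----------
    pixels
        2D float array of finite intensities, indexed ``(row, col)``.
    spacing
        Optional ``(row_mm, col_mm)`` physical pixel size.
    """

    pixels: np.ndarray
    spacing: tuple[float, float] | None = None

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.shape[0] < 2 or px.shape[1] < 2:
            raise ImageIOError(f"image must be at least 2x2, got shape {px.shape}")
        if not np.all(np.isfinite(px)):
            raise ImageIOError("image contains non-finite intensities")
        object.__setattr__(self, "pixels", px)
        if self.spacing is not None:
            sp = (float(self.spacing[0]), float(self.spacing[1]))
            if sp[0] <= 0 or sp[1] <= 0:
                raise ImageIOError(f"pixel spacing must be positive, got {sp}")
            object.__setattr__(self, "spacing", sp)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class ROIBox:
    """Half-open rectangular region of interest.

    ``label`` is free-form; the scoring pipeline uses ``"tumor"`` and
    ``"healthy"`` for the two constant-size boxes of the paired design.
    """

    top: int
    left: int
    height: int
    width: int
    label: str = ""

    def __post_init__(self):
        if self.height < 8 or self.width < 8:
            raise ROIError(
                f"ROI must be at least 8x8 px, got {self.height}x{self.width}"
            )

    @property
    def bottom(self) -> int:
        """One past the last included row."""
        return self.top + self.height

    @property
    def right(self) -> int:
        """One past the last included column."""
        return self.left + self.width

    def validate_within(self, shape: tuple[int, int]) -> None:
        rows, cols = shape
        if self.top < 0:
            raise ROIError(f"ROI exceeds the top edge (top={self.top})")
        if self.left < 0:
            raise ROIError(f"ROI exceeds the left edge (left={self.left})")
        if self.bottom > rows:
            raise ROIError(
                f"ROI exceeds the bottom edge (rows {self.bottom} > {rows})"
            )
        if self.right > cols:
            raise ROIError(
                f"ROI exceeds the right edge (cols {self.right} > {cols})"
            )

    @classmethod
    def from_string(cls, text: str, label: str = "") -> "ROIBox":
        """Parse the flat ``"top,left,height,width"`` config syntax."""
        parts = [p.strip() for p in text.split(",")]
        if len(parts) != 4:
            raise ROIError(f"ROI spec must be 'top,left,height,width', got {text!r}")
        try:
            top, left, height, width = (int(p) for p in parts)
        except ValueError as exc:
            raise ROIError(f"non-integer ROI spec {text!r}") from exc
        return cls(top=top, left=left, height=height, width=width, label=label)

    def to_string(self) -> str:
        return f"{self.top},{self.left},{self.height},{self.width}"


@dataclass
class ManifestEntry:
    """One row of a batch manifest: a patient's image and its two boxes."""

    patient_id: str
    image_path: Path
    roi_tumor: ROIBox
    roi_healthy: ROIBox
    extras: dict = field(default_factory=dict)


def load_image(path) -> GrayImage:
    """Read a single-frame DICOM, PNG, or TIFF as a :class:`GrayImage`.

    DICOM stored values are converted with the standard rescale
    (``slope * stored + intercept``) and ``PixelSpacing`` is captured when
    present. PNG/TIFF images carry no spacing. Color images are rejected:
    CT data is single-channel, and a silent luminance conversion would hide
    upstream mistakes.
    """
    path = Path(path)
    if not path.exists():
        raise ImageIOError(f"image file not found: {path}")
    suffix = path.suffix.lower()
    if suffix in _DICOM_SUFFIXES:
        return _load_dicom(path)
    if suffix in _RASTER_SUFFIXES:
        return _load_raster(path)
    raise ImageIOError(
        f"unsupported image format {suffix!r} for {path} "
        "(expected .dcm/.dicom, .png, .tif or .tiff)"
    )


def _load_dicom(path: Path) -> GrayImage:
    try:
        ds = pydicom.dcmread(path)
    except Exception as exc:  # pydicom raises several types
        raise ImageIOError(f"unreadable DICOM file {path}: {exc}") from exc
    n_frames = int(getattr(ds, "NumberOfFrames", 1) or 1)
    if n_frames != 1:
        raise ImageIOError(
            f"multi-frame DICOM not supported ({path} has {n_frames} frames)"
        )
    if int(getattr(ds, "SamplesPerPixel", 1)) != 1:
        raise ImageIOError(f"color DICOM not supported: {path}")
    arr = ds.pixel_array.astype(float)
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    arr = arr * slope + intercept
    spacing = None
    if getattr(ds, "PixelSpacing", None) is not None:
        spacing = (float(ds.PixelSpacing[0]), float(ds.PixelSpacing[1]))
    return GrayImage(pixels=arr, spacing=spacing)


def _load_raster(path: Path) -> GrayImage:
    try:
        arr = iio.imread(path)
    except Exception as exc:
        raise ImageIOError(f"unreadable image file {path}: {exc}") from exc
    if arr.ndim == 3:
        raise ImageIOError(
            f"color image not supported ({path} has {arr.shape[-1]} channels); "
            "provide a single-channel grayscale image"
        )
    return GrayImage(pixels=arr.astype(float), spacing=None)


def save_image(image: GrayImage, path) -> Path:
    """Write a :class:`GrayImage` as 16-bit PNG/TIFF or single-frame DICOM.

    Intensities are rounded and clipped to the unsigned 16-bit range, so
    integer-valued images within range round-trip exactly.
    """
    path = Path(path)
    stored = np.clip(np.rint(image.pixels), 0, 65535).astype(np.uint16)
    suffix = path.suffix.lower()
    if suffix in _RASTER_SUFFIXES:
        iio.imwrite(path, stored)
        return path
    if suffix in _DICOM_SUFFIXES:
        _save_dicom(stored, image.spacing, path)
        return path
    raise ImageIOError(f"unsupported output format {suffix!r} for {path}")


def _save_dicom(stored: np.ndarray, spacing, path: Path) -> None:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    # UID derived from the pixel payload: equal images yield equal files.
    uid = generate_uid(entropy_srcs=[stored.tobytes().hex()])
    meta.MediaStorageSOPInstanceUID = uid
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = SecondaryCaptureImageStorage
    ds.SOPInstanceUID = uid
    ds.Modality = "OT"
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.Rows, ds.Columns = stored.shape
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.RescaleSlope = 1.0
    ds.RescaleIntercept = 0.0
    if spacing is not None:
        ds.PixelSpacing = [spacing[0], spacing[1]]
    ds.PixelData = stored.astype("<u2").tobytes()
    ds.save_as(path, enforce_file_format=True)


def crop(image: GrayImage, roi: ROIBox) -> GrayImage:
    """Extract an ROI; pixel ``(r, c)`` of the crop is source ``(top+r, left+c)``."""
    roi.validate_within(image.shape)
    sub = image.pixels[roi.top : roi.bottom, roi.left : roi.right]
    return GrayImage(pixels=sub.copy(), spacing=image.spacing)


_MANIFEST_COLUMNS = ("patient_id", "image_path", "roi_tumor", "roi_healthy")


def load_manifest(path) -> list[ManifestEntry]:
    """Read and validate a batch manifest CSV.

    Required columns: ``patient_id, image_path, roi_tumor, roi_healthy`` with
    ROIs as ``"top,left,height,width"``; additional columns (ground-truth
    roughness, seeds, ...) are carried through in ``extras``. Relative image
    paths resolve against the manifest's directory. All boxes in one manifest
    must share a single (height, width): the paired study design keeps the
    sampling boxes constant in size across images and patients.
    """
    path = Path(path)
    if not path.exists():
        raise ImageIOError(f"manifest not found: {path}")
    try:
        table = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise ImageIOError(f"manifest {path} is empty") from exc
    if table.empty:
        raise ImageIOError(f"manifest {path} has no data rows")
    missing = [c for c in _MANIFEST_COLUMNS if c not in table.columns]
    if missing:
        raise ImageIOError(f"manifest {path} lacks columns {missing}")

    entries: list[ManifestEntry] = []
    box_shape: tuple[int, int] | None = None
    for idx, row in table.iterrows():
        rownum = idx + 2  # header is line 1
        img_path = Path(str(row["image_path"]))
        if not img_path.is_absolute():
            img_path = path.parent / img_path
        if not img_path.exists():
            raise ImageIOError(f"manifest row {rownum}: image not found: {img_path}")
        roi_tumor = ROIBox.from_string(str(row["roi_tumor"]), label="tumor")
        roi_healthy = ROIBox.from_string(str(row["roi_healthy"]), label="healthy")
        for roi in (roi_tumor, roi_healthy):
            shape = (roi.height, roi.width)
            if box_shape is None:
                box_shape = shape
            elif shape != box_shape:
                raise ImageIOError(
                    f"manifest row {rownum}: box {shape} differs from {box_shape}; "
                    "sampling boxes must be kept constant in size across the study"
                )
        image = load_image(img_path)
        for roi in (roi_tumor, roi_healthy):
            try:
                roi.validate_within(image.shape)
            except ROIError as exc:
                raise ImageIOError(f"manifest row {rownum}: {exc}") from exc
        extras = {
            k: row[k]
            for k in table.columns
            if k not in _MANIFEST_COLUMNS and pd.notna(row[k])
        }
        entries.append(
            ManifestEntry(
                patient_id=str(row["patient_id"]),
                image_path=img_path,
                roi_tumor=roi_tumor,
                roi_healthy=roi_healthy,
                extras=extras,
            )
        )
    return entries


def shifted(roi: ROIBox, d_top: int, d_left: int) -> ROIBox:
    """Return a copy of ``roi`` translated by ``(d_top, d_left)``."""
    return replace(roi, top=roi.top + d_top, left=roi.left + d_left)
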