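"""Volume and structure-set I/O and the grid/coordinate model.

All geometry lives in patient millimetre coordinates using the DICOM
patient convention (LPS): +x = patient left, +y = patient posterior,
+z = superior.  Voxel indices are 0-based and the volume origin is the
centre of voxel (0, 0, 0) — the DICOM ImagePositionPatient convention —
so RTSTRUCT contour points can be compared with voxel positions without
any half-voxel bookkeeping.

Supported formats: DICOM CT series (one file per axial slice), NIfTI-1
(.nii / .nii.gz), DICOM RTSTRUCT planar contours and DICOM RTDOSE grids.
Only axial, axis-aligned acquisitions are accepted; oblique direction
matrices are rejected rather than silently resampled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileDataset, FileMetaDataset
from pydicom.uid import (
    CTImageStorage,
    ExplicitVRLittleEndian,
    RTDoseStorage,
    RTStructureSetStorage,
    generate_uid,
)
from shapely.geometry import Polygon as _ShapelyPolygon

__all__ = [
    "ImageVolume",
    "Contour",
    "StructureSet",
    "load_ct_series",
    "write_ct_series",
    "convert_to_nifti",
    "load_nifti",
    "read_structure_set",
    "write_structure_set",
    "read_dose_grid",
    "write_dose_grid",
]

_AXIAL_ORIENTATION = np.array([1.0, 0.0, 0.0, 0.0, 1.0, 0.0])


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ImageVolume:
    """A 3D scalar grid (HU for CT, Gy for dose) in patient mm coordinates.

    Parameters
    ----------
    voxels : ndarray, shape (nz, ny, nx)
        Scalar values, slice-major (axial slices stacked along axis 0).
    spacing : tuple of float
        Voxel pitch ``(dx, dy, dz)`` in mm; strictly positive.
    origin : tuple of float
        Patient-mm position ``(x0, y0, z0)`` of the centre of voxel
        index ``(i=0, j=0, k=0)``.
    axes : ndarray, shape (3, 3)
        Direction matrix; only the identity (axial) is supported.
    frame : str
        Label identifying the frame of reference this volume defines.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axes: np.ndarray = field(default_factory=lambda: np.eye(3))
    frame: str = "unnamed"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"voxels must be 3D, got shape {self.voxels.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)
        self.axes = np.asarray(self.axes, dtype=float)
        if not np.allclose(self.axes, np.eye(3), atol=1e-6):
            raise ValueError(
                "non-axial direction matrix: only identity orientation is "
                "supported (oblique acquisitions are rejected, not resampled)"
            )

    # -- geometry -----------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        """Array shape ``(nz, ny, nx)``."""
        return self.voxels.shape

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    def index_to_mm(self, index: np.ndarray) -> np.ndarray:
        """Map voxel indices ``(i, j, k)`` (x, y, z order) to patient mm."""
        index = np.asarray(index, dtype=float)
        return index * np.asarray(self.spacing) + np.asarray(self.origin)

    def mm_to_index(self, point: np.ndarray) -> np.ndarray:
        """Map patient-mm points to continuous voxel indices ``(i, j, k)``."""
        point = np.asarray(point, dtype=float)
        return (point - np.asarray(self.origin)) / np.asarray(self.spacing)

    @property
    def z_planes(self) -> np.ndarray:
        """Patient-mm z coordinate of every slice plane."""
        return self.origin[2] + self.spacing[2] * np.arange(self.n_slices)

    def extent_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """Bounding box (lo, hi) of voxel centres in mm, (x, y, z) order."""
        nz, ny, nx = self.shape
        lo = np.asarray(self.origin)
        hi = lo + np.asarray(self.spacing) * (np.array([nx, ny, nz]) - 1)
        return lo, hi


@dataclass
class Contour:
    """One closed planar polygon at a fixed z.

    The polygon is stored without repeating the first vertex; closure is
    implicit.  ``is_open`` flags polylines read from RTSTRUCT that were
    not declared closed — they are kept as-is, never silently closed.
    """

    z: float
    points: np.ndarray  # (n, 2) x,y in mm
    is_open: bool = False

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("contour points must have shape (n, 2)")

    @property
    def area(self) -> float:
        """Unsigned shoelace area in mm^2."""
        x, y = self.points[:, 0], self.points[:, 1]
        return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))

    def is_simple(self) -> bool:
        return _ShapelyPolygon(self.points).is_valid


@dataclass
class StructureSet:
    """A named organ as a z-ordered list of closed planar contours."""

    name: str
    contours: list[Contour]
    frame: str = "unnamed"

    def __post_init__(self) -> None:
        for c in self.contours:
            if len(c.points) < 3:
                raise ValueError(
                    f"contour at z={c.z} has {len(c.points)} vertices; need >= 3"
                )
            if c.area <= 0:
                raise ValueError(f"contour at z={c.z} has zero area")
        self.contours = sorted(self.contours, key=lambda c: (c.z,))

    @property
    def z_values(self) -> np.ndarray:
        return np.array([c.z for c in self.contours])

    def slices(self) -> dict[float, list[Contour]]:
        """Contours grouped by z (several polygons may share one plane)."""
        out: dict[float, list[Contour]] = {}
        for c in self.contours:
            out.setdefault(c.z, []).append(c)
        return out


# ---------------------------------------------------------------------------
# DICOM CT series
# ---------------------------------------------------------------------------

def load_ct_series(directory: str | Path) -> ImageVolume:
    """Read an axial DICOM CT series (one file per slice) into HU.

    Slices are sorted by their z position regardless of file order, the
    rescale slope/intercept is applied, and the z sampling is checked
    for uniformity (a missing slice shows up as a doubled gap).
    """
    directory = Path(directory)
    datasets = []
    for path in sorted(directory.iterdir()):
        if not path.is_file():
            continue
        try:
            ds = pydicom.dcmread(path)
        except Exception:
            continue
        if getattr(ds, "Modality", None) == "CT":
            datasets.append(ds)
    if len(datasets) < 2:
        raise ValueError(f"fewer than 2 slices: found {len(datasets)} CT slices in {directory}")

    series_uids = {ds.SeriesInstanceUID for ds in datasets}
    if len(series_uids) > 1:
        raise ValueError(f"mixed series: {len(series_uids)} SeriesInstanceUIDs in {directory}")
    for ds in datasets:
        orient = np.asarray(ds.ImageOrientationPatient, dtype=float)
        if not np.allclose(orient, _AXIAL_ORIENTATION, atol=1e-4):
            raise ValueError(f"non-axial orientation {orient.tolist()} is not supported")

    datasets.sort(key=lambda ds: float(ds.ImagePositionPatient[2]))
    zs = np.array([float(ds.ImagePositionPatient[2]) for ds in datasets])
    gaps = np.diff(zs)
    if np.any(gaps <= 0):
        raise ValueError("duplicate or non-increasing slice positions")
    if np.ptp(gaps) > 0.01 * gaps.mean():
        raise ValueError(
            f"missing slices: non-uniform z gaps (min {gaps.min():.3f}, max {gaps.max():.3f} mm)"
        )

    ref = datasets[0]
    dy, dx = (float(v) for v in ref.PixelSpacing)  # row spacing, column spacing
    dz = float(gaps.mean())
    slices = []
    for ds in datasets:
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        arr = ds.pixel_array.astype(np.float64) * slope + intercept
        slices.append(arr)
    voxels = np.stack(slices, axis=0)
    if np.allclose(voxels, np.round(voxels)):
        voxels = voxels.astype(np.int16)
    origin = tuple(float(v) for v in ref.ImagePositionPatient)
    return ImageVolume(voxels, (dx, dy, dz), origin, frame=str(ref.FrameOfReferenceUID))


def _base_file_meta(sop_class_uid, sop_instance_uid) -> FileMetaDataset:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = sop_class_uid
    meta.MediaStorageSOPInstanceUID = sop_instance_uid
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    return meta


def write_ct_series(volume: ImageVolume, directory: str | Path) -> list[Path]:
    """Write a volume as a minimal axial DICOM CT series (int16 HU)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    import re

    series_uid = generate_uid()
    study_uid = generate_uid()
    # reuse the frame label as FrameOfReferenceUID only when it is one
    if re.fullmatch(r"[0-9.]+", volume.frame or ""):
        frame_uid = volume.frame
    else:
        frame_uid = generate_uid()
    nz, ny, nx = volume.shape
    data = np.round(volume.voxels).astype(np.int16)
    paths = []
    for k in range(nz):
        sop_uid = generate_uid()
        ds = FileDataset(None, Dataset(), file_meta=_base_file_meta(CTImageStorage, sop_uid))
        ds.SOPClassUID = CTImageStorage
        ds.SOPInstanceUID = sop_uid
        ds.Modality = "CT"
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.FrameOfReferenceUID = frame_uid
        ds.PatientName = "PHANTOM"
        ds.PatientID = "PHANTOM"
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.ImagePositionPatient = [
            volume.origin[0],
            volume.origin[1],
            volume.origin[2] + k * volume.spacing[2],
        ]
        ds.PixelSpacing = [volume.spacing[1], volume.spacing[0]]  # row, column
        ds.SliceThickness = volume.spacing[2]
        ds.InstanceNumber = k + 1
        ds.Rows, ds.Columns = ny, nx
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1  # signed
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.RescaleSlope = 1
        ds.RescaleIntercept = 0
        ds.PixelData = data[k].tobytes()
        path = directory / f"ct_{k:04d}.dcm"
        ds.save_as(path, enforce_file_format=True)
        paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# NIfTI
# ---------------------------------------------------------------------------

def convert_to_nifti(volume: ImageVolume, path: str | Path) -> Path:
    """Write a volume to NIfTI-1.

    The array is stored (x, y, z)-major with an RAS affine; since the
    in-memory convention is LPS, the x and y axes carry negative steps.
    """
    path = Path(path)
    dx, dy, dz = volume.spacing
    x0, y0, z0 = volume.origin
    affine = np.array(
        [
            [-dx, 0, 0, -x0],
            [0, -dy, 0, -y0],
            [0, 0, dz, z0],
            [0, 0, 0, 1.0],
        ]
    )
    data = np.transpose(volume.voxels, (2, 1, 0))  # (nx, ny, nz)
    img = nib.Nifti1Image(data, affine)
    img.header.set_xyzt_units("mm")
    nib.save(img, str(path))
    return path


def load_nifti(path: str | Path, frame: str = "unnamed") -> ImageVolume:
    """Read a NIfTI-1 volume back into the LPS voxel-centre convention."""
    img = nib.load(str(path))
    affine = img.affine
    rot = affine[:3, :3]
    if np.count_nonzero(np.abs(rot) > 1e-6 * np.abs(rot).max()) > 3:
        raise ValueError("oblique NIfTI affine is not supported")
    img = nib.as_closest_canonical(img)  # RAS, positive diagonal
    affine = img.affine
    data = np.asarray(img.dataobj)
    steps = np.diag(affine)[:3]
    trans = affine[:3, 3]
    nx, ny, nz = data.shape
    # RAS -> LPS: negate x and y, flipping those axes so spacing stays positive.
    data = data[::-1, ::-1, :]
    x0 = -(trans[0] + (nx - 1) * steps[0])
    y0 = -(trans[1] + (ny - 1) * steps[1])
    z0 = trans[2]
    voxels = np.ascontiguousarray(np.transpose(data, (2, 1, 0)))
    return ImageVolume(
        voxels,
        (float(steps[0]), float(steps[1]), float(steps[2])),
        (float(x0), float(y0), float(z0)),
        frame=frame,
    )


# ---------------------------------------------------------------------------
# RTSTRUCT
# ---------------------------------------------------------------------------

def write_structure_set(ss: StructureSet, path: str | Path, frame_uid: str | None = None) -> Path:
    """Write a structure set as a minimal DICOM RTSTRUCT."""
    path = Path(path)
    sop_uid = generate_uid()
    ds = FileDataset(None, Dataset(), file_meta=_base_file_meta(RTStructureSetStorage, sop_uid))
    ds.SOPClassUID = RTStructureSetStorage
    ds.SOPInstanceUID = sop_uid
    ds.Modality = "RTSTRUCT"
    ds.StructureSetLabel = ss.name
    ds.PatientName = "PHANTOM"
    ds.PatientID = "PHANTOM"
    frame_uid = frame_uid or generate_uid()

    roi = Dataset()
    roi.ROINumber = 1
    roi.ROIName = ss.name
    roi.ReferencedFrameOfReferenceUID = frame_uid
    roi.ROIGenerationAlgorithm = "AUTOMATIC"
    ds.StructureSetROISequence = [roi]

    contour_items = []
    for c in ss.contours:
        item = Dataset()
        item.ContourGeometricType = "OPEN_PLANAR" if c.is_open else "CLOSED_PLANAR"
        item.NumberOfContourPoints = len(c.points)
        flat = np.column_stack([c.points, np.full(len(c.points), c.z)]).ravel()
        item.ContourData = [f"{v:.6f}" for v in flat]
        contour_items.append(item)
    roi_contour = Dataset()
    roi_contour.ReferencedROINumber = 1
    roi_contour.ContourSequence = contour_items
    ds.ROIContourSequence = [roi_contour]
    ds.save_as(path, enforce_file_format=True)
    return path


def read_structure_set(path: str | Path, frame: ImageVolume | str | None = None) -> StructureSet:
    """Read the first ROI of a DICOM RTSTRUCT into patient-mm contours.

    Open polylines are kept with ``is_open=True`` and a warning; they are
    never silently closed.
    """
    ds = pydicom.dcmread(str(path))
    if not getattr(ds, "StructureSetROISequence", None):
        raise ValueError("no contours: RTSTRUCT has no ROIs")
    name = str(ds.StructureSetROISequence[0].ROIName)
    if not getattr(ds, "ROIContourSequence", None):
        raise ValueError("no contours: RTSTRUCT has no ROIContourSequence")
    roi_contour = ds.ROIContourSequence[0]
    seq = getattr(roi_contour, "ContourSequence", None)
    if not seq:
        raise ValueError(f"no contours: ROI '{name}' is empty")

    contours = []
    for item in seq:
        pts = np.asarray([float(v) for v in item.ContourData]).reshape(-1, 3)
        zs = pts[:, 2]
        if np.ptp(zs) > 1e-3:
            raise ValueError("non-planar contour (z varies within one polygon)")
        is_open = str(getattr(item, "ContourGeometricType", "CLOSED_PLANAR")).startswith("OPEN")
        if is_open:
            warnings.warn("open polyline in RTSTRUCT kept as-is (not closed)", stacklevel=2)
        contours.append(Contour(float(zs.mean()), pts[:, :2], is_open=is_open))
    if not contours:
        raise ValueError(f"no contours: ROI '{name}' is empty")
    frame_label = "unnamed"
    if isinstance(frame, ImageVolume):
        frame_label = frame.frame
    elif isinstance(frame, str):
        frame_label = frame
    return StructureSet(name, contours, frame=frame_label)


# ---------------------------------------------------------------------------
# RTDOSE
# ---------------------------------------------------------------------------

def write_dose_grid(volume: ImageVolume, path: str | Path) -> Path:
    """Write a dose volume (Gy) as a minimal multi-frame DICOM RTDOSE."""
    path = Path(path)
    sop_uid = generate_uid()
    ds = FileDataset(None, Dataset(), file_meta=_base_file_meta(RTDoseStorage, sop_uid))
    ds.SOPClassUID = RTDoseStorage
    ds.SOPInstanceUID = sop_uid
    ds.Modality = "RTDOSE"
    ds.PatientName = "PHANTOM"
    ds.PatientID = "PHANTOM"
    ds.DoseUnits = "GY"
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = "FRACTION"
    nz, ny, nx = volume.shape
    scale = max(float(volume.voxels.max()), 1e-6) / (2**31 - 1)
    ds.DoseGridScaling = scale
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.ImagePositionPatient = list(volume.origin)
    ds.PixelSpacing = [volume.spacing[1], volume.spacing[0]]
    ds.GridFrameOffsetVector = [k * volume.spacing[2] for k in range(nz)]
    ds.NumberOfFrames = nz
    ds.Rows, ds.Columns = ny, nx
    ds.BitsAllocated = 32
    ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.PixelData = np.round(volume.voxels / scale).astype(np.uint32).tobytes()
    ds.save_as(path, enforce_file_format=True)
    return path


def read_dose_grid(path: str | Path, frame: str = "unnamed") -> ImageVolume:
    """Read a DICOM RTDOSE grid into an ImageVolume in Gy."""
    ds = pydicom.dcmread(str(path))
    if getattr(ds, "Modality", None) != "RTDOSE":
        raise ValueError("not an RTDOSE file")
    scale = float(getattr(ds, "DoseGridScaling", 1.0))
    voxels = ds.pixel_array.astype(np.float64) * scale
    dy, dx = (float(v) for v in ds.PixelSpacing)
    offsets = np.asarray([float(v) for v in ds.GridFrameOffsetVector])
    gaps = np.diff(offsets)
    if np.ptp(gaps) > 1e-3:
        raise ValueError("non-uniform RTDOSE frame offsets")
    dz = float(gaps.mean())
    origin = tuple(float(v) for v in ds.ImagePositionPatient)
    return ImageVolume(voxels, (dx, dy, dz), origin, frame=frame)
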