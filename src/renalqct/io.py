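"""Reading/writing CT volumes, ROI sets, and the cohort table.

Volumes are held as HU-valued arrays indexed ``(slice, row, col)`` =
(axial z, y, x) with per-axis spacing in mm.  Voxel indices are 0-based and
the physical coordinate of voxel ``i`` along an axis is ``i * spacing`` (mm
at voxel centres).

ROIs are planar polygons (vertices in mm, in-plane) or boolean masks tied to
one slice of one plane.  Rasterization rule: a voxel belongs to a polygon
iff its **centre** is inside under the even-odd rule, so small hand counts
can replicate the tool's output exactly.

The cohort table is a plain CSV, one row per kidney, with the fixed header
in :data:`COHORT_COLUMNS`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CTVolume",
    "ROI",
    "ROISet",
    "COHORT_COLUMNS",
    "read_ct_volume",
    "write_nifti",
    "write_dicom_series",
    "points_in_polygon",
    "polygon_mask",
    "roi_mean_hu",
    "read_roi_set",
    "write_roi_set",
    "read_cohort",
    "write_cohort",
]

PLANES = ("axial", "coronal", "sagittal")


@dataclass
class CTVolume:
    """An HU-calibrated CT volume.

    ``voxels`` is (nz, ny, nx); ``spacing`` is (dz, dy, dx) in mm; the
    rescale slope/intercept have already been applied so values are HU.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    fov_diameter_mm: float
    orientation: str = "axial"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3-D array")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"all spacing entries must be > 0, got {self.spacing}")
        if self.fov_diameter_mm <= 0:
            raise ValueError("fov_diameter_mm must be > 0")

    def plane_slice(self, plane: str, index: int) -> tuple[np.ndarray, tuple[float, float]]:
        """Extract a 2-D slice and its (row, col) spacing for a given plane."""
        dz, dy, dx = self.spacing
        if plane == "axial":
            return self.voxels[index], (dy, dx)
        if plane == "coronal":
            return self.voxels[:, index, :], (dz, dx)
        if plane == "sagittal":
            return self.voxels[:, :, index], (dz, dy)
        raise ValueError(f"unknown plane {plane!r}; expected one of {PLANES}")


@dataclass
class ROI:
    """A planar region of interest on one slice.

    Exactly one of ``vertices_mm`` (polygon, (n, 2) array of in-plane
    (x, y) mm coordinates: x = column * col-spacing, y = row * row-spacing)
    or ``mask`` (boolean raster of the slice shape) is set.
    """

    label: str
    plane: str
    slice_index: int
    vertices_mm: np.ndarray | None = None
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.plane not in PLANES:
            raise ValueError(f"unknown plane {self.plane!r}")
        if (self.vertices_mm is None) == (self.mask is None):
            raise ValueError("exactly one of vertices_mm or mask must be given")
        if self.vertices_mm is not None:
            self.vertices_mm = np.asarray(self.vertices_mm, dtype=float)
            if self.vertices_mm.ndim != 2 or self.vertices_mm.shape[1] != 2:
                raise ValueError("vertices_mm must be (n, 2)")
            if len(self.vertices_mm) < 3:
                raise ValueError("polygon needs at least 3 vertices")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)


@dataclass
class ROISet:
    """A named collection of ROIs with unique labels."""

    rois: list[ROI] = field(default_factory=list)

    def __post_init__(self) -> None:
        labels = [r.label for r in self.rois]
        if len(set(labels)) != len(labels):
            raise ValueError("ROI labels must be unique within a set")

    def __iter__(self):
        return iter(self.rois)

    def __len__(self) -> int:
        return len(self.rois)

    def __getitem__(self, label: str) -> ROI:
        for r in self.rois:
            if r.label == label:
                return r
        raise KeyError(label)


# ---------------------------------------------------------------------------
# volume I/O
# ---------------------------------------------------------------------------


def read_ct_volume(
    path: str | Path,
    format: Literal["dicom-series", "nifti", None] = None,
    fov_diameter_mm: float | None = None,
) -> CTVolume:
    """Read a CT volume from a DICOM series directory or a NIfTI file.

    ``fov_diameter_mm`` overrides the header-derived field of view; for
    NIfTI (which carries no FOV tag) the default is the in-plane extent.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "dicom-series" if path.is_dir() else "nifti"
    if format == "nifti":
        return _read_nifti(path, fov_diameter_mm)
    if format == "dicom-series":
        return _read_dicom_series(path, fov_diameter_mm)
    raise ValueError(f"unknown format {format!r}")


def _read_nifti(path: Path, fov_diameter_mm: float | None) -> CTVolume:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(float)  # (x, y, z)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D NIfTI, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]  # (dx, dy, dz)
    voxels = np.transpose(data, (2, 1, 0))  # -> (z, y, x)
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    if fov_diameter_mm is None:
        fov_diameter_mm = voxels.shape[2] * spacing[2]
    return CTVolume(voxels, spacing, fov_diameter_mm)


def write_nifti(volume: CTVolume, path: str | Path) -> None:
    """Write a volume as NIfTI; voxel values are stored as float32 HU."""
    import nibabel as nib

    data = np.transpose(volume.voxels, (2, 1, 0)).astype(np.float32)
    dz, dy, dx = volume.spacing
    affine = np.diag([dx, dy, dz, 1.0])
    nib.save(nib.Nifti1Image(data, affine), str(path))


def _read_dicom_series(directory: Path, fov_diameter_mm: float | None) -> CTVolume:
    import pydicom

    files = sorted(p for p in directory.iterdir() if p.suffix.lower() == ".dcm")
    if not files:
        raise FileNotFoundError(f"no .dcm files in {directory}")
    datasets = [(p, pydicom.dcmread(str(p))) for p in files]
    series_uid = datasets[0][1].SeriesInstanceUID
    for p, ds in datasets:
        if ds.SeriesInstanceUID != series_uid:
            raise ValueError(
                f"directory mixes DICOM series: {p.name} belongs to "
                f"{ds.SeriesInstanceUID}, expected {series_uid}"
            )
        if "RescaleSlope" not in ds or "RescaleIntercept" not in ds:
            raise ValueError(f"{p.name}: missing HU rescale metadata")
    spacing0 = tuple(float(v) for v in datasets[0][1].PixelSpacing)
    for p, ds in datasets:
        if tuple(float(v) for v in ds.PixelSpacing) != spacing0:
            raise ValueError(f"{p.name}: pixel spacing differs within the series")
    datasets.sort(key=lambda t: float(t[1].ImagePositionPatient[2]))
    slices = []
    for _, ds in datasets:
        raw = ds.pixel_array.astype(float)
        slices.append(raw * float(ds.RescaleSlope) + float(ds.RescaleIntercept))
    voxels = np.stack(slices)
    ds0 = datasets[0][1]
    if len(datasets) > 1:
        z0 = float(datasets[0][1].ImagePositionPatient[2])
        z1 = float(datasets[1][1].ImagePositionPatient[2])
        dz = abs(z1 - z0)
    else:
        dz = float(getattr(ds0, "SliceThickness", 1.0))
    if fov_diameter_mm is None:
        fov_diameter_mm = float(
            getattr(ds0, "ReconstructionDiameter", voxels.shape[2] * spacing0[1])
        )
    return CTVolume(voxels, (dz, spacing0[0], spacing0[1]), fov_diameter_mm)


def write_dicom_series(
    volume: CTVolume,
    directory: str | Path,
    rescale_slope: float = 1.0,
    rescale_intercept: float = -1024.0,
) -> list[Path]:
    """Write a volume as a minimal single-series DICOM CT directory.

    Raw stored values are int16 ``(HU - intercept) / slope``; intended for
    round-trip testing and for exporting synthetic volumes.
    """
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    series_uid = generate_uid()
    study_uid = generate_uid()
    dz, dy, dx = volume.spacing
    paths: list[Path] = []
    for i, sl in enumerate(volume.voxels):
        raw = np.round((sl - rescale_intercept) / rescale_slope).astype(np.int16)
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = CTImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = Dataset()
        ds.file_meta = meta
        ds.SOPClassUID = CTImageStorage
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.Modality = "CT"
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.InstanceNumber = i + 1
        ds.ImagePositionPatient = [0.0, 0.0, float(i * dz)]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.PixelSpacing = [dy, dx]
        ds.SliceThickness = dz
        ds.ReconstructionDiameter = volume.fov_diameter_mm
        ds.RescaleSlope = rescale_slope
        ds.RescaleIntercept = rescale_intercept
        ds.Rows, ds.Columns = raw.shape
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.PixelData = raw.tobytes()
        p = directory / f"slice_{i:04d}.dcm"
        pydicom.dcmwrite(str(p), ds, enforce_file_format=True)
        paths.append(p)
    return paths


# ---------------------------------------------------------------------------
# ROI rasterization and means
# ---------------------------------------------------------------------------


def points_in_polygon(px: np.ndarray, py: np.ndarray, vertices: np.ndarray) -> np.ndarray:
    """Even-odd (ray casting) point-in-polygon test, vectorized over points.

    Points exactly on an edge follow the half-open convention of the
    crossing test; vertex order (CW/CCW) does not matter.
    """
    px = np.asarray(px, dtype=float)
    py = np.asarray(py, dtype=float)
    inside = np.zeros(px.shape, dtype=bool)
    x0, y0 = vertices[-1]
    for x1, y1 in vertices:
        crosses = (y0 > py) != (y1 > py)
        with np.errstate(divide="ignore", invalid="ignore"):
            xint = (x1 - x0) * (py - y0) / (y1 - y0) + x0
        inside ^= crosses & (px < xint)
        x0, y0 = x1, y1
    return inside


def polygon_mask(
    shape: tuple[int, int],
    spacing: tuple[float, float],
    vertices_mm: np.ndarray,
) -> np.ndarray:
    """Rasterize a polygon: pixel centre at (row*dr, col*dc) inside even-odd."""
    nr, nc = shape
    dr, dc = spacing
    cols, rows = np.meshgrid(np.arange(nc), np.arange(nr))
    return points_in_polygon(
        cols.ravel() * dc, rows.ravel() * dr, np.asarray(vertices_mm, float)
    ).reshape(shape)


def roi_mean_hu(volume: CTVolume, rois: ROISet | Iterable[ROI]) -> tuple[dict[str, float], float]:
    """Mean HU per ROI and the unweighted mean across ROIs.

    The per-ROI value is the arithmetic mean of enclosed voxel HU; the
    aggregate (e.g. the kidney-level cortical value from three coronal
    ROIs) is the unweighted mean of the per-ROI means.
    """
    means: dict[str, float] = {}
    for roi in rois:
        sl, spacing2d = volume.plane_slice(roi.plane, roi.slice_index)
        if roi.mask is not None:
            mask = roi.mask
            if mask.shape != sl.shape:
                raise ValueError(f"ROI {roi.label!r}: mask shape {mask.shape} != slice {sl.shape}")
        else:
            mask = polygon_mask(sl.shape, spacing2d, roi.vertices_mm)
        n = int(mask.sum())
        if n == 0:
            raise ValueError(f"ROI {roi.label!r} encloses no voxel centres")
        means[roi.label] = float(sl[mask].mean())
    if not means:
        raise ValueError("no ROIs supplied")
    return means, float(np.mean(list(means.values())))


# ---------------------------------------------------------------------------
# ROI set JSON schema
# ---------------------------------------------------------------------------


def write_roi_set(rois: ROISet, path: str | Path) -> None:
    """Serialize polygon ROIs to JSON: [{label, plane, slice_index, vertices_mm}]."""
    records = []
    for r in rois:
        if r.vertices_mm is None:
            raise ValueError(f"ROI {r.label!r}: only polygon ROIs are JSON-serializable")
        records.append(
            {
                "label": r.label,
                "plane": r.plane,
                "slice_index": int(r.slice_index),
                "vertices_mm": np.asarray(r.vertices_mm).tolist(),
            }
        )
    Path(path).write_text(json.dumps({"rois": records}, indent=2))


def read_roi_set(path: str | Path) -> ROISet:
    payload = json.loads(Path(path).read_text())
    return ROISet(
        [
            ROI(
                label=r["label"],
                plane=r["plane"],
                slice_index=int(r["slice_index"]),
                vertices_mm=np.asarray(r["vertices_mm"], dtype=float),
            )
            for r in payload["rois"]
        ]
    )


# ---------------------------------------------------------------------------
# cohort table
# ---------------------------------------------------------------------------

COHORT_COLUMNS: Sequence[str] = (
    "animal_id",
    "side",
    "group",
    "measured_hu",
    "size_index",
    "corrected_hu",
    "fibrosis_score",
    "blue_fraction",
    "bun",
)

SIDES = ("left", "right", "unknown")


def validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Check the cohort-table invariants; returns the frame unchanged."""
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    bad_side = ~df["side"].isin(SIDES)
    if bad_side.any():
        raise ValueError(f"invalid side values: {sorted(df.loc[bad_side, 'side'].unique())}")
    scores = df["fibrosis_score"].dropna()
    if ((scores < 0) | (scores > 4)).any():
        raise ValueError("fibrosis_score must lie in [0, 4]")
    counts = df.groupby("animal_id").size()
    if (counts > 2).any():
        raise ValueError(
            f"animals with more than 2 kidney rows: {list(counts[counts > 2].index)}"
        )
    return df


def read_cohort(path: str | Path) -> pd.DataFrame:
    return validate_cohort(pd.read_csv(path))


def write_cohort(df: pd.DataFrame, path: str | Path) -> None:
    validate_cohort(df)
    df.loc[:, COHORT_COLUMNS].to_csv(path, index=False)
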