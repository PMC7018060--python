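"""Subject-size indices computed from axial CT slices.

Beam hardening depresses measured CT numbers as the amount of absorbing
material in the scan plane grows, so any HU biomarker must be referenced to
subject size.  Two candidate size indices are provided:

* **TSI** (total signal index): ``(mean FOV HU - air HU) * FOV area / 1e7``,
  a dimensionless surrogate for the total x-ray energy absorbed in the slice.
  Subtracting the scanner's air value (default -1024 HU) makes it
  non-negative; the 1e7 divisor scales a typical small-primate slice into the
  single digits.
* **CSA** (tissue cross-sectional area, mm^2): the area of x-ray-absorbing
  material in the slice, either from a hand-traced ROI or from a simple
  threshold + morphology segmentation.

Per-slice indices from the slices intersecting the organ of interest are
averaged into a single animal-level size index.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage
from skimage.morphology import closing, disk

__all__ = [
    "SliceSignal",
    "SizeIndices",
    "AnimalSizeIndex",
    "fov_mask",
    "slice_signal",
    "compute_tsi",
    "compute_csa",
    "animal_size_index",
]

#: HU of air on the scanner used throughout; some scanners report -1000.
DEFAULT_AIR_HU = -1024.0

#: Denominator that maps (HU-offset x mm^2) totals into a 0-10ish range.
TSI_SCALE = 1.0e7


@dataclass(frozen=True)
class SliceSignal:
    """Summary of one axial slice over the reconstruction circle."""

    mean_fov_hu: float
    fov_area_mm2: float
    air_hu: float = DEFAULT_AIR_HU

    def __post_init__(self) -> None:
        if self.fov_area_mm2 <= 0:
            raise ValueError(f"fov_area_mm2 must be > 0, got {self.fov_area_mm2}")


@dataclass(frozen=True)
class SizeIndices:
    """Both size indices for one slice."""

    tsi: float
    csa: float
    slice_ref: object = None

    def __post_init__(self) -> None:
        if self.tsi < 0 or self.csa < 0:
            raise ValueError("size indices must be non-negative")


@dataclass(frozen=True)
class AnimalSizeIndex:
    """Animal-level size index: mean of the per-slice values."""

    value: float
    n_slices: int
    index_kind: Literal["tsi", "csa"]


def fov_mask(
    shape: tuple[int, int],
    spacing: tuple[float, float],
    fov_diameter_mm: float,
) -> np.ndarray:
    """Boolean mask of the reconstruction circle centred in the matrix.

    A pixel belongs to the field of view iff its *center* lies within the
    circle of diameter ``fov_diameter_mm`` centred on the matrix centre.
    Pixel centres sit at ``index * spacing`` (0-based).
    """
    ny, nx = shape
    dy, dx = spacing
    cy = (ny - 1) / 2.0 * dy
    cx = (nx - 1) / 2.0 * dx
    yy = np.arange(ny)[:, None] * dy - cy
    xx = np.arange(nx)[None, :] * dx - cx
    return yy**2 + xx**2 <= (fov_diameter_mm / 2.0) ** 2


def slice_signal(
    slice_hu: np.ndarray,
    spacing: tuple[float, float],
    fov_diameter_mm: float,
    air_hu: float = DEFAULT_AIR_HU,
) -> SliceSignal:
    """Measure the FOV mean HU and FOV area of a 2-D HU raster.

    Pixels outside the reconstruction circle are excluded from both the
    mean and the area.
    """
    slice_hu = np.asarray(slice_hu, dtype=float)
    if slice_hu.ndim != 2:
        raise ValueError("slice_hu must be 2-D")
    mask = fov_mask(slice_hu.shape, spacing, fov_diameter_mm)
    if not mask.any():
        raise ValueError("FOV circle contains no pixel centres")
    pixel_area = spacing[0] * spacing[1]
    return SliceSignal(
        mean_fov_hu=float(slice_hu[mask].mean()),
        fov_area_mm2=float(mask.sum() * pixel_area),
        air_hu=air_hu,
    )


def compute_tsi(signal: SliceSignal) -> float:
    """Total signal index of one slice.

    ``(mean_fov_hu - air_hu) * fov_area_mm2 / 1e7``; non-negative whenever
    the slice mean is at or above the air value, and exactly 0 for an
    all-air slice.
    """
    return (signal.mean_fov_hu - signal.air_hu) * signal.fov_area_mm2 / TSI_SCALE


def compute_csa(
    slice_hu: np.ndarray,
    spacing: tuple[float, float],
    threshold_hu: float = -400.0,
    closing_radius: int = 2,
    roi_mask: np.ndarray | None = None,
) -> float:
    """Cross-sectional area of absorbing material in a slice, mm^2.

    When ``roi_mask`` is given (a hand-traced tissue outline) its pixel
    count times the pixel area is returned directly.  Otherwise pixels above
    ``threshold_hu`` are taken as material, small gaps are closed with a
    morphological closing of the given radius, and interior holes (air
    pockets surrounded by tissue) are filled — a reproducible stand-in for
    manual tracing.
    """
    slice_hu = np.asarray(slice_hu, dtype=float)
    if slice_hu.ndim != 2:
        raise ValueError("slice_hu must be 2-D")
    pixel_area = spacing[0] * spacing[1]
    if roi_mask is not None:
        roi_mask = np.asarray(roi_mask, dtype=bool)
        if roi_mask.shape != slice_hu.shape:
            raise ValueError("roi_mask shape must match the slice")
        return float(roi_mask.sum() * pixel_area)
    material = slice_hu > threshold_hu
    if closing_radius > 0 and material.any():
        material = closing(material, disk(closing_radius))
        material = ndimage.binary_fill_holes(material)
    return float(material.sum() * pixel_area)


def animal_size_index(
    per_slice: Sequence[SizeIndices] | Sequence[float],
    kind: Literal["tsi", "csa"] = "tsi",
) -> AnimalSizeIndex:
    """Average per-slice indices into the animal-level size index.

    Accepts either :class:`SizeIndices` records or bare floats already of
    the requested kind.
    """
    if len(per_slice) == 0:
        raise ValueError("need at least one slice")
    if kind not in ("tsi", "csa"):
        raise ValueError(f"unknown index kind {kind!r}")
    values = [
        float(getattr(s, kind)) if isinstance(s, SizeIndices) else float(s)
        for s in per_slice
    ]
    return AnimalSizeIndex(
        value=float(np.mean(values)), n_slices=len(values), index_kind=kind
    )
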