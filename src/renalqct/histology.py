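"""Fibrosis ground truth from Masson-trichrome histology.

Trichrome renders collagen blue and other tissue pink/red, so the blue-area
fraction of a cortical ROI is a quantitative fibrosis measure.  Pixels are
classified in Hue/Saturation/Brightness space on the ImageJ-style 0-255
scale; the default window (hue 140-200, saturation >= 60, brightness >= 40)
separates trichrome blue from pink and from empty (white) space and every
bound is configurable, since published threshold values vary by stain batch
and scanner.

The per-section value averages 3 cortical ROIs each measured twice (6
values).  Semiquantitative reader scores (0 = none ... 4 = all fields
fibrotic, two masked reads averaged) are binarized at mean >= 1 to define
"fibrotic" for diagnostic analyses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skimage import color

__all__ = [
    "HSBThresholds",
    "FibrosisAreaResult",
    "SemiquantScore",
    "rgb_to_hsb",
    "blue_mask",
    "blue_area_fraction",
    "aggregate_fibrosis_area",
    "binarize_fibrosis",
]


@dataclass(frozen=True)
class HSBThresholds:
    """Channel windows on the 0-255 HSB scale selecting "blue" pixels.

    The hue window may wrap around 255 (lo > hi means hue >= lo or
    hue <= hi); saturation and brightness windows must not wrap.
    """

    hue: tuple[int, int] = (140, 200)
    saturation: tuple[int, int] = (60, 255)
    brightness: tuple[int, int] = (40, 255)

    def __post_init__(self) -> None:
        for name in ("saturation", "brightness"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} window must satisfy lo <= hi")
        for name in ("hue", "saturation", "brightness"):
            lo, hi = getattr(self, name)
            if not (0 <= lo <= 255 and 0 <= hi <= 255):
                raise ValueError(f"{name} bounds must lie in [0, 255]")


@dataclass(frozen=True)
class FibrosisAreaResult:
    """Blue-area fractions for one histological section."""

    fractions: tuple[float, ...]
    section_value: float
    n_rois: int
    n_reads: int


@dataclass(frozen=True)
class SemiquantScore:
    """Two masked 0-4 reads of one kidney's cortical fibrosis extent."""

    reads: tuple[float, float]

    def __post_init__(self) -> None:
        for r in self.reads:
            if not 0 <= r <= 4:
                raise ValueError(f"read {r} outside the 0-4 scale")

    @property
    def mean(self) -> float:
        return float(np.mean(self.reads))

    @property
    def fibrotic(self) -> bool:
        return binarize_fibrosis(self.mean)


def _check_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an RGB image (h, w, 3), got shape {image.shape}")
    return image


def rgb_to_hsb(image: np.ndarray) -> np.ndarray:
    """Convert an 8-bit RGB image to HSB, all channels scaled to 0-255.

    Standard RGB->HSV conversion; hue 0-255 maps the full 0-360 degree
    circle (pure blue, 240 degrees, lands at 170).
    """
    image = _check_rgb(image)
    hsv = color.rgb2hsv(image.astype(np.uint8))
    return np.clip(np.round(hsv * 255.0), 0, 255).astype(np.uint8)


def blue_mask(
    image: np.ndarray, thresholds: HSBThresholds = HSBThresholds()
) -> np.ndarray:
    """Boolean mask of pixels passing all three HSB windows."""
    hsb = rgb_to_hsb(image)
    h, s, b = hsb[..., 0].astype(int), hsb[..., 1].astype(int), hsb[..., 2].astype(int)
    lo, hi = thresholds.hue
    if lo <= hi:
        m = (h >= lo) & (h <= hi)
    else:  # wrapped hue window
        m = (h >= lo) | (h <= hi)
    m &= (s >= thresholds.saturation[0]) & (s <= thresholds.saturation[1])
    m &= (b >= thresholds.brightness[0]) & (b <= thresholds.brightness[1])
    return m


def blue_area_fraction(
    image: np.ndarray,
    thresholds: HSBThresholds = HSBThresholds(),
    roi: np.ndarray | None = None,
) -> float:
    """Blue pixels / total pixels within the ROI (whole image by default)."""
    m = blue_mask(image, thresholds)
    if roi is not None:
        roi = np.asarray(roi, dtype=bool)
        if roi.shape != m.shape:
            raise ValueError("roi shape must match the image")
        if not roi.any():
            raise ValueError("empty ROI")
        return float(m[roi].sum() / roi.sum())
    return float(m.mean())


def aggregate_fibrosis_area(
    fractions: Sequence[float], n_rois: int = 3, n_reads: int = 2
) -> FibrosisAreaResult:
    """Average the n_rois x n_reads blue fractions into the section value."""
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != n_rois * n_reads:
        raise ValueError(
            f"expected {n_rois * n_reads} fractions ({n_rois} ROIs x {n_reads} reads), "
            f"got {len(fractions)}"
        )
    if any(not 0 <= f <= 1 for f in fractions):
        raise ValueError("fractions must lie in [0, 1]")
    return FibrosisAreaResult(
        fractions=fractions,
        section_value=float(np.mean(fractions)),
        n_rois=n_rois,
        n_reads=n_reads,
    )


def binarize_fibrosis(mean_score: float) -> bool:
    """Fibrotic iff the mean semiquantitative score is 1 or greater."""
    if not 0 <= mean_score <= 4:
        raise ValueError(f"mean score {mean_score} outside [0, 4]")
    return bool(mean_score >= 1.0)
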