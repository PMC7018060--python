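"""Synthetic inputs with known ground truth for every pipeline stage.

Four generators emulate the study's data:

* phantom observations obeying CT# = B_r - A_r*ln(size index) + noise, the
  generative inverse of the calibration model;
* cohorts of irradiated animals whose measured cortical HU combines a
  fibrosis-driven true HU (base + effect x score) with a size-driven
  beam-hardening bias -A*ln(size/size0) and measurement noise;
* axial CT slice rasters (air background, elliptical body and organs inside
  a circular field of view) with matching ROI masks and a closed-form TSI;
* trichrome-like RGB images with an exactly controlled blue-pixel fraction.

The beam-hardening artifact is injected at the measurement level as
-A*ln(size/size0) rather than through x-ray physics: the correction model
is exactly this log-linear form, so truth stays exactly recoverable and
every downstream claim can be checked against configured parameters.  All
generators are deterministic given a seeded ``numpy.random.Generator``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import ROI, ROISet
from .size_index import DEFAULT_AIR_HU, TSI_SCALE, fov_mask

__all__ = [
    "PhantomSimConfig",
    "CohortSimConfig",
    "Ellipse",
    "SliceSimConfig",
    "TrichromeSimConfig",
    "simulate_phantom_observations",
    "simulate_cohort",
    "render_ct_slice",
    "analytic_tsi",
    "render_trichrome",
]


def _as_rng(rng: np.random.Generator | int | None) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


# ---------------------------------------------------------------------------
# phantom observations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhantomSimConfig:
    """Generator for phantom-ROI calibration observations.

    Defaults: four hydroxyapatite regions whose intercepts B rise with
    density and whose artifact slopes A grow with density; size indices
    log-uniform over the cohort's observed (2, 9) range; 1 HU measurement
    noise; two slices per animal (each slice contributes one observation
    per region).
    """

    B: Mapping[str, float] = field(
        default_factory=lambda: {"P1": 60.0, "P2": 110.0, "P3": 160.0, "P4": 260.0}
    )
    A: Mapping[str, float] = field(
        default_factory=lambda: {"P1": 8.0, "P2": 9.0, "P3": 15.0, "P4": 24.0}
    )
    n_slices: int = 18
    size_range: tuple[float, float] = (2.0, 9.0)
    noise_sd: float = 1.0
    slices_per_animal: int = 2
    csa_per_tsi: float = 4500.0  # mm^2 of tissue per TSI unit, order-of-magnitude realistic
    csa_log_noise_sd: float = 0.25

    def __post_init__(self) -> None:
        if self.size_range[0] <= 0 or self.size_range[1] <= self.size_range[0]:
            raise ValueError("size_range must be increasing and positive")
        if self.noise_sd < 0 or self.csa_log_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")


def simulate_phantom_observations(
    cfg: PhantomSimConfig = PhantomSimConfig(),
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Draw phantom ROI means on the configured log-linear lines plus noise.

    Returns one row per (slice, region) with columns animal_id, slice_id,
    region, size_index (= tsi), tsi, csa, mean_hu.  CSA is proportional to
    TSI up to multiplicative log-normal noise, emulating a size index that
    tracks the same underlying size but explains the artifact less exactly.
    """
    rng = _as_rng(rng)
    lo, hi = cfg.size_range
    sizes = np.exp(rng.uniform(np.log(lo), np.log(hi), size=cfg.n_slices))
    csa = cfg.csa_per_tsi * sizes * np.exp(
        rng.normal(0.0, cfg.csa_log_noise_sd, size=cfg.n_slices)
    )
    rows = []
    for i, s in enumerate(sizes):
        for region in cfg.B:
            hu = cfg.B[region] - cfg.A[region] * np.log(s) + rng.normal(0.0, cfg.noise_sd)
            rows.append(
                {
                    "animal_id": f"A{i // cfg.slices_per_animal:03d}",
                    "slice_id": i,
                    "region": region,
                    "size_index": s,
                    "tsi": s,
                    "csa": csa[i],
                    "mean_hu": hu,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortSimConfig:
    """Generator for kidney-level cohort tables.

    Defaults mirror the study design: 10 total-body-irradiated animals
    (scores centred near 2), 10 chest-only (near 0.5), 2 unirradiated
    controls; two kidneys per animal; healthy cortical base ~30 HU with an
    8 HU rise per fibrosis-score unit; size indices uniform over (2, 9)
    with the beam-hardening bias -A*ln(size/size0) and 3 HU measurement
    noise.  Scores are the mean of two integer 0-4 reads.  When
    ``prevalence`` is set, the per-kidney fibrosis flag is drawn directly
    (Bernoulli) instead of via group score distributions.
    """

    n_per_group: Mapping[str, int] = field(
        default_factory=lambda: {"total_body": 10, "chest_only": 10, "control": 2}
    )
    score_mu: Mapping[str, float] = field(
        default_factory=lambda: {"total_body": 2.0, "chest_only": 0.5, "control": 0.0}
    )
    score_sd: float = 0.8
    base_hu: float = 30.0
    effect_hu_per_score: float = 8.0
    A: float = 8.5
    noise_sd: float = 3.0
    size_range: tuple[float, float] = (2.0, 9.0)
    reference_size: float | None = None  # None -> midpoint of size_range
    kidneys_per_animal: int = 2
    prevalence: float | None = None
    blue_per_score: float = 0.08
    blue_noise_sd: float = 0.01

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.score_sd < 0:
            raise ValueError("SDs must be >= 0")
        if self.prevalence is not None and not 0 <= self.prevalence <= 1:
            raise ValueError("prevalence must be in [0, 1]")

    @property
    def size0(self) -> float:
        if self.reference_size is not None:
            return self.reference_size
        return (self.size_range[0] + self.size_range[1]) / 2.0


def _draw_reads(cfg: CohortSimConfig, group: str, rng: np.random.Generator) -> tuple[int, int]:
    if cfg.prevalence is not None:
        if rng.uniform() < cfg.prevalence:
            reads = np.clip(np.round(rng.normal(2.0, cfg.score_sd, 2)), 1, 4)
        else:
            reads = np.zeros(2)
    else:
        reads = np.clip(np.round(rng.normal(cfg.score_mu[group], cfg.score_sd, 2)), 0, 4)
    return int(reads[0]), int(reads[1])


def simulate_cohort(
    cfg: CohortSimConfig = CohortSimConfig(),
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Simulate a cohort table with truth columns.

    Per kidney: two reads -> fibrosis_score; true_hu = base + effect*score;
    measured_hu = true_hu - A*ln(size/size0) + noise.  The corrected_hu
    column is left NaN for the pipeline to fill.  Truth columns (true_hu,
    fibrotic) make generator parameters recoverable in tests.
    """
    rng = _as_rng(rng)
    lo, hi = cfg.size_range
    rows = []
    i = 0
    for group, n in cfg.n_per_group.items():
        for _ in range(n):
            animal = f"N{i:03d}"
            i += 1
            size = rng.uniform(lo, hi)
            for side in ("left", "right")[: cfg.kidneys_per_animal]:
                r1, r2 = _draw_reads(cfg, group, rng)
                score = (r1 + r2) / 2.0
                true_hu = cfg.base_hu + cfg.effect_hu_per_score * score
                measured = (
                    true_hu
                    - cfg.A * np.log(size / cfg.size0)
                    + rng.normal(0.0, cfg.noise_sd)
                )
                blue = float(
                    np.clip(
                        0.02 + cfg.blue_per_score * score + rng.normal(0, cfg.blue_noise_sd),
                        0.0,
                        1.0,
                    )
                )
                rows.append(
                    {
                        "animal_id": animal,
                        "side": side,
                        "group": group,
                        "measured_hu": measured,
                        "size_index": size,
                        "corrected_hu": np.nan,
                        "fibrosis_score": score,
                        "blue_fraction": blue,
                        "bun": np.nan,
                        "true_hu": true_hu,
                        "fibrotic": score >= 1.0,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# CT slice rasters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Ellipse:
    """Axis-aligned ellipse in mm, origin at the matrix centre."""

    center_mm: tuple[float, float]  # (x, y)
    semiaxes_mm: tuple[float, float]  # (a along x, b along y)
    hu: float
    label: str = ""

    @property
    def area_mm2(self) -> float:
        return float(np.pi * self.semiaxes_mm[0] * self.semiaxes_mm[1])

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        cx, cy = self.center_mm
        a, b = self.semiaxes_mm
        return ((x - cx) / a) ** 2 + ((y - cy) / b) ** 2 <= 1.0


@dataclass(frozen=True)
class SliceSimConfig:
    """Geometry of a synthetic axial slice: body ellipse(s) plus organs."""

    matrix: int = 512
    fov_diameter_mm: float = 320.0
    bodies: tuple[Ellipse, ...] = ()
    organs: tuple[Ellipse, ...] = ()  # each must lie inside the first body
    air_hu: float = DEFAULT_AIR_HU

    @property
    def spacing(self) -> tuple[float, float]:
        d = self.fov_diameter_mm / self.matrix
        return (d, d)

    def validate(self) -> None:
        r = self.fov_diameter_mm / 2.0
        for e in self.bodies:
            reach = np.hypot(*e.center_mm) + max(e.semiaxes_mm)
            if reach > r + 1e-9:
                raise ValueError(f"body {e.label or e.center_mm} extends outside the FOV")
        if self.organs and not self.bodies:
            raise ValueError("organs require a body")
        for o in self.organs:
            b = self.bodies[0]
            dx = abs(o.center_mm[0] - b.center_mm[0]) + o.semiaxes_mm[0]
            dy = abs(o.center_mm[1] - b.center_mm[1]) + o.semiaxes_mm[1]
            if (dx / b.semiaxes_mm[0]) ** 2 + (dy / b.semiaxes_mm[1]) ** 2 > 1.0 + 1e-9:
                raise ValueError(f"organ {o.label or o.center_mm} not inside the body")


def render_ct_slice(cfg: SliceSimConfig) -> tuple[np.ndarray, ROISet]:
    """Rasterize the configured geometry to an HU image plus ROI masks.

    Pixel centres at index*spacing; air outside the bodies, body HU inside,
    organ HU painted over.  Returned ROIs: one mask per labelled body/organ
    plus the FOV circle (label "FOV").
    """
    cfg.validate()
    n = cfg.matrix
    dy, dx = cfg.spacing
    cx = (n - 1) / 2.0 * dx
    cy = (n - 1) / 2.0 * dy
    xs = np.arange(n)[None, :] * dx - cx
    ys = np.arange(n)[:, None] * dy - cy
    x = np.broadcast_to(xs, (n, n))
    y = np.broadcast_to(ys, (n, n))
    img = np.full((n, n), cfg.air_hu, dtype=float)
    rois: list[ROI] = [
        ROI(label="FOV", plane="axial", slice_index=0,
            mask=fov_mask((n, n), cfg.spacing, cfg.fov_diameter_mm))
    ]
    for i, e in enumerate(list(cfg.bodies) + list(cfg.organs)):
        m = e.contains(x, y)
        img[m] = e.hu
        rois.append(
            ROI(label=e.label or f"region_{i}", plane="axial", slice_index=0, mask=m)
        )
    return img, ROISet(rois)


def analytic_tsi(cfg: SliceSimConfig) -> float:
    """Closed-form TSI of the configured geometry.

    Area-weighted: each body contributes (hu - air) x area and each organ
    replaces body HU by organ HU over its area.  Assumes bodies are
    disjoint and organs lie inside the first body (checked by validate).
    """
    cfg.validate()
    total = 0.0
    for e in cfg.bodies:
        total += (e.hu - cfg.air_hu) * e.area_mm2
    for o in cfg.organs:
        total += (o.hu - cfg.bodies[0].hu) * o.area_mm2
    return total / TSI_SCALE


# ---------------------------------------------------------------------------
# trichrome images
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrichromeSimConfig:
    """Blue/pink patchwork with a white border, emulating a stained section.

    Colors sit well inside (blue) or outside (pink, white) the default HSB
    window even after per-pixel jitter, so the generator's blue count is the
    exact ground truth for threshold-based measurement.
    """

    size: tuple[int, int] = (192, 192)
    border: int = 10
    blue_rgb: tuple[int, int, int] = (45, 70, 190)
    pink_rgb: tuple[int, int, int] = (225, 140, 170)
    white_rgb: tuple[int, int, int] = (250, 250, 250)
    jitter: int = 8
    blob_sigma: float = 6.0


def render_trichrome(
    target_fraction: float,
    cfg: TrichromeSimConfig = TrichromeSimConfig(),
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Render an RGB image whose blue-pixel fraction is round(f*N)/N.

    A smoothed random field is thresholded at the exact count quantile, so
    blue forms contiguous patches (like collagen bundles) while the realized
    fraction matches the target to within half a pixel.  Blue is assigned
    inside the tissue rectangle first and spills into the border only when
    the target exceeds the tissue area.
    """
    if not 0.0 <= target_fraction <= 1.0:
        raise ValueError("target_fraction must be in [0, 1]")
    rng = _as_rng(rng)
    h, w = cfg.size
    n_total = h * w
    k = int(round(target_fraction * n_total))
    field_ = ndimage.gaussian_filter(rng.standard_normal((h, w)), cfg.blob_sigma)
    tissue = np.zeros((h, w), dtype=bool)
    b = cfg.border
    tissue[b : h - b, b : w - b] = True
    # tissue pixels take priority; within a class, patchy by the smooth field
    priority = field_ + np.where(tissue, 1e6, 0.0)
    order = np.argsort(-priority.ravel())
    blue = np.zeros(n_total, dtype=bool)
    blue[order[:k]] = True
    blue = blue.reshape(h, w)
    img = np.empty((h, w, 3), dtype=float)
    img[...] = cfg.white_rgb
    img[tissue & ~blue] = cfg.pink_rgb
    img[blue] = cfg.blue_rgb
    img += rng.integers(-cfg.jitter, cfg.jitter + 1, size=img.shape)
    return np.clip(img, 0, 255).astype(np.uint8)
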