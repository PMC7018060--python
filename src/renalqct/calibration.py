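"""Phantom-based calibration of the size-dependent CT-number artifact.

A QCT phantom with four calcium-hydroxyapatite regions (P1-P4: 0, 50, 100,
200 mg/ml) is scanned alongside subjects of different sizes.  Each phantom
ROI's mean CT number falls as subject size grows (residual beam hardening),
and the drop is well described by the log-linear model

    CT# = B - A * ln(size index)                                (per region)

so B is the region's CT number at size index 1 and A (HU per ln-unit)
quantifies the artifact.  A grows with region density.  Soft tissue of
interest falls between P1 and P2, so when a Wald test finds the P1/P2
slopes compatible a common-slope (separate-intercept) model is fit and its
pooled A becomes the correction coefficient.

Akaike's information criterion on the full four-region model (region-
specific intercepts and slopes) compares candidate size indices; the
Gaussian-profile convention AIC = n*(ln(2*pi*RSS/n) + 1) + 2k is used, whose
additive constant cancels in comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "PHANTOM_REGIONS",
    "PHANTOM_DENSITIES_MG_ML",
    "RegionFit",
    "SlopeTest",
    "PooledFit",
    "ModelComparison",
    "fit_region_calibration",
    "wald_slope_test",
    "fit_pooled_calibration",
    "compare_size_indices",
    "BeamHardeningCalibrator",
]

PHANTOM_REGIONS: Sequence[str] = ("P1", "P2", "P3", "P4")
PHANTOM_DENSITIES_MG_ML: Mapping[str, float] = {
    "P1": 0.0,
    "P2": 50.0,
    "P3": 100.0,
    "P4": 200.0,
}


@dataclass(frozen=True)
class RegionFit:
    """OLS fit of one region's CT# = B - A*ln(s)."""

    region: str
    A: float
    B: float
    se_A: float
    se_B: float
    resid_var: float
    nobs: int
    aic: float

    def predict(self, size_index: np.ndarray | float) -> np.ndarray | float:
        return self.B - self.A * np.log(size_index)


@dataclass(frozen=True)
class SlopeTest:
    """Wald test of the region x ln(size) interaction between two regions."""

    estimate: float
    se: float
    wald: float
    p_value: float
    alpha: float
    pool: bool


@dataclass(frozen=True)
class PooledFit:
    """Common-slope, separate-intercept fit over a set of regions."""

    regions: tuple[str, ...]
    A: float
    se_A: float
    intercepts: dict[str, float]
    resid_var: float
    nobs: int


@dataclass(frozen=True)
class ModelComparison:
    """AIC comparison of the full four-region model under two size indices."""

    aic_csa: float
    aic_tsi: float
    selected: str  # "tsi", "csa", or "tie"


def _validate_region_obs(size_index: np.ndarray, mean_hu: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(size_index, dtype=float)
    y = np.asarray(mean_hu, dtype=float)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("size_index and mean_hu must be equal-length 1-D arrays")
    if (s <= 0).any():
        raise ValueError("size indices must be > 0 (the model takes their log)")
    if len(s) < 3:
        raise ValueError("need at least 3 observations per region")
    if np.unique(s).size < 2:
        raise ValueError("all size indices equal: design is rank-deficient")
    return s, y


def fit_region_calibration(
    size_index: np.ndarray, mean_hu: np.ndarray, region: str = ""
) -> RegionFit:
    """Fit CT# = B - A*ln(size index) to one region by ordinary least squares.

    The regression is of mean HU on ln(size index); A is the negated slope
    so the reported coefficients match the display form.
    """
    s, y = _validate_region_obs(size_index, mean_hu)
    X = sm.add_constant(np.log(s))
    res = sm.OLS(y, X).fit()
    return RegionFit(
        region=region,
        A=float(-res.params[1]),
        B=float(res.params[0]),
        se_A=float(res.bse[1]),
        se_B=float(res.bse[0]),
        resid_var=float(res.mse_resid) if res.df_resid > 0 else float("nan"),
        nobs=int(res.nobs),
        aic=float(res.aic),
    )


def wald_slope_test(
    size_a: np.ndarray,
    hu_a: np.ndarray,
    size_b: np.ndarray,
    hu_b: np.ndarray,
    alpha: float = 0.05,
) -> SlopeTest:
    """Test whether two regions share a slope on ln(size index).

    Fits the two-region regression with a region main effect and a
    region x ln(size) interaction; the Wald statistic is
    (interaction / SE)^2, referred to F(1, residual df) — the exact
    reference in the Gaussian linear model, which converges to chi-square
    with 1 df as observations accumulate.  Pooling is recommended iff
    p >= alpha.
    """
    sa, ya = _validate_region_obs(size_a, hu_a)
    sb, yb = _validate_region_obs(size_b, hu_b)
    ln_s = np.concatenate([np.log(sa), np.log(sb)])
    grp = np.concatenate([np.zeros(len(sa)), np.ones(len(sb))])
    y = np.concatenate([ya, yb])
    X = np.column_stack([np.ones_like(ln_s), grp, ln_s, grp * ln_s])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("degenerate design: cannot separate slopes")
    res = sm.OLS(y, X).fit()
    est = float(res.params[3])
    se = float(res.bse[3])
    wald = (est / se) ** 2
    p = float(stats.f.sf(wald, 1, res.df_resid))
    return SlopeTest(estimate=est, se=se, wald=wald, p_value=p, alpha=alpha, pool=p >= alpha)


def fit_pooled_calibration(
    obs_by_region: Mapping[str, tuple[np.ndarray, np.ndarray]]
) -> PooledFit:
    """Fit a common slope with separate intercepts across regions.

    ``obs_by_region`` maps region label -> (size_index, mean_hu).  The
    shared negated slope is the pooled A used for the size correction.  A
    single region reduces exactly to :func:`fit_region_calibration`.
    """
    if not obs_by_region:
        raise ValueError("no regions supplied")
    regions = tuple(obs_by_region)
    blocks, ys = [], []
    for i, r in enumerate(regions):
        s, y = _validate_region_obs(*obs_by_region[r])
        dummies = np.zeros((len(s), len(regions)))
        dummies[:, i] = 1.0
        blocks.append(np.column_stack([dummies, np.log(s)]))
        ys.append(y)
    X = np.vstack(blocks)
    y = np.concatenate(ys)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("degenerate design for the pooled fit")
    res = sm.OLS(y, X).fit()
    return PooledFit(
        regions=regions,
        A=float(-res.params[-1]),
        se_A=float(res.bse[-1]),
        intercepts={r: float(res.params[i]) for i, r in enumerate(regions)},
        resid_var=float(res.mse_resid) if res.df_resid > 0 else float("nan"),
        nobs=int(res.nobs),
    )


def _full_model_aic(df: pd.DataFrame, index_col: str) -> float:
    """AIC of the four-region full-interaction model for one size index."""
    regions = sorted(df["region"].unique())
    ln_s = np.log(df[index_col].to_numpy(dtype=float))
    cols = []
    for r in regions:
        ind = (df["region"] == r).to_numpy(dtype=float)
        cols.extend([ind, ind * ln_s])
    X = np.column_stack(cols)
    res = sm.OLS(df["mean_hu"].to_numpy(dtype=float), X).fit()
    return float(res.aic)


def compare_size_indices(obs: pd.DataFrame) -> ModelComparison:
    """Compare TSI against CSA as the size index by per-region AIC.

    ``obs`` needs columns region, mean_hu, tsi, csa with both indices
    present on every row.  Each index's full model (region-specific
    intercepts and slopes) is fit once; the index with the lower AIC is
    selected.
    """
    for col in ("region", "mean_hu", "tsi", "csa"):
        if col not in obs.columns:
            raise ValueError(f"missing column {col!r}")
    bad = obs.index[obs["tsi"].isna() | obs["csa"].isna()]
    if len(bad):
        raise ValueError(f"rows missing a size index: {list(bad)}")
    if (obs["tsi"] <= 0).any() or (obs["csa"] <= 0).any():
        raise ValueError("size indices must be > 0")
    aic_tsi = _full_model_aic(obs, "tsi")
    aic_csa = _full_model_aic(obs, "csa")
    if np.isclose(aic_tsi, aic_csa, rtol=0, atol=1e-9):
        selected = "tie"
    else:
        selected = "tsi" if aic_tsi < aic_csa else "csa"
    return ModelComparison(aic_csa=aic_csa, aic_tsi=aic_tsi, selected=selected)


class BeamHardeningCalibrator(BaseEstimator):
    """Learn the size-correction coefficient A from phantom observations.

    Fits per-region log-linear calibrations, tests slope homogeneity of the
    soft-tissue-bracketing regions (default P1 and P2) with a Wald test,
    and — when pooling is justified or forced — fits the common-slope model
    whose negated slope ``pooled_A_`` is the correction coefficient.

    Parameters
    ----------
    pool_regions : tuple of str
        Regions whose CT numbers bracket the tissue of interest.
    alpha : float
        Significance level of the slope-homogeneity test.
    force_pool : bool or None
        None (default): pool iff the Wald test does not reject.  True/False
        overrides the test outcome (the test is still reported).

    Attributes (after :meth:`fit`)
    ------------------------------
    region_fits_ : dict of region -> RegionFit
    slope_test_ : SlopeTest
    pooled_ : PooledFit or None   (None when pooling is rejected and not forced)
    pooled_A_ : float             (falls back to the first pool region's A)
    comparison_ : ModelComparison or None  (set when a csa column is present)
    """

    def __init__(
        self,
        pool_regions: tuple[str, str] = ("P1", "P2"),
        alpha: float = 0.05,
        force_pool: bool | None = None,
    ):
        self.pool_regions = pool_regions
        self.alpha = alpha
        self.force_pool = force_pool

    def fit(self, X: pd.DataFrame, y=None) -> "BeamHardeningCalibrator":
        """X: frame with columns region, size_index, mean_hu (optionally csa)."""
        for col in ("region", "size_index", "mean_hu"):
            if col not in X.columns:
                raise ValueError(f"missing column {col!r}")
        self.region_fits_ = {}
        grouped = {
            r: (g["size_index"].to_numpy(float), g["mean_hu"].to_numpy(float))
            for r, g in X.groupby("region")
        }
        for r, (s, hu) in grouped.items():
            self.region_fits_[r] = fit_region_calibration(s, hu, region=r)
        r1, r2 = self.pool_regions
        if r1 not in grouped or r2 not in grouped:
            raise ValueError(f"pool regions {self.pool_regions} not all present")
        self.slope_test_ = wald_slope_test(*grouped[r1], *grouped[r2], alpha=self.alpha)
        do_pool = self.slope_test_.pool if self.force_pool is None else self.force_pool
        if do_pool:
            self.pooled_ = fit_pooled_calibration({r: grouped[r] for r in (r1, r2)})
            self.pooled_A_ = self.pooled_.A
        else:
            self.pooled_ = None
            self.pooled_A_ = self.region_fits_[r1].A
        if "csa" in X.columns and X["csa"].notna().all():
            obs = X if "tsi" in X.columns else X.rename(columns={"size_index": "tsi"})
            self.comparison_ = compare_size_indices(obs)
        else:
            self.comparison_ = None
        return self

    def report(self) -> dict:
        """JSON-serializable calibration report for the correction stage."""
        out = {
            "regions": {
                r: {"A": f.A, "B": f.B, "se_A": f.se_A, "se_B": f.se_B, "n": f.nobs}
                for r, f in self.region_fits_.items()
            },
            "slope_test": {
                "estimate": self.slope_test_.estimate,
                "se": self.slope_test_.se,
                "wald": self.slope_test_.wald,
                "p_value": self.slope_test_.p_value,
                "alpha": self.slope_test_.alpha,
                "pool": self.slope_test_.pool,
            },
            "pooled_A": self.pooled_A_,
            "pooled_A_se": self.pooled_.se_A if self.pooled_ else None,
            "pooled_regions": list(self.pool_regions),
        }
        if self.comparison_ is not None:
            out["size_index_comparison"] = {
                "aic_tsi": self.comparison_.aic_tsi,
                "aic_csa": self.comparison_.aic_csa,
                "selected": self.comparison_.selected,
            }
        return out
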