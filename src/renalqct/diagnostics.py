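"""Diagnostic evaluation of corrected CT number as a fibrosis biomarker.

Animals contribute two kidneys (repeated measures), so inference clusters on
animal: a GEE logistic regression with an exchangeable working correlation
and robust (sandwich) standard errors links the fibrosis flag to corrected
HU; empirical ROC analysis quantifies discrimination; paired t-tests check
left/right exchangeability; a random-intercept mixed model estimates the
correlation between measurement methods; and group comparisons contrast
exposure arms after aggregating to the animal level.

ROC conventions (fixed so results are reproducible by hand): cutoffs are the
midpoints between consecutive distinct scores, extended by -inf/+inf; a
kidney is called positive iff its score strictly exceeds the cutoff, so ties
at a cutoff are negative; AUC is the trapezoidal area, identical to the
Mann-Whitney concordance probability with ties counted 1/2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "GEEFit",
    "ROCResult",
    "OperatingPoint",
    "PairedTestResult",
    "MethodCorrelation",
    "GroupComparison",
    "gee_logistic_fibrosis",
    "roc_analysis",
    "operating_point",
    "paired_side_test",
    "method_correlation",
    "group_comparison",
]


@dataclass(frozen=True)
class GEEFit:
    intercept: float
    slope: float
    se_intercept: float
    se_slope: float
    working_correlation: str
    n_clusters: int
    separation_flag: bool
    slope_p_value: float


@dataclass(frozen=True)
class ROCResult:
    cutoffs: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    ppv: np.ndarray
    npv: np.ndarray
    auc: float
    prevalence: float
    n_positive: int
    n_negative: int


@dataclass(frozen=True)
class OperatingPoint:
    cutoff: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    tp: int
    fp: int
    fn: int
    tn: int


@dataclass(frozen=True)
class PairedTestResult:
    mean_difference: float
    t: float
    p_value: float
    n_pairs: int


@dataclass(frozen=True)
class MethodCorrelation:
    methods: tuple[str, str]
    estimate: float
    pearson: float
    subset: str
    model: str
    n_animals: int
    n_kidneys: int


@dataclass(frozen=True)
class GroupComparison:
    groups: tuple[str, str]
    means: tuple[float, float]
    mean_difference: float
    t: float
    p_value: float
    n_animals: tuple[int, int]


def _check_two_classes(y: np.ndarray) -> None:
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("both outcome classes must be present")


def gee_logistic_fibrosis(
    records: pd.DataFrame,
    score_col: str = "corrected_hu",
    flag_col: str = "fibrotic",
    cluster_col: str = "animal_id",
) -> GEEFit:
    """GEE logistic regression of the fibrosis flag on a continuous score.

    Binomial mean model, exchangeable working correlation over kidneys
    within animal, cluster-robust standard errors.  Perfect separation of
    the two classes by the score is flagged; estimates are still returned
    but should be read as diverging.
    """
    y = records[flag_col].to_numpy(dtype=float)
    x = records[score_col].to_numpy(dtype=float)
    groups = records[cluster_col].to_numpy()
    _check_two_classes(y)
    if len(np.unique(groups)) < 2:
        raise ValueError("need at least 2 clusters (animals)")
    separated = float(x[y == 1].min()) > float(x[y == 0].max()) or float(
        x[y == 1].max()
    ) < float(x[y == 0].min())
    X = sm.add_constant(x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GEE(
            y, X, groups=groups, family=sm.families.Binomial(),
            cov_struct=sm.cov_struct.Exchangeable(),
        )
        res = model.fit()
    return GEEFit(
        intercept=float(res.params[0]),
        slope=float(res.params[1]),
        se_intercept=float(res.bse[0]),
        se_slope=float(res.bse[1]),
        working_correlation="exchangeable",
        n_clusters=int(len(np.unique(groups))),
        separation_flag=bool(separated),
        slope_p_value=float(res.pvalues[1]),
    )


def _confusion(scores: np.ndarray, labels: np.ndarray, cutoff: float):
    pos = scores > cutoff
    tp = int(np.sum(pos & (labels == 1)))
    fp = int(np.sum(pos & (labels == 0)))
    fn = int(np.sum(~pos & (labels == 1)))
    tn = int(np.sum(~pos & (labels == 0)))
    return tp, fp, fn, tn


def _metrics(tp: int, fp: int, fn: int, tn: int) -> tuple[float, float, float, float]:
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    ppv = tp / (tp + fp) if tp + fp else float("nan")
    npv = tn / (tn + fn) if tn + fn else float("nan")
    return sens, spec, ppv, npv


def roc_analysis(
    records: pd.DataFrame | None = None,
    score_col: str = "corrected_hu",
    flag_col: str = "fibrotic",
    scores: np.ndarray | None = None,
    labels: np.ndarray | None = None,
) -> ROCResult:
    """Empirical ROC of a positively-oriented score against a binary label.

    Accepts either a records frame (score_col/flag_col) or raw arrays.
    AUC is computed as the Mann-Whitney concordance probability (ties 1/2),
    which equals the trapezoidal area under the empirical curve.
    """
    if records is not None:
        scores = records[score_col].to_numpy(dtype=float)
        labels = records[flag_col].to_numpy()
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    _check_two_classes(labels)
    distinct = np.unique(scores)
    mids = (distinct[:-1] + distinct[1:]) / 2.0 if len(distinct) > 1 else np.array([])
    cutoffs = np.concatenate([[-np.inf], mids, [np.inf]])
    sens, spec, ppv, npv = [], [], [], []
    for c in cutoffs:
        m = _metrics(*_confusion(scores, labels, c))
        sens.append(m[0]); spec.append(m[1]); ppv.append(m[2]); npv.append(m[3])
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    # Mann-Whitney concordance via rank sums (ties get 1/2 credit)
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2.0
    auc = float(u / (len(pos) * len(neg)))
    return ROCResult(
        cutoffs=cutoffs,
        sensitivity=np.asarray(sens),
        specificity=np.asarray(spec),
        ppv=np.asarray(ppv),
        npv=np.asarray(npv),
        auc=auc,
        prevalence=float(labels.mean()),
        n_positive=int(len(pos)),
        n_negative=int(len(neg)),
    )


def operating_point(
    scores: np.ndarray, labels: np.ndarray, cutoff: float
) -> OperatingPoint:
    """Confusion-matrix metrics at one cutoff (positive iff score > cutoff).

    PPV/NPV are computed from the same sample, i.e. at its observed
    prevalence.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    tp, fp, fn, tn = _confusion(scores, labels, cutoff)
    sens, spec, ppv, npv = _metrics(tp, fp, fn, tn)
    return OperatingPoint(
        cutoff=float(cutoff), sensitivity=sens, specificity=spec,
        ppv=ppv, npv=npv, tp=tp, fp=fp, fn=fn, tn=tn,
    )


def paired_side_test(
    records: pd.DataFrame, value_col: str, cluster_col: str = "animal_id"
) -> PairedTestResult:
    """Paired t-test on right-minus-left differences across animals.

    Only animals with both sides known contribute; used to justify pooling
    left and right kidneys in the marginal analyses.
    """
    known = records[records["side"].isin(["left", "right"])]
    wide = known.pivot_table(index=cluster_col, columns="side", values=value_col)
    wide = wide.dropna(subset=["left", "right"]) if {"left", "right"} <= set(wide.columns) else wide.iloc[0:0]
    if len(wide) < 2:
        raise ValueError("need at least 2 animals with both sides measured")
    diffs = wide["right"].to_numpy(float) - wide["left"].to_numpy(float)
    t, p = stats.ttest_rel(wide["right"], wide["left"])
    return PairedTestResult(
        mean_difference=float(diffs.mean()), t=float(t), p_value=float(p),
        n_pairs=int(len(diffs)),
    )


def method_correlation(
    records: pd.DataFrame,
    methods: tuple[str, str] = ("fibrosis_score", "corrected_hu"),
    subset: Literal["all", "score>0"] = "all",
    cluster_col: str = "animal_id",
) -> MethodCorrelation:
    """Correlation between two measurement methods with repeated measures.

    Both method columns are z-scored and stacked long (one row per kidney x
    method; method and side are repeated measures on the animal); a linear
    mixed model with a fixed method effect and a random intercept per kidney
    (the unit both methods measure, kidneys nested in animals) is fit, and
    the intraclass correlation var(kidney) / (var(kidney) + var(residual))
    estimates the between-method correlation: methods that agree exactly on
    every kidney leave no residual variance and give 1.  When every animal
    contributes a single kidney the repeated-measures structure is vacuous
    and the textbook Pearson r over kidneys is returned instead.  Pearson r
    is always reported alongside.
    """
    m1, m2 = methods
    df = records.dropna(subset=[m1, m2]).copy()
    if subset == "score>0":
        df = df[df["fibrosis_score"] > 0]
    elif subset != "all":
        raise ValueError(f"unknown subset {subset!r}")
    n_animals = df[cluster_col].nunique()
    if n_animals < 3:
        raise ValueError("need at least 3 animals")
    x1 = df[m1].to_numpy(float)
    x2 = df[m2].to_numpy(float)
    pearson = float(stats.pearsonr(x1, x2)[0])
    one_per_animal = df.groupby(cluster_col).size().max() == 1
    if one_per_animal:
        return MethodCorrelation(
            methods=methods, estimate=pearson, pearson=pearson, subset=subset,
            model="pearson (one kidney per animal)",
            n_animals=int(n_animals), n_kidneys=int(len(df)),
        )
    z1 = (x1 - x1.mean()) / x1.std(ddof=1)
    z2 = (x2 - x2.mean()) / x2.std(ddof=1)
    kidney = (df[cluster_col].astype(str) + ":" + df["side"].astype(str)).to_numpy()
    long = pd.DataFrame(
        {
            "value": np.concatenate([z1, z2]),
            "method": np.repeat([0.0, 1.0], len(df)),
            "kidney": np.tile(kidney, 2),
        }
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.MixedLM.from_formula(
            "value ~ method", groups="kidney", data=long
        ).fit(reml=True)
    var_kidney = float(res.cov_re.iloc[0, 0])
    var_resid = float(res.scale)
    icc = var_kidney / (var_kidney + var_resid)
    return MethodCorrelation(
        methods=methods, estimate=float(icc), pearson=pearson, subset=subset,
        model="random-intercept-per-kidney ICC on z-scored methods",
        n_animals=int(n_animals), n_kidneys=int(len(df)),
    )


def group_comparison(
    records: pd.DataFrame,
    groups: tuple[str, str],
    value_col: str = "corrected_hu",
    group_col: str = "group",
    cluster_col: str = "animal_id",
) -> GroupComparison:
    """Compare two exposure groups on an animal-aggregated value.

    Kidney rows are averaged within animal first (animals are the
    independent units), then a Welch two-sample t-test compares the groups.
    """
    g1, g2 = groups
    per_animal = (
        records[records[group_col].isin(groups)]
        .groupby([cluster_col, group_col], observed=True)[value_col]
        .mean()
        .reset_index()
    )
    a = per_animal.loc[per_animal[group_col] == g1, value_col].to_numpy(float)
    b = per_animal.loc[per_animal[group_col] == g2, value_col].to_numpy(float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError(f"empty group among {groups}")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return GroupComparison(
        groups=groups,
        means=(float(a.mean()), float(b.mean())),
        mean_difference=float(a.mean() - b.mean()),
        t=float(t),
        p_value=float(p),
        n_animals=(int(len(a)), int(len(b))),
    )
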