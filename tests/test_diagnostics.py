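"""Diagnostic statistics: GEE, ROC, operating points, paired/group tests."""

import numpy as np
import pandas as pd
import pytest

from renalqct.diagnostics import (
    gee_logistic_fibrosis,
    group_comparison,
    method_correlation,
    operating_point,
    paired_side_test,
    roc_analysis,
)


def _frame(scores, labels, animals=None, sides=None):
    n = len(scores)
    return pd.DataFrame(
        {
            "animal_id": animals if animals is not None else [f"a{i}" for i in range(n)],
            "side": sides if sides is not None else ["left"] * n,
            "corrected_hu": scores,
            "fibrotic": labels,
        }
    )


# ---------------------------------------------------------------------- GEE


def test_gee_one_kidney_per_animal_matches_independent_logistic(rng):
    import statsmodels.api as sm

    x = rng.normal(50, 8, 60)
    p = 1 / (1 + np.exp(-(x - 50) / 4))
    y = (rng.uniform(size=60) < p).astype(int)
    if y.min() == y.max():
        pytest.skip("degenerate draw")
    df = _frame(x, y)
    fit = gee_logistic_fibrosis(df)
    glm = sm.GLM(y, sm.add_constant(x), family=sm.families.Binomial()).fit()
    assert fit.intercept == pytest.approx(glm.params[0], abs=1e-4)
    assert fit.slope == pytest.approx(glm.params[1], abs=1e-5)


def test_gee_zero_within_cluster_correlation_matches_logistic(rng):
    """With independent kidneys inside animals the exchangeable GEE collapses
    to the ordinary logistic fit."""
    import statsmodels.api as sm

    n_animals = 100
    animals = np.repeat([f"a{i}" for i in range(n_animals)], 2)
    x = rng.normal(50, 8, 2 * n_animals)
    y = (rng.uniform(size=2 * n_animals) < 1 / (1 + np.exp(-(x - 50) / 4))).astype(int)
    fit = gee_logistic_fibrosis(_frame(x, y, animals=animals))
    glm = sm.GLM(y, sm.add_constant(x), family=sm.families.Binomial()).fit()
    # correlation is estimated near 0, so point estimates agree closely
    assert fit.slope == pytest.approx(glm.params[1], abs=0.02)


def test_gee_robust_ci_coverage_under_null(rng):
    cover = 0
    n_rep = 150
    for _ in range(n_rep):
        n_animals = 30
        animals = np.repeat(np.arange(n_animals), 2)
        u = rng.normal(0, 1, n_animals)  # shared animal effect -> clustering
        x = rng.normal(50, 8, 2 * n_animals)
        logit = -0.3 + u[animals]  # true slope on x is 0
        y = (rng.uniform(size=2 * n_animals) < 1 / (1 + np.exp(-logit))).astype(int)
        if y.min() == y.max():
            continue
        fit = gee_logistic_fibrosis(_frame(x, y, animals=animals))
        if abs(fit.slope) <= 1.96 * fit.se_slope:
            cover += 1
    assert cover / n_rep == pytest.approx(0.95, abs=0.05)


def test_gee_flags_perfect_separation():
    df = _frame([40.0, 42.0, 60.0, 62.0], [0, 0, 1, 1], animals=["a", "b", "c", "d"])
    fit = gee_logistic_fibrosis(df)
    assert fit.separation_flag


def test_gee_input_validation():
    with pytest.raises(ValueError, match="classes"):
        gee_logistic_fibrosis(_frame([1.0, 2.0, 3.0], [1, 1, 1]))
    with pytest.raises(ValueError, match="clusters"):
        gee_logistic_fibrosis(_frame([1.0, 2.0], [0, 1], animals=["a", "a"]))


# ---------------------------------------------------------------------- ROC


def test_roc_perfect_discrimination_toy():
    res = roc_analysis(scores=[1, 2, 3, 4], labels=[0, 0, 1, 1])
    assert res.auc == 1.0
    op = operating_point(np.array([1, 2, 3, 4]), np.array([0, 0, 1, 1]), 2.5)
    assert op.sensitivity == 1.0 and op.specificity == 1.0


def test_roc_null_labels_auc_half(rng):
    scores = rng.normal(size=2000)
    labels = rng.integers(0, 2, size=2000)
    assert roc_analysis(scores=scores, labels=labels).auc == pytest.approx(0.5, abs=0.03)


def test_roc_all_scores_tied_gives_half():
    assert roc_analysis(scores=[3.0] * 10, labels=[0, 1] * 5).auc == 0.5


def test_roc_requires_both_classes():
    with pytest.raises(ValueError):
        roc_analysis(scores=[1.0, 2.0], labels=[1, 1])


def test_auc_equals_exhaustive_pair_concordance(rng):
    scores = np.round(rng.normal(size=40), 1)  # ties likely
    labels = rng.integers(0, 2, size=40)
    if labels.min() == labels.max():
        labels[0] = 1 - labels[0]
    res = roc_analysis(scores=scores, labels=labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    conc = sum((p > n_) + 0.5 * (p == n_) for p in pos for n_ in neg)
    assert res.auc == pytest.approx(conc / (len(pos) * len(neg)))


def test_auc_matches_sklearn(rng):
    from sklearn.metrics import roc_auc_score

    scores = rng.normal(size=200)
    labels = (scores + rng.normal(0, 1, 200) > 0).astype(int)
    assert roc_analysis(scores=scores, labels=labels).auc == pytest.approx(
        roc_auc_score(labels, scores)
    )


def test_roc_curve_monotone(rng):
    scores = rng.normal(size=100)
    labels = rng.integers(0, 2, size=100)
    res = roc_analysis(scores=scores, labels=labels)
    assert np.all(np.diff(res.sensitivity) <= 1e-12)  # non-increasing with cutoff
    assert np.all(np.diff(res.specificity) >= -1e-12)  # non-decreasing with cutoff


def test_operating_point_extremes_and_confusion_arithmetic(rng):
    scores = rng.normal(50, 5, 30)
    labels = rng.integers(0, 2, 30)
    below = operating_point(scores, labels, scores.min() - 1)
    assert below.sensitivity == 1.0 and below.specificity == 0.0
    above = operating_point(scores, labels, scores.max() + 1)
    assert above.sensitivity == 0.0 and above.specificity == 1.0

    # toy table TP=7 FP=1 FN=2 TN=5
    s = np.array([1.0] * 7 + [1.0] + [0.0] * 2 + [0.0] * 5)
    y = np.array([1] * 7 + [0] + [1] * 2 + [0] * 5)
    op = operating_point(s, y, 0.5)
    assert (op.tp, op.fp, op.fn, op.tn) == (7, 1, 2, 5)
    assert op.sensitivity == pytest.approx(7 / 9)
    assert op.specificity == pytest.approx(5 / 6)
    assert op.ppv == pytest.approx(7 / 8)
    assert op.npv == pytest.approx(5 / 7)


def test_ties_at_cutoff_called_negative():
    op = operating_point(np.array([1.0, 2.0]), np.array([1, 1]), 1.0)
    assert op.tp == 1 and op.fn == 1


# ------------------------------------------------------------- paired tests


def test_paired_identical_sides_zero_difference():
    df = pd.DataFrame(
        {
            "animal_id": ["a", "a", "b", "b"],
            "side": ["left", "right"] * 2,
            "corrected_hu": [50.0, 50.0, 60.0, 60.0],
        }
    )
    res = paired_side_test(df, "corrected_hu")
    assert res.mean_difference == 0.0


def test_paired_t_closed_form():
    # right-minus-left differences {1, 2, 3}: t = mean/(sd/sqrt(n)) = 2*sqrt(3)
    df = pd.DataFrame(
        {
            "animal_id": ["a", "a", "b", "b", "c", "c"],
            "side": ["left", "right"] * 3,
            "corrected_hu": [10.0, 11.0, 20.0, 22.0, 30.0, 33.0],
        }
    )
    res = paired_side_test(df, "corrected_hu")
    assert res.mean_difference == pytest.approx(2.0)
    assert res.t == pytest.approx(2 * np.sqrt(3))
    assert res.n_pairs == 3


def test_paired_detects_one_sd_shift_usually(rng):
    hits = 0
    n_rep = 100
    for _ in range(n_rep):
        left = rng.normal(50, 3, 10)
        right = left + rng.normal(3, 3, 10)  # shift = 1 SD of the difference
        df = pd.DataFrame(
            {
                "animal_id": np.repeat(np.arange(10), 2),
                "side": ["left", "right"] * 10,
                "corrected_hu": np.column_stack([left, right]).ravel(),
            }
        )
        if paired_side_test(df, "corrected_hu").p_value < 0.05:
            hits += 1
    assert hits / n_rep > 0.5


def test_paired_requires_complete_pairs():
    df = pd.DataFrame(
        {"animal_id": ["a", "b"], "side": ["left", "unknown"], "corrected_hu": [1.0, 2.0]}
    )
    with pytest.raises(ValueError):
        paired_side_test(df, "corrected_hu")


# -------------------------------------------------------- method correlation


def _method_frame(x1, x2, animals, sides=None):
    n = len(x1)
    return pd.DataFrame(
        {
            "animal_id": animals,
            "side": sides if sides is not None else ["left"] * n,
            "fibrosis_score": x1,
            "corrected_hu": x2,
        }
    )


def test_one_kidney_per_animal_equals_pearson(rng):
    from scipy import stats

    x1 = rng.normal(2, 1, 20)
    x2 = 40 + 8 * x1 + rng.normal(0, 3, 20)
    df = _method_frame(x1, x2, [f"a{i}" for i in range(20)])
    res = method_correlation(df)
    assert res.estimate == pytest.approx(stats.pearsonr(x1, x2)[0])
    assert "pearson" in res.model


def test_exactly_linear_methods_give_unit_correlation(rng):
    x1 = np.clip(rng.normal(2, 1, 40), 0, 4)
    animals = np.repeat([f"a{i}" for i in range(20)], 2)
    sides = ["left", "right"] * 20
    df = _method_frame(x1, 40 + 8 * x1, animals, sides)
    res = method_correlation(df)
    assert res.estimate == pytest.approx(1.0, abs=1e-4)
    assert res.pearson == pytest.approx(1.0)


def test_independent_methods_near_zero(rng):
    n = 200
    animals = np.repeat([f"a{i}" for i in range(n)], 2)
    sides = ["left", "right"] * n
    df = _method_frame(rng.normal(2, 1, 2 * n), rng.normal(50, 5, 2 * n), animals, sides)
    res = method_correlation(df)
    assert abs(res.estimate) <= 0.1
    assert abs(res.pearson) <= 0.1


def test_score_positive_subset_and_min_animals(cohort):
    from renalqct.correction import SizeCorrector

    df = SizeCorrector(A=8.5).fit(cohort).transform(cohort)
    res_all = method_correlation(df, subset="all")
    res_pos = method_correlation(df, subset="score>0")
    assert -1 <= res_pos.estimate <= 1
    assert res_pos.n_kidneys <= res_all.n_kidneys
    with pytest.raises(ValueError, match="3 animals"):
        method_correlation(df[df["animal_id"] == df["animal_id"].iloc[0]])


# ------------------------------------------------------------ group contrast


def test_group_means_and_identical_groups():
    df = pd.DataFrame(
        {
            "animal_id": list("abcd"),
            "side": ["left"] * 4,
            "group": ["tbi", "tbi", "chest", "chest"],
            "corrected_hu": [50.0, 52.0, 60.0, 62.0],
        }
    )
    res = group_comparison(df, ("tbi", "chest"))
    assert res.means == pytest.approx((51.0, 61.0))
    assert res.mean_difference == pytest.approx(-10.0)

    same = df.copy()
    same["corrected_hu"] = [50.0, 52.0, 50.0, 52.0]
    assert group_comparison(same, ("tbi", "chest")).mean_difference == pytest.approx(0.0)


def test_group_comparison_aggregates_kidneys_within_animal():
    df = pd.DataFrame(
        {
            "animal_id": ["a", "a", "b", "c"],
            "side": ["left", "right", "left", "left"],
            "group": ["tbi", "tbi", "tbi", "chest"],
            "corrected_hu": [40.0, 60.0, 50.0, 55.0],
        }
    )
    res = group_comparison(df, ("tbi", "chest"))
    assert res.means[0] == pytest.approx(50.0)  # (mean(40,60), 50) -> 50
    assert res.n_animals == (2, 1)


def test_group_comparison_detects_6hu_shift_mostly(rng):
    hits = 0
    n_rep = 100
    for _ in range(n_rep):
        df = pd.DataFrame(
            {
                "animal_id": [f"a{i}" for i in range(20)],
                "side": ["left"] * 20,
                "group": ["tbi"] * 10 + ["chest"] * 10,
                "corrected_hu": np.concatenate(
                    [rng.normal(56, 3, 10), rng.normal(50, 3, 10)]
                ),
            }
        )
        if group_comparison(df, ("tbi", "chest")).p_value < 0.05:
            hits += 1
    assert hits / n_rep > 0.5


def test_group_comparison_empty_group_raises():
    df = pd.DataFrame(
        {
            "animal_id": ["a"],
            "side": ["left"],
            "group": ["tbi"],
            "corrected_hu": [50.0],
        }
    )
    with pytest.raises(ValueError, match="empty"):
        group_comparison(df, ("tbi", "chest"))
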