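"""ROC/Youden, agreement, correlation, group tests, regression diagnostics."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mhri import cohort as ch
from mhri import prognostats as ps


# ----------------------------------------------------------------- ROC


def _auc_pairwise(scores, labels):
    """Exhaustive pairwise win fraction (ties 0.5) — the AUC definition."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p, n in itertools.product(pos, neg))
    return wins / (len(pos) * len(neg))


def test_roc_perfect_separation():
    r = ps.roc_analysis([1, 2, 3, 4], [0, 0, 1, 1], n_boot=50)
    assert r.auc == 1.0
    assert r.youden_j == 1.0 and r.sensitivity == 1.0 and r.specificity == 1.0
    assert 2 < r.cutoff < 3  # midpoint between the classes
    assert r.direction == "higher"


def test_roc_chance_level_by_enumeration():
    # pairs: (1,3) loss, (1,2) loss, (4,3) win, (4,2) win -> AUC 0.5
    r = ps.roc_analysis([3, 1, 2, 4], [0, 1, 0, 1], n_boot=50)
    assert r.auc == 0.5
    assert r.auc == _auc_pairwise([3, 1, 2, 4], [0, 1, 0, 1])


def test_roc_all_ties_degenerate():
    r = ps.roc_analysis([5, 5, 5, 5], [0, 1, 0, 1])
    assert r.degenerate and r.auc == 0.5 and math.isnan(r.cutoff)
    assert r.youden_j == 0.0


def test_roc_matches_pairwise_oracle_on_random_instances(rng):
    """AUC equals the exhaustive pairwise win fraction on 100 instances."""
    for _ in range(100):
        n = int(rng.integers(4, 31))
        labels = np.zeros(n, bool)
        labels[: int(rng.integers(1, n))] = True
        rng.shuffle(labels)
        scores = rng.choice(np.arange(10), size=n).astype(float)  # many ties
        if np.unique(scores).size < 2:
            continue
        r = ps.roc_analysis(scores, labels, positive_orientation="higher", n_boot=10)
        assert r.auc == pytest.approx(_auc_pairwise(scores, labels), abs=1e-12)


def test_roc_invariance_under_monotone_transform(rng):
    scores = rng.normal(size=60)
    labels = rng.random(60) < 0.4
    if labels.sum() in (0, 60):
        labels[0] = ~labels[0]
    a = ps.roc_analysis(scores, labels, n_boot=10)
    b = ps.roc_analysis(np.exp(3 * scores), labels, n_boot=10)
    assert a.auc == pytest.approx(b.auc, abs=1e-12)
    assert a.sensitivity == pytest.approx(b.sensitivity)
    assert a.specificity == pytest.approx(b.specificity)


def test_roc_auto_orientation_flips_lower_is_positive(rng):
    pos = rng.normal(1.4, 0.2, size=40)   # lower scores in positives
    neg = rng.normal(2.2, 0.3, size=10)
    scores = np.concatenate([pos, neg])
    labels = np.concatenate([np.ones(40, bool), np.zeros(10, bool)])
    r = ps.roc_analysis(scores, labels, n_boot=50)
    assert r.direction == "lower" and r.auc > 0.9
    # the rule "score < cutoff predicts positive" reproduces sens/spec
    pred = scores < r.cutoff
    assert np.mean(pred[labels]) == pytest.approx(r.sensitivity)
    assert np.mean(~pred[~labels]) == pytest.approx(r.specificity)


def test_roc_errors():
    with pytest.raises(ValueError):
        ps.roc_analysis([1, 2, 3], [1, 1, 1])
    with pytest.raises(ValueError):
        ps.roc_analysis([1.0], [1])


def test_roc_delong_ci_brackets_auc(rng):
    scores = np.concatenate([rng.normal(1, 1, 50), rng.normal(0, 1, 50)])
    labels = np.concatenate([np.ones(50, bool), np.zeros(50, bool)])
    r = ps.roc_analysis(scores, labels, ci_method="delong")
    assert r.auc_ci_low < r.auc < r.auc_ci_high


def test_youden_from_rates_worked_values():
    assert ps.youden_from_rates(0.91, 1.00) == pytest.approx(0.91)
    assert ps.youden_from_rates(1.0, 1.0) == pytest.approx(1.0)
    assert round(ps.youden_from_rates(0.923, 0.789), 2) == 0.71
    with pytest.raises(ValueError):
        ps.youden_from_rates(1.2, 0.5)


# ------------------------------------------------------------ agreement


def test_bland_altman_identical_raters():
    r = ps.bland_altman([1.0, 1.2, 1.4], [1.0, 1.2, 1.4])
    assert r.bias == 0 and r.loa_low == 0 and r.loa_high == 0


def test_bland_altman_hand_computation():
    r1 = np.array([1.0, 2.0, 3.0, 4.0])
    r2 = r1 - np.array([1.0, -1.0, 1.0, -1.0])
    r = ps.bland_altman(r1, r2)
    sd = math.sqrt(4 / 3)  # sample SD of [1,-1,1,-1]
    assert r.bias == pytest.approx(0.0)
    assert r.loa_high == pytest.approx(1.96 * sd)
    assert r.loa_low == pytest.approx(-1.96 * sd)


def test_bland_altman_constant_offset():
    r = ps.bland_altman([1.1, 1.2, 1.3], [1.0, 1.1, 1.2])
    assert r.bias == pytest.approx(0.1)
    assert r.loa_high - r.loa_low == pytest.approx(0.0, abs=1e-9)


def test_bland_altman_length_mismatch():
    with pytest.raises(ValueError):
        ps.bland_altman([1, 2], [1, 2, 3])


def test_icc_identical_raters_is_one():
    x = np.arange(10, dtype=float)
    value, label = ps.icc(np.column_stack([x, x]))
    assert value == pytest.approx(1.0)
    assert "ICC(2,1)" in label


def test_icc_increases_as_rater_noise_vanishes(rng):
    subject = rng.normal(size=200)
    values = []
    for sd in (1.0, 0.3, 0.1, 0.01):
        ratings = subject[:, None] + rng.normal(0, sd, size=(200, 2))
        values.append(ps.icc(ratings)[0])
    assert values == sorted(values)
    assert values[-1] > 0.99


def test_icc_independent_noise_is_near_zero(rng):
    ratings = rng.normal(size=(500, 2))
    assert abs(ps.icc(ratings)[0]) < 0.1


def test_icc_matches_pingouin():
    pg = pytest.importorskip("pingouin")
    rng = np.random.default_rng(0)
    ratings = rng.normal(size=(25, 3)) + rng.normal(size=(25, 1))
    long = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(25), 3),
            "rater": np.tile(np.arange(3), 25),
            "score": ratings.ravel(),
        }
    )
    table = pg.intraclass_corr(long, targets="subject", raters="rater", ratings="score")
    # pingouin labels ICC(2,1) as ICC(A,1): two-way random, absolute agreement
    want = float(table.loc[table.Type == "ICC(A,1)", "ICC"].iloc[0])
    assert ps.icc(ratings)[0] == pytest.approx(want, abs=1e-9)


def test_icc_dimension_errors():
    with pytest.raises(ValueError):
        ps.icc(np.ones((2, 2)))
    with pytest.raises(ValueError):
        ps.icc(np.ones((5, 1)))


# ---------------------------------------------------------- correlations


def test_spearman_monotone_and_oracle():
    x = np.array([3.0, 1.0, 4.0, 1.5, 5.0, 9.0, 2.6])
    assert ps.spearman(x, x)[0] == pytest.approx(1.0)
    assert ps.spearman(x, -(x**3))[0] == pytest.approx(-1.0)
    y = np.array([2.0, 7.0, 1.0, 8.0, 2.8, 1.8, 3.1])
    # no ties: rho = 1 - 6*sum(d^2)/(n(n^2-1))
    d = sps.rankdata(x) - sps.rankdata(y)
    want = 1 - 6 * np.sum(d**2) / (7 * 48)
    assert ps.spearman(x, y)[0] == pytest.approx(want, abs=1e-12)


def test_spearman_constant_vector_errors():
    with pytest.raises(ValueError):
        ps.spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


# ----------------------------------------------------------- group tests


def test_identical_groups_give_p_one():
    res = ps.mann_whitney(np.ones(10), np.ones(12))
    assert res["p_value"] == 1.0


def test_exact_mann_whitney_minimum_p_small_groups():
    """Complete separation at n=3 vs 45: exact two-sided p = 2/C(48,3)."""
    a = np.arange(3, dtype=float)
    b = np.arange(10, 55, dtype=float)
    res = ps.mann_whitney(a, b)
    assert "exact" in res["test"]
    assert res["p_value"] == pytest.approx(2 / math.comb(48, 3), rel=1e-12)


def test_normal_groups_dispatch_to_t_test(rng):
    a = rng.normal(0, 1, 40)
    b = rng.normal(0.2, 1, 40)
    res = ps._two_sample_continuous(a, b)
    assert res["test"] == "student-t"
    want = sps.ttest_ind(a, b, equal_var=True)
    assert res["p_value"] == pytest.approx(want.pvalue)


def test_skewed_groups_dispatch_to_mann_whitney(rng):
    a = rng.exponential(1.0, 60)
    b = rng.exponential(1.5, 60)
    res = ps._two_sample_continuous(a, b)
    assert res["test"].startswith("mann-whitney")


def _hypergeom_fisher(table):
    """Two-sided Fisher p by summation over all tables with fixed margins."""
    (a, b), (c, d) = table
    n1, n2, m1 = a + b, c + d, a + c
    total = n1 + n2
    p_obs = sps.hypergeom.pmf(a, total, m1, n1)
    p = 0.0
    for x in range(max(0, m1 - n2), min(m1, n1) + 1):
        px = sps.hypergeom.pmf(x, total, m1, n1)
        if px <= p_obs * (1 + 1e-9):
            p += px
    return min(p, 1.0)


def test_fisher_matches_hypergeometric_enumeration(rng):
    tables = [[[2, 1], [27, 18]]] + [
        rng.integers(0, 12, size=(2, 2)).tolist() for _ in range(30)
    ]
    for t in tables:
        if min(sum(t[0]), sum(t[1]), t[0][0] + t[1][0], t[0][1] + t[1][1]) == 0:
            continue
        got = ps._fisher_2x2(t)["p_value"]
        assert got == pytest.approx(_hypergeom_fisher(t), rel=1e-9)


def test_group_tests_table(rng):
    df = ch.cohort_to_frame(ch.generate_cohort(ch.CohortConfig(n_eyes=60, seed=9)))
    table = ps.group_tests(df, grouping="closure")
    assert {"variable", "test", "p_value"} <= set(table.columns)
    assert "mhri" in set(table.variable)
    assert (table.p_value.dropna() <= 1).all()
    with pytest.raises(ValueError):
        ps.group_tests(df.assign(closure="success"), grouping="closure")


def test_paired_prepost():
    pre = np.array([0.9, 1.0, 0.8, 1.2, 0.7])
    post = pre - np.array([0.5, 0.3, 0.6, 0.4, 0.2])
    res = ps.paired_prepost_test(pre, post)
    want = sps.ttest_rel(pre, post)
    assert res["p_value"] == pytest.approx(want.pvalue)


# ------------------------------------------------------------ regression


def test_orthogonal_predictors_have_unit_vif(rng):
    n = 64
    M = rng.normal(size=(n, 3))
    # centred orthonormal columns: orthogonal to each other and the intercept
    X = np.linalg.qr(M - M.mean(axis=0))[0]
    df = pd.DataFrame(X, columns=["mhri", "mld_um", "age_years"])
    df["post_va_logmar"] = X @ [0.5, 0.2, -0.1] + rng.normal(0, 0.01, n)
    res = ps.fit_postva_regression(df, predictors=("mhri", "mld_um", "age_years"))
    for stats in res.predictors.values():
        assert stats.vif == pytest.approx(1.0, abs=1e-6)
        assert stats.tolerance == pytest.approx(1.0, abs=1e-6)


def test_duplicated_predictor_is_rank_deficiency_error(rng):
    n = 50
    df = pd.DataFrame({"mhri": rng.normal(size=n)})
    df["mld_um"] = df["mhri"]
    df["post_va_logmar"] = rng.normal(size=n)
    with pytest.raises(ValueError, match="mhri~mld_um"):
        ps.fit_postva_regression(df, predictors=("mhri", "mld_um"))


def test_tolerance_is_reciprocal_vif():
    assert round(ps.tolerance_from_vif(1.13), 2) == 0.88
    with pytest.raises(ValueError):
        ps.tolerance_from_vif(0.5)


def test_regression_recovers_known_betas():
    """OLS on a large uncensored simulated cohort recovers the generating
    coefficients within 3 standard errors."""
    vm = ch.VAModel(intercept=0.5, beta_mhri=0.58, beta_mld=0.003,
                    beta_preva=0.2, residual_sd=0.1)
    cfg = ch.CohortConfig(n_eyes=2000, va_model=vm, seed=10)
    df = ch.cohort_to_frame(ch.generate_cohort(cfg))
    res = ps.fit_postva_regression(df)
    truth = {"mhri": vm.beta_mhri, "mld_um": vm.beta_mld,
             "pre_va_logmar": vm.beta_preva, "age_years": 0.0, "surgery_vitx_pe": 0.0}
    for name, beta in truth.items():
        stats = res.predictors[name]
        se = (stats.ci_high - stats.ci_low) / (2 * 1.96)
        assert abs(stats.coefficient - beta) < 3 * se, name


# --------------------------------------------------------------- outcomes


def test_classify_outcomes_boundary_and_denominator():
    df = pd.DataFrame(
        {
            "closure": ["success", "success", "failure"],
            "post_va_logmar": [0.3, 0.4, 0.1],
        }
    )
    out = ps.classify_outcomes(df)
    assert out.visual_success.tolist()[:2] == [True, False]
    assert pd.isna(out.visual_success.iloc[2])  # failures never counted
    closed = out[out.closure_success]
    assert len(closed) == 2  # the visual-success denominator
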