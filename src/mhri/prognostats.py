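"""Prognostic statistics for macular-hole cohorts.

Everything the outcome analysis needs: ROC curves with Youden-index cutoffs
(AUC as the tie-aware Mann-Whitney statistic, bootstrap or DeLong CIs),
Bland-Altman limits of agreement, ICC(2,1) inter-rater agreement, Spearman
correlation, normality-dispatched two-group tests (Student t / Mann-Whitney /
Fisher exact), paired pre/post comparison, and the multiple linear regression
of post-operative VA with VIF/tolerance collinearity diagnostics.

No multiple-testing correction is applied anywhere; reported p-values are
per-comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_auc_score
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import variance_inflation_factor

__all__ = [
    "RocResult",
    "BlandAltmanResult",
    "AgreementResult",
    "RegressionResult",
    "roc_analysis",
    "youden_from_rates",
    "tolerance_from_vif",
    "bland_altman",
    "icc",
    "spearman",
    "mann_whitney",
    "group_tests",
    "paired_prepost_test",
    "fit_postva_regression",
    "classify_outcomes",
]


# ---------------------------------------------------------------- ROC / Youden


@dataclass(frozen=True)
class RocResult:
    auc: float
    auc_ci_low: float
    auc_ci_high: float
    cutoff: float
    youden_j: float
    sensitivity: float
    specificity: float
    direction: str  # 'higher' or 'lower' raw score predicts the positive class
    p_value: float
    n_positive: int
    n_negative: int
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.auc <= 1:
            raise ValueError("AUC outside [0, 1]")
        if abs(self.youden_j - (self.sensitivity + self.specificity - 1)) > 1e-9:
            raise ValueError("Youden J must equal sensitivity + specificity - 1")


def youden_from_rates(sensitivity: float, specificity: float) -> float:
    """Youden's index J = sensitivity + specificity - 1."""
    for name, v in (("sensitivity", sensitivity), ("specificity", specificity)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    return sensitivity + specificity - 1


def tolerance_from_vif(vif: float) -> float:
    """Collinearity tolerance, the reciprocal of the variance inflation factor."""
    if vif < 1:
        raise ValueError("VIF cannot be below 1")
    return 1.0 / vif


def _auc_mw(x: np.ndarray, y: np.ndarray) -> float:
    """Tie-aware AUC of positives x vs negatives y via mid-ranks (the
    normalized Mann-Whitney statistic); used in the bootstrap loop."""
    ranks = sps.rankdata(np.concatenate([x, y]))
    m = len(x)
    u = ranks[:m].sum() - m * (m + 1) / 2
    return u / (m * len(y))


def _sens_spec(oriented: np.ndarray, pos: np.ndarray, threshold: float) -> tuple[float, float]:
    pred = oriented > threshold
    sens = float(np.mean(pred[pos]))
    spec = float(np.mean(~pred[~pos]))
    return sens, spec


def roc_analysis(
    scores,
    labels,
    positive_orientation: str = "auto",
    n_boot: int = 2000,
    seed: int = 0,
    ci_method: str = "bootstrap",
) -> RocResult:
    """ROC analysis with a Youden-maximal cutoff.

    AUC is the normalized Mann-Whitney statistic (ties count 0.5). Cutoff
    candidates are midpoints between consecutive distinct sorted scores; ties
    in J are broken toward higher specificity, then the lower threshold.
    ``positive_orientation`` is 'higher', 'lower' or 'auto' (flip so that
    AUC >= 0.5, recording the flip in ``direction``). The reported cutoff is
    on the original score scale: for direction='lower' the positive-class
    rule is score < cutoff. The AUC CI is a seeded stratified bootstrap
    (percentile, ``n_boot`` replicates) or DeLong (``ci_method='delong'``);
    the p-value is the two-sided Mann-Whitney test between classes.
    """
    scores = np.asarray(scores, dtype=float)
    pos = np.asarray(labels, dtype=bool)
    if scores.shape != pos.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D arrays")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    if scores.size < 2:
        raise ValueError("need at least two observations")

    if np.unique(scores).size < 2:
        # tie-only case: no discriminative cutoff exists
        return RocResult(
            auc=0.5, auc_ci_low=0.5, auc_ci_high=0.5, cutoff=float("nan"),
            youden_j=0.0, sensitivity=1.0, specificity=0.0,
            direction="higher", p_value=1.0, n_positive=n_pos, n_negative=n_neg,
            degenerate=True,
        )

    raw_auc = float(roc_auc_score(pos, scores))
    if positive_orientation == "higher":
        flip = False
    elif positive_orientation == "lower":
        flip = True
    elif positive_orientation == "auto":
        flip = raw_auc < 0.5
    else:
        raise ValueError("positive_orientation must be 'higher', 'lower' or 'auto'")
    oriented = -scores if flip else scores
    auc = float(roc_auc_score(pos, oriented))

    distinct = np.unique(oriented)
    candidates = 0.5 * (distinct[:-1] + distinct[1:])
    best = None
    for t in candidates:
        sens, spec = _sens_spec(oriented, pos, t)
        j = sens + spec - 1
        key = (round(j, 12), round(spec, 12), -t)  # maximize J, then spec, then lower t
        if best is None or key > best[0]:
            best = (key, t, j, sens, spec)
    _, t_star, j, sens, spec = best

    mw = sps.mannwhitneyu(scores[pos], scores[~pos], alternative="two-sided")
    if ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        x, y = oriented[pos], oriented[~pos]
        boots = np.empty(n_boot)
        for b in range(n_boot):
            boots[b] = _auc_mw(
                x[rng.integers(0, n_pos, n_pos)], y[rng.integers(0, n_neg, n_neg)]
            )
        lo, hi = (float(v) for v in np.percentile(boots, [2.5, 97.5]))
    elif ci_method == "delong":
        lo, hi = _delong_ci(oriented, pos)
    else:
        raise ValueError("ci_method must be 'bootstrap' or 'delong'")

    return RocResult(
        auc=auc,
        auc_ci_low=max(0.0, lo),
        auc_ci_high=min(1.0, hi),
        cutoff=float(-t_star if flip else t_star),
        youden_j=float(j),
        sensitivity=float(sens),
        specificity=float(spec),
        direction="lower" if flip else "higher",
        p_value=float(mw.pvalue),
        n_positive=n_pos,
        n_negative=n_neg,
    )


def _delong_ci(oriented: np.ndarray, pos: np.ndarray, level: float = 0.95):
    """DeLong variance of the AUC via placement values (mid-ranks for ties)."""
    x, y = oriented[pos], oriented[~pos]  # positives, negatives
    m, n = len(x), len(y)

    def placements(a, b):
        # for each a_i: fraction of b below it, ties 0.5
        order = np.sort(b)
        lo = np.searchsorted(order, a, side="left")
        hi = np.searchsorted(order, a, side="right")
        return (lo + 0.5 * (hi - lo)) / len(b)

    v10 = placements(x, y)
    v01 = 1.0 - placements(y, x)
    auc = float(np.mean(v10))
    var = np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n
    z = sps.norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(max(var, 0.0))
    return auc - half, auc + half


# ------------------------------------------------------------------ agreement


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    loa_low: float
    loa_high: float
    means: np.ndarray
    differences: np.ndarray

    def __post_init__(self) -> None:
        if not self.loa_low <= self.bias <= self.loa_high:
            raise ValueError("limits of agreement must bracket the bias")


@dataclass(frozen=True)
class AgreementResult:
    icc_value: float
    icc_model_label: str
    bias: float
    loa_low: float
    loa_high: float


def bland_altman(values_rater1, values_rater2) -> BlandAltmanResult:
    """Bland-Altman agreement: bias = mean(r1 - r2), 95% limits of agreement
    = bias ± 1.96 × sample SD (ddof 1) of the differences."""
    r1 = np.asarray(values_rater1, dtype=float)
    r2 = np.asarray(values_rater2, dtype=float)
    if r1.shape != r2.shape or r1.ndim != 1:
        raise ValueError("rater vectors must be equal-length 1-D arrays")
    if r1.size < 2:
        raise ValueError("need at least two paired measurements")
    diff = r1 - r2
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return BlandAltmanResult(
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        means=0.5 * (r1 + r2),
        differences=diff,
    )


def icc(ratings, model: str = "ICC(2,1)") -> tuple[float, str]:
    """Intraclass correlation from a subjects × raters matrix.

    Default ICC(2,1): two-way random effects, absolute agreement, single
    measurement, computed from the two-way ANOVA mean squares. ICC(3,1)
    (two-way mixed, consistency) is also available. Returns (value, label).
    """
    X = np.asarray(ratings, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3 or X.shape[1] < 2:
        raise ValueError("ratings must be an n>=3 subjects by k>=2 raters matrix")
    if not np.all(np.isfinite(X)):
        raise ValueError("ratings must not contain missing values")
    n, k = X.shape
    grand = X.mean()
    row_m = X.mean(axis=1)
    col_m = X.mean(axis=0)
    ss_rows = k * np.sum((row_m - grand) ** 2)
    ss_cols = n * np.sum((col_m - grand) ** 2)
    ss_err = np.sum((X - row_m[:, None] - col_m[None, :] + grand) ** 2)
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if model in ("ICC(2,1)", "ICC2"):
        denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
        value = (msr - mse) / denom if denom > 0 else 1.0
        label = "ICC(2,1) two-way random, absolute agreement, single measurement"
    elif model in ("ICC(3,1)", "ICC3"):
        denom = msr + (k - 1) * mse
        value = (msr - mse) / denom if denom > 0 else 1.0
        label = "ICC(3,1) two-way mixed, consistency, single measurement"
    else:
        raise ValueError(f"unsupported ICC model {model!r}")
    return float(value), label


def rater_agreement(values_rater1, values_rater2, model: str = "ICC(2,1)") -> AgreementResult:
    """ICC plus Bland-Altman summary for one pair of raters."""
    value, label = icc(np.column_stack([values_rater1, values_rater2]), model=model)
    ba = bland_altman(values_rater1, values_rater2)
    return AgreementResult(
        icc_value=value, icc_model_label=label,
        bias=ba.bias, loa_low=ba.loa_low, loa_high=ba.loa_high,
    )


# --------------------------------------------------------------- correlations


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties), p by the
    t-approximation. Errors on constant input, where ranks are undefined."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("rank correlation undefined for a constant vector")
    res = sps.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------- group tests


def mann_whitney(a, b) -> dict:
    """Two-sided Mann-Whitney U test.

    Exact null distribution when min(n) <= 8 and there are no ties, otherwise
    the tie-corrected normal approximation. Fully tied data (every pooled
    value identical) is reported as degenerate with p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty group")
    pooled = np.concatenate([a, b])
    if np.unique(pooled).size == 1:
        return {
            "test": "mann-whitney (degenerate)",
            "statistic": float(a.size * b.size / 2),
            "p_value": 1.0,
        }
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (min(a.size, b.size) <= 8 and no_ties) else "asymptotic"
    r = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return {
        "test": f"mann-whitney ({method})",
        "statistic": float(r.statistic),
        "p_value": float(r.pvalue),
    }


def _two_sample_continuous(a: np.ndarray, b: np.ndarray, alpha: float = 0.05) -> dict:
    """Normality-dispatched two-group comparison of one continuous variable:
    Shapiro-Wilk on each group, Student's t if both pass at ``alpha``, else
    :func:`mann_whitney`."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty group")
    pooled = np.concatenate([a, b])
    if np.unique(pooled).size == 1:
        return mann_whitney(a, b)
    normal = (
        a.size >= 3
        and b.size >= 3
        and sps.shapiro(a).pvalue > alpha
        and sps.shapiro(b).pvalue > alpha
    )
    if normal:
        r = sps.ttest_ind(a, b, equal_var=True)
        return {"test": "student-t", "statistic": float(r.statistic), "p_value": float(r.pvalue)}
    return mann_whitney(a, b)


def _fisher_2x2(table) -> dict:
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2):
        raise ValueError("Fisher exact test needs a 2x2 table")
    odds, p = sps.fisher_exact(t, alternative="two-sided")
    return {"test": "fisher-exact", "statistic": float(odds), "p_value": float(p)}


def group_tests(
    records: pd.DataFrame,
    grouping: str = "closure",
    continuous_vars: tuple[str, ...] = (
        "age_years", "pre_va_logmar", "mld_um",
        "cri_max", "cri_mean", "pcri_min", "pcri_mean", "mhri", "post_va_logmar",
    ),
    categorical_vars: tuple[str, ...] = ("sex", "pseudophakic", "surgery"),
) -> pd.DataFrame:
    """Per-variable two-group comparison table (the Table-2-style analysis).

    Continuous variables are dispatched by Shapiro-Wilk normality to Student's
    t or Mann-Whitney; binary categorical variables go to Fisher's exact test
    on the 2×2 contingency table. Returns one row per variable with the test
    used, its statistic, the p-value, and group summaries.
    """
    levels = records[grouping].dropna().unique()
    if len(levels) != 2:
        raise ValueError(f"grouping {grouping!r} must have exactly 2 levels, got {list(levels)}")
    g1 = records[records[grouping] == levels[0]]
    g2 = records[records[grouping] == levels[1]]
    if len(g1) == 0 or len(g2) == 0:
        raise ValueError("empty group")
    rows = []
    for var in continuous_vars:
        if var not in records.columns:
            continue
        res = _two_sample_continuous(g1[var].to_numpy(), g2[var].to_numpy())
        rows.append({
            "variable": var,
            f"{levels[0]}_mean": float(g1[var].mean()),
            f"{levels[0]}_sd": float(g1[var].std(ddof=1)),
            f"{levels[1]}_mean": float(g2[var].mean()),
            f"{levels[1]}_sd": float(g2[var].std(ddof=1)),
            **res,
        })
    for var in categorical_vars:
        if var not in records.columns:
            continue
        cats = records[var].dropna().unique()
        if len(cats) != 2:
            continue
        table = [
            [int((g[var] == cats[0]).sum()), int((g[var] == cats[1]).sum())]
            for g in (g1, g2)
        ]
        rows.append({"variable": var, **_fisher_2x2(table)})
    return pd.DataFrame(rows)


def paired_prepost_test(pre, post) -> dict:
    """Paired-sample t-test for the pre- vs post-operative comparison."""
    r = sps.ttest_rel(np.asarray(pre, float), np.asarray(post, float))
    return {"test": "paired-t", "statistic": float(r.statistic), "p_value": float(r.pvalue)}


# ----------------------------------------------------------------- regression


@dataclass(frozen=True)
class PredictorStats:
    coefficient: float
    ci_low: float
    ci_high: float
    p_value: float
    vif: float
    tolerance: float

    def __post_init__(self) -> None:
        if abs(self.tolerance * self.vif - 1.0) > 1e-9:
            raise ValueError("tolerance must be the reciprocal of VIF")
        if not self.ci_low <= self.coefficient <= self.ci_high:
            raise ValueError("CI must bracket the coefficient")


@dataclass(frozen=True)
class RegressionResult:
    predictors: dict[str, PredictorStats]
    intercept: float
    r_squared: float
    n: int


DEFAULT_PREDICTORS = ("mhri", "mld_um", "age_years", "pre_va_logmar", "surgery_vitx_pe")


def fit_postva_regression(
    records: pd.DataFrame,
    predictors: tuple[str, ...] = DEFAULT_PREDICTORS,
    outcome: str = "post_va_logmar",
) -> RegressionResult:
    """OLS of post-operative VA on the indices and covariates.

    Restricted to anatomical-closure successes (the visual analyses exclude
    failed holes). Surgery type is coded 0/1 as ``surgery_vitx_pe``.
    Per-coefficient 95% CIs come from the t distribution; VIFs from the
    auxiliary regressions among predictors (constant included); tolerance is
    1/VIF. Raises on a rank-deficient design, naming the collinear columns.
    """
    df = records
    if "closure" in df.columns:
        df = df[df["closure"] == "success"]
    df = df.copy()
    if "surgery_vitx_pe" in predictors and "surgery_vitx_pe" not in df.columns:
        if "surgery" not in df.columns:
            raise ValueError("records must carry 'surgery' or 'surgery_vitx_pe'")
        df["surgery_vitx_pe"] = (df["surgery"] == "vitx_pe").astype(float)
    missing = [p for p in predictors if p not in df.columns]
    if missing:
        raise ValueError(f"missing predictor columns: {missing}")
    if len(df) <= len(predictors) + 1:
        raise ValueError("not enough rows to fit the regression")
    X = df.loc[:, list(predictors)].astype(float)
    exog = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(exog.to_numpy())
    if rank < exog.shape[1]:
        corr = X.corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        pairs = [
            f"{a}~{b}" for a in corr.index for b in corr.columns
            if a < b and corr.loc[a, b] > 0.999999
        ]
        raise ValueError(f"rank-deficient design; collinear columns: {pairs or list(predictors)}")
    fit = sm.OLS(df[outcome].astype(float), exog).fit()
    ci = fit.conf_int(alpha=0.05)
    stats: dict[str, PredictorStats] = {}
    for j, name in enumerate(predictors, start=1):  # column 0 is the constant
        v = float(variance_inflation_factor(exog.to_numpy(), j))
        stats[name] = PredictorStats(
            coefficient=float(fit.params[name]),
            ci_low=float(ci.loc[name, 0]),
            ci_high=float(ci.loc[name, 1]),
            p_value=float(fit.pvalues[name]),
            vif=v,
            tolerance=1.0 / v,
        )
    return RegressionResult(
        predictors=stats,
        intercept=float(fit.params["const"]),
        r_squared=float(fit.rsquared),
        n=int(fit.nobs),
    )


# -------------------------------------------------------------------- outcomes

VISUAL_SUCCESS_LOGMAR = 0.3  # post-op VA <= 0.3 logMAR, boundary inclusive


def classify_outcomes(records: pd.DataFrame) -> pd.DataFrame:
    """Add outcome labels: ``closure_success`` (bool) for every eye and
    ``visual_success`` (bool, post-VA <= 0.3 logMAR inclusive) defined only
    among closed eyes — failures get NA and never enter visual denominators."""
    out = records.copy()
    out["closure_success"] = out["closure"] == "success"
    vs = out["post_va_logmar"] <= VISUAL_SUCCESS_LOGMAR
    out["visual_success"] = vs.where(out["closure_success"], other=pd.NA)
    return out
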