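"""Group-level inference for Fastball cohorts.

The inferential layer mirrors the study design: ANCOVA of f+ on group
and electrode controlling for the base-frequency response F,
Kruskal-Wallis tests with Bonferroni-corrected Mann-Whitney post hocs
for behavioural scores, case-resampling bootstrap regressions of
neuropsychological scores on Fastball outputs, pooled-SD Cohen's d,
and two-way intraclass correlations for test-retest reliability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

__all__ = [
    "ancova_group_by_electrode",
    "ancova_max_electrode",
    "kruskal_wallis_posthoc",
    "BootstrapRegressionResult",
    "bootstrap_regression",
    "cohens_d",
    "ICCResult",
    "icc_two_way",
    "icc_band",
]


def cohens_d(x, y) -> float:
    """Pooled-SD standardized mean difference (mean_x - mean_y) / s_p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError("need at least 2 observations per sample")
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    if sp2 == 0:
        return 0.0
    return float((x.mean() - y.mean()) / np.sqrt(sp2))


def _check_full_rank(exog: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        # name columns that are linear combinations of earlier ones
        aliased = []
        for j in range(1, exog.shape[1]):
            if np.linalg.matrix_rank(exog[:, : j + 1]) == np.linalg.matrix_rank(exog[:, :j]):
                aliased.append(names[j])
        raise ValueError(f"singular design; aliased terms: {aliased}")


def _pairwise_d(tbl: pd.DataFrame, outcome: str, group_col: str) -> dict[str, float]:
    per_subj = tbl.groupby(["subject_id", group_col], sort=False)[outcome].mean().reset_index()
    out = {}
    labels = list(dict.fromkeys(per_subj[group_col]))
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            out[f"{a} vs {b}"] = cohens_d(
                per_subj.loc[per_subj[group_col] == a, outcome],
                per_subj.loc[per_subj[group_col] == b, outcome],
            )
    return out


def ancova_group_by_electrode(
    tbl: pd.DataFrame,
    outcome: str = "f_plus",
    covariate: str = "F_snr",
    group_col: str = "group",
) -> dict:
    """Group x electrode ANCOVA on stacked per-electrode rows.

    Fits ``outcome ~ group + electrode + group:electrode + covariate``
    by OLS with sum-to-zero contrasts and Type-III sums of squares; no
    subject random effect is included, mirroring the stacked-row
    design. Returns the effect table plus pairwise Cohen's d between
    groups on the subject-level (electrode-averaged) outcome.
    """
    counts = tbl.groupby(["subject_id"])["electrode"].nunique()
    if counts.nunique() != 1:
        raise ValueError("unbalanced electrode coverage across subjects")
    formula = f"{outcome} ~ C({group_col}, Sum) * C(electrode, Sum) + {covariate}"
    model = smf.ols(formula, data=tbl)
    _check_full_rank(model.exog, list(model.exog_names))
    fit = model.fit()
    table = anova_lm(fit, typ=3)
    return {
        "anova": table,
        "cohens_d": _pairwise_d(tbl, outcome, group_col),
        "model": fit,
    }


def ancova_max_electrode(
    tbl: pd.DataFrame,
    outcome: str = "f_plus_max",
    covariate: str = "F_snr_scalp_avg",
    group_col: str = "group",
) -> dict:
    """One-way group ANCOVA on each subject's maximal-electrode f+."""
    per_subj = tbl.drop_duplicates("subject_id")[["subject_id", group_col, outcome, covariate]]
    formula = f"{outcome} ~ C({group_col}, Sum) + {covariate}"
    model = smf.ols(formula, data=per_subj)
    _check_full_rank(model.exog, list(model.exog_names))
    fit = model.fit()
    table = anova_lm(fit, typ=3)
    d = {}
    labels = list(dict.fromkeys(per_subj[group_col]))
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            d[f"{a} vs {b}"] = cohens_d(
                per_subj.loc[per_subj[group_col] == a, outcome],
                per_subj.loc[per_subj[group_col] == b, outcome],
            )
    return {"anova": table, "cohens_d": d, "model": fit}


def _mannwhitney_z(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """U of the first sample, tie-corrected normal-approximation Z and p."""
    n1, n2 = len(x), len(y)
    combined = np.r_[x, y]
    ranks = sps.rankdata(combined)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2
    mu = n1 * n2 / 2
    n = n1 + n2
    _, t = np.unique(combined, return_counts=True)
    tie_term = ((t**3 - t).sum()) / (n * (n - 1)) if n > 1 else 0.0
    sigma2 = n1 * n2 / 12 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return float(u1), 0.0, 1.0
    z = (u1 - mu) / np.sqrt(sigma2)
    p = 2 * sps.norm.sf(abs(z))
    return float(u1), float(z), float(p)


def kruskal_wallis_posthoc(
    tbl: pd.DataFrame,
    outcome: str,
    group_col: str = "group",
) -> dict:
    """Kruskal-Wallis across groups with Bonferroni Mann-Whitney post hocs.

    The omnibus H test uses scipy's tie-corrected statistic; pairwise
    two-sided Mann-Whitney U tests report tie-corrected normal
    approximation Z, with p multiplied by the number of pairwise
    comparisons (capped at 1).
    """
    labels = list(dict.fromkeys(tbl[group_col]))
    samples = [tbl.loc[tbl[group_col] == g, outcome].dropna().to_numpy() for g in labels]
    if any(len(s) == 0 for s in samples):
        raise ValueError("every group must be non-empty")
    H, p = sps.kruskal(*samples)
    pairs = []
    m = len(labels) * (len(labels) - 1) // 2
    for i, a in enumerate(labels):
        for j in range(i + 1, len(labels)):
            u, z, p_unc = _mannwhitney_z(samples[i], samples[j])
            pairs.append(
                {
                    "group1": a,
                    "group2": labels[j],
                    "U": u,
                    "Z": z,
                    "p": p_unc,
                    "p_bonferroni": min(1.0, m * p_unc),
                }
            )
    return {
        "H": float(H),
        "df": len(labels) - 1,
        "p": float(p),
        "posthoc": pd.DataFrame(pairs),
    }


@dataclass
class BootstrapRegressionResult:
    """OLS coefficients with case-resampling bootstrap inference."""

    terms: list[str]
    coef: pd.Series
    std_coef: pd.Series
    ci: pd.DataFrame           # columns lower, upper (raw coefficients)
    std_ci: pd.DataFrame
    p_boot: pd.Series
    B: int
    n: int
    seed: int


def bootstrap_regression(
    X: pd.DataFrame,
    y,
    B: int = 1000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> BootstrapRegressionResult:
    """OLS with percentile bootstrap CIs and p-values (case resampling).

    Rows with missing values are dropped (complete cases). Each of the
    B resamples refits ordinary least squares on subjects drawn with
    replacement; CIs are the 2.5/97.5 percentiles of the resampled
    coefficients and the bootstrap p-value is
    ``2 * min(P(b* <= 0), P(b* >= 0))`` with a +1 correction.
    Standardized coefficients rescale by the predictor and outcome SDs.
    """
    if B < 100:
        warnings.warn(f"B = {B} bootstrap samples is small; CIs will be unstable", stacklevel=2)
    X = pd.DataFrame(X).astype(float)
    y = pd.Series(np.asarray(y, dtype=float), index=X.index, name="y")
    keep = X.notna().all(axis=1) & y.notna()
    X, y = X.loc[keep], y.loc[keep]
    n, p = X.shape
    terms = ["intercept"] + list(X.columns)
    Z = np.column_stack([np.ones(n), X.to_numpy()])
    if np.linalg.matrix_rank(Z) < p + 1:
        raise ValueError("collinear predictors: design matrix is rank deficient")
    yv = y.to_numpy()
    beta = np.linalg.lstsq(Z, yv, rcond=None)[0]

    sy = yv.std(ddof=1)
    sx = X.to_numpy().std(axis=0, ddof=1)
    std_full = np.r_[np.nan, beta[1:] * sx / sy]

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(B, n))
    Zb = Z[idx]                      # (B, n, p+1)
    yb = yv[idx]                     # (B, n)
    G = np.einsum("bij,bik->bjk", Zb, Zb)
    h = np.einsum("bij,bi->bj", Zb, yb)
    try:
        betas = np.linalg.solve(G, h[..., None])[..., 0]
    except np.linalg.LinAlgError:
        betas = np.einsum("bjk,bk->bj", np.linalg.pinv(G), h)
    sxb = Zb[:, :, 1:].std(axis=1, ddof=1)
    syb = yb.std(axis=1, ddof=1)
    std_betas = betas[:, 1:] * sxb / syb[:, None]

    alpha = 1 - ci_level
    lo, hi = np.percentile(betas, [100 * alpha / 2, 100 * (1 - alpha / 2)], axis=0)
    slo, shi = np.percentile(std_betas, [100 * alpha / 2, 100 * (1 - alpha / 2)], axis=0)
    n_le = (betas <= 0).sum(axis=0)
    n_ge = (betas >= 0).sum(axis=0)
    p_boot = np.minimum(1.0, 2 * (1 + np.minimum(n_le, n_ge)) / (B + 1))

    return BootstrapRegressionResult(
        terms=terms,
        coef=pd.Series(beta, index=terms),
        std_coef=pd.Series(std_full, index=terms),
        ci=pd.DataFrame({"lower": lo, "upper": hi}, index=terms),
        std_ci=pd.DataFrame({"lower": slo, "upper": shi}, index=list(X.columns)),
        p_boot=pd.Series(p_boot, index=terms),
        B=B,
        n=n,
        seed=seed,
    )


@dataclass
class ICCResult:
    """Two-way mixed-model intraclass correlations with F-based CIs."""

    icc_single_consistency: float
    icc_single_agreement: float
    icc_average_consistency: float
    icc_average_agreement: float
    ci: dict[str, tuple[float, float]]
    bands: dict[str, str]
    bias_F: tuple[float, tuple[int, int], float]   # (statistic, (df1, df2), p)
    n_subjects: int
    k: int
    n_dropped: int = 0
    mean_squares: dict[str, float] = field(default_factory=dict)


def icc_band(value: float) -> str:
    """Interpretation band for an ICC.

    Below 0.40 poor; 0.41-0.59 moderate; 0.60-0.74 good; above 0.75
    excellent (values compared at two decimals).
    """
    r = round(value, 2)
    if r <= 0.40:
        return "poor"
    if r <= 0.59:
        return "moderate"
    if r <= 0.74:
        return "good"
    return "excellent"


def icc_two_way(matrix, alpha: float = 0.05) -> ICCResult:
    """Two-way mixed-model ICCs from a subjects x sessions matrix.

    Computes single- and average-measure consistency (C) and absolute
    agreement (A) coefficients from the two-way ANOVA mean squares
    (MSR rows, MSC columns, MSE error), with the standard F-based 95%
    confidence intervals and a session-bias F test (MSC / MSE).
    Subjects with missing sessions are dropped (complete cases).
    """
    M = np.asarray(matrix, dtype=float)
    if M.ndim != 2:
        raise ValueError("matrix must be subjects x sessions")
    complete = ~np.isnan(M).any(axis=1)
    n_dropped = int((~complete).sum())
    M = M[complete]
    n, k = M.shape
    if n < 3:
        raise ValueError("need at least 3 complete subjects")
    if k < 2:
        raise ValueError("need at least 2 sessions")

    grand = M.mean()
    row_means = M.mean(axis=1)
    col_means = M.mean(axis=0)
    ssr = k * ((row_means - grand) ** 2).sum()
    ssc = n * ((col_means - grand) ** 2).sum()
    sse = ((M - row_means[:, None] - col_means[None, :] + grand) ** 2).sum()
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))

    df1, df2 = n - 1, (n - 1) * (k - 1)
    q = 1 - alpha / 2
    if mse == 0:  # perfectly consistent sessions
        icc_c1 = icc_ck = 1.0
        ci_c1 = ci_ck = (1.0, 1.0)
    else:
        icc_c1 = (msr - mse) / (msr + (k - 1) * mse)
        icc_ck = (msr - mse) / msr
        # consistency CIs from F = MSR / MSE
        Fobs = msr / mse
        fl = Fobs / sps.f.ppf(q, df1, df2)
        fu = Fobs * sps.f.ppf(q, df2, df1)
        ci_c1 = ((fl - 1) / (fl + k - 1), (fu - 1) / (fu + k - 1))
        ci_ck = (1 - 1 / fl, 1 - 1 / fu)
    denom_a1 = msr + (k - 1) * mse + k * (msc - mse) / n
    icc_a1 = (msr - mse) / denom_a1 if denom_a1 > 0 else 1.0
    denom_ak = msr + (msc - mse) / n
    icc_ak = (msr - mse) / denom_ak if denom_ak > 0 else 1.0
    # agreement CIs via the Satterthwaite approximation
    r = icc_a1
    a = k * r / (n * (1 - r)) if r < 1 else np.inf
    b = 1 + k * r * (n - 1) / (n * (1 - r)) if r < 1 else np.inf
    if np.isfinite(a) and (msc > 0 or mse > 0):
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
        f_star = sps.f.ppf(q, df1, v)
        f_star2 = sps.f.ppf(q, v, df1)
        lower_a1 = n * (msr - f_star * mse) / (
            f_star * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        upper_a1 = n * (f_star2 * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_star2 * msr
        )
    else:
        lower_a1 = upper_a1 = 1.0
    sb = lambda x: k * x / (1 + (k - 1) * x)  # noqa: E731  Spearman-Brown
    ci_a1 = (float(lower_a1), float(upper_a1))
    ci_ak = (sb(lower_a1), sb(upper_a1))

    if mse == 0:
        bias_stat = np.inf if msc > 0 else np.nan
        bias_p = 0.0 if msc > 0 else float("nan")
    else:
        bias_stat = msc / mse
        bias_p = float(sps.f.sf(bias_stat, k - 1, df2))

    values = {
        "single_consistency": float(icc_c1),
        "single_agreement": float(icc_a1),
        "average_consistency": float(icc_ck),
        "average_agreement": float(icc_ak),
    }
    return ICCResult(
        icc_single_consistency=values["single_consistency"],
        icc_single_agreement=values["single_agreement"],
        icc_average_consistency=values["average_consistency"],
        icc_average_agreement=values["average_agreement"],
        ci={
            "single_consistency": tuple(map(float, ci_c1)),
            "single_agreement": ci_a1,
            "average_consistency": tuple(map(float, ci_ck)),
            "average_agreement": tuple(map(float, ci_ak)),
        },
        bands={name: icc_band(v) for name, v in values.items()},
        bias_F=(float(bias_stat), (k - 1, df2), bias_p),
        n_subjects=n,
        k=k,
        n_dropped=n_dropped,
        mean_squares={"msr": float(msr), "msc": float(msc), "mse": float(mse)},
    )
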