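"""Covariate-adjusted cohort statistics.

One-way ANCOVA with the pre-viewing baseline as covariate (homogeneous
slopes), Bonferroni-corrected significance per outcome family, partial
eta-squared effect sizes, and partial correlations between SSQ scores and
cardiac features with the baseline residualized out.

The two post-viewing conditions are compared as independent groups, matching
the degrees of freedom reported for this design (df2 = n - 3 with n pooled
observations); within-subject dependence across conditions is deliberately
not modeled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as spstats

from vimshrv.synthetic_data import CohortDataset

__all__ = [
    "AncovaResult",
    "PartialCorrResult",
    "StatsTables",
    "ancova",
    "partial_eta_squared",
    "bonferroni_alpha",
    "partial_correlation",
    "interpret_effect_size",
    "run_feature_stats",
    "CARDIAC_FEATURES",
    "SSQ_OUTCOMES",
]

CARDIAC_FEATURES = ("heart_rate", "sdnn", "pnn50", "ln_vlf", "ln_hf", "ln_ratio")
SSQ_OUTCOMES = ("ssq_n", "ssq_o", "ssq_d", "ssq_total")


@dataclass(frozen=True)
class AncovaResult:
    f_stat: float
    df1: int
    df2: int
    p_value: float
    eta_p2: float
    adjusted_means: dict[str, float]


@dataclass(frozen=True)
class PartialCorrResult:
    r: float
    p_value: float
    df: int
    interpretation: str


def ancova(post: np.ndarray, group: np.ndarray, baseline: np.ndarray) -> AncovaResult:
    """One-way ANCOVA of post-viewing values on a binary group with baseline covariate.

    Fits ``post ~ intercept + group + baseline`` by OLS and F-tests the group
    term (df1 = 1, df2 = n - 3). Partial eta-squared is computed from the
    effect and error sums of squares; adjusted group means are evaluated at
    the grand covariate mean.

    Raises
    ------
    ValueError
        On length mismatch, fewer than 2 observations in either group, or a
        singular design (covariate collinear with the group coding).
    """
    post = np.asarray(post, dtype=float)
    baseline = np.asarray(baseline, dtype=float)
    group = np.asarray(group)
    if not (post.shape == baseline.shape == group.shape):
        raise ValueError("post, group, and baseline must have equal length")
    if np.any(~np.isfinite(post)) or np.any(~np.isfinite(baseline)):
        raise ValueError("missing values are not allowed")
    levels = np.unique(group)
    if levels.size != 2:
        raise ValueError(f"group must be binary, got levels {levels}")
    g = (group == levels[1]).astype(float)
    if min((g == 0).sum(), (g == 1).sum()) < 2:
        raise ValueError("need at least 2 observations per group")
    design = sm.add_constant(np.column_stack([g, baseline]))
    if np.linalg.matrix_rank(design) < 3:
        raise ValueError("singular design: covariate collinear with group coding")
    fit = sm.OLS(post, design).fit()
    n = post.size
    df1, df2 = 1, n - 3
    # F of the group term = squared t of its coefficient in the full model
    t_group = fit.tvalues[1]
    f_stat = float(t_group**2)
    p_value = float(spstats.f.sf(f_stat, df1, df2))
    sse = float(fit.ssr)
    ss_effect = f_stat * df1 * sse / df2
    eta_p2 = ss_effect / (ss_effect + sse) if (ss_effect + sse) > 0 else 0.0
    grand_cov = float(baseline.mean())
    b0, b_group, b_cov = fit.params
    adjusted_means = {
        str(levels[0]): float(b0 + b_cov * grand_cov),
        str(levels[1]): float(b0 + b_group + b_cov * grand_cov),
    }
    return AncovaResult(
        f_stat=f_stat,
        df1=df1,
        df2=df2,
        p_value=p_value,
        eta_p2=float(eta_p2),
        adjusted_means=adjusted_means,
    )


def partial_eta_squared(f: float, df1: int, df2: int) -> float:
    """Partial eta-squared from an F statistic: ``F df1 / (F df1 + df2)``."""
    if f < 0:
        raise ValueError("F statistic must be non-negative")
    if df1 < 1 or df2 < 1:
        raise ValueError("degrees of freedom must be >= 1")
    return f * df1 / (f * df1 + df2)


def bonferroni_alpha(base_alpha: float = 0.05, n_tests: int = 1) -> float:
    """Family-wise corrected significance level ``base_alpha / n_tests``."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return base_alpha / n_tests


#: absolute-r bins -> qualitative correlation strength
_CORR_BINS = (
    (0.10, "negligible"),
    (0.40, "weak"),
    (0.70, "moderate"),
    (0.90, "strong"),
    (np.inf, "very strong"),
)


def interpret_correlation(r: float) -> str:
    a = abs(r)
    for upper, label in _CORR_BINS:
        if a < upper:
            return label
    return "very strong"


def partial_correlation(x: np.ndarray, y: np.ndarray, covariate: np.ndarray) -> PartialCorrResult:
    """Pearson correlation of x and y after regressing each on the covariate.

    df = n - 3; two-sided p via the t transform. Interpretation uses the
    |r| bins 0.00-0.09 negligible, 0.10-0.39 weak, 0.40-0.69 moderate,
    0.70-0.89 strong, 0.90-1.00 very strong.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    covariate = np.asarray(covariate, dtype=float)
    if not (x.shape == y.shape == covariate.shape):
        raise ValueError("x, y, covariate must have equal length")
    n = x.size
    if n < 4:
        raise ValueError("partial correlation needs n >= 4")
    for name, v in (("x", x), ("y", y), ("covariate", covariate)):
        if np.ptp(v) == 0:
            raise ValueError(f"{name} is constant")
    design = np.column_stack([np.ones(n), covariate])
    rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
    ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 3
    r_clamped = min(max(r, -1.0), 1.0)
    if abs(r_clamped) >= 1.0:
        p = 0.0
    else:
        t = r_clamped * np.sqrt(df / (1 - r_clamped**2))
        p = float(2 * spstats.t.sf(abs(t), df))
    return PartialCorrResult(r=r, p_value=p, df=df, interpretation=interpret_correlation(r))


def interpret_effect_size(eta_p2: float) -> str:
    """Qualitative effect-size bin: thresholds 0.01 / 0.06 / 0.14."""
    if not 0 <= eta_p2 <= 1:
        raise ValueError("eta_p2 must be in [0, 1]")
    if eta_p2 >= 0.14:
        return "large"
    if eta_p2 >= 0.06:
        return "medium"
    if eta_p2 >= 0.01:
        return "small"
    return "negligible"


@dataclass
class StatsTables:
    """ANCOVA table (10 outcomes) + partial-correlation table (6 features)."""

    ancova_table: pd.DataFrame
    correlation_table: pd.DataFrame


def _cell(table: pd.DataFrame, outcome: str, condition: str, phase: str) -> np.ndarray:
    sel = table[(table["condition"] == condition) & (table["phase"] == phase)]
    return sel.sort_values("subject")[outcome].to_numpy(dtype=float)


def run_feature_stats(cohort: CohortDataset) -> StatsTables:
    """ANCOVA + partial correlations across the cohort.

    For each of the 6 cardiac features and 4 SSQ outcomes, the two
    post-viewing conditions are compared with the matching pre-viewing values
    as covariate; significance is flagged at the family Bonferroni level
    (0.05/4 = 0.0125 for SSQ, 0.05/6 ~ 0.0083 for cardiac features). Partial
    correlations relate the post-viewing total SSQ to each post-viewing
    cardiac feature, residualizing the feature's own baseline.
    """
    table = cohort.table
    required = {"subject", "condition", "phase", *CARDIAC_FEATURES, *SSQ_OUTCOMES}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    if table[[*CARDIAC_FEATURES, *SSQ_OUTCOMES]].isna().any().any():
        raise ValueError("cohort table contains missing cells; extract features first")

    families = [("ssq", SSQ_OUTCOMES), ("cardiac", CARDIAC_FEATURES)]
    rows = []
    for family, outcomes in families:
        alpha = bonferroni_alpha(0.05, len(outcomes))
        for outcome in outcomes:
            post = np.concatenate(
                [_cell(table, outcome, "2D", "post"), _cell(table, outcome, "VR", "post")]
            )
            baseline = np.concatenate(
                [_cell(table, outcome, "2D", "pre"), _cell(table, outcome, "VR", "pre")]
            )
            group = np.array(["2D"] * (post.size // 2) + ["VR"] * (post.size // 2))
            res = ancova(post, group, baseline)
            rows.append(
                {
                    "outcome": outcome,
                    "family": family,
                    "f_stat": res.f_stat,
                    "df1": res.df1,
                    "df2": res.df2,
                    "p_value": res.p_value,
                    "eta_p2": res.eta_p2,
                    "effect_size": interpret_effect_size(res.eta_p2),
                    "alpha": alpha,
                    "significant": res.p_value < alpha,
                    "adjusted_mean_2D": res.adjusted_means["2D"],
                    "adjusted_mean_VR": res.adjusted_means["VR"],
                    "adjusted_diff_VR_minus_2D": res.adjusted_means["VR"]
                    - res.adjusted_means["2D"],
                }
            )
    ancova_table = pd.DataFrame(rows)

    corr_rows = []
    ssq_post = np.concatenate(
        [_cell(table, "ssq_total", "2D", "post"), _cell(table, "ssq_total", "VR", "post")]
    )
    for feature in CARDIAC_FEATURES:
        feat_post = np.concatenate(
            [_cell(table, feature, "2D", "post"), _cell(table, feature, "VR", "post")]
        )
        feat_pre = np.concatenate(
            [_cell(table, feature, "2D", "pre"), _cell(table, feature, "VR", "pre")]
        )
        res = partial_correlation(ssq_post, feat_post, feat_pre)
        corr_rows.append(
            {
                "feature": feature,
                "r": res.r,
                "p_value": res.p_value,
                "df": res.df,
                "interpretation": res.interpretation,
            }
        )
    return StatsTables(ancova_table=ancova_table, correlation_table=pd.DataFrame(corr_rows))
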