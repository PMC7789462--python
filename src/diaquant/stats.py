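"""Validation and cohort statistics.

Covers the study-style analysis chain: intraclass correlation (two-way
mixed-effects, absolute agreement, single measurement) and Bland-Altman for
measurement validation; Spearman correlations between MRI outcomes and
pulmonary-function values; covariate-adjusted multiple linear regression for
the three-group comparison with Bonferroni-corrected pairwise significance
(0.05 / 3 pairwise contrasts, i.e. p <= 0.017).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.formula.api as smf

#: Pairwise significance threshold after Bonferroni correction of 0.05 over
#: the three pairwise group contrasts.
BONFERRONI_ALPHA = 0.017

MRI_OUTCOMES = ("cc_ratio", "ap_ratio", "cc_ap_ratio", "area_ratio",
                "da_ratio", "dh_ratio", "ant_displacement_mm",
                "post_displacement_mm")
PFT_OUTCOMES = ("fvc_upright_pct", "fvc_supine_pct", "delta_fvc_pct",
                "mip_pct", "mep_pct")


class StatsError(ValueError):
    """Raised for invalid statistical inputs."""


@dataclass(frozen=True)
class PFTRecord:
    """Pulmonary-function values of one subject, as % of predicted."""

    subject_id: str
    fvc_upright_pct: float
    fvc_supine_pct: float
    mip_pct: float
    mep_pct: float
    delta_fvc_pct: float = field(default=math.nan)

    def __post_init__(self) -> None:
        expected = delta_fvc(self.fvc_upright_pct, self.fvc_supine_pct)
        if math.isnan(self.delta_fvc_pct):
            object.__setattr__(self, "delta_fvc_pct", expected)
        elif not math.isclose(self.delta_fvc_pct, expected, abs_tol=1e-9):
            raise StatsError("delta_fvc_pct must equal upright minus supine")


def delta_fvc(upright_pct: float, supine_pct: float) -> float:
    """Postural FVC drop: upright minus supine, in % of predicted.

    A large positive drop is a clinical marker of diaphragmatic weakness
    (the abdominal contents load the weak diaphragm when supine).
    """
    return upright_pct - supine_pct


def classify_subgroup(fvc_supine_pct: float, z: float) -> str:
    """Spirometry subgroup: normal iff FVC supine >= 80% and z >= -1.64."""
    if fvc_supine_pct >= 80.0 and z >= -1.64:
        return "normal_spiro"
    return "decreased_spiro"


# --------------------------------------------------------------------------
# measurement validation


@dataclass(frozen=True)
class ICCResult:
    """Single-measurement absolute-agreement ICC from a two-way model."""

    icc: float
    n_subjects: int
    n_raters: int
    model_tag: str = "two-way mixed, absolute agreement, single measurement"
    undefined: bool = False


def icc_absolute_agreement(measurements: np.ndarray) -> ICCResult:
    """ICC from a subjects x raters matrix of single measurements.

    Uses the two-way mean squares:
    ``(MS_s - MS_e) / (MS_s + (k-1) MS_e + (k/n)(MS_r - MS_e))``
    with n subjects and k raters.  A constant matrix has no subject variance
    to apportion and is flagged undefined.
    """
    x = np.asarray(measurements, dtype=float)
    if x.ndim != 2:
        raise StatsError("need a 2-D subjects x raters matrix")
    if np.isnan(x).any():
        raise StatsError("missing cells are not supported")
    n, k = x.shape
    if n < 2 or k < 2:
        raise StatsError("need >= 2 subjects and >= 2 raters")
    grand = x.mean()
    subj_means = x.mean(axis=1)
    rater_means = x.mean(axis=0)
    ss_subj = k * np.sum((subj_means - grand) ** 2)
    ss_rater = n * np.sum((rater_means - grand) ** 2)
    ss_err = np.sum((x - subj_means[:, None] - rater_means[None, :] + grand) ** 2)
    ms_subj = ss_subj / (n - 1)
    ms_rater = ss_rater / (k - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    denom = ms_subj + (k - 1) * ms_err + (k / n) * (ms_rater - ms_err)
    if abs(denom) < 1e-15:
        return ICCResult(icc=math.nan, n_subjects=n, n_raters=k,
                         undefined=True)
    return ICCResult(icc=float((ms_subj - ms_err) / denom),
                     n_subjects=n, n_raters=k)


def bland_altman(a, b) -> tuple[float, float, float]:
    """Bias and 95% limits of agreement between paired measurements.

    Returns ``(bias, loa_low, loa_high)`` where bias = mean(a - b) and the
    limits are bias +/- 1.96 sd(a - b).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise StatsError("need two equal-length 1-D arrays with >= 2 values")
    diff = a - b
    bias = float(diff.mean())
    half = 1.96 * float(diff.std(ddof=1))
    return bias, bias - half, bias + half


# --------------------------------------------------------------------------
# correlations


def spearman(x, y) -> float:
    """Spearman rank correlation with average ranks for ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise StatsError("need two equal-length arrays with >= 3 values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise StatsError("Spearman correlation is undefined for a constant "
                         "input")
    rho, _ = sps.spearmanr(x, y)
    return float(rho)


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def correlation_table(outcomes: pd.DataFrame, pfts: pd.DataFrame,
                      *, mri_columns=MRI_OUTCOMES, pft_columns=PFT_OUTCOMES
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman coefficients of MRI outcomes against PFT values.

    Both tables must carry ``subject_id``; unmatched ids are an error.
    Returns ``(coefficients, stars)`` data frames with MRI outcomes as rows
    and PFT columns as columns; stars mark p < 0.05 / 0.01 / 0.001.
    """
    missing = set(outcomes["subject_id"]).symmetric_difference(pfts["subject_id"])
    if missing:
        raise StatsError(f"unmatched subject ids: {sorted(missing)}")
    merged = outcomes.merge(pfts, on="subject_id")
    coef = pd.DataFrame(index=list(mri_columns), columns=list(pft_columns),
                        dtype=float)
    stars = pd.DataFrame(index=list(mri_columns), columns=list(pft_columns),
                         dtype=object)
    for m in mri_columns:
        for p in pft_columns:
            sub = merged[[m, p]].dropna()
            rho, pval = sps.spearmanr(sub[m], sub[p])
            coef.loc[m, p] = rho
            stars.loc[m, p] = _stars(pval)
    return coef, stars


# --------------------------------------------------------------------------
# covariate-adjusted group comparison


@dataclass
class GroupComparisonResult:
    """OLS group comparison of one outcome, with pairwise contrasts."""

    outcome_name: str
    overall_p: float
    pairwise: list[tuple[str, str, float, float]]  # (a, b, estimate, p)
    alpha_pairwise: float = BONFERRONI_ALPHA
    n: int = 0
    residual_summary: dict = field(default_factory=dict)

    def significant_pairs(self) -> list[tuple[str, str]]:
        return [(a, b) for a, b, _, p in self.pairwise
                if p <= self.alpha_pairwise]


def adjusted_group_comparison(table: pd.DataFrame, outcome: str,
                              group_col: str = "group",
                              covariates: list[str] | None = None
                              ) -> GroupComparisonResult:
    """Multiple linear regression of an outcome on group, with covariates.

    The overall group difference is the joint F-test on the group indicator
    variables; pairwise group contrasts are tested at the Bonferroni level
    of 0.017.  Residual diagnostics (a linearity proxy and normality
    moments) are returned as summary numbers.
    """
    covariates = list(covariates or [])
    cols = [outcome, group_col, *covariates]
    missing_cols = [c for c in cols if c not in table.columns]
    if missing_cols:
        raise StatsError(f"missing columns: {missing_cols}")
    data = table[cols].dropna().copy()
    levels = sorted(data[group_col].astype(str).unique())
    if len(levels) < 2:
        raise StatsError("need at least two groups")
    counts = data[group_col].value_counts()
    if (counts < 2).any():
        raise StatsError("every group needs n >= 2")
    data["_y"] = data[outcome]
    terms = [f"C({group_col})"] + covariates
    formula = "_y ~ " + " + ".join(terms)
    fit = smf.ols(formula, data=data).fit()
    if np.linalg.matrix_rank(fit.model.exog) < fit.model.exog.shape[1]:
        names = fit.model.exog_names
        raise StatsError(f"singular design matrix; check columns {names}")

    group_params = [p for p in fit.params.index
                    if p.startswith(f"C({group_col})")]
    overall_p = float(fit.f_test(" = ".join(group_params) + " = 0").pvalue) \
        if len(group_params) > 1 else float(
            fit.f_test(f"{group_params[0]} = 0").pvalue)

    def param_name(level: str) -> str | None:
        name = f"C({group_col})[T.{level}]"
        return name if name in fit.params.index else None

    pairwise = []
    k = len(fit.params)
    for a, b in itertools.combinations(levels, 2):
        vec = np.zeros(k)
        for level, sign in ((a, 1.0), (b, -1.0)):
            name = param_name(level)
            if name is not None:
                vec[list(fit.params.index).index(name)] = sign
        tt = fit.t_test(vec)
        pairwise.append((a, b, float(np.squeeze(tt.effect)),
                         float(np.squeeze(tt.pvalue))))

    resid = fit.resid
    fitted = fit.fittedvalues
    lin_slope = 0.0
    # curvature of residuals vs fitted (a numeric stand-in for eyeballing
    # the residual plot); needs >= 3 distinct fitted values to be defined
    if np.unique(np.round(fitted, 12)).size >= 3:
        lin_slope = float(np.polyfit(fitted, resid, 2)[0])
    residual_summary = {
        "resid_sd": float(resid.std(ddof=1)),
        "resid_skew": float(sps.skew(resid)),
        "resid_kurtosis": float(sps.kurtosis(resid)),
        "resid_vs_fitted_curvature": lin_slope,
        "r_squared": float(fit.rsquared),
    }
    return GroupComparisonResult(outcome_name=outcome, overall_p=overall_p,
                                 pairwise=pairwise, n=len(data),
                                 residual_summary=residual_summary)


def group_comparison_table(outcomes: pd.DataFrame, metadata: pd.DataFrame,
                           covariates: list[str] | None = None,
                           mri_columns=MRI_OUTCOMES) -> pd.DataFrame:
    """Run the adjusted comparison for every MRI outcome; long-format rows."""
    merged = outcomes.merge(metadata, on="subject_id")
    rows = []
    for m in mri_columns:
        res = adjusted_group_comparison(merged, m, covariates=covariates)
        for a, b, est, p in res.pairwise:
            rows.append({"outcome": m, "overall_p": res.overall_p,
                         "group_a": a, "group_b": b, "estimate": est,
                         "pairwise_p": p, "alpha_pairwise": res.alpha_pairwise,
                         "significant": p <= res.alpha_pairwise,
                         "n": res.n})
    return pd.DataFrame(rows)
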