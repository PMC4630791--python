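"""Demographic regression and group-comparison statistics.

The demographic model is an ordinary least squares fit of the
non-age-normed sum score on gender (male reference), years of education
and age (both continuous), plus the education-by-age,
gender-by-education, and gender-by-age interactions, on complete cases.
Group comparisons use the Welch unequal-variance t-test (from raw
samples or printed summary statistics), a classical one-way ANOVA, and
mean differences expressed in reference-SD units.  Concurrent-validity
analyses are plain paired correlations and reuse
:func:`cognorm.structure.correlation_matrix`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

logger = logging.getLogger(__name__)

#: Term order of the demographic model, as conventionally reported.
MODEL_TERMS = (
    "Intercept",
    "female",
    "education",
    "age",
    "education:age",
    "female:education",
    "female:age",
)


@dataclass
class RegressionResult:
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    r_squared: float
    f_stat: float
    f_pvalue: float
    df_model: int
    df_resid: int
    n_obs: int
    n_excluded: int

    def coefficient_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "estimate": self.params,
                "std_error": self.bse,
                "t_value": self.tvalues,
                "p_value": self.pvalues,
            }
        )


@dataclass
class WelchResult:
    t: float
    df: float
    p_value: float


def fit_demographic_model(
    cohort: pd.DataFrame, score_col: str = "sum_score"
) -> RegressionResult:
    """OLS of a (non-age-normed) score on demographics with interactions.

    Rows with missing gender, education, age, or score are excluded
    (complete-case analysis) with a logged count.  Gender enters as a
    female dummy with males as reference; subjects with undisclosed
    gender are part of the excluded incomplete cases.
    """
    needed = ["gender", "education_years", "age", score_col]
    df = cohort[needed].copy()
    df["female"] = df["gender"].map({"F": 1.0, "M": 0.0})
    df = df.rename(columns={"education_years": "education", score_col: "score"})
    complete = df.dropna(subset=["female", "education", "age", "score"])
    n_excluded = len(df) - len(complete)
    if n_excluded:
        logger.info("demographic model: excluded %d incomplete rows", n_excluded)
    if len(complete) < 20:
        raise ValueError("need at least 20 complete cases")

    fit = smf.ols(
        "score ~ female + education + age + education:age"
        " + female:education + female:age",
        data=complete,
    ).fit()
    if np.linalg.matrix_rank(fit.model.exog) < fit.model.exog.shape[1]:
        raise ValueError("design matrix is rank deficient")
    return RegressionResult(
        params=fit.params,
        bse=fit.bse,
        tvalues=fit.tvalues,
        pvalues=fit.pvalues,
        r_squared=float(fit.rsquared),
        f_stat=float(fit.fvalue),
        f_pvalue=float(fit.f_pvalue),
        df_model=int(fit.df_model),
        df_resid=int(fit.df_resid),
        n_obs=int(fit.nobs),
        n_excluded=n_excluded,
    )


def welch_two_sample(
    mean1: float | None = None,
    sd1: float | None = None,
    n1: int | None = None,
    mean2: float | None = None,
    sd2: float | None = None,
    n2: int | None = None,
    sample1=None,
    sample2=None,
) -> WelchResult:
    """Welch unequal-variance t-test from summaries or raw samples.

    Either pass the six summary statistics, or ``sample1``/``sample2``
    arrays.  The Welch-Satterthwaite df is used un-rounded.
    """
    if sample1 is not None or sample2 is not None:
        x = np.asarray(sample1, dtype=float)
        y = np.asarray(sample2, dtype=float)
        if x.size < 2 or y.size < 2:
            raise ValueError("each sample needs at least 2 observations")
        mean1, sd1, n1 = x.mean(), x.std(ddof=1), x.size
        mean2, sd2, n2 = y.mean(), y.std(ddof=1), y.size
    if None in (mean1, sd1, n1, mean2, sd2, n2):
        raise ValueError("provide summary statistics or raw samples")
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 == 0 and sd2 == 0:
        raise ValueError("zero variance in both groups")
    se1, se2 = sd1**2 / n1, sd2**2 / n2
    t = (mean1 - mean2) / np.sqrt(se1 + se2)
    df = (se1 + se2) ** 2 / (se1**2 / (n1 - 1) + se2**2 / (n2 - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return WelchResult(t=float(t), df=float(df), p_value=float(p))


def anova_oneway(*groups) -> tuple[float, int, int, float]:
    """One-way ANOVA; returns ``(F, df_between, df_within, p)``."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs at least 2 observations")
    F, p = stats.f_oneway(*arrays)
    df_between = len(arrays) - 1
    df_within = sum(a.size for a in arrays) - len(arrays)
    return float(F), df_between, df_within, float(p)


def sd_effect_size(mean_ref: float, mean_group: float, sd_ref: float) -> float:
    """Mean difference in units of the reference group's SD.

    ``(mean_ref - mean_group) / sd_ref``: positive when the group
    scores below the reference.  The denominator is an explicit
    argument because published effect sizes do not always state it.
    """
    if sd_ref <= 0:
        raise ValueError("sd_ref must be positive")
    return (mean_ref - mean_group) / sd_ref
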