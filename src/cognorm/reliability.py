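"""Test-retest reliability: Pearson r, Fisher CIs, bootstrap, moderators.

Reliability of a repeatable battery is summarized by the Pearson
correlation between two administrations.  Uncertainty comes two ways:
analytically via the Fisher z transform, ``tanh(atanh(r) ± z*/sqrt(n-3))``,
and non-parametrically by resampling whole (time-1, time-2) pairs with
replacement and taking percentiles of the resampled correlations.
Two independent correlations are compared with the two-sample Fisher
r-to-z test.  Moderation analyses split pairs into groups (inter-test
interval bins around the mean, engagement quartiles, or explicit
labels) and estimate each group separately; the engagement variance
model regresses time-2 scores on time-1 scores plus an engagement
counter, then regresses the squared residuals on engagement — a
positive slope means noisier retests (lower reliability) at higher
engagement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)


class DegenerateVarianceError(ValueError):
    """A correlation was requested on (near-)constant input."""


@dataclass
class BootstrapSummary:
    median: float
    iqr: float
    ci_low: float
    ci_high: float
    n_iter: int
    n_dropped: int  # degenerate resamples excluded


@dataclass
class ReliabilityEstimate:
    """Pearson reliability with analytic and (optional) bootstrap CIs."""

    r: float
    fisher_z: float
    ci_low: float
    ci_high: float
    n_pairs: int
    level: float = 0.95
    bootstrap: BootstrapSummary | None = None


@dataclass
class OLSStage:
    params: dict[str, float]
    bse: dict[str, float]
    tvalues: dict[str, float]
    pvalues: dict[str, float]
    r_squared: float
    f_stat: float
    f_pvalue: float
    df_model: int
    df_resid: int


@dataclass
class EngagementModelResult:
    """Two-stage engagement variance model.

    ``stage1``: score2 ~ score1 + engagement (levels).
    ``stage2``: squared stage-1 residuals ~ engagement (variance).
    A positive, significant stage-2 slope indicates retest noise
    growing with engagement, i.e. reliability decreasing.
    """

    stage1: OLSStage
    stage2: OLSStage


def _as_pairs(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have the same length")
    return x, y


def pearson_fisher_ci(x, y, level: float = 0.95) -> ReliabilityEstimate:
    """Pearson correlation with the Fisher-z analytic confidence interval."""
    x, y = _as_pairs(x, y)
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateVarianceError("constant input; correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0:
        z = np.inf if r > 0 else -np.inf
        lo = hi = r
    else:
        z = float(np.arctanh(r))
        half = stats.norm.ppf(0.5 + level / 2.0) / np.sqrt(n - 3)
        lo, hi = float(np.tanh(z - half)), float(np.tanh(z + half))
    return ReliabilityEstimate(
        r=r, fisher_z=z, ci_low=lo, ci_high=hi, n_pairs=n, level=level
    )


def bootstrap_reliability(
    x, y, n_iter: int = 10_000, seed: int | None = None, level: float = 0.95
) -> BootstrapSummary:
    """Nonparametric pair-resampling bootstrap of the correlation.

    Resamples whole pairs with replacement ``n_iter`` times; reports
    the median, IQR, and the percentile interval of the resampled
    correlations.  Degenerate resamples (constant in either coordinate)
    are dropped and counted.
    """
    x, y = _as_pairs(x, y)
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 pairs")
    rng = np.random.default_rng(seed)
    rs = np.empty(n_iter)
    chunk = max(1, int(2_000_000 // max(n, 1)))
    done = 0
    while done < n_iter:
        m = min(chunk, n_iter - done)
        idx = rng.integers(0, n, size=(m, n))
        xs, ys = x[idx], y[idx]
        xc = xs - xs.mean(axis=1, keepdims=True)
        yc = ys - ys.mean(axis=1, keepdims=True)
        denom = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            rs[done : done + m] = (xc * yc).sum(axis=1) / denom
        done += m
    good = np.isfinite(rs)
    n_dropped = int((~good).sum())
    if n_dropped:
        logger.warning("bootstrap: dropped %d degenerate resamples", n_dropped)
    rs = rs[good]
    alpha = 1.0 - level
    lo, hi = np.quantile(rs, [alpha / 2.0, 1.0 - alpha / 2.0])
    q1, q3 = np.quantile(rs, [0.25, 0.75])
    return BootstrapSummary(
        median=float(np.median(rs)),
        iqr=float(q3 - q1),
        ci_low=float(lo),
        ci_high=float(hi),
        n_iter=n_iter,
        n_dropped=n_dropped,
    )


def reliability_estimate(
    x,
    y,
    n_iter: int = 10_000,
    seed: int | None = None,
    level: float = 0.95,
) -> ReliabilityEstimate:
    """Analytic and bootstrap reliability in one object."""
    est = pearson_fisher_ci(x, y, level=level)
    est.bootstrap = bootstrap_reliability(x, y, n_iter=n_iter, seed=seed, level=level)
    return est


def fisher_z_two_sample(
    r1: float, n1: int, r2: float, n2: int
) -> tuple[float, float]:
    """Two-sample Fisher r-to-z comparison of independent correlations.

    Returns ``(z, p)`` with
    ``z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3))`` and a
    two-sided normal p-value.
    """
    if n1 <= 3 or n2 <= 3:
        raise ValueError("both samples must have n > 3")
    if abs(r1) >= 1.0 or abs(r2) >= 1.0:
        raise ValueError("|r| must be < 1 for the Fisher transform")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(
        1.0 / (n1 - 3) + 1.0 / (n2 - 3)
    )
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def sd_bin_edges(values, width: float = 0.5, outer: float = 1.5) -> list[float]:
    """Integer bin edges at mean ± width·SD and mean + outer·SD.

    Reproduces the inter-test-interval binning convention: four bins
    (below mean−0.5SD, mean±0.5SD, +0.5 to +1.5SD, above +1.5SD) with
    edges rounded to integer days and boundary days assigned downward.
    """
    v = np.asarray(values, dtype=float)
    m, s = v.mean(), v.std(ddof=1)
    return [
        float(np.round(m - width * s)),
        float(np.round(m + width * s)),
        float(np.round(m + outer * s)),
    ]


def quartile_edges(values) -> list[float]:
    """Integer quartile cuts (right-closed intervals at integer cuts)."""
    v = np.asarray(values, dtype=float)
    return [float(q) for q in np.quantile(v, [0.25, 0.5, 0.75], method="lower")]


def _bin_labels_from_edges(g: np.ndarray, edges: list[float], closed: str) -> np.ndarray:
    # closed="left": bins are x < e0 | e0 <= x < e1 | ... (interval-bin
    # convention: an edge day starts its bin)
    # closed="right": x <= e0 | e0 < x <= e1 | ... (quartile convention)
    side = "left" if closed == "right" else "right"
    return np.searchsorted(np.asarray(edges), g, side=side)


def grouped_reliability(
    x,
    y,
    groups,
    scheme: str = "labels",
    min_pairs: int = 4,
    level: float = 0.95,
) -> tuple[dict, list[float] | None]:
    """Per-group reliability estimates.

    Parameters
    ----------
    x, y
        Paired scores.
    groups
        Grouping variable (per pair): explicit labels
        (``scheme="labels"``), or a numeric moderator to be binned by
        ``scheme="sd_bins"`` (mean ± 0.5/1.5 SD, integer edges,
        boundary down) or ``scheme="quartiles"`` (right-closed integer
        cuts).
    min_pairs
        Groups smaller than this are skipped with a warning.

    Returns
    -------
    (estimates, edges)
        ``estimates`` maps group key -> :class:`ReliabilityEstimate`;
        ``edges`` is the list of numeric cut points (None for labels).
    """
    x, y = _as_pairs(x, y)
    g = np.asarray(groups)
    if g.size != x.size:
        raise ValueError("groups must align with pairs")

    edges: list[float] | None = None
    if scheme == "labels":
        keys = g
    elif scheme == "sd_bins":
        edges = sd_bin_edges(g.astype(float))
        keys = _bin_labels_from_edges(g.astype(float), edges, closed="left")
    elif scheme == "quartiles":
        edges = quartile_edges(g.astype(float))
        keys = _bin_labels_from_edges(g.astype(float), edges, closed="right")
    else:
        raise ValueError(f"unknown scheme {scheme!r}")

    estimates: dict = {}
    for key in np.unique(keys):
        mask = keys == key
        if int(mask.sum()) < min_pairs:
            logger.warning(
                "group %r has %d pairs (min %d); skipped", key, int(mask.sum()), min_pairs
            )
            continue
        estimates[key if not isinstance(key, np.generic) else key.item()] = (
            pearson_fisher_ci(x[mask], y[mask], level=level)
        )
    return estimates, edges


def _stage(fit) -> OLSStage:
    return OLSStage(
        params=dict(fit.params),
        bse=dict(fit.bse),
        tvalues=dict(fit.tvalues),
        pvalues=dict(fit.pvalues),
        r_squared=float(fit.rsquared),
        f_stat=float(fit.fvalue),
        f_pvalue=float(fit.f_pvalue),
        df_model=int(fit.df_model),
        df_resid=int(fit.df_resid),
    )


def engagement_variance_model(
    score1, score2, engagement, robust: bool = False
) -> EngagementModelResult:
    """Two-stage model of engagement's effect on retest variance.

    Stage 1: OLS of time-2 scores on time-1 scores and the engagement
    counter.  Stage 2: OLS of the squared stage-1 residuals on
    engagement.  Conventional OLS standard errors by default;
    ``robust=True`` switches stage 2 to HC3 errors.
    """
    s1, s2 = _as_pairs(score1, score2)
    e = np.asarray(engagement, dtype=float).ravel()
    if e.size != s1.size:
        raise ValueError("engagement must align with score pairs")
    if s1.size < 10:
        raise ValueError("need at least 10 complete triples")

    X1 = sm.add_constant(
        np.column_stack([s1, e]), has_constant="add"
    )
    if np.linalg.matrix_rank(X1) < X1.shape[1]:
        raise ValueError("collinear predictors in stage 1")
    X1 = pd.DataFrame(X1, columns=["const", "score1", "engagement"])
    fit1 = sm.OLS(s2, X1).fit()
    resid2 = np.asarray(fit1.resid) ** 2

    X2 = pd.DataFrame(
        sm.add_constant(e[:, None], has_constant="add"),
        columns=["const", "engagement"],
    )
    fit2 = sm.OLS(resid2, X2).fit(cov_type="HC3" if robust else "nonrobust")
    return EngagementModelResult(stage1=_stage(fit1), stage2=_stage(fit2))
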