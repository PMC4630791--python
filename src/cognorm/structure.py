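"""Inter-subtest structure: correlations, clustering, and factor analysis.

Pipeline stages, in the order they are usually run:

1. :func:`correlation_matrix` — product-moment correlations between
   scaled subtest scores.
2. :func:`agglomerative_dendrogram` — hierarchical clustering on the
   distance ``d = sqrt(2 (1 - r))``, which treats subtests as unit
   vectors, so perfectly correlated subtests sit at distance zero.
3. :func:`parallel_analysis` — factor retention: eigenvalues of the
   reduced correlation matrix (communalities from a fitted factor
   solution on the diagonal) are compared position by position against
   the same quantity computed on i.i.d. standard-normal data of the
   same shape; factors whose observed eigenvalue exceeds the simulated
   reference (95th percentile by default) are retained.
4. :func:`fit_ml_factor_model` — maximum-likelihood factor extraction
   on the correlation matrix via the profile-likelihood algorithm
   (optimize uniquenesses; loadings follow from an
   eigen-decomposition), varimax rotation with Kaiser row
   normalization, and fit statistics: Bartlett-corrected chi-square,
   df = ((p-k)^2 - (p+k))/2, and RMSEA with a noncentral-chi-square
   confidence interval.
5. :func:`simple_structure_screen` — the conventional 0.4 primary /
   0.3 cross-loading screen per variable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)


# ----- correlations and clustering ----------------------------------------


def correlation_matrix(scores: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation matrix of a subject-by-subtest table."""
    X = scores.to_numpy(dtype=float)
    if X.shape[0] < 4:
        raise ValueError("need at least 4 subjects")
    sds = X.std(axis=0)
    if np.any(sds == 0):
        bad = scores.columns[np.where(sds == 0)[0][0]]
        raise ValueError(f"subtest {bad!r} has zero variance")
    R = np.corrcoef(X, rowvar=False)
    np.fill_diagonal(R, 1.0)
    return pd.DataFrame(R, index=scores.columns, columns=scores.columns)


@dataclass
class Dendrogram:
    """Agglomerative merge tree over subtests."""

    labels: list[str]
    merge_order: list[tuple[int, int]]  # scipy cluster ids joined at each step
    heights: list[float]
    linkage_matrix: np.ndarray  # scipy (n-1, 4) linkage encoding

    def to_newick(self) -> str:
        """Nested-parenthesis text rendering with branch heights."""
        n = len(self.labels)
        nodes: dict[int, str] = {i: self.labels[i] for i in range(n)}
        for step, ((a, b), h) in enumerate(zip(self.merge_order, self.heights)):
            nodes[n + step] = f"({nodes[int(a)]},{nodes[int(b)]}):{h:.4f}"
        return nodes[n + len(self.merge_order) - 1] + ";"


def correlation_distance(corr: np.ndarray) -> np.ndarray:
    """Euclidean distance between unit vectors: ``sqrt(2 (1 - r))``."""
    r = np.clip(np.asarray(corr, dtype=float), -1.0, 1.0)
    return np.sqrt(np.maximum(2.0 * (1.0 - r), 0.0))


def agglomerative_dendrogram(
    corr: pd.DataFrame | np.ndarray, method: str = "average"
) -> Dendrogram:
    """Hierarchical clustering of subtests from their correlations.

    Starts from singletons and iteratively joins the two most similar
    clusters (``method`` in {"average", "single", "complete"}) until a
    single cluster remains.
    """
    if isinstance(corr, pd.DataFrame):
        labels = list(corr.columns)
        R = corr.to_numpy(dtype=float)
    else:
        R = np.asarray(corr, dtype=float)
        labels = [f"v{i}" for i in range(R.shape[0])]
    if R.shape[0] != R.shape[1] or not np.allclose(R, R.T, atol=1e-10):
        raise ValueError("correlation matrix must be square and symmetric")
    D = correlation_distance(R)
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method=method)
    merges = [(int(a), int(b)) for a, b in Z[:, :2]]
    heights = [float(h) for h in Z[:, 2]]
    return Dendrogram(
        labels=labels, merge_order=merges, heights=heights, linkage_matrix=Z
    )


# ----- parallel analysis ---------------------------------------------------


@dataclass
class ParallelResult:
    observed_eigenvalues: np.ndarray
    reference_mean: np.ndarray
    reference_p95: np.ndarray
    n_factors_retained: int
    criterion: str
    n_iter: int


def _smc(R: np.ndarray) -> np.ndarray:
    """Squared multiple correlations of each variable with the rest."""
    return 1.0 - 1.0 / np.diag(linalg.inv(R))


def _factor_solution_eigenvalues(R: np.ndarray, n_paf: int = 1, iters: int = 100,
                                 tol: float = 1e-6) -> np.ndarray:
    """Eigenvalues of the reduced correlation matrix.

    The diagonal holds communalities from an iterated principal-axis
    factor solution (started at the squared multiple correlations), the
    convention of the reference parallel-analysis implementation.
    """
    h = np.clip(_smc(R), 0.0, 1.0)
    for _ in range(iters):
        Rr = R.copy()
        np.fill_diagonal(Rr, h)
        w, V = linalg.eigh(Rr)
        w, V = w[::-1], V[:, ::-1]
        lam = V[:, :n_paf] * np.sqrt(np.maximum(w[:n_paf], 0.0))
        h_new = np.minimum((lam**2).sum(axis=1), 1.0)
        if np.abs(h_new - h).max() < tol:
            h = h_new
            break
        h = h_new
    Rr = R.copy()
    np.fill_diagonal(Rr, h)
    return np.sort(linalg.eigvalsh(Rr))[::-1]


def parallel_analysis(
    scores: pd.DataFrame | np.ndarray,
    n_iter: int = 10_000,
    criterion: str = "p95",
    seed: int | None = None,
) -> ParallelResult:
    """Factor retention by comparison against random-data eigenvalues.

    Observed eigenvalues of the reduced correlation matrix are compared
    position-wise against the same quantity on ``n_iter`` independent
    standard-normal matrices of identical shape.  Retention stops at
    the first position where the observed eigenvalue no longer exceeds
    the reference (``criterion="p95"`` for the 95th percentile,
    ``"mean"`` for the mean).
    """
    X = np.asarray(scores, dtype=float)
    if X.ndim != 2 or not np.issubdtype(X.dtype, np.number):
        raise ValueError("scores must be a numeric 2-D array")
    n, p = X.shape
    if n <= p:
        raise ValueError("need more subjects than variables")
    if n_iter < 100:
        warnings.warn("parallel analysis with n_iter < 100 is unstable")
    if criterion not in ("p95", "mean"):
        raise ValueError(f"unknown criterion {criterion!r}")

    obs = _factor_solution_eigenvalues(np.corrcoef(X, rowvar=False))
    rng = np.random.default_rng(seed)
    sims = np.empty((n_iter, p))
    for i in range(n_iter):
        Rn = np.corrcoef(rng.standard_normal((n, p)), rowvar=False)
        sims[i] = _factor_solution_eigenvalues(Rn)
    ref_mean = sims.mean(axis=0)
    ref_p95 = np.percentile(sims, 95, axis=0)
    ref = ref_p95 if criterion == "p95" else ref_mean

    retained = 0
    for o, r in zip(obs, ref):
        if o > r:
            retained += 1
        else:
            break
    return ParallelResult(
        observed_eigenvalues=obs,
        reference_mean=ref_mean,
        reference_p95=ref_p95,
        n_factors_retained=retained,
        criterion=criterion,
        n_iter=n_iter,
    )


# ----- maximum-likelihood factor analysis ----------------------------------


@dataclass
class FactorSolution:
    loadings: np.ndarray  # rotated if rotation requested
    uniquenesses: np.ndarray
    proportion_variance: np.ndarray
    cumulative_variance: np.ndarray
    chi_square: float | None
    df: int
    p_value: float | None
    rmsea: float | None
    rmsea_ci: tuple[float, float] | None
    n_obs: int | None
    rotation: str | None
    rotation_matrix: np.ndarray | None
    heywood: bool
    variable_names: list[str] = field(default_factory=list)
    unrotated_loadings: np.ndarray | None = None

    @property
    def communalities(self) -> np.ndarray:
        return (self.loadings**2).sum(axis=1)


def ml_discrepancy(R: np.ndarray, loadings: np.ndarray, psi: np.ndarray) -> float:
    """ML discrepancy F = log|Σ| - log|R| + tr(R Σ^-1) - p."""
    p = R.shape[0]
    Sigma = loadings @ loadings.T + np.diag(psi)
    sign, logdet_s = np.linalg.slogdet(Sigma)
    _, logdet_r = np.linalg.slogdet(R)
    return float(logdet_s - logdet_r + np.trace(R @ linalg.inv(Sigma)) - p)


def _ml_objective(logpsi: np.ndarray, R: np.ndarray, k: int):
    """Profile log-likelihood discrepancy in psi, with gradient."""
    psi = np.exp(logpsi)
    s = 1.0 / np.sqrt(psi)
    Rs = R * np.outer(s, s)
    w, V = linalg.eigh(Rs)
    w, V = w[::-1], V[:, ::-1]
    tail = np.maximum(w[k:], 1e-12)
    f = -(np.log(tail) - tail + 1.0).sum()
    lam = (V[:, :k] * np.sqrt(np.maximum(w[:k] - 1.0, 0.0))) / s[:, None]
    Sigma = lam @ lam.T + np.diag(psi)
    iS = linalg.inv(Sigma)
    grad_psi = np.diag(iS @ (Sigma - R) @ iS)
    return f, grad_psi * psi


def _ml_loadings(R: np.ndarray, psi: np.ndarray, k: int) -> np.ndarray:
    s = 1.0 / np.sqrt(psi)
    Rs = R * np.outer(s, s)
    w, V = linalg.eigh(Rs)
    w, V = w[::-1], V[:, ::-1]
    return (V[:, :k] * np.sqrt(np.maximum(w[:k] - 1.0, 0.0))) / s[:, None]


def varimax_rotation(
    loadings: np.ndarray,
    normalize: bool = True,
    tol: float = 1e-12,
    max_iter: int = 1000,
) -> tuple[np.ndarray, np.ndarray]:
    """Varimax rotation (SVD algorithm) with Kaiser row normalization.

    Returns ``(rotated, T)`` with ``rotated = loadings @ T`` and ``T``
    orthogonal.  Columns are ordered by explained variance and signed
    so each column's loading sum is non-negative.
    """
    A = np.asarray(loadings, dtype=float)
    p, k = A.shape
    if k == 1:
        return A.copy(), np.eye(1)
    h = np.sqrt((A**2).sum(axis=1)) if normalize else np.ones(p)
    h = np.where(h == 0, 1.0, h)
    B = A / h[:, None]
    T = np.eye(k)
    d_old = 0.0
    for _ in range(max_iter):
        L = B @ T
        U, s, Vt = linalg.svd(
            B.T @ (L**3 - L @ np.diag((L**2).sum(axis=0)) / p)
        )
        T = U @ Vt
        d = s.sum()
        if d < d_old * (1.0 + tol):
            break
        d_old = d
    L = (B @ T) * h[:, None]
    # order columns by sum of squared loadings, sign for positive column sums
    order = np.argsort(-(L**2).sum(axis=0), kind="stable")
    L = L[:, order]
    T = T[:, order]
    signs = np.where(L.sum(axis=0) < 0, -1.0, 1.0)
    return L * signs, T * signs


def factor_df(p: int, k: int) -> int:
    """Degrees of freedom of the k-factor model for p variables."""
    return int(((p - k) ** 2 - (p + k)) // 2)


def rmsea_from_fit(
    chi_square: float, df: int, n_obs: int, level: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """RMSEA point estimate and CI from chi-square, df, and N.

    ``RMSEA = sqrt(max(chi2 - df, 0) / (df (N - 1)))``; the interval
    comes from inverting the noncentral chi-square distribution for the
    noncentrality parameter.
    """
    if df <= 0:
        raise ValueError("df must be positive for RMSEA")
    point = float(np.sqrt(max(chi_square - df, 0.0) / (df * (n_obs - 1))))

    alpha = 1.0 - level

    def ncp_for(prob: float) -> float:
        # find lambda with ncx2.cdf(chi2; df, lambda) == prob
        f = lambda lam: stats.ncx2.cdf(chi_square, df, lam) - prob
        if f(0.0) < 0.0:
            return 0.0
        hi = max(chi_square, 1.0)
        while f(hi) > 0.0:
            hi *= 2.0
            if hi > 1e8:
                break
        return float(optimize.brentq(f, 0.0, hi))

    lam_lo = ncp_for(1.0 - alpha / 2.0)
    lam_hi = ncp_for(alpha / 2.0)
    ci = (
        float(np.sqrt(lam_lo / (df * (n_obs - 1)))),
        float(np.sqrt(lam_hi / (df * (n_obs - 1)))),
    )
    return point, ci


def fit_ml_factor_model(
    scores: pd.DataFrame | np.ndarray | None = None,
    corr: pd.DataFrame | np.ndarray | None = None,
    n_obs: int | None = None,
    k: int = 4,
    rotation: str | None = "varimax",
    psi_floor: float = 0.005,
) -> FactorSolution:
    """Maximum-likelihood factor analysis with optional varimax rotation.

    Provide either raw ``scores`` (a subject-by-variable table) or a
    correlation matrix ``corr`` together with ``n_obs`` for the fit
    statistics.  Uniquenesses are estimated by minimizing the ML
    discrepancy (profile likelihood, analytic gradient); Heywood cases
    are flagged and floored at ``psi_floor``.
    """
    names: list[str] = []
    if scores is not None:
        if isinstance(scores, pd.DataFrame):
            names = list(scores.columns)
        X = np.asarray(scores, dtype=float)
        R = np.corrcoef(X, rowvar=False)
        if n_obs is None:
            n_obs = X.shape[0]
    elif corr is not None:
        if isinstance(corr, pd.DataFrame):
            names = list(corr.columns)
        R = np.asarray(corr, dtype=float)
    else:
        raise ValueError("provide scores or corr")
    p = R.shape[0]
    if not names:
        names = [f"v{i}" for i in range(p)]
    df = factor_df(p, k)
    if df < 0:
        raise ValueError(f"k={k} factors over-parameterize p={p} variables (df<0)")

    x0 = np.log(np.clip(1.0 - np.clip(_smc(R), 0.0, 0.95), 1e-3, 1.0))
    bounds = [(np.log(psi_floor), np.log(1.0))] * p
    res = optimize.minimize(
        _ml_objective,
        x0,
        args=(R, k),
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": 500, "ftol": 1e-14, "gtol": 1e-10},
    )
    psi = np.exp(res.x)
    heywood = bool(np.any(psi <= psi_floor * (1.0 + 1e-6)))
    if heywood:
        logger.warning("Heywood case: uniqueness floored at %g", psi_floor)
    lam = _ml_loadings(R, psi, k)

    rot_T = None
    unrotated = lam.copy()
    if rotation == "varimax":
        lam, rot_T = varimax_rotation(lam)
    elif rotation is not None:
        raise ValueError(f"unsupported rotation {rotation!r}")

    prop = (lam**2).sum(axis=0) / p
    cum = np.cumsum(prop)

    chi2 = p_value = rmsea = None
    rmsea_ci = None
    if n_obs is not None and df > 0:
        disc = ml_discrepancy(R, unrotated, psi)
        correction = n_obs - 1 - (2 * p + 5) / 6.0 - 2 * k / 3.0
        chi2 = float(correction * disc)
        p_value = float(stats.chi2.sf(chi2, df))
        rmsea, rmsea_ci = rmsea_from_fit(chi2, df, n_obs)

    return FactorSolution(
        loadings=lam,
        uniquenesses=psi,
        proportion_variance=prop,
        cumulative_variance=cum,
        chi_square=chi2,
        df=df,
        p_value=p_value,
        rmsea=rmsea,
        rmsea_ci=rmsea_ci,
        n_obs=n_obs,
        rotation=rotation,
        rotation_matrix=rot_T,
        heywood=heywood,
        variable_names=names,
        unrotated_loadings=unrotated,
    )


def loading_variance(loadings: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Proportion of total variance per factor and its cumulative sum.

    ``prop_k = sum_j loadings_jk^2 / p``.
    """
    lam = np.asarray(loadings, dtype=float)
    prop = (lam**2).sum(axis=0) / lam.shape[0]
    return prop, np.cumsum(prop)


def simple_structure_screen(
    loadings: np.ndarray, primary: float = 0.4, cross: float = 0.3
) -> pd.DataFrame:
    """Per-variable simple-structure flags on rotated loadings.

    A variable passes iff its largest absolute loading is at least
    ``primary`` and its second-largest absolute loading is strictly
    below ``cross``.
    """
    lam = np.abs(np.asarray(loadings, dtype=float))
    order = np.sort(lam, axis=1)[:, ::-1]
    top = order[:, 0]
    second = order[:, 1] if lam.shape[1] > 1 else np.zeros(lam.shape[0])
    return pd.DataFrame(
        {
            "primary_loading": top,
            "max_cross_loading": second,
            "primary_factor": np.argmax(lam, axis=1),
            "passes": (top >= primary) & (second < cross),
        }
    )
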