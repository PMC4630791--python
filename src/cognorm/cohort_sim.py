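"""Synthetic cohort generator with calibrated psychometric structure.

The simulator emulates the statistical anatomy of a large web-recruited
normative cohort for the eight-subtest battery:

* subtest inter-correlations arise from a four-factor model
  ``z = Λ f + sqrt(ψ) ε`` with the published varimax loadings;
* demographic gradients (age, education, gender, and their pairwise
  interactions) enter every subtest's standardized score through a
  shared linear predictor whose variance share is solved so that the
  demographic regression on the non-age-normed sum score recovers the
  published R² (0.361);
* retest scores are generated as ``t2 = r·t1 + sqrt(1 - r²)·ε`` per
  subtest, so each subtest's observable test-retest correlation matches
  its published target, plus a mean practice shift on the Grand Index
  scale;
* self-reported MCI / AD groups receive a deficit spread across
  subtests in proportion to the published profile and rescaled so the
  model-implied Grand Index gap equals the configured target;
* engagement counters (inter-test interval, unique days played, games
  played) follow the published moments and ranges, independent of the
  scores unless the heteroscedasticity knob is turned on.

Raw scores are produced from the standardized scores through monotone
links: affine-plus-rounding for count-type subtests and a log-scale
affine for completion times (right-skewed seconds, lower = better).
The links are plumbing, not calibrated to any published raw-score
distribution; the norming transformation is rank-based, so any strictly
monotone link yields the same scaled scores up to tie granularity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from . import battery
from .battery import SUBTESTS, derive_uniquenesses

__all__ = [
    "SimulationConfig",
    "simulate_cohort",
    "derive_uniquenesses",
    "RAW_SCORE_LINKS",
]

#: Monotone standardized-score -> raw-score links.
#: count: raw = clip(round(loc + scale * t), lo, hi)
#: time:  raw = round(loc * exp(-scale * t), 1)  (lower = better)
RAW_SCORE_LINKS: dict[str, tuple] = {
    "trail_a_s": ("time", 42.0, 0.32, None, None),
    "trail_b_s": ("time", 85.0, 0.38, None, None),
    "digit_symbol": ("count", 38.0, 9.0, 0, None),
    "fwd_span": ("count", 8.0, 2.2, 0, None),
    "rev_span": ("count", 7.0, 2.2, 0, None),
    "matrices": ("count", 9.0, 3.0, 0, 17),
    "arithmetic": ("count", 14.0, 6.0, 0, None),
    "grammatical": ("count", 12.0, 5.0, 0, None),
}

#: Internal seed for the calibration draw that standardizes the
#: demographic predictor; fixed so that link scales are a property of
#: the configuration, not of the cohort seed.
_CALIBRATION_SEED = 20151103
_CALIBRATION_N = 200_000

#: Age distribution of the clinical self-report groups: truncated
#: normal (mean, sd) on ``CLINICAL_AGE_BOUNDS`` (older adults only).
CLINICAL_AGE_PARAMS: dict[str, tuple[float, float]] = {
    "MCI": (65.2, 8.53),
    "AD": (68.8, 8.31),
}
CLINICAL_AGE_BOUNDS: tuple[float, float] = (50.0, 89.9)


def _apply_link(subtest: str, t: np.ndarray) -> np.ndarray:
    kind, loc, scale, lo, hi = RAW_SCORE_LINKS[subtest]
    if kind == "time":
        return np.round(loc * np.exp(-scale * t), 1)
    raw = np.round(loc + scale * t)
    if lo is not None:
        raw = np.maximum(raw, lo)
    if hi is not None:
        raw = np.minimum(raw, hi)
    return raw


@dataclass
class SimulationConfig:
    """Everything the generator needs; defaults are the study conditions.

    Attributes
    ----------
    n_subjects, n_mci, n_ad
        Healthy / clinical group sizes (clinical groups are 50+ only).
    seed
        Seed for all cohort randomness; identical config + seed gives a
        bit-identical cohort.
    loadings
        8x4 standardized factor loadings (rows follow
        :data:`cognorm.battery.SUBTESTS`).
    demographic_coefficients
        Linear-predictor coefficients keyed like the published
        regression table (``female``, ``education``, ``age``, and the
        three interactions); only their direction and relative size
        matter, the overall scale is set by ``demographic_r2``.
    demographic_r2
        Target share of non-age-normed sum-score variance explained by
        demographics.
    retest_reliability
        Per-subtest target test-retest correlations, each in (0, 1].
    practice_shift
        (mean, sd) of the time-2 Grand Index change for non-engaged
        retakers; only the mean is injected, the sd is emergent.
    group_gi_deficits / group_profiles
        Grand-Index-scale deficits for the clinical groups and the
        subtest profile over which each deficit is spread.
    iti / days_played / games_played
        (mean, sd, low, high) of the engagement counters.
    engagement_noise
        Heteroscedasticity knob kappa >= 0: session-2 unique noise
        variance is multiplied by ``1 + kappa * games / mean_games``.
        0 (default) keeps engagement independent of the scores.
    two_sessions
        Generate a second session per healthy subject.
    """

    n_subjects: int = 1000
    seed: int = 0
    n_mci: int = 0
    n_ad: int = 0
    two_sessions: bool = False
    loadings: np.ndarray = field(
        default_factory=lambda: battery.FACTOR_LOADINGS.copy()
    )
    demographic_coefficients: dict[str, float] = field(
        default_factory=lambda: dict(battery.DEMOGRAPHIC_COEFFICIENTS)
    )
    demographic_r2: float = battery.DEMOGRAPHIC_R2
    retest_reliability: dict[str, float] = field(
        default_factory=lambda: dict(battery.RETEST_RELIABILITY)
    )
    practice_shift: tuple[float, float] = (1.1, 8.47)
    group_gi_deficits: dict[str, float] = field(
        default_factory=lambda: dict(battery.GROUP_GI_DEFICITS)
    )
    group_profiles: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            g: dict(p) for g, p in battery.GROUP_DEFICIT_PROFILES.items()
        }
    )
    mean_age: float = 46.3
    gender_probs: tuple[float, float, float] = (0.533, 0.401, 0.066)  # F, M, ND
    education_probs: tuple[float, float, float, float] = (0.144, 0.454, 0.302, 0.099)
    iti: tuple[float, float, float, float] = (78.8, 19.86, 29, 235)
    days_played: tuple[float, float, float, float] = (36.7, 19.2, 0, 185)
    games_played: tuple[float, float, float, float] = (353.7, 432.2, 0, 8997)
    engagement_noise: float = 0.0

    def __post_init__(self) -> None:
        self.loadings = np.asarray(self.loadings, dtype=float)
        if self.loadings.shape != (len(SUBTESTS), self.loadings.shape[1]):
            raise ValueError("loadings must have one row per subtest")
        derive_uniquenesses(self.loadings)  # raises on Heywood rows
        for name, r in self.retest_reliability.items():
            if not (0.0 < r <= 1.0):
                raise ValueError(
                    f"retest reliability target for {name} is {r}; must be in (0, 1]"
                )
        if not (0.0 <= self.demographic_r2 < 1.0):
            raise ValueError("demographic_r2 must be in [0, 1)")
        self._moments: tuple[float, float, float] | None = None
        self._bin_vars: np.ndarray | None = None
        self._bin_weights: np.ndarray | None = None
        self._attenuation: dict[str, float] | None = None

    # ----- model-implied quantities ---------------------------------------

    @property
    def uniquenesses(self) -> np.ndarray:
        return derive_uniquenesses(self.loadings)

    def implied_correlation_sum(self) -> float:
        """Sum of all entries of the latent correlation matrix ΛΛ'+diag ψ."""
        R = self.loadings @ self.loadings.T + np.diag(self.uniquenesses)
        return float(R.sum())

    def demographic_variance_share(self) -> float:
        """Per-subtest variance share v of the demographic predictor.

        Solved from the target sum-score R²: with a predictor common to
        all p subtests, R² = p²v / ((1-v)·S_R + p²v) where S_R is the
        entrywise sum of the latent correlation matrix.
        """
        p2 = float(len(SUBTESTS)) ** 2
        s_r = self.implied_correlation_sum()
        r2 = self.demographic_r2
        if r2 == 0.0:
            return 0.0
        return r2 * s_r / (p2 - p2 * r2 + r2 * s_r)

    def sum_score_variance(self) -> float:
        """Variance of the summed standardized subtest scores."""
        v = self.demographic_variance_share()
        return (1.0 - v) * self.implied_correlation_sum() + 64.0 * v

    def _linear_predictor(self, female, education, age) -> np.ndarray:
        b = self.demographic_coefficients
        return (
            b.get("female", 0.0) * female
            + b.get("education", 0.0) * education
            + b.get("age", 0.0) * age
            + b.get("education:age", 0.0) * education * age
            + b.get("female:education", 0.0) * female * education
            + b.get("female:age", 0.0) * female * age
        )

    def _demographic_moments(self) -> tuple[float, float, float]:
        """Moments of the raw linear predictor over the population.

        Returns ``(mean, sd, between_bin_share)`` where the last entry
        is the share of predictor variance explained by the standard
        age bins — the part that age-binned norming strips from scaled
        scores.  Computed once from a large fixed-seed draw so the
        implied scales are deterministic properties of the
        configuration.
        """
        if self._moments is None:
            from .norming import default_age_bins

            rng = np.random.default_rng(_CALIBRATION_SEED)
            female, _ = _draw_gender(rng, _CALIBRATION_N, self.gender_probs)
            years, _ = _draw_education(rng, _CALIBRATION_N, self.education_probs)
            age = _draw_ages(rng, _CALIBRATION_N, self.mean_age)
            eta = self._linear_predictor(female, years, age)
            var = float(eta.var())
            between = 0.0
            bin_vars: list[float] = []
            for b in default_age_bins():
                mask = (age >= b.lower) & (age < b.upper)
                bin_vars.append(float(eta[mask].var() / var) if var > 0 and mask.any() else 0.0)
            if var > 0:
                bin_means = np.full(age.size, eta.mean())
                for b in default_age_bins():
                    mask = (age >= b.lower) & (age < b.upper)
                    if mask.any():
                        bin_means[mask] = eta[mask].mean()
                between = float(bin_means.var() / var)
            weights = np.array(
                [((age >= b.lower) & (age < b.upper)).mean() for b in default_age_bins()]
            )
            self._moments = (float(eta.mean()), float(np.sqrt(var)), between)
            self._bin_vars = np.asarray(bin_vars)
            self._bin_weights = weights / weights.sum()
        return self._moments

    def expected_sum_coefficients(self) -> dict[str, float]:
        """Model-implied coefficients of the demographic regression.

        These are the targets a refit on a simulated cohort should
        recover: the configured coefficients rescaled by
        ``15·p·sqrt(v)/sd(η)`` (the predictor is standardized before it
        enters each subtest's unit-variance standardized score, and the
        analysis outcome is the sum of p scores on the 100/15 scale).
        """
        v = self.demographic_variance_share()
        _, sd_eta, _ = self._demographic_moments()
        factor = 15.0 * len(SUBTESTS) * np.sqrt(v) / sd_eta
        return {k: b * factor for k, b in self.demographic_coefficients.items()}

    def within_bin_sum_variance(self, group: str = "healthy") -> float:
        """Variance of the summed standardized scores inside age bins.

        Age-binned norming strips the between-bin share of the
        demographic predictor, so conversions onto the age-normed
        Grand Index scale use this quantity rather than the marginal
        sum variance.  For the clinical groups the within-bin
        demographic variance is averaged over that group's (older) age
        distribution — the age interactions shrink the education and
        gender slopes with age, so older bins are more homogeneous.
        """
        from .norming import default_age_bins

        v = self.demographic_variance_share()
        _, _, b = self._demographic_moments()
        s_r = self.implied_correlation_sum()
        if group == "healthy":
            within = 1.0 - b
        else:
            mean_age, sd_age = CLINICAL_AGE_PARAMS[group]
            lo, hi = CLINICAL_AGE_BOUNDS
            a, bb = (lo - mean_age) / sd_age, (hi - mean_age) / sd_age
            dist = truncnorm(a, bb, loc=mean_age, scale=sd_age)
            weights = np.array(
                [dist.cdf(ab.upper) - dist.cdf(ab.lower) for ab in default_age_bins()]
            )
            weights = weights / weights.sum()
            within = float(weights @ self._bin_vars)
        return (1.0 - v) * s_r + 64.0 * v * within

    def implied_scored_correlation(self) -> np.ndarray:
        """Model-implied correlation matrix of age-normed scaled scores.

        The latent structure ``ΛΛ' + diag ψ`` plus the within-bin
        remainder of the shared demographic component:
        ``[(1-v) R_jk + v (1-b)] / (1 - v b)`` off-diagonal.
        """
        R = self.loadings @ self.loadings.T + np.diag(self.uniquenesses)
        v = self.demographic_variance_share()
        _, _, b = self._demographic_moments()
        out = ((1.0 - v) * R + v * (1.0 - b)) / (1.0 - v * b)
        np.fill_diagonal(out, 1.0)
        return out

    def _link_attenuation(self) -> dict[str, float]:
        """Correlation attenuation through the observation chain.

        Rounded raw-score links (and the step-function lookup of
        session-2 scores through session-1 tables) tie nearby latent
        values together and shave a little off any latent correlation.
        The factor is estimated once per subtest from a large
        fixed-seed draw replaying the exact chain: link both sessions,
        rank-transform session 1, look session 2 up through the
        resulting table.
        """
        if self._attenuation is None:
            from .norming import BinTable, AgeBin, rank_inverse_normal, _dedupe

            rng = np.random.default_rng(_CALIBRATION_SEED + 1)
            # bins the size the configured cohort will actually produce:
            # ties and step-lookup clamping bite harder in small bins
            m_bin = int(np.clip(self.n_subjects // 14, 50, 20_000))
            reps = max(4, int(400_000 // m_bin))
            rho0 = 0.6
            out = {}
            for name, (kind, *_rest) in RAW_SCORE_LINKS.items():
                direction = "lower_better" if kind == "time" else "higher_better"
                acc = 0.0
                for _ in range(reps):
                    t1 = rng.standard_normal(m_bin)
                    t2 = rho0 * t1 + np.sqrt(1.0 - rho0**2) * rng.standard_normal(m_bin)
                    r1 = _apply_link(name, t1)
                    r2 = _apply_link(name, t2)
                    s1 = rank_inverse_normal(r1, direction)
                    raw_u, scaled_u = _dedupe(r1, s1)
                    table = BinTable(bin=AgeBin(13, 90), raw=raw_u, scaled=scaled_u)
                    s2 = table.lookup_many(r2, direction)
                    acc += float(np.corrcoef(s1, s2)[0, 1])
                out[name] = acc / reps / rho0
            self._attenuation = out
        return self._attenuation

    def retest_generation_coefficients(self) -> dict[str, float]:
        """Per-subtest autoregressive weights ρ* for session 2.

        Solved so the *observable* retest correlation of age-normed
        scaled scores equals the configured target r.  Two corrections
        apply to the naive choice ρ* = r.  First, the rounded links
        attenuate latent correlations by a per-subtest factor a.
        Second, per-bin norming recenters and restandardizes each age
        bin, while session 2 carries only ρ* of the session-1
        demographic component; the pooled observable correlation is
        the bin-weighted mean of

            ρ_i(ρ*) = ρ* sqrt(V_i / (ρ*² V_i + 1 - ρ*²)),
            V_i = (1 - v) + v w_i,

        with w_i the within-bin demographic variance share, and ρ* is
        solved numerically from  Σ_i π_i ρ_i(ρ*) = r / a.
        """
        from scipy.optimize import brentq

        v = self.demographic_variance_share()
        self._demographic_moments()
        atten = self._link_attenuation()
        V = (1.0 - v) + v * self._bin_vars
        pi = self._bin_weights

        def observable(rho: float) -> float:
            rho_i = rho * np.sqrt(V / (rho * rho * V + 1.0 - rho * rho))
            return float(pi @ rho_i)

        out = {}
        for name, r in self.retest_reliability.items():
            target = min(r / atten.get(name, 1.0), observable(0.9999) - 1e-9)
            out[name] = float(brentq(lambda x: observable(x) - target, 1e-9, 0.9999))
        return out

    def group_latent_shifts(self, group: str) -> np.ndarray:
        """Per-subtest standardized-score shifts implementing a deficit.

        The published subtest profile (scaled points) is rescaled so
        that the model-implied Grand Index gap equals the configured
        Grand-Index-scale deficit.
        """
        profile = np.array([self.group_profiles[group][s] for s in SUBTESTS])
        target = self.group_gi_deficits[group]
        # implied age-normed GI gap for shifts δ_j: 15 Σδ_j / sd_within(sum)
        sd_sum = np.sqrt(self.within_bin_sum_variance(group))
        scale = target * sd_sum / profile.sum()
        return scale * profile / 15.0

    def practice_latent_shift(self) -> float:
        """Common per-subtest time-2 shift giving the target mean Grand
        Index practice effect."""
        mean_shift = self.practice_shift[0]
        sd_sum = np.sqrt(self.within_bin_sum_variance())
        return mean_shift * sd_sum / (15.0 * len(SUBTESTS))


# ----- demographic draws ---------------------------------------------------


def _draw_ages(rng: np.random.Generator, n: int, mean_age: float) -> np.ndarray:
    """Uniform mixture over [13, 45) and [45, 89] hitting the target mean."""
    m_lo, m_hi = (13.0 + 45.0) / 2.0, (45.0 + 89.0) / 2.0
    w = (m_hi - mean_age) / (m_hi - m_lo)
    w = float(np.clip(w, 0.0, 1.0))
    young = rng.random(n) < w
    ages = np.where(
        young,
        rng.uniform(13.0, 45.0, size=n),
        rng.uniform(45.0, 89.0, size=n),
    )
    return np.round(ages, 2)


def _draw_gender(
    rng: np.random.Generator, n: int, probs: tuple[float, float, float]
) -> tuple[np.ndarray, np.ndarray]:
    """Returns (latent female dummy, recorded category F/M/ND)."""
    u = rng.random(n)
    p_f, p_m, _ = probs
    recorded = np.where(u < p_f, "F", np.where(u < p_f + p_m, "M", "ND"))
    latent_female = (u < p_f).astype(float)
    nd = recorded == "ND"
    if nd.any():  # undisclosed subjects still have a latent gender
        latent_female[nd] = (rng.random(int(nd.sum())) < p_f / (p_f + p_m)).astype(float)
    return latent_female, recorded


def _draw_education(
    rng: np.random.Generator, n: int, probs: tuple[float, float, float, float]
) -> tuple[np.ndarray, np.ndarray]:
    """Returns (latent years, recorded years with NaN for undisclosed)."""
    cat = rng.choice(4, size=n, p=np.asarray(probs) / np.sum(probs))
    years = np.empty(n)
    years[cat == 0] = rng.integers(8, 13, size=int((cat == 0).sum()))
    years[cat == 1] = rng.integers(13, 17, size=int((cat == 1).sum()))
    years[cat == 2] = rng.integers(17, 21, size=int((cat == 2).sum()))
    # undisclosed: latent years from the disclosed mixture
    nd = cat == 3
    if nd.any():
        sub = rng.choice(3, size=int(nd.sum()), p=np.asarray(probs[:3]) / sum(probs[:3]))
        lo = np.array([8, 13, 17])[sub]
        hi = np.array([13, 17, 21])[sub]
        years[nd] = lo + (rng.random(int(nd.sum())) * (hi - lo)).astype(int)
    recorded = years.copy()
    recorded[nd] = np.nan
    return years, recorded


def _truncated_normal(
    rng: np.random.Generator,
    n: int,
    mean: float,
    sd: float,
    lo: float,
    hi: float,
    match_mean: bool = False,
) -> np.ndarray:
    """Truncated-normal draw; with ``match_mean`` the location is
    solved so the truncated distribution's mean equals ``mean`` (the
    published moments describe the observed, already-truncated data)."""
    loc = mean
    if match_mean:
        from scipy.optimize import brentq

        def gap(m):
            a, b = (lo - m) / sd, (hi - m) / sd
            return truncnorm.mean(a, b, loc=m, scale=sd) - mean

        loc = brentq(gap, lo - 5 * sd, hi + 5 * sd)
    a, b = (lo - loc) / sd, (hi - loc) / sd
    return truncnorm.rvs(a, b, loc=loc, scale=sd, size=n, random_state=rng)


def _draw_engagement(rng: np.random.Generator, n: int, cfg: SimulationConfig):
    iti = np.round(_truncated_normal(rng, n, *cfg.iti, match_mean=True))
    days = np.round(_truncated_normal(rng, n, *cfg.days_played, match_mean=True))
    g_mean, g_sd, g_lo, g_hi = cfg.games_played
    sigma2 = np.log1p((g_sd / g_mean) ** 2)
    mu = np.log(g_mean) - sigma2 / 2.0
    games = np.round(np.exp(rng.normal(mu, np.sqrt(sigma2), size=n)))
    games = np.clip(games, g_lo, g_hi)
    return iti, days, games


# ----- main entry ----------------------------------------------------------


def _simulate_group(
    rng: np.random.Generator,
    cfg: SimulationConfig,
    n: int,
    group: str,
    id_offset: int,
) -> pd.DataFrame:
    lam = cfg.loadings
    psi = cfg.uniquenesses
    v = cfg.demographic_variance_share()
    mu_eta, sd_eta, _ = cfg._demographic_moments()

    if group == "healthy":
        age = _draw_ages(rng, n, cfg.mean_age)
    else:
        # clinical self-report groups: older adults (50+)
        mean_age, sd_age = CLINICAL_AGE_PARAMS.get(group, (65.0, 8.5))
        lo, hi = CLINICAL_AGE_BOUNDS
        age = np.round(_truncated_normal(rng, n, mean_age, sd_age, lo, hi), 2)
    female, gender = _draw_gender(rng, n, cfg.gender_probs)
    years, education = _draw_education(rng, n, cfg.education_probs)

    eta = cfg._linear_predictor(female, years, age)
    eta_std = (eta - mu_eta) / sd_eta if sd_eta > 0 else np.zeros(n)

    f = rng.standard_normal((n, lam.shape[1]))
    eps = rng.standard_normal((n, len(SUBTESTS)))
    z = f @ lam.T + eps * np.sqrt(psi)
    t1 = np.sqrt(1.0 - v) * z + np.sqrt(v) * eta_std[:, None]
    if group != "healthy":
        t1 = t1 - cfg.group_latent_shifts(group)[None, :]

    iti, days, games = _draw_engagement(rng, n, cfg)
    ids = [f"S{j:06d}" for j in range(id_offset, id_offset + n)]

    def frame(session: int, t: np.ndarray, engaged: bool) -> pd.DataFrame:
        d = {
            "subject_id": ids,
            "age": age,
            "gender": gender,
            "education_years": education,
            "group": group,
            "session": session,
            "iti_days": iti if engaged else np.zeros(n),
            "days_played": days if engaged else np.zeros(n),
            "games_played": games if engaged else np.zeros(n),
        }
        for j, s in enumerate(SUBTESTS):
            d[s] = _apply_link(s, t[:, j])
        return pd.DataFrame(d)

    frames = [frame(1, t1, engaged=False)]
    if cfg.two_sessions and group == "healthy":
        shift = cfg.practice_latent_shift()
        noise_scale = np.ones(n)
        if cfg.engagement_noise > 0:
            noise_scale = np.sqrt(1.0 + cfg.engagement_noise * games / cfg.games_played[0])
        t2 = np.empty_like(t1)
        e2 = rng.standard_normal((n, len(SUBTESTS)))
        rho = cfg.retest_generation_coefficients()
        for j, s in enumerate(SUBTESTS):
            r = rho[s]
            t2[:, j] = r * t1[:, j] + np.sqrt(1.0 - r * r) * e2[:, j] * noise_scale
        t2 = t2 + shift
        frames.append(frame(2, t2, engaged=True))
    return pd.concat(frames, ignore_index=True)


def simulate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Generate a cohort table per the configuration.

    One row per subject-session, columns per the standard cohort
    schema; fully reproducible given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    frames = []
    offset = 0
    for group, n in (
        ("healthy", config.n_subjects),
        ("MCI", config.n_mci),
        ("AD", config.n_ad),
    ):
        if n > 0:
            frames.append(_simulate_group(rng, config, n, group, offset))
            offset += n
    if not frames:
        raise ValueError("no subjects requested")
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["session", "subject_id"], kind="mergesort").reset_index(
        drop=True
    )
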