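"""Battery definition: the eight subtests, score directions, and calibration tables.

The battery covered here consists of eight brief subtests spanning four
putative cognitive domains (mental flexibility, visuospatial memory,
attention/processing speed, and fluid reasoning).  Raw scores are counts
of correct responses for six subtests and completion time in seconds for
the two trail-making subtests, which is why those two are scored
``lower_better``.

The module also carries the published calibration constants used by the
cohort simulator and by cross-checks elsewhere in the package: the
varimax-rotated four-factor loading matrix, per-subtest test-retest
reliability targets, demographic regression coefficients on the
(non-age-normed) sum-score scale, and the clinical-group deficit
profiles on the scaled-score metric.
"""

from __future__ import annotations

import numpy as np

#: Canonical column order for raw scores in a cohort table.
SUBTESTS: tuple[str, ...] = (
    "trail_a_s",
    "trail_b_s",
    "digit_symbol",
    "fwd_span",
    "rev_span",
    "matrices",
    "arithmetic",
    "grammatical",
)

#: Human-readable names, keyed by column name.
SUBTEST_LABELS: dict[str, str] = {
    "trail_a_s": "Trail Making A",
    "trail_b_s": "Trail Making B",
    "digit_symbol": "Digit Symbol Coding",
    "fwd_span": "Forward Memory Span",
    "rev_span": "Reverse Memory Span",
    "matrices": "Progressive Matrices",
    "arithmetic": "Arithmetic Reasoning",
    "grammatical": "Grammatical Reasoning",
}

#: Score direction per subtest. Completion times: smaller is better.
DIRECTIONS: dict[str, str] = {
    "trail_a_s": "lower_better",
    "trail_b_s": "lower_better",
    "digit_symbol": "higher_better",
    "fwd_span": "higher_better",
    "rev_span": "higher_better",
    "matrices": "higher_better",
    "arithmetic": "higher_better",
    "grammatical": "higher_better",
}

#: Published varimax-rotated loadings on four factors (rows follow
#: ``SUBTESTS``; loadings below the display threshold are taken as 0).
FACTOR_LOADINGS: np.ndarray = np.array(
    [
        # F1     F2     F3     F4
        [0.186, 0.178, 0.671, 0.000],  # trail_a_s
        [0.376, 0.228, 0.455, 0.300],  # trail_b_s
        [0.450, 0.260, 0.388, 0.000],  # digit_symbol
        [0.179, 0.621, 0.196, 0.000],  # fwd_span
        [0.158, 0.731, 0.158, 0.112],  # rev_span
        [0.219, 0.217, 0.000, 0.211],  # matrices
        [0.754, 0.154, 0.211, 0.000],  # arithmetic
        [0.442, 0.160, 0.160, 0.218],  # grammatical
    ]
)

#: Published test-retest reliability targets per subtest (Pearson r).
RETEST_RELIABILITY: dict[str, float] = {
    "trail_a_s": 0.570,
    "trail_b_s": 0.529,
    "digit_symbol": 0.738,
    "fwd_span": 0.530,
    "rev_span": 0.510,
    "matrices": 0.388,
    "arithmetic": 0.734,
    "grammatical": 0.533,
}

#: Published coefficients of the demographic regression on the
#: non-age-normed sum score (eight subtests, each on the 100/15 scale).
#: Gender is coded with male as reference (dummy = 1 for female).
DEMOGRAPHIC_COEFFICIENTS: dict[str, float] = {
    "female": -11.766653,
    "education": 13.290844,
    "age": -0.797219,
    "education:age": -0.139730,
    "female:education": -0.342012,
    "female:age": 0.201607,
}

#: Share of sum-score variance explained by demographics in the source
#: normative cohort; the simulator is calibrated to reproduce it.
DEMOGRAPHIC_R2: float = 0.361

#: Clinical-group mean deficits relative to healthy controls, in scaled
#: points per subtest (rows follow SUBTESTS) and in Grand Index points.
GROUP_DEFICIT_PROFILES: dict[str, dict[str, float]] = {
    "MCI": {
        "trail_a_s": 7.8,
        "trail_b_s": 8.1,
        "digit_symbol": 10.5,
        "fwd_span": 6.5,
        "rev_span": 6.7,
        "matrices": 3.6,
        "arithmetic": 7.5,
        "grammatical": 4.5,
    },
    "AD": {
        "trail_a_s": 9.7,
        "trail_b_s": 12.0,
        "digit_symbol": 17.3,
        "fwd_span": 7.5,
        "rev_span": 9.4,
        "matrices": 4.0,
        "arithmetic": 12.0,
        "grammatical": 8.9,
    },
}

#: Grand-Index-scale deficit targets for the clinical groups.
GROUP_GI_DEFICITS: dict[str, float] = {"MCI": 11.0, "AD": 16.1}


def implied_correlation(loadings: np.ndarray | None = None) -> np.ndarray:
    """Model-implied subtest correlation matrix ``R = ΛΛ' + diag(ψ)``.

    Parameters
    ----------
    loadings
        Standardized factor loadings, one row per subtest.  Defaults to
        the published four-factor solution.
    """
    lam = FACTOR_LOADINGS if loadings is None else np.asarray(loadings, dtype=float)
    psi = derive_uniquenesses(lam)
    return lam @ lam.T + np.diag(psi)


def derive_uniquenesses(loadings: np.ndarray) -> np.ndarray:
    """Uniquenesses ``ψ_j = 1 − Σ_k Λ_jk²`` for standardized loadings.

    Raises
    ------
    ValueError
        If any row has squared norm above 1 (a Heywood row cannot come
        from a proper standardized factor model).
    """
    lam = np.asarray(loadings, dtype=float)
    comm = (lam**2).sum(axis=1)
    if np.any(comm > 1.0 + 1e-12):
        bad = int(np.argmax(comm))
        raise ValueError(
            f"Heywood row: squared loadings of variable {bad} sum to {comm[bad]:.4f} > 1"
        )
    return 1.0 - np.minimum(comm, 1.0)
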