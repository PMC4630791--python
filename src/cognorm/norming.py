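"""Percentile-rank inverse-normal norming and the Grand Index.

The scoring model: within each age bin, raw scores on a subtest are
ranked (mid-rank for ties), converted to percentiles, and the percentile
is mapped through the standard normal quantile function onto a scale
with mean 100 and SD 15:

    s = 100 + 15 * Phi^-1((rank - 0.5) / n)

One lookup table per subtest and age bin results.  Per-subtest scaled
scores are summed and the same transformation, applied to the sums over
the norming cohort, defines the battery-level aggregate ("Grand Index")
table.  Subtests where smaller raw values mean better performance
(completion times) are ranked on the negated raw score, so a faster time
always earns a higher scaled score.

Age bins span 13-19, twelve 5-year bins, and 80-89; ages outside
[13, 90) are outside the normative range and rejected.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import rankdata

from .battery import DIRECTIONS, SUBTESTS

TARGET_MEAN = 100.0
TARGET_SD = 15.0

#: Supported percentile (plotting-position) conventions.
POSITIONS = ("midpoint", "rankit")


class BinUnderflowError(ValueError):
    """An age bin contains fewer than two subjects."""


class CoverageError(ValueError):
    """A subject's age is not covered by the norm tables."""


class IncompleteBatteryError(ValueError):
    """A subject is missing one or more raw subtest scores."""


@dataclass(frozen=True)
class AgeBin:
    """Half-open age interval ``[lower, upper)`` in years.

    The conventional scheme makes the first bin 13-19 and the last
    80-89; display labels use the inclusive integer convention.
    """

    lower: float
    upper: float

    def __contains__(self, age: float) -> bool:
        return self.lower <= age < self.upper

    @property
    def label(self) -> str:
        return f"{self.lower:g}-{self.upper - 1:g}"


def default_age_bins() -> list[AgeBin]:
    """The 14-bin scheme: 13-19, 20-24, ..., 75-79, 80-89."""
    bins = [AgeBin(13, 20)]
    bins += [AgeBin(lo, lo + 5) for lo in range(20, 80, 5)]
    bins.append(AgeBin(80, 90))
    return bins


def single_age_bin() -> list[AgeBin]:
    """One bin spanning the whole normative age range."""
    return [AgeBin(13, 90)]


def rank_inverse_normal(
    values,
    direction: str = "higher_better",
    position: str = "midpoint",
    mean: float = TARGET_MEAN,
    sd: float = TARGET_SD,
) -> np.ndarray:
    """Scale raw measurements by the percentile-rank inverse-normal map.

    Parameters
    ----------
    values
        Raw measurements; at least two, all finite.
    direction
        ``"higher_better"`` or ``"lower_better"``.  With
        ``lower_better`` the negated values are ranked, so smaller raw
        values receive larger scaled scores.
    position
        Plotting position for the percentile of mid-rank ``r`` among
        ``n``: ``"midpoint"`` uses ``(r - 0.5)/n`` (exactly symmetric,
        sample mean exactly ``mean`` for distinct values); ``"rankit"``
        uses ``r/(n + 1)``.
    mean, sd
        Target location and scale of the output (default 100 and 15).

    Returns
    -------
    numpy.ndarray
        Scaled scores aligned with the input; ties share a value.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        x = x.ravel()
    if x.size < 2:
        raise ValueError("rank_inverse_normal requires at least 2 values")
    if not np.all(np.isfinite(x)):
        raise ValueError("rank_inverse_normal requires finite values")
    if direction not in ("higher_better", "lower_better"):
        raise ValueError(f"unknown direction {direction!r}")
    if position not in POSITIONS:
        raise ValueError(f"unknown plotting position {position!r}")

    perf = x if direction == "higher_better" else -x
    ranks = rankdata(perf, method="average")
    n = x.size
    if position == "midpoint":
        pct = (ranks - 0.5) / n
    else:
        pct = ranks / (n + 1)
    return mean + sd * ndtri(pct)


@dataclass
class BinTable:
    """Raw-to-scaled lookup for one age bin of one subtest."""

    bin: AgeBin
    raw: np.ndarray  # ascending raw values (unique)
    scaled: np.ndarray  # aligned scaled scores

    def lookup(self, value: float, direction: str) -> float:
        """Scaled score for a raw value, seen or unseen.

        Unseen values take the scaled score of the nearest observed raw
        value on the worse-performance side (a step function, so
        performance not demonstrated is never credited); values beyond
        the observed range clamp to the bin's extreme scaled score.
        """
        if direction == "higher_better":
            idx = np.searchsorted(self.raw, value, side="right") - 1
            idx = max(idx, 0)
        else:
            idx = np.searchsorted(self.raw, value, side="left")
            idx = min(idx, self.raw.size - 1)
        return float(self.scaled[idx])

    def lookup_many(self, values: np.ndarray, direction: str) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        if direction == "higher_better":
            idx = np.searchsorted(self.raw, values, side="right") - 1
            idx = np.maximum(idx, 0)
        else:
            idx = np.searchsorted(self.raw, values, side="left")
            idx = np.minimum(idx, self.raw.size - 1)
        return self.scaled[idx]


@dataclass
class NormTable:
    """Per-subtest normative table: one raw-to-scaled map per age bin."""

    subtest: str
    direction: str
    bins: list[BinTable]
    target_mean: float = TARGET_MEAN
    target_sd: float = TARGET_SD

    def bin_for(self, age: float) -> BinTable:
        for bt in self.bins:
            if age in bt.bin:
                return bt
        raise CoverageError(
            f"age {age:g} outside the bins of the {self.subtest} norm table"
        )

    def score(self, age: float, raw: float) -> float:
        return self.bin_for(age).lookup(raw, self.direction)


@dataclass
class AggregateTable:
    """Battery-level sum-score to Grand Index step function."""

    raw: np.ndarray  # ascending sum scores observed in the norming cohort
    scaled: np.ndarray

    def lookup_many(self, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        idx = np.searchsorted(self.raw, values, side="right") - 1
        idx = np.maximum(idx, 0)
        return self.scaled[idx]


def _dedupe(raw: np.ndarray, scaled: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    order = np.argsort(raw, kind="mergesort")
    raw, scaled = raw[order], scaled[order]
    keep = np.empty(raw.size, dtype=bool)
    keep[0] = True
    keep[1:] = np.diff(raw) != 0
    return raw[keep].copy(), scaled[keep].copy()


def build_norm_tables(
    cohort: pd.DataFrame,
    bin_scheme: list[AgeBin] | None = None,
    subtests: tuple[str, ...] = SUBTESTS,
    position: str = "midpoint",
) -> dict[str, NormTable]:
    """Build one :class:`NormTable` per subtest from a norming cohort.

    Every subject's age must fall in some bin and every bin must hold at
    least two subjects (a percentile needs company).
    """
    bins = default_age_bins() if bin_scheme is None else list(bin_scheme)
    ages = cohort["age"].to_numpy(dtype=float)
    membership = np.full(ages.size, -1)
    for i, b in enumerate(bins):
        membership[(ages >= b.lower) & (ages < b.upper)] = i
    if np.any(membership < 0):
        bad = ages[membership < 0][0]
        raise CoverageError(f"age {bad:g} outside all age bins")

    tables: dict[str, NormTable] = {}
    for subtest in subtests:
        direction = DIRECTIONS.get(subtest, "higher_better")
        raws_all = cohort[subtest].to_numpy(dtype=float)
        bin_tables = []
        for i, b in enumerate(bins):
            mask = membership == i
            count = int(mask.sum())
            if count < 2:
                raise BinUnderflowError(
                    f"age bin {b.label} holds {count} subject(s); need >= 2"
                )
            raws = raws_all[mask]
            scaled = rank_inverse_normal(raws, direction, position=position)
            raw_u, scaled_u = _dedupe(raws, scaled)
            bin_tables.append(BinTable(bin=b, raw=raw_u, scaled=scaled_u))
        tables[subtest] = NormTable(subtest=subtest, direction=direction, bins=bin_tables)
    return tables


def build_aggregate_table(sum_scores, position: str = "midpoint") -> AggregateTable:
    """Grand Index table: the inverse-normal map applied to sum scores."""
    sums = np.asarray(sum_scores, dtype=float)
    gi = rank_inverse_normal(sums, "higher_better", position=position)
    raw_u, scaled_u = _dedupe(sums, gi)
    return AggregateTable(raw=raw_u, scaled=scaled_u)


def score_subjects(
    cohort: pd.DataFrame,
    tables: dict[str, NormTable],
    aggregate_table: AggregateTable | None = None,
    position: str = "midpoint",
) -> pd.DataFrame:
    """Score a cohort through norm tables; returns per-subject results.

    Output columns: ``scaled_<subtest>`` for every subtest in
    ``tables``, ``sum_score``, and ``grand_index``.  The index of
    ``cohort`` is preserved.

    If ``aggregate_table`` is None the Grand Index table is built from
    this cohort's own sum scores (the norming-cohort case); pass a
    stored table to score new individuals against existing norms.
    """
    missing_cols = [s for s in tables if s not in cohort.columns]
    if missing_cols:
        raise IncompleteBatteryError(f"cohort lacks raw-score columns: {missing_cols}")
    raw_block = cohort[list(tables)]
    if raw_block.isna().any().any():
        n_bad = int(raw_block.isna().any(axis=1).sum())
        raise IncompleteBatteryError(
            f"{n_bad} subject(s) missing raw subtest scores; the battery must be complete"
        )

    ages = cohort["age"].to_numpy(dtype=float)
    out = pd.DataFrame(index=cohort.index)
    for subtest, table in tables.items():
        raws = cohort[subtest].to_numpy(dtype=float)
        scaled = np.empty_like(raws)
        assigned = np.zeros(raws.size, dtype=bool)
        for bt in table.bins:
            mask = (ages >= bt.bin.lower) & (ages < bt.bin.upper)
            if mask.any():
                scaled[mask] = bt.lookup_many(raws[mask], table.direction)
                assigned |= mask
        if not assigned.all():
            bad = ages[~assigned][0]
            raise CoverageError(f"age {bad:g} outside the norm tables")
        out[f"scaled_{subtest}"] = scaled

    out["sum_score"] = out.sum(axis=1)
    if aggregate_table is None:
        aggregate_table = build_aggregate_table(
            out["sum_score"].to_numpy(), position=position
        )
    out["grand_index"] = aggregate_table.lookup_many(out["sum_score"].to_numpy())
    return out


def scale_without_age(
    cohort: pd.DataFrame,
    subtests: tuple[str, ...] = SUBTESTS,
    position: str = "midpoint",
) -> pd.DataFrame:
    """Non-age-normed scaling: a single bin spanning the whole cohort.

    Used by the demographic regression, where age must stay visible in
    the outcome.  Returns ``scaled_<subtest>`` columns and their
    ``sum_score``; no Grand Index (the aggregate is age-normed by
    definition in this pipeline).
    """
    out = pd.DataFrame(index=cohort.index)
    for subtest in subtests:
        direction = DIRECTIONS.get(subtest, "higher_better")
        out[f"scaled_{subtest}"] = rank_inverse_normal(
            cohort[subtest].to_numpy(dtype=float), direction, position=position
        )
    out["sum_score"] = out.sum(axis=1)
    return out


@dataclass
class NormModel:
    """Bundle of per-subtest norm tables plus the Grand Index table.

    ``fit`` builds everything from a norming cohort; ``score`` applies
    the stored tables to any cohort (including the norming cohort
    itself, which reproduces its scores bit-for-bit).
    """

    tables: dict[str, NormTable]
    aggregate: AggregateTable
    bin_scheme: list[AgeBin] = field(default_factory=default_age_bins)
    position: str = "midpoint"

    @classmethod
    def fit(
        cls,
        cohort: pd.DataFrame,
        bin_scheme: list[AgeBin] | None = None,
        subtests: tuple[str, ...] = SUBTESTS,
        position: str = "midpoint",
    ) -> "NormModel":
        bins = default_age_bins() if bin_scheme is None else list(bin_scheme)
        tables = build_norm_tables(cohort, bins, subtests, position=position)
        scored = score_subjects(cohort, tables, aggregate_table=None, position=position)
        aggregate = build_aggregate_table(
            scored["sum_score"].to_numpy(), position=position
        )
        return cls(tables=tables, aggregate=aggregate, bin_scheme=bins, position=position)

    def score(self, cohort: pd.DataFrame) -> pd.DataFrame:
        return score_subjects(cohort, self.tables, self.aggregate)

    # ----- JSON round trip -------------------------------------------------

    FORMAT_VERSION = 1

    def to_dict(self) -> dict:
        return {
            "format_version": self.FORMAT_VERSION,
            "position": self.position,
            "subtests": {
                name: {
                    "direction": t.direction,
                    "bins": [
                        {
                            "lower": bt.bin.lower,
                            "upper": bt.bin.upper,
                            "raw": bt.raw.tolist(),
                            "scaled": bt.scaled.tolist(),
                        }
                        for bt in t.bins
                    ],
                }
                for name, t in self.tables.items()
            },
            "aggregate": {
                "raw": self.aggregate.raw.tolist(),
                "scaled": self.aggregate.scaled.tolist(),
            },
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "NormModel":
        version = payload.get("format_version")
        if version != cls.FORMAT_VERSION:
            raise ValueError(
                f"norm-table format version {version!r} is not supported "
                f"(expected {cls.FORMAT_VERSION})"
            )
        tables = {}
        bin_scheme: list[AgeBin] = []
        for name, entry in payload["subtests"].items():
            bts = []
            for b in entry["bins"]:
                ab = AgeBin(b["lower"], b["upper"])
                bts.append(
                    BinTable(
                        bin=ab,
                        raw=np.asarray(b["raw"], dtype=float),
                        scaled=np.asarray(b["scaled"], dtype=float),
                    )
                )
            tables[name] = NormTable(subtest=name, direction=entry["direction"], bins=bts)
            if not bin_scheme:
                bin_scheme = [bt.bin for bt in bts]
        aggregate = AggregateTable(
            raw=np.asarray(payload["aggregate"]["raw"], dtype=float),
            scaled=np.asarray(payload["aggregate"]["scaled"], dtype=float),
        )
        return cls(
            tables=tables,
            aggregate=aggregate,
            bin_scheme=bin_scheme,
            position=payload.get("position", "midpoint"),
        )
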