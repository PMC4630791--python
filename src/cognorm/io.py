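"""Cohort and norm-table readers and writers.

Cohort files are comma-delimited (TSV accepted by extension), UTF-8,
with a header.  Required columns: ``subject_id``, ``age``, ``gender``,
``education_years``, ``group``, ``session``, plus the eight raw-score
columns.  ``ND`` parses as missing; rows violating the schema (age
outside the 13-89 normative range, non-positive completion times,
negative counts, unparseable numbers) are rejected with line-numbered
diagnostics.  Norm tables round-trip losslessly through JSON.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .battery import SUBTESTS
from .norming import NormModel

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = (
    "subject_id",
    "age",
    "gender",
    "education_years",
    "group",
    "session",
) + SUBTESTS

ENGAGEMENT_COLUMNS = ("iti_days", "days_played", "games_played")

GENDER_CATEGORIES = {"F", "M", "ND"}
GROUP_CATEGORIES = {"healthy", "MCI", "AD", "other"}

#: Subtests whose raw score is a completion time (must be > 0).
TIME_SUBTESTS = ("trail_a_s", "trail_b_s")


class SchemaError(ValueError):
    """The file is structurally unusable (missing columns, bad header)."""


def _delimiter_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_cohort(path, strict: bool = True) -> pd.DataFrame:
    """Read and validate a cohort table.

    Invalid rows are dropped with line-numbered diagnostics (or raise
    when ``strict`` and every row is invalid).  Missing engagement
    columns are added as 0 with a warning — a legitimately disengaged
    cohort looks the same.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_delimiter_for(path), na_values=["ND", ""], dtype=str)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s): {missing}")

    for col in ENGAGEMENT_COLUMNS:
        if col not in df.columns:
            logger.warning("%s: column %r absent; defaulting to 0", path.name, col)
            df[col] = "0"
    df[list(ENGAGEMENT_COLUMNS)] = df[list(ENGAGEMENT_COLUMNS)].fillna("0")

    numeric_cols = ("age", "education_years", "session", *ENGAGEMENT_COLUMNS, *SUBTESTS)
    parsed = df.copy()
    for col in numeric_cols:
        parsed[col] = pd.to_numeric(df[col], errors="coerce")

    # line numbers: header is line 1
    lines = np.arange(2, len(df) + 2)
    bad = pd.Series(False, index=df.index)
    reasons: list[str] = []

    def flag(mask: pd.Series, reason: str) -> None:
        nonlocal bad
        mask = mask.fillna(False) if mask.dtype == object else mask
        new = mask & ~bad
        for ln in lines[new.to_numpy()][:5]:
            reasons.append(f"line {ln}: {reason}")
        bad |= mask

    for col in ("age", "session", *SUBTESTS):
        flag(parsed[col].isna(), f"unparseable or missing {col}")
    flag(~parsed["age"].between(13, 90, inclusive="left") & parsed["age"].notna(),
         "age outside the normative range 13-89")
    flag(~parsed["session"].isin([1, 2]) & parsed["session"].notna(),
         "session must be 1 or 2")
    gender_ok = df["gender"].isna() | df["gender"].isin(GENDER_CATEGORIES)
    flag(~gender_ok, "gender must be F, M, or ND")
    group_ok = df["group"].isna() | df["group"].isin(GROUP_CATEGORIES)
    flag(~group_ok, "unknown group label")
    for col in TIME_SUBTESTS:
        flag((parsed[col] <= 0) & parsed[col].notna(), f"{col} must be > 0")
    for col in SUBTESTS:
        if col not in TIME_SUBTESTS:
            flag((parsed[col] < 0) & parsed[col].notna(), f"{col} must be >= 0")

    n_bad = int(bad.sum())
    if n_bad:
        for msg in reasons:
            logger.warning("%s: rejected row — %s", path.name, msg)
        logger.warning("%s: rejected %d invalid row(s) of %d", path.name, n_bad, len(df))
        if strict and n_bad == len(df):
            raise ValueError(f"{path.name}: no valid rows")

    out = parsed[~bad].copy()
    out["gender"] = df.loc[~bad, "gender"]
    out["group"] = df.loc[~bad, "group"].fillna("healthy")
    out["session"] = out["session"].astype(int)
    dup = out.duplicated(subset=["subject_id", "session"])
    if dup.any():
        logger.warning("%s: dropped %d duplicate subject-session row(s)",
                       path.name, int(dup.sum()))
        out = out[~dup]
    return out.reset_index(drop=True)


def write_cohort(cohort: pd.DataFrame, path) -> None:
    path = Path(path)
    cohort.to_csv(path, sep=_delimiter_for(path), index=False, na_rep="ND")


def write_norm_tables(model: NormModel, path) -> None:
    """Serialize a fitted norm model (per-subtest tables + aggregate)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        json.dump(model.to_dict(), fh)


def read_norm_tables(path) -> NormModel:
    """Load a norm model; raises on truncation or version mismatch."""
    path = Path(path)
    try:
        with path.open("r", encoding="utf-8") as fh:
            payload = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path.name}: not a valid norm-table file ({exc})") from exc
    return NormModel.from_dict(payload)
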