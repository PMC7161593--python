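"""Long-format cohort schema: reading, validation, exclusions, missing coding.

The canonical container is a :class:`Cohort`: a pandas DataFrame with one row
per person-wave, plus the ordered wave labels and the covariate-role lists.
Long format is canonical; any wide layout is a derived view.

Clock times are stored on disk as ``"HH:MM"`` strings and in memory as integer
minutes since midnight (0-1439).  Missing values are empty cells or the
literal ``NA`` on disk and ``pd.NA``/``NaN`` in memory; no numeric sentinels.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: Study-wave labels, in follow-up order (unequally spaced survey waves).
DEFAULT_WAVES: tuple[int, ...] = (1, 2, 3, 6, 8, 9)

#: Depression bands: average symptom score grouped into four ordered bands.
DEPRESSION_BANDS: tuple[str, ...] = ("0", "<=1", "<=2", ">2")

#: Extra level appended by the missing-indicator coding.
MISSING_LEVEL = "MISSING"

CLOCK_COLUMNS = ("wd_bed", "wd_wake", "we_bed", "we_wake")
DISTURBANCE_COLUMNS = ("dist_insomnia", "dist_early_wake", "dist_night_wake")
OUTCOME_COLUMNS = ("outcome_cig", "outcome_alc")

DEFAULT_TIME_INVARIANT = (
    "gender",
    "school_urbanization",
    "township_type",
    "pubertal_timing",
    "expected_achievement",
    "father_ethnicity",
)
DEFAULT_TIME_VARYING = ("depression", "self_rated_health", "cram_school")

_CLOCK_RE = re.compile(r"^(\d{1,2}):(\d{2})$")


class CohortValidationError(ValueError):
    """Raised when a cohort file violates the schema."""


# ---------------------------------------------------------------------------
# clock times
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClockTime:
    """A time of day, stored as minutes since midnight in [0, 1439]."""

    minutes_since_midnight: int

    def __post_init__(self) -> None:
        m = self.minutes_since_midnight
        if not (0 <= m <= 1439):
            raise ValueError(f"clock time out of range: {m} minutes")

    @classmethod
    def parse(cls, text: str) -> "ClockTime":
        match = _CLOCK_RE.match(str(text).strip())
        if not match:
            raise ValueError(f"cannot parse clock time {text!r} (expected HH:MM)")
        hours, minutes = int(match.group(1)), int(match.group(2))
        if hours > 23 or minutes > 59:
            raise ValueError(f"clock time out of range: {text!r}")
        return cls(hours * 60 + minutes)

    def __str__(self) -> str:
        h, m = divmod(self.minutes_since_midnight, 60)
        return f"{h:02d}:{m:02d}"


def parse_clock_minutes(value) -> float:
    """Parse one ``HH:MM`` cell to float minutes; NaN for missing."""
    if value is None or (isinstance(value, float) and np.isnan(value)) or value is pd.NA:
        return np.nan
    if isinstance(value, ClockTime):
        return float(value.minutes_since_midnight)
    text = str(value).strip()
    if text == "" or text.upper() == "NA":
        return np.nan
    return float(ClockTime.parse(text).minutes_since_midnight)


def format_clock_minutes(minutes: float) -> str:
    if pd.isna(minutes):
        return ""
    return str(ClockTime(int(round(minutes))))


# ---------------------------------------------------------------------------
# cohort container
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    """Long-format panel: one row per (person, wave).

    ``data`` carries clock columns as float minutes since midnight,
    disturbance items as floats (NaN = missing), covariates as strings
    (or NaN), and outcomes as floats present only at the final wave.
    """

    data: pd.DataFrame
    wave_order: tuple[int, ...] = DEFAULT_WAVES
    time_invariant: tuple[str, ...] = DEFAULT_TIME_INVARIANT
    time_varying: tuple[str, ...] = DEFAULT_TIME_VARYING

    @property
    def exposure_waves(self) -> tuple[int, ...]:
        """Waves at which sleep practices are assessed (all but the first)."""
        return self.wave_order[1:]

    @property
    def outcome_wave(self) -> int:
        return self.wave_order[-1]

    @property
    def persons(self) -> pd.Index:
        w1 = self.data[self.data["wave"] == self.wave_order[0]]
        return pd.Index(w1["pid"].to_numpy(), name="pid")

    def wave_frame(self, wave: int) -> pd.DataFrame:
        """Rows for one wave, indexed by person id."""
        sub = self.data[self.data["wave"] == wave]
        return sub.set_index("pid")

    def with_data(self, data: pd.DataFrame) -> "Cohort":
        return replace(self, data=data.reset_index(drop=True))


# ---------------------------------------------------------------------------
# read / write / validate
# ---------------------------------------------------------------------------

def load_schema_config(path) -> dict:
    """Read a YAML column-mapping config ({csv column -> canonical field})."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise CohortValidationError("schema config must be a mapping")
    return cfg


def read_cohort(path, schema_config: dict | None = None,
                wave_order: tuple[int, ...] | None = None,
                time_invariant: tuple[str, ...] = DEFAULT_TIME_INVARIANT,
                time_varying: tuple[str, ...] = DEFAULT_TIME_VARYING) -> Cohort:
    """Read and validate a long-format cohort CSV.

    Parameters
    ----------
    schema_config
        Optional mapping ``{csv_column: canonical_field}`` (or a dict loaded
        from YAML via :func:`load_schema_config`) renaming columns before
        validation; may also carry a ``waves`` list.
    wave_order
        Ordered wave labels.  When omitted, the sorted labels present in the
        file are used, after checking they are known study waves.
    """
    df = pd.read_csv(path, dtype={"pid": str}, na_values=["NA", ""],
                     keep_default_na=True)
    if schema_config:
        column_map = schema_config.get("columns", schema_config)
        if isinstance(column_map, dict):
            df = df.rename(columns=column_map)
        if wave_order is None and "waves" in schema_config:
            wave_order = tuple(schema_config["waves"])
    if wave_order is None:
        labels = tuple(sorted(df["wave"].unique()))
        unknown = set(labels) - set(DEFAULT_WAVES)
        if unknown:
            raise CohortValidationError(
                f"unknown wave labels {sorted(unknown)}; "
                f"expected a subset of {DEFAULT_WAVES}")
        wave_order = labels
    for col in CLOCK_COLUMNS:
        if col in df.columns:
            df[col] = df[col].map(parse_clock_minutes)
    cohort = Cohort(df.reset_index(drop=True), tuple(wave_order),
                    tuple(time_invariant), tuple(time_varying))
    validate_cohort(cohort)
    return cohort


def write_cohort(cohort: Cohort, path) -> None:
    """Write the cohort back to CSV (clock columns rendered as HH:MM)."""
    out = cohort.data.copy()
    for col in CLOCK_COLUMNS:
        if col in out.columns:
            out[col] = out[col].map(format_clock_minutes)
    out.to_csv(path, index=False, na_rep="")


def validate_cohort(cohort: Cohort) -> None:
    """Hard-fail validation of the long-format invariants."""
    df = cohort.data
    for col in ("pid", "wave", "observed"):
        if col not in df.columns:
            raise CohortValidationError(f"missing required column {col!r}")

    unknown = set(df["wave"].unique()) - set(cohort.wave_order)
    if unknown:
        raise CohortValidationError(
            f"unknown wave labels {sorted(unknown)}; expected {cohort.wave_order}")

    dup = df.duplicated(subset=["pid", "wave"])
    if dup.any():
        row = df[dup].iloc[0]
        raise CohortValidationError(
            f"duplicate record for person {row['pid']!r} at wave {row['wave']}")

    first = cohort.wave_order[0]
    have_first = set(df.loc[df["wave"] == first, "pid"])
    missing_first = set(df["pid"]) - have_first
    if missing_first:
        raise CohortValidationError(
            f"persons without a wave-{first} record: {sorted(missing_first)[:5]}")

    for col in DISTURBANCE_COLUMNS:
        if col not in df.columns:
            continue
        vals = pd.to_numeric(df[col], errors="coerce")
        bad_parse = df[col].notna() & vals.isna()
        if bad_parse.any():
            raise CohortValidationError(
                f"non-numeric disturbance item in {col!r} at row "
                f"{int(np.flatnonzero(bad_parse)[0])}")
        ok = vals.isna() | (vals.isin([0, 1, 2, 3, 4]))
        if not ok.all():
            row = int(np.flatnonzero(~ok)[0])
            raise CohortValidationError(
                f"disturbance item out of 0-4 range in {col!r} at row {row} "
                f"(value {df[col].iloc[row]!r})")

    for col in OUTCOME_COLUMNS:
        if col not in df.columns:
            continue
        off_wave = df[col].notna() & (df["wave"] != cohort.outcome_wave)
        if off_wave.any():
            row = int(np.flatnonzero(off_wave)[0])
            raise CohortValidationError(
                f"outcome {col!r} present off the final wave at row {row}")

    if "depression" in df.columns:
        levels = set(map(str, df["depression"].dropna().unique()))
        allowed = set(DEPRESSION_BANDS) | {MISSING_LEVEL}
        extra = levels - allowed
        if extra:
            raise CohortValidationError(
                f"unknown depression bands {sorted(extra)}; allowed {sorted(allowed)}")

    # unobserved person-waves must carry no wave-specific measurements
    wave_specific = [c for c in
                     (*CLOCK_COLUMNS, *DISTURBANCE_COLUMNS, *cohort.time_varying)
                     if c in df.columns]
    unobs = ~df["observed"].astype(bool)
    if wave_specific and unobs.any():
        present = df.loc[unobs, wave_specific].notna()
        if present.any().any():
            col = present.any()[present.any()].index[0]
            raise CohortValidationError(
                f"unobserved person-wave carries a value in {col!r}")


# ---------------------------------------------------------------------------
# baseline exclusions
# ---------------------------------------------------------------------------

def baseline_exclusion_counts(cohort: Cohort,
                              baseline_use_col: str = "ever_substance") -> dict:
    """Counts removed by each entry rule, without applying them."""
    first = cohort.wave_order[0]
    w1 = cohort.wave_frame(first)
    w9 = cohort.wave_frame(cohort.outcome_wave)

    if baseline_use_col in w1.columns:
        users = set(w1.index[w1[baseline_use_col].astype("string") == "yes"])
    else:
        users = set()
    missing_outcome = set(
        w9.index[w9[list(OUTCOME_COLUMNS)].isna().any(axis=1)])
    missing_outcome |= set(w1.index) - set(w9.index)

    return {
        "baseline_substance_use": len(users),
        "missing_final_outcome": len(missing_outcome - users),
        "retained": len(set(w1.index) - users - missing_outcome),
    }


def apply_baseline_exclusions(cohort: Cohort,
                              baseline_use_col: str = "ever_substance") -> Cohort:
    """Apply the two cohort-entry rules.

    Removes (1) persons reporting any smoking or drinking at the first wave
    and (2) persons with a missing substance-use outcome at the final wave.
    Idempotent; logs the count removed per rule.
    """
    first = cohort.wave_order[0]
    w1 = cohort.wave_frame(first)
    w9 = cohort.wave_frame(cohort.outcome_wave)

    if baseline_use_col in w1.columns:
        users = set(w1.index[w1[baseline_use_col].astype("string") == "yes"])
    else:
        users = set()
    missing_outcome = set(
        w9.index[w9[list(OUTCOME_COLUMNS)].isna().any(axis=1)])
    missing_outcome |= set(w1.index) - set(w9.index)

    logger.info("baseline exclusions: %d first-wave substance users, "
                "%d missing final-wave outcomes", len(users),
                len(missing_outcome - users))

    drop = users | missing_outcome
    keep = ~cohort.data["pid"].isin(drop)
    return cohort.with_data(cohort.data[keep])


# ---------------------------------------------------------------------------
# missing-indicator coding
# ---------------------------------------------------------------------------

def encode_missing_indicator(cohort: Cohort, variables: list[str]) -> Cohort:
    """Replace item non-response in categorical variables with a MISSING level.

    This is the classic indicator-variable treatment of item non-response:
    every listed variable gains one extra category and no row is dropped.
    Values are only rewritten where they are missing; observed levels are
    untouched.  Applying it to a numeric (undeclared-coding) column is an
    error — a continuous variable has no natural extra category.
    """
    df = cohort.data.copy()
    for var in variables:
        if var not in df.columns:
            raise KeyError(f"unknown variable {var!r}")
        col = df[var]
        if pd.api.types.is_numeric_dtype(col) and not pd.api.types.is_bool_dtype(col):
            raise TypeError(
                f"{var!r} is numeric; declare a categorical binning before "
                "missing-indicator coding")
        df[var] = col.astype("object").where(col.notna(), MISSING_LEVEL)
    return cohort.with_data(df)
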