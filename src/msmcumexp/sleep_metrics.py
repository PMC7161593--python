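"""Derive the three dichotomized unhealthy-sleep exposures from raw survey fields.

Practices and their dichotomization cutoffs:

``short_sleep``
    Weekly average nightly sleep (5 weekday + 2 weekend nights, divided by 7)
    strictly below a cutoff of 8, 7, or 6 hours.
``social_jetlag``
    Weekend bedtime minus weekday bedtime (hours, signed), at or above a
    cutoff of 2, 1, or 0.5 hours.  Positive means a later weekend bedtime.
``disturbance``
    Sum of three 0-4 insomnia/awakening items; present when the sum
    exceeds 0.

Bedtime-day convention: a reported bedtime in [12:00, 24:00) belongs to the
same evening; one in [00:00, 12:00) is past midnight and counted as next-day
(+24 h) before any subtraction.  Without this, a 01:00 bedtime would appear
22 hours *earlier* than a 23:00 one.

The cumulative exposure of a person is the count of exposed waves over the
five assessment waves; a missing wave contributes zero (the person is kept,
and wave-level attrition is handled by the attrition weights downstream).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel_io import Cohort, DISTURBANCE_COLUMNS, parse_clock_minutes

PRACTICES = ("short_sleep", "social_jetlag", "disturbance")

SHORT_SLEEP_CUTOFFS = (8.0, 7.0, 6.0)
JETLAG_CUTOFFS = (2.0, 1.0, 0.5)

#: Default cutoff used when one practice enters another practice's analysis
#: as a covariate.
DEFAULT_CUTOFFS = {"short_sleep": 8.0, "social_jetlag": 1.0, "disturbance": 0.0}


def _to_minutes(value) -> float:
    """Accept HH:MM strings, ClockTime, or numeric minutes."""
    if isinstance(value, (int, float, np.integer, np.floating)):
        return float(value)
    return parse_clock_minutes(value)


# ---------------------------------------------------------------------------
# scalar / vectorized metric operations
# ---------------------------------------------------------------------------

def sleep_duration(bed, wake) -> float:
    """Hours asleep from bed to wake clock times; crosses midnight as needed.

    Equal bed and wake times are rejected: a same-clock report is ambiguous
    between 0 and 24 hours.
    """
    b, w = _to_minutes(bed), _to_minutes(wake)
    if np.isnan(b) or np.isnan(w):
        return np.nan
    if b == w:
        raise ValueError("bed and wake times are equal: 0 vs 24 h is ambiguous")
    span = (w - b) % 1440.0
    return span / 60.0


def weekly_average_sleep(weekday_hours, weekend_hours):
    """Weekly average nightly sleep: (5 x weekday + 2 x weekend) / 7."""
    return (5.0 * np.asarray(weekday_hours) + 2.0 * np.asarray(weekend_hours)) / 7.0


def short_sleep_indicator(weekly_hours, cutoff: float, *, strict_cutoffs: bool = True):
    """1 if the weekly average is strictly below the cutoff ("less than")."""
    if strict_cutoffs and cutoff not in SHORT_SLEEP_CUTOFFS:
        raise ValueError(
            f"short-sleep cutoff {cutoff} not in {SHORT_SLEEP_CUTOFFS}; "
            "pass strict_cutoffs=False to override")
    h = np.asarray(weekly_hours, dtype=float)
    out = np.where(np.isnan(h), np.nan, (h < cutoff).astype(float))
    return out if out.ndim else float(out)


def _bedtime_day_hours(minutes: np.ndarray) -> np.ndarray:
    """Map clock minutes to hours on the bedtime-day axis ([12, 36))."""
    hours = minutes / 60.0
    return np.where(hours < 12.0, hours + 24.0, hours)


def social_jetlag(weekday_bed, weekend_bed) -> float:
    """Signed weekend-minus-weekday bedtime difference in hours."""
    wd = np.asarray(_to_minutes(weekday_bed) if np.isscalar(weekday_bed)
                    or isinstance(weekday_bed, str) else weekday_bed, dtype=float)
    we = np.asarray(_to_minutes(weekend_bed) if np.isscalar(weekend_bed)
                    or isinstance(weekend_bed, str) else weekend_bed, dtype=float)
    out = _bedtime_day_hours(we) - _bedtime_day_hours(wd)
    return out if out.ndim else float(out)


def jetlag_indicator(jetlag_hours, cutoff: float, *, strict_cutoffs: bool = True):
    """1 if jetlag is at or above the cutoff (inclusive)."""
    if strict_cutoffs and cutoff not in JETLAG_CUTOFFS:
        raise ValueError(
            f"social-jetlag cutoff {cutoff} not in {JETLAG_CUTOFFS}; "
            "pass strict_cutoffs=False to override")
    j = np.asarray(jetlag_hours, dtype=float)
    out = np.where(np.isnan(j), np.nan, (j >= cutoff).astype(float))
    return out if out.ndim else float(out)


def disturbance_score(items) -> float:
    """Sum of the three 0-4 disturbance items (0-12)."""
    arr = np.asarray(items, dtype=float)
    if arr.shape[-1] != 3:
        raise ValueError("expected exactly three disturbance items")
    if np.any((arr < 0) | (arr > 4)):
        raise ValueError("disturbance items must lie in 0-4")
    return arr.sum(axis=-1)


def disturbance_indicator(score):
    """1 if the disturbance sum score exceeds 0."""
    s = np.asarray(score, dtype=float)
    out = np.where(np.isnan(s), np.nan, (s > 0).astype(float))
    return out if out.ndim else float(out)


def cumulative_exposure(indicators) -> float:
    """Count of exposed waves; missing waves count as unexposed.

    Returns NaN when every wave is missing (no information at all).
    """
    a = np.asarray(indicators, dtype=float)
    if np.all(np.isnan(a)):
        return np.nan
    return float(np.nansum(a))


# ---------------------------------------------------------------------------
# cohort-level derivation
# ---------------------------------------------------------------------------

@dataclass
class ExposureSeries:
    """Per-person wave indicators and cumulative count for one practice/cutoff.

    ``indicators`` is persons x exposure-waves (columns ``a_w{wave}``,
    values 0/1/NaN); ``cumulative`` is the per-person count of exposed waves.
    """

    practice: str
    cutoff: float
    indicators: pd.DataFrame
    cumulative: pd.Series

    @property
    def wave_columns(self) -> list[str]:
        return list(self.indicators.columns)

    def frame(self) -> pd.DataFrame:
        out = self.indicators.copy()
        out["cumulative"] = self.cumulative
        return out


def wave_indicator(frame: pd.DataFrame, practice: str, cutoff: float,
                   *, strict_cutoffs: bool = True) -> pd.Series:
    """Indicator for one practice at one wave, from that wave's raw fields.

    ``frame`` is a person-indexed wave frame (see ``Cohort.wave_frame``).
    """
    if practice == "short_sleep":
        wd = (frame["wd_wake"] - frame["wd_bed"]) % 1440.0 / 60.0
        we = (frame["we_wake"] - frame["we_bed"]) % 1440.0 / 60.0
        weekly = weekly_average_sleep(wd, we)
        values = short_sleep_indicator(weekly, cutoff, strict_cutoffs=strict_cutoffs)
    elif practice == "social_jetlag":
        jl = social_jetlag(frame["wd_bed"].to_numpy(), frame["we_bed"].to_numpy())
        values = jetlag_indicator(jl, cutoff, strict_cutoffs=strict_cutoffs)
    elif practice == "disturbance":
        items = frame[list(DISTURBANCE_COLUMNS)].to_numpy(dtype=float)
        score = items.sum(axis=1)
        score[np.isnan(items).any(axis=1)] = np.nan
        values = disturbance_indicator(score)
    else:
        raise ValueError(f"unknown practice {practice!r}; expected one of {PRACTICES}")
    return pd.Series(np.asarray(values, dtype=float), index=frame.index)


def derive_exposures(cohort: Cohort, practice: str, cutoff: float,
                     *, strict_cutoffs: bool = True) -> ExposureSeries:
    """Derive the per-wave indicators and cumulative count for one practice."""
    persons = cohort.persons
    cols = {}
    for wave in cohort.exposure_waves:
        frame = cohort.wave_frame(wave)
        ind = wave_indicator(frame, practice, cutoff, strict_cutoffs=strict_cutoffs)
        cols[f"a_w{wave}"] = ind.reindex(persons)
    indicators = pd.DataFrame(cols, index=persons)
    cumulative = pd.Series(
        [cumulative_exposure(row) for row in indicators.to_numpy()],
        index=persons, name="cumulative")
    return ExposureSeries(practice, cutoff, indicators, cumulative)


def derive_all_exposures(cohort: Cohort,
                         cutoffs: dict[str, float] | None = None
                         ) -> dict[str, ExposureSeries]:
    """Derive every practice at its designated cutoff (for covariate use)."""
    cutoffs = dict(DEFAULT_CUTOFFS if cutoffs is None else cutoffs)
    return {practice: derive_exposures(cohort, practice, cut, strict_cutoffs=False)
            for practice, cut in cutoffs.items()}
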