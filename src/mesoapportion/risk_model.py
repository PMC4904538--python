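"""Exposure data model and the latency-lagged power-of-time risk computation.

The central quantity is an exposure period's absolute mesotheliogenic risk

    risk = concentration × potency × (months / 12) × T**e

where ``T`` is the elapsed time from the exposure year to the diagnosis
year, reduced by a latency lag (default 10 years, the window after
exposure during which mesothelioma risk is essentially nil) and optionally
saturated at a plateau, and ``e`` is the time exponent (default 2; the
lag-10-then-square form closely tracks the unlagged cube found in cohort
data).  Risk is relative: only ratios of concentration and potency between
entries matter, so the absolute scale of the inputs cancels when
contributions are normalised into percentages.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterator, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "RoundingMode",
    "ExposureEntry",
    "CaseConfig",
    "EntryRisk",
    "ValidationError",
    "lagged_time",
    "entry_risk",
    "expand_range",
]


class ValidationError(ValueError):
    """Raised when an exposure entry or case configuration is inconsistent."""


class RoundingMode(str, Enum):
    """How per-entry risks are reported.

    ``EXACT`` keeps full floating precision.  ``PAPER_TRUNCATE`` floors each
    entry's risk to an integer before any summation or percentage is taken,
    matching the convention of the original report printout (e.g. an exact
    risk of 1140.833... prints as 1140 and subtotals are sums of the
    truncated values).
    """

    EXACT = "exact"
    PAPER_TRUNCATE = "paper_truncate"


@dataclass(frozen=True)
class ExposureEntry:
    """One above-background asbestos exposure period within a calendar year.

    Parameters
    ----------
    year:
        Calendar year of the exposure (positive integer).
    months:
        Months of exposure within that year, ``0 < months <= 12``.
        Fractional values are allowed (a two-week stint is 0.5 months).
    concentration:
        Relative average 8-hour TWA fiber concentration during the period
        (positive).  Alternatively a cumulative dose in fiber/cc·years may
        be entered here with ``months=12``.
    potency:
        Relative mesotheliogenic potency of the fiber mix (positive;
        commercial chrysotile is conventionally 1).
    description:
        Optional free-text note, e.g. a plant or job description.
    group:
        Optional free-text group label used for subtotaling, e.g. a
        product name.  Entries sharing a label are reported together.
    """

    year: int
    months: float
    concentration: float
    potency: float
    description: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        if not isinstance(self.year, int) or isinstance(self.year, bool):
            raise ValidationError(f"year must be an integer, got {self.year!r}")
        if self.year <= 0:
            raise ValidationError(f"year must be positive, got {self.year}")
        if not 0 < self.months <= 12:
            raise ValidationError(
                f"months must be in (0, 12], got {self.months}"
            )
        if self.concentration <= 0:
            raise ValidationError(
                "concentration must be positive (entries represent "
                f"above-background exposure), got {self.concentration}"
            )
        if self.potency <= 0:
            raise ValidationError(
                f"potency must be positive, got {self.potency}"
            )
        object.__setattr__(self, "description", self.description.strip())
        object.__setattr__(self, "group", self.group.strip())


@dataclass(frozen=True)
class CaseConfig:
    """Case-level model configuration.

    Parameters
    ----------
    diagnosis_year:
        Calendar year the mesothelioma was diagnosed.
    lag_years:
        Latency lag subtracted from elapsed time before exponentiation.
        Default 10.
    time_exponent:
        Power applied to the lagged elapsed time.  Default 2.  Setting
        ``lag_years=0, time_exponent=3`` gives the unlagged-cube variant.
    max_years:
        Optional plateau: a time since exposure beyond which the time term
        stops growing.  Expressed in the same "time since exposure" sense
        as the lag, so the lagged term saturates at ``max_years -
        lag_years``.  Must exceed ``lag_years`` when given.
    rounding_mode:
        See :class:`RoundingMode`.
    """

    diagnosis_year: int
    lag_years: int = 10
    time_exponent: float = 2.0
    max_years: int | None = None
    rounding_mode: RoundingMode = RoundingMode.EXACT

    def __post_init__(self) -> None:
        if self.lag_years < 0:
            raise ValidationError(f"lag_years must be >= 0, got {self.lag_years}")
        if self.time_exponent <= 0:
            raise ValidationError(
                f"time_exponent must be positive, got {self.time_exponent}"
            )
        if self.max_years is not None and self.max_years <= self.lag_years:
            raise ValidationError(
                f"max_years ({self.max_years}) must exceed lag_years "
                f"({self.lag_years})"
            )
        # tolerate string input ("paper_truncate") from config files
        object.__setattr__(
            self, "rounding_mode", RoundingMode(self.rounding_mode)
        )


@dataclass(frozen=True)
class EntryRisk:
    """An exposure entry joined with its computed risk and contribution.

    ``lagged_time`` is the effective lagged elapsed time in years (after
    any plateau cap), ``risk`` the absolute mesotheliogenic risk (floored
    to an integer in paper-truncate mode) and ``percent`` the entry's
    percentage of the case total.
    """

    entry: ExposureEntry
    lagged_time: float
    risk: float
    percent: float = 0.0

    def __post_init__(self) -> None:
        if self.risk < 0 or self.lagged_time < 0 or self.percent < 0:
            raise ValidationError("risk, lagged_time and percent must be >= 0")

    def with_percent(self, percent: float) -> "EntryRisk":
        return replace(self, percent=percent)


def lagged_time(entry_year: int, config: CaseConfig) -> float:
    """Effective lagged elapsed time for an exposure year, in years.

    Returns ``max(0, diagnosis_year - (entry_year + lag_years))``, further
    capped at ``max_years - lag_years`` when a plateau is configured.

    Raises
    ------
    ValidationError
        If the exposure year is after the diagnosis year.
    """
    if entry_year > config.diagnosis_year:
        raise ValidationError(
            f"exposure after diagnosis: entry year {entry_year} > "
            f"diagnosis year {config.diagnosis_year}"
        )
    t = config.diagnosis_year - (entry_year + config.lag_years)
    if t <= 0:
        return 0.0
    if config.max_years is not None:
        t = min(t, config.max_years - config.lag_years)
    return float(t)


def entry_risk(entry: ExposureEntry, config: CaseConfig) -> float:
    """Absolute mesotheliogenic risk of a single exposure entry.

    ``concentration × potency × months/12 × lagged_time**time_exponent``,
    floored to an integer in paper-truncate mode.  Zero when the exposure
    falls inside the latency lag window (logged as a warning, not an
    error: such periods are legitimate history but contribute no risk).
    """
    t = lagged_time(entry.year, config)
    if t == 0.0:
        logger.warning(
            "exposure in %d lies within the %d-year latency lag of "
            "diagnosis year %d; it contributes zero risk",
            entry.year,
            config.lag_years,
            config.diagnosis_year,
        )
        return 0.0
    risk = (
        entry.concentration
        * entry.potency
        * (entry.months / 12.0)
        * t**config.time_exponent
    )
    if config.rounding_mode is RoundingMode.PAPER_TRUNCATE:
        return float(math.floor(risk))
    return risk


def expand_range(
    start_year: int,
    end_year: int,
    months: float,
    concentration: float,
    potency: float,
    description: str = "",
    group: str = "",
) -> list[ExposureEntry]:
    """One :class:`ExposureEntry` per year in ``[start_year, end_year]``.

    All entries share the given months, concentration, potency and labels;
    this mirrors entering a constant job exposure once with a final year.
    """
    if start_year > end_year:
        raise ValidationError(
            f"start_year {start_year} is after end_year {end_year}"
        )
    return [
        ExposureEntry(
            year=y,
            months=months,
            concentration=concentration,
            potency=potency,
            description=description,
            group=group,
        )
        for y in range(start_year, end_year + 1)
    ]
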