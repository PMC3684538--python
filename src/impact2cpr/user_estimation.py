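"""Convert service-provision counts into modelled numbers of users per year.

Long-acting and permanent methods (LAPMs) protect for several years from a
single service, so each provision year spawns a *virtual cohort* whose size
is traced forward: IUD/implant cohorts shrink along the method's cumulative
continuation rates (CCRs) and are removed entirely at the method's maximum
duration; sterilisation cohorts shrink only through mortality and are
removed once the cohort's median age passes the reproductive-age boundary.
Stacking every cohort and summing the column for a calendar year yields the
modelled LAPM users in that year.

Short-term methods need several commodity units per year of coverage, so
users are simply services divided by units-per-year; a "user" is taken to
have full coverage for the entire year (13 pill cycles = one pill user),
the conservative reading of commodity data.

User counts are kept as non-negative reals throughout; rounding to whole
women is a rendering concern only, since the iterative CPR engine would
otherwise accumulate rounding bias.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .assumptions import (
    LONG_ACTING,
    MAX_REPRODUCTIVE_AGE,
    PERMANENT,
    SHORT_TERM,
    AssumptionSet,
    MethodSpec,
)

__all__ = [
    "EARLIEST_HISTORY_YEAR",
    "DEFAULT_EXCLUDE",
    "ServiceHistory",
    "CohortMatrix",
    "UserEstimates",
    "longacting_cohort",
    "sterilisation_cohort",
    "shortterm_users",
    "first_year_users",
    "build_cohort_matrix",
    "users_in_year",
    "estimate_users",
    "cyp_total",
]

logger = logging.getLogger(__name__)

#: First calendar year of service history the model accepts, so that all
#: surviving cohorts are captured from the first analysable trend year on.
EARLIEST_HISTORY_YEAR = 1982

#: Methods excluded from user estimates by default: condom counts suffer
#: wastage and dual-protection double counting, so contributions to CPR are
#: normally computed without them.
DEFAULT_EXCLUDE = frozenset({"condom"})


class ServiceHistory:
    """Year x method table of services/commodities provided.

    Missing (year, method) combinations count as zero services; sparse input
    files are the norm for field data.
    """

    def __init__(self, entries: Mapping[tuple[int, str], float]) -> None:
        clean: dict[tuple[int, str], float] = {}
        for (year, method), units in entries.items():
            year = int(year)
            units = float(units)
            if year < EARLIEST_HISTORY_YEAR:
                raise ValueError(
                    f"service year {year} predates {EARLIEST_HISTORY_YEAR}, the "
                    f"earliest year the cohort model tracks"
                )
            if units < 0:
                raise ValueError(f"negative units for ({year}, {method!r}): {units}")
            if (year, method) in clean:
                raise ValueError(f"duplicate entry for ({year}, {method!r})")
            clean[(year, method)] = units
        self._entries = clean

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[int, str, float]]
    ) -> "ServiceHistory":
        entries: dict[tuple[int, str], float] = {}
        for year, method, units in records:
            key = (int(year), str(method))
            if key in entries:
                raise ValueError(f"duplicate entry for {key}")
            entries[key] = float(units)
        return cls(entries)

    def units(self, year: int, method: str) -> float:
        return self._entries.get((year, method), 0.0)

    def services_in_year(self, year: int) -> dict[str, float]:
        return {m: u for (y, m), u in self._entries.items() if y == year}

    @property
    def years(self) -> list[int]:
        return sorted({y for y, _ in self._entries})

    @property
    def method_names(self) -> list[str]:
        return sorted({m for _, m in self._entries})

    def scaled(self, k: float) -> "ServiceHistory":
        """History with every entry multiplied by ``k`` (k >= 0)."""
        if k < 0:
            raise ValueError("scale factor must be non-negative")
        return ServiceHistory({key: u * k for key, u in self._entries.items()})

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"year": y, "method": m, "units": u}
            for (y, m), u in sorted(self._entries.items())
        ]
        return pd.DataFrame(rows, columns=["year", "method", "units"])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ServiceHistory):
            return NotImplemented
        return self._entries == other._entries

    def __len__(self) -> int:
        return len(self._entries)


def longacting_cohort(services: float, method: MethodSpec) -> np.ndarray:
    """User trajectory of one IUD/implant cohort.

    ``trajectory[n] = services * mean(CCR_n, CCR_{n+1})`` for n = 0 ..
    max_duration - 1 — the average of the year's starting and ending
    continuation rates, so mid-year discontinuers count for half a year.
    The cohort is absent from ``n = max_duration`` onward.
    """
    if method.category != LONG_ACTING:
        raise ValueError(f"method {method.name!r} is {method.category}, not long-acting")
    if services < 0:
        raise ValueError("services must be non-negative")
    ccr = np.asarray(method.ccr_table, dtype=float)
    return services * 0.5 * (ccr[:-1] + ccr[1:])


def sterilisation_cohort(
    services: float, start_year: int, assumptions: AssumptionSet
) -> np.ndarray:
    """User trajectory of one sterilisation cohort.

    Survival is applied recursively: each year the previous year's estimate
    is multiplied by the one-year survival probability for the cohort's
    current median age (starting at the median age of sterilisation and
    ageing one year per step) under the e0 projected for that calendar year.
    The trajectory ends in the year the cohort's median age passes
    reproductive age (ages up to and including 49 count).

    For male sterilisation the protected female partner is the counted user;
    the same median age applies for want of partner-age data.
    """
    if services < 0:
        raise ValueError("services must be non-negative")
    median_age = assumptions.median_age_sterilisation
    n_years = int(MAX_REPRODUCTIVE_AGE - int(median_age)) + 1
    traj = np.empty(n_years, dtype=float)
    level = services
    for n in range(n_years):
        s = assumptions.sterilisation_annual_survival(
            int(median_age) + n, start_year + n
        )
        level *= s
        traj[n] = level
    return traj


def shortterm_users(services: float, method: MethodSpec) -> float:
    """Users of a short-term method: services / units needed for a year.

    Counts users as having full coverage for the entire year, e.g. 13 pill
    cycles are attributed to a single pill user.
    """
    if method.category != SHORT_TERM:
        raise ValueError(f"method {method.name!r} is {method.category}, not short-term")
    if services < 0:
        raise ValueError("services must be non-negative")
    if not method.units_per_year:
        raise ValueError(f"method {method.name!r} has no positive units_per_year")
    return services / method.units_per_year


def first_year_users(
    services_by_method: Mapping[str, float],
    assumptions: AssumptionSet,
    year: int | None = None,
) -> dict[str, float]:
    """New users created in the provision year itself, per method.

    First-year LAPM user numbers sit slightly below the client count because
    of first-year discontinuation (long-acting) or mortality (sterilisation);
    short-term users are the plain units-per-year division.  ``year`` is
    needed whenever sterilisation services are present (its survival depends
    on that year's e0).
    """
    out: dict[str, float] = {}
    for name, services in services_by_method.items():
        spec = assumptions.method(name)
        if spec.category == LONG_ACTING:
            out[name] = services * 0.5 * (spec.ccr_table[0] + spec.ccr_table[1])
        elif spec.category == PERMANENT:
            if year is None:
                raise ValueError("year is required for sterilisation first-year users")
            s = assumptions.sterilisation_annual_survival(
                int(assumptions.median_age_sterilisation), year
            )
            out[name] = services * s
        else:
            out[name] = shortterm_users(services, spec)
    return out


@dataclass
class CohortMatrix:
    """Per-method, per-provision-year LAPM user trajectories.

    ``trajectories[method][provision_year]`` holds the cohort's users at
    offsets 0, 1, ...; the column sum over all cohorts alive in a calendar
    year gives the modelled LAPM users of that year.
    """

    trajectories: dict[str, dict[int, np.ndarray]] = field(default_factory=dict)

    def add(self, method: str, provision_year: int, trajectory: np.ndarray) -> None:
        self.trajectories.setdefault(method, {})[provision_year] = trajectory

    def users_in_year(
        self,
        year: int,
        methods: Iterable[str] | None = None,
        max_provision_year: int | None = None,
    ) -> dict[str, float]:
        """Column sum for ``year``, optionally restricted by method and by
        latest provision year (used to isolate pre-existing cohorts)."""
        names = list(self.trajectories) if methods is None else list(methods)
        out: dict[str, float] = {}
        for name in names:
            total = 0.0
            for py, traj in self.trajectories.get(name, {}).items():
                if max_provision_year is not None and py > max_provision_year:
                    continue
                n = year - py
                if 0 <= n < len(traj):
                    total += float(traj[n])
            out[name] = total
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "method": m,
                "provision_year": py,
                "year": py + n,
                "users": float(u),
            }
            for m, cohorts in sorted(self.trajectories.items())
            for py, traj in sorted(cohorts.items())
            for n, u in enumerate(traj)
        ]
        return pd.DataFrame(rows, columns=["method", "provision_year", "year", "users"])


def build_cohort_matrix(
    history: ServiceHistory,
    assumptions: AssumptionSet,
    max_provision_year: int | None = None,
) -> CohortMatrix:
    """One trajectory per (LAPM method, provision year) with positive services."""
    matrix = CohortMatrix()
    for year in history.years:
        if max_provision_year is not None and year > max_provision_year:
            continue
        for name, services in history.services_in_year(year).items():
            spec = assumptions.method(name)
            if not spec.is_lapm or services <= 0:
                continue
            if spec.category == LONG_ACTING:
                traj = longacting_cohort(services, spec)
            else:
                traj = sterilisation_cohort(services, year, assumptions)
            matrix.add(name, year, traj)
    return matrix


@dataclass
class YearUsers:
    """Modelled users in one calendar year, by method and subtotal."""

    year: int
    by_method: dict[str, float]
    lapm_total: float
    short_term_total: float

    @property
    def total(self) -> float:
        return self.lapm_total + self.short_term_total


def users_in_year(
    matrix: CohortMatrix,
    history: ServiceHistory,
    year: int,
    assumptions: AssumptionSet,
    exclude: frozenset[str] = DEFAULT_EXCLUDE,
) -> YearUsers:
    """Total modelled users in ``year``: LAPM column sum + short-term division."""
    by_method: dict[str, float] = {}
    lapm_names = [n for n in assumptions.lapm_names if n not in exclude]
    lapm = matrix.users_in_year(year, methods=lapm_names)
    by_method.update(lapm)
    short_total = 0.0
    for name, services in history.services_in_year(year).items():
        spec = assumptions.method(name)
        if spec.category != SHORT_TERM or name in exclude:
            continue
        users = shortterm_users(services, spec)
        by_method[name] = users
        short_total += users
    return YearUsers(
        year=year,
        by_method=by_method,
        lapm_total=sum(lapm.values()),
        short_term_total=short_total,
    )


@dataclass
class UserEstimates:
    """Per-year modelled users (Figure-style totals) over a span of years."""

    years: list[YearUsers]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for yu in self.years:
            rows.append(
                {
                    "year": yu.year,
                    "lapm_users": yu.lapm_total,
                    "short_term_users": yu.short_term_total,
                    "total_users": yu.total,
                }
            )
        return pd.DataFrame(rows).set_index("year")

    def to_long_frame(self) -> pd.DataFrame:
        rows = [
            {"year": yu.year, "method": m, "users": u}
            for yu in self.years
            for m, u in sorted(yu.by_method.items())
        ]
        return pd.DataFrame(rows, columns=["year", "method", "users"])


def estimate_users(
    history: ServiceHistory,
    assumptions: AssumptionSet,
    years: Iterable[int],
    exclude: frozenset[str] = DEFAULT_EXCLUDE,
) -> UserEstimates:
    """Modelled users for each requested calendar year."""
    matrix = build_cohort_matrix(history, assumptions)
    return UserEstimates(
        [users_in_year(matrix, history, y, assumptions, exclude) for y in years]
    )


def cyp_total(
    services_by_method: Mapping[str, float], assumptions: AssumptionSet
) -> float:
    """Couple-years of protection: sum of services x per-method CYP factor.

    A comparison metric only — CYPs are realised over an undefined span of
    future years and cannot be annualised into users.
    """
    total = 0.0
    for name, services in services_by_method.items():
        if services == 0:
            continue
        spec = assumptions.method(name)
        if spec.cyp_factor is None:
            raise ValueError(f"method {name!r} has no CYP factor")
        total += services * spec.cyp_factor
    return total
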