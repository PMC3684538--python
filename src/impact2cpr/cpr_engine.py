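"""The organisation's percentage-point contribution to increasing modern CPR.

An organisation increases the national modern contraceptive prevalence rate
only after (a) maintaining its own previous-year contribution — replacing
users who stop, and reaching extra users to offset growth in the number of
women of reproductive age — and (b) discounting clients who merely switched
provider (the substitution effect).  The engine iterates year by year:

1. a baseline: total modelled users in the year before the trend, and that
   number as a share of the (in-union) WRA denominator;
2. pre-existing users: LAPM cohorts provided at or before the baseline year
   that still persist in each trend year;
3. new users created by the year's services (first-year estimates);
4. allocation of new users — split by the client profile into continuers and
   adopters — between maintaining the prior year's total and increasing it
   (provider changers are never allocated: the CPR already counted them);
5. the counting fraction: the share of new users credited toward CPR;
6. existing users: counted LAPM cohorts from earlier trend years projected
   forward, scaled by their year's counting fraction;
7. the decomposition total users in CPR = pre-existing + existing +
   maintain + increase, which becomes the next year's maintenance target;
8. percentage points: the total divided by the year's denominator, minus
   the baseline contribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .assumptions import LONG_ACTING, AssumptionSet
from .user_estimation import (
    DEFAULT_EXCLUDE,
    CohortMatrix,
    ServiceHistory,
    build_cohort_matrix,
    first_year_users,
    longacting_cohort,
    sterilisation_cohort,
    users_in_year,
)

__all__ = [
    "ClientProfile",
    "Baseline",
    "Allocation",
    "YearResult",
    "TrendResult",
    "compute_baseline",
    "pre_existing_series",
    "users_needed_to_maintain",
    "allocate_new_users",
    "counting_fraction",
    "project_existing_users",
    "run_trend",
    "percentage_point_series",
]

logger = logging.getLogger(__name__)

_PROFILE_TOL = 1e-6

#: Interpretation caveat that accompanies every trend report.
INTERPRETATION_CAVEAT = (
    "Results can be read as a contribution to increasing the national modern "
    "CPR only assuming all other providers at least maintain their baseline "
    "contributions."
)


class ClientProfile:
    """Per-year split of clients into adopters / continuers / provider changers.

    Adopters were not using a modern method before; continuers already used
    one from this organisation; provider changers used one from a different
    provider.  A single-year profile is broadcast to every requested year
    (with a logged warning), mirroring the common practice of using one
    exit-interview round as a proxy for a whole trend.
    """

    def __init__(
        self, proportions: Mapping[int, tuple[float, float, float]] | tuple[float, float, float]
    ) -> None:
        if isinstance(proportions, tuple):
            self._single = self._validate(proportions, year=None)
            self._by_year: dict[int, tuple[float, float, float]] = {}
        else:
            self._single = None
            self._by_year = {
                int(y): self._validate(p, year=int(y)) for y, p in proportions.items()
            }
            if len(self._by_year) == 1:
                self._single = next(iter(self._by_year.values()))
            if not self._by_year:
                raise ValueError("client profile is empty")
        self._warned = False

    @staticmethod
    def _validate(
        p: tuple[float, float, float], year: int | None
    ) -> tuple[float, float, float]:
        a, c, pc = (float(v) for v in p)
        where = f" for year {year}" if year is not None else ""
        if any(v < 0 or v > 1 for v in (a, c, pc)):
            raise ValueError(f"client profile proportions{where} must lie in [0, 1]")
        if abs(a + c + pc - 1.0) > _PROFILE_TOL:
            raise ValueError(
                f"client profile proportions{where} must sum to 1, got {a + c + pc}"
            )
        return (a, c, pc)

    @classmethod
    def constant(cls, adopters: float, continuers: float, changers: float) -> "ClientProfile":
        return cls((adopters, continuers, changers))

    def for_year(self, year: int) -> tuple[float, float, float]:
        """(pct_adopters, pct_continuers, pct_provider_changers) for ``year``."""
        if year in self._by_year:
            return self._by_year[year]
        if self._single is not None:
            if self._by_year and not self._warned:
                logger.warning(
                    "client profile supplied for a single year; applying it to "
                    "all trend years as a proxy"
                )
                self._warned = True
            return self._single
        raise KeyError(f"client profile has no entry for year {year}")

    @property
    def years(self) -> list[int]:
        return sorted(self._by_year)

    def to_frame(self) -> pd.DataFrame:
        if self._by_year:
            rows = [
                {"year": y, "pct_adopters": a, "pct_continuers": c, "pct_provider_changers": p}
                for y, (a, c, p) in sorted(self._by_year.items())
            ]
        else:
            a, c, p = self._single
            rows = [
                {"year": None, "pct_adopters": a, "pct_continuers": c, "pct_provider_changers": p}
            ]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class Baseline:
    """The organisation's position in the year before the trend starts."""

    year: int
    users: float
    cpr_contribution: float  # fraction of the (in-union) WRA denominator

    @property
    def cpr_contribution_points(self) -> float:
        return 100.0 * self.cpr_contribution


@dataclass(frozen=True)
class Allocation:
    """Split of one year's new users between maintaining and increasing.

    ``dropped_continuers`` surfaces continuers in excess of the maintenance
    need (situation 1), whom the counting-fraction formula does not credit.
    """

    situation: int
    maintain_users: float
    increase_users: float
    dropped_continuers: float = 0.0


@dataclass
class YearResult:
    """Full decomposition of one trend year."""

    year: int
    pre_existing: float
    existing: float
    maintain: float
    increase: float
    new_users: float
    new_adopters: float
    situation: int
    counting_fraction: float
    dropped_continuers: float
    total_users_in_cpr: float
    total_pct_contribution: float = 0.0
    pct_point_increase: float = 0.0


@dataclass
class TrendResult:
    """Baseline plus the ordered per-year decompositions of a trend."""

    baseline: Baseline
    years: list[YearResult]
    new_cpr_users_by_method: pd.DataFrame  # index year, one column per method
    exclude: frozenset[str] = DEFAULT_EXCLUDE

    @property
    def cumulative_pct_point_increase(self) -> float:
        """Final-year percentage-point increase over the baseline contribution."""
        return self.years[-1].pct_point_increase

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for yr in self.years:
            rows.append(
                {
                    "year": yr.year,
                    "pre_existing_users": yr.pre_existing,
                    "existing_users": yr.existing,
                    "maintain_users": yr.maintain,
                    "increase_users": yr.increase,
                    "new_users": yr.new_users,
                    "new_adopters": yr.new_adopters,
                    "situation": yr.situation,
                    "counting_fraction": yr.counting_fraction,
                    "dropped_continuers": yr.dropped_continuers,
                    "total_users_in_cpr": yr.total_users_in_cpr,
                    "total_pct_contribution": 100.0 * yr.total_pct_contribution,
                    "pct_point_increase": 100.0 * yr.pct_point_increase,
                }
            )
        return pd.DataFrame(rows).set_index("year")

    def summary_report(self) -> str:
        lines = [
            "Contribution to increasing modern CPR",
            "=====================================",
            f"Baseline year: {self.baseline.year}",
            f"Baseline users: {self.baseline.users:,.0f}",
            f"Baseline CPR contribution: {self.baseline.cpr_contribution_points:.2f} percentage points",
            f"Trend: {self.years[0].year}-{self.years[-1].year}"
            + (f" (excluding {', '.join(sorted(self.exclude))})" if self.exclude else ""),
            "",
            f"{'year':>6} {'total in CPR':>14} {'pct points':>11} {'increase':>9}",
        ]
        for yr in self.years:
            lines.append(
                f"{yr.year:>6} {yr.total_users_in_cpr:>14,.0f} "
                f"{100 * yr.total_pct_contribution:>11.2f} "
                f"{100 * yr.pct_point_increase:>9.2f}"
            )
        lines += [
            "",
            f"Cumulative percentage-point increase: "
            f"{100 * self.cumulative_pct_point_increase:.2f}",
            "",
            INTERPRETATION_CAVEAT,
        ]
        return "\n".join(lines)


def compute_baseline(
    history: ServiceHistory,
    assumptions: AssumptionSet,
    y0: int,
    exclude: frozenset[str] = DEFAULT_EXCLUDE,
) -> Baseline:
    """Step 1: total modelled users in the baseline year and their share of WRA."""
    matrix = build_cohort_matrix(history, assumptions)
    yu = users_in_year(matrix, history, y0, assumptions, exclude)
    denom = assumptions.denominator(y0)
    return Baseline(year=y0, users=yu.total, cpr_contribution=yu.total / denom)


def pre_existing_series(
    history: ServiceHistory,
    assumptions: AssumptionSet,
    years: Iterable[int],
    y0: int,
    exclude: frozenset[str] = DEFAULT_EXCLUDE,
) -> dict[int, float]:
    """Step 2: surviving users of LAPM cohorts provided in or before ``y0``."""
    matrix = build_cohort_matrix(history, assumptions, max_provision_year=y0)
    names = [n for n in assumptions.lapm_names if n not in exclude]
    return {
        y: sum(matrix.users_in_year(y, methods=names).values()) for y in years
    }


def users_needed_to_maintain(
    previous_total: float, pre_existing: float, existing: float
) -> float:
    """New users required to hold the previous year's total users in CPR.

    Clamped at zero: when surviving cohorts alone exceed the previous
    total, no new users are needed for maintenance.
    """
    if min(previous_total, pre_existing, existing) < 0:
        raise ValueError("user counts must be non-negative")
    return max(0.0, previous_total - pre_existing - existing)


def allocate_new_users(
    needed: float, new_users: float, profile_slice: tuple[float, float, float]
) -> Allocation:
    """Step 4: split new users between maintaining and increasing.

    With C = new continuers and A = new adopters (provider changers are
    never allocated):

    * situation 1 — enough continuers to maintain (C >= needed): maintain =
      needed, increase = A, and C - needed continuers go uncounted;
    * situation 2 — continuers plus adopters cannot maintain (C + A <=
      needed): all of both maintain, increase = 0;
    * situation 3 — otherwise: adopters top up maintenance, the remainder
      increases.
    """
    if needed < 0 or new_users < 0:
        raise ValueError("needed and new_users must be non-negative")
    a, c, _ = ClientProfile._validate(profile_slice, year=None)
    continuers = new_users * c
    adopters = new_users * a
    if continuers >= needed:
        return Allocation(
            situation=1,
            maintain_users=needed,
            increase_users=adopters,
            dropped_continuers=continuers - needed,
        )
    if continuers + adopters <= needed:
        return Allocation(situation=2, maintain_users=continuers + adopters, increase_users=0.0)
    return Allocation(
        situation=3,
        maintain_users=needed,
        increase_users=adopters - (needed - continuers),
    )


def counting_fraction(allocation: Allocation, new_users: float) -> float:
    """Step 5: share of the year's new users credited toward the CPR."""
    if new_users < 0:
        raise ValueError("new_users must be non-negative")
    if new_users == 0:
        return 0.0
    return (allocation.maintain_users + allocation.increase_users) / new_users


def project_existing_users(
    new_cpr_lapm_users: Mapping[str, float],
    services_by_method: Mapping[str, float],
    provision_year: int,
    assumptions: AssumptionSet,
    years: Iterable[int],
) -> dict[int, float]:
    """Step 6: carry counted LAPM cohorts into later trend years.

    Each counted first-year cohort is the full service-derived trajectory
    scaled by the ratio of counted to first-year users (the counting
    fraction); only offsets >= 1 contribute — there are no existing users in
    a cohort's own provision year.
    """
    fy = first_year_users(services_by_method, assumptions, year=provision_year)
    out = {y: 0.0 for y in years}
    for name, counted in new_cpr_lapm_users.items():
        spec = assumptions.method(name)
        if not spec.is_lapm or counted == 0:
            continue
        services = services_by_method.get(name, 0.0)
        if services <= 0 or fy[name] <= 0:
            continue
        scale = counted / fy[name]
        if spec.category == LONG_ACTING:
            traj = longacting_cohort(services, spec)
        else:
            traj = sterilisation_cohort(services, provision_year, assumptions)
        for y in out:
            n = y - provision_year
            if 1 <= n < len(traj):
                out[y] += scale * float(traj[n])
    return out


def run_trend(
    history: ServiceHistory,
    assumptions: AssumptionSet,
    profile: ClientProfile,
    y_start: int,
    y_end: int,
    exclude: frozenset[str] = DEFAULT_EXCLUDE,
) -> TrendResult:
    """Steps 1-8 iterated over a contiguous trend of calendar years.

    The first trend year is measured against the baseline year
    ``y_start - 1``; each later year against the year immediately prior.
    """
    if y_start > y_end:
        raise ValueError(f"y_start {y_start} must not exceed y_end {y_end}")
    y0 = y_start - 1
    baseline = compute_baseline(history, assumptions, y0, exclude)
    years = list(range(y_start, y_end + 1))
    pre_existing = pre_existing_series(history, assumptions, years, y0, exclude)

    existing_by_year: dict[int, float] = {y: 0.0 for y in years}
    results: list[YearResult] = []
    method_rows: list[dict[str, float]] = []
    previous_total = baseline.users

    for y in years:
        services = {
            m: u
            for m, u in history.services_in_year(y).items()
            if m not in exclude and u > 0
        }
        new_by_method = first_year_users(services, assumptions, year=y)
        new_total = sum(new_by_method.values())
        new_adopters = new_total * profile.for_year(y)[0]

        existing = existing_by_year[y]
        needed = users_needed_to_maintain(previous_total, pre_existing[y], existing)
        allocation = allocate_new_users(needed, new_total, profile.for_year(y))
        fraction = counting_fraction(allocation, new_total)

        new_cpr_by_method = {m: fraction * u for m, u in new_by_method.items()}
        method_rows.append({"year": y, **new_cpr_by_method})

        # project the year's counted LAPM cohorts into the remaining years
        if fraction > 0:
            for name, svc in services.items():
                spec = assumptions.method(name)
                if not spec.is_lapm:
                    continue
                if spec.category == LONG_ACTING:
                    traj = longacting_cohort(svc, spec)
                else:
                    traj = sterilisation_cohort(svc, y, assumptions)
                for yy in years:
                    n = yy - y
                    if 1 <= n < len(traj):
                        existing_by_year[yy] += fraction * float(traj[n])

        total = pre_existing[y] + existing + allocation.maintain_users + allocation.increase_users
        results.append(
            YearResult(
                year=y,
                pre_existing=pre_existing[y],
                existing=existing,
                maintain=allocation.maintain_users,
                increase=allocation.increase_users,
                new_users=new_total,
                new_adopters=new_adopters,
                situation=allocation.situation,
                counting_fraction=fraction,
                dropped_continuers=allocation.dropped_continuers,
                total_users_in_cpr=total,
            )
        )
        previous_total = total

    frame = pd.DataFrame(method_rows).set_index("year").fillna(0.0)
    trend = TrendResult(
        baseline=baseline, years=results, new_cpr_users_by_method=frame, exclude=exclude
    )
    percentage_point_series(trend, assumptions)  # fills the pct fields in place
    return trend


def percentage_point_series(
    trend: TrendResult, assumptions: AssumptionSet
) -> pd.DataFrame:
    """Step 8: percentage-point contribution per year.

    Divides each year's total users in CPR by that year's (in-union) WRA —
    a denominator that grows with the population, which is how the need for
    additional users to offset population growth binds — then subtracts the
    baseline contribution.  Updates the trend's per-year fields and returns
    a tidy frame.
    """
    rows = []
    for yr in trend.years:
        denom = assumptions.denominator(yr.year)
        yr.total_pct_contribution = yr.total_users_in_cpr / denom
        yr.pct_point_increase = (
            yr.total_pct_contribution - trend.baseline.cpr_contribution
        )
        rows.append(
            {
                "year": yr.year,
                "total_pct_contribution": 100.0 * yr.total_pct_contribution,
                "pct_point_increase": 100.0 * yr.pct_point_increase,
            }
        )
    return pd.DataFrame(rows).set_index("year")
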