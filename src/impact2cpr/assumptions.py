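"""Background data and assumptions for the user-estimation and CPR engines.

This module houses the three assumption blocks every calculation draws on:

* :class:`MethodSpec` — per-method modelling parameters: cumulative
  continuation rates (CCRs) and a maximum duration for long-acting methods
  (IUDs, implants), units needed for one year of coverage for short-term
  methods (pills, injectables, condoms), and an optional couple-years of
  protection (CYP) factor used only for the comparison metric.
* :class:`DemographicSeries` — women of reproductive age (WRA), the
  proportion in union, and projected female life expectancy at birth (e0)
  per calendar year.  WRA (possibly restricted to in-union women) is the
  denominator of the contraceptive prevalence rate (CPR).
* :class:`LifeTableFamily` — model life-table anchor levels giving the
  five-year survival probability 5px per age group, interpolated in e0.
  Survival applies only to sterilisation cohorts, where the protected woman
  remains a contraceptive user until death or age 50.

An :class:`AssumptionSet` bundles the three with the median age of
sterilisation and the CPR basis (all women vs in-union women).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LONG_ACTING",
    "PERMANENT",
    "SHORT_TERM",
    "MethodSpec",
    "DemographicSeries",
    "LifeTableFamily",
    "AssumptionSet",
    "survival_5px",
    "annual_survival",
    "get_ccr",
]

LONG_ACTING = "long-acting"
PERMANENT = "permanent"
SHORT_TERM = "short-term"

_CATEGORIES = (LONG_ACTING, PERMANENT, SHORT_TERM)

#: Oldest age (inclusive) at which a woman still counts toward the CPR
#: denominator; sterilisation cohorts are removed once past it.
MAX_REPRODUCTIVE_AGE = 49


@dataclass(frozen=True)
class MethodSpec:
    """Modelling parameters for one contraceptive method.

    Exactly the fields for the method's category must be populated:
    long-acting methods need ``max_duration`` and ``ccr_table`` (CCR_0..
    CCR_max_duration), short-term methods need ``units_per_year``, and
    permanent methods (sterilisation) need neither — their persistence is
    governed by survival, not continuation.  A ``ccr_table`` supplied with
    ``max_duration`` entries (terminal value missing) is padded with a
    terminal 0, reflecting removal of the whole cohort when the maximum
    duration of use is reached.
    """

    name: str
    category: str
    max_duration: int | None = None
    ccr_table: tuple[float, ...] | None = None
    units_per_year: float | None = None
    cyp_factor: float | None = None

    def __post_init__(self) -> None:
        if self.category not in _CATEGORIES:
            raise ValueError(
                f"method {self.name!r}: unknown category {self.category!r}; "
                f"expected one of {_CATEGORIES}"
            )
        if self.category == LONG_ACTING:
            if self.max_duration is None or self.ccr_table is None:
                raise ValueError(
                    f"long-acting method {self.name!r} needs max_duration and ccr_table"
                )
            if self.units_per_year is not None:
                raise ValueError(
                    f"long-acting method {self.name!r} must not set units_per_year"
                )
            if self.max_duration < 1:
                raise ValueError(f"method {self.name!r}: max_duration must be >= 1")
            table = tuple(float(c) for c in self.ccr_table)
            if len(table) == self.max_duration:
                # missing terminal entry: cohort fully removed at max duration
                table = table + (0.0,)
            if len(table) != self.max_duration + 1:
                raise ValueError(
                    f"method {self.name!r}: ccr_table must have max_duration+1 "
                    f"entries (CCR_0..CCR_{self.max_duration}), got {len(table)}"
                )
            if table[0] != 1.0:
                raise ValueError(
                    f"method {self.name!r}: CCR_0 must be 1 (all women are using "
                    f"the method at insertion), got {table[0]}"
                )
            if any(c < 0.0 or c > 1.0 for c in table):
                raise ValueError(f"method {self.name!r}: CCRs must lie in [0, 1]")
            if any(b > a + 1e-12 for a, b in zip(table, table[1:])):
                raise ValueError(f"method {self.name!r}: ccr_table must be non-increasing")
            object.__setattr__(self, "ccr_table", table)
        elif self.category == PERMANENT:
            if self.max_duration is not None or self.ccr_table is not None:
                raise ValueError(
                    f"permanent method {self.name!r} must not set max_duration/ccr_table"
                )
            if self.units_per_year is not None:
                raise ValueError(
                    f"permanent method {self.name!r} must not set units_per_year"
                )
        else:  # short-term
            if self.units_per_year is None or self.units_per_year <= 0:
                raise ValueError(
                    f"short-term method {self.name!r} needs units_per_year > 0"
                )
            if self.max_duration is not None or self.ccr_table is not None:
                raise ValueError(
                    f"short-term method {self.name!r} must not set max_duration/ccr_table"
                )
        if self.cyp_factor is not None and self.cyp_factor <= 0:
            raise ValueError(f"method {self.name!r}: cyp_factor must be positive")

    @property
    def is_lapm(self) -> bool:
        return self.category in (LONG_ACTING, PERMANENT)


def get_ccr(method: MethodSpec, n: int) -> float:
    """Cumulative continuation rate CCR_n for a long-acting method.

    CCR_n is the probability a woman is still using the method ``n`` years
    after insertion; CCR_0 = 1.  Asking beyond ``max_duration`` is an error:
    the cohort must already have been removed from the model.
    """
    if method.category != LONG_ACTING:
        raise ValueError(f"method {method.name!r} is {method.category}, not long-acting")
    if n < 0 or n > method.max_duration:
        raise ValueError(
            f"method {method.name!r}: CCR_{n} requested but the cohort is removed "
            f"after year {method.max_duration}"
        )
    return method.ccr_table[n]


class DemographicSeries:
    """Per-calendar-year demographic inputs: WRA, proportion in union, e0.

    WRA and the in-union proportion are looked up strictly (a missing year is
    an error naming the year, since the CPR denominator is undefined without
    it).  e0 is linearly interpolated between supplied years and clamped to
    the nearest endpoint outside them: sterilisation cohort tails can extend
    decades beyond any projection horizon, where the nearest projected
    mortality level is the only defensible choice.
    """

    def __init__(self, table: pd.DataFrame) -> None:
        required = {"wra", "prop_in_union", "e0"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"demographic series missing columns: {sorted(missing)}")
        table = table.sort_index()
        if table.index.has_duplicates:
            raise ValueError("demographic series has duplicate years")
        if (table["wra"] <= 0).any():
            raise ValueError("wra must be positive for every modelled year")
        if ((table["prop_in_union"] < 0) | (table["prop_in_union"] > 1)).any():
            raise ValueError("prop_in_union must lie in [0, 1]")
        if (table["e0"] <= 0).any():
            raise ValueError("e0 must be positive")
        self._table = table

    @classmethod
    def from_records(
        cls, records: Mapping[int, tuple[float, float, float]]
    ) -> "DemographicSeries":
        """Build from ``{year: (wra, prop_in_union, e0)}``."""
        frame = pd.DataFrame.from_dict(
            records, orient="index", columns=["wra", "prop_in_union", "e0"]
        )
        frame.index.name = "year"
        return cls(frame)

    @property
    def years(self) -> list[int]:
        return [int(y) for y in self._table.index]

    def to_frame(self) -> pd.DataFrame:
        return self._table.copy()

    def _strict(self, year: int, column: str, what: str) -> float:
        if year not in self._table.index:
            raise KeyError(f"demographic series has no entry for year {year} ({what})")
        return float(self._table.at[year, column])

    def wra(self, year: int) -> float:
        return self._strict(year, "wra", "women of reproductive age")

    def prop_in_union(self, year: int) -> float:
        return self._strict(year, "prop_in_union", "proportion in union")

    def e0(self, year: int) -> float:
        years = self._table.index.to_numpy(dtype=float)
        return float(np.interp(float(year), years, self._table["e0"].to_numpy(dtype=float)))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DemographicSeries):
            return NotImplemented
        return self._table.equals(other._table)


class LifeTableFamily:
    """Anchor levels of one model life-table family.

    ``levels`` maps an e0 anchor value to ``{age_group_start: 5px}`` for
    5-year age groups; all levels must cover the same age groups, 5px must
    lie in (0, 1], and anchors are kept in increasing order.
    """

    def __init__(self, name: str, levels: Mapping[float, Mapping[int, float]]) -> None:
        if not levels:
            raise ValueError(f"life table family {name!r} has no levels")
        anchors = sorted(float(a) for a in levels)
        if len(set(anchors)) != len(anchors):
            raise ValueError(f"life table family {name!r}: duplicate e0 anchors")
        groups = None
        clean: dict[float, dict[int, float]] = {}
        for anchor in anchors:
            level = {int(g): float(p) for g, p in dict(levels[anchor]).items()}
            if groups is None:
                groups = sorted(level)
            elif sorted(level) != groups:
                raise ValueError(
                    f"life table family {name!r}: levels cover different age groups"
                )
            for g, p in level.items():
                if not (0.0 < p <= 1.0):
                    raise ValueError(
                        f"life table family {name!r}: 5px must be in (0, 1], "
                        f"got {p} for age group {g}"
                    )
            clean[anchor] = level
        self.name = name
        self._anchors = anchors
        self._groups = groups or []
        self._levels = clean

    @property
    def anchors(self) -> list[float]:
        return list(self._anchors)

    @property
    def age_groups(self) -> list[int]:
        return list(self._groups)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"family": self.name, "e0_level": a, "age_group_start": g, "p5x": p}
            for a, level in self._levels.items()
            for g, p in sorted(level.items())
        ]
        return pd.DataFrame(rows)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LifeTableFamily):
            return NotImplemented
        return self.name == other.name and self._levels == other._levels


def survival_5px(family: LifeTableFamily, e0: float, age: float) -> float:
    """5-year survival probability for the age group containing ``age``.

    Linearly interpolated in e0 between the two bracketing anchor levels of
    the family; outside the anchor range the nearest level applies.
    """
    if e0 <= 0:
        raise ValueError("e0 must be positive")
    if age < 0:
        raise ValueError("age must be non-negative")
    group = int(age // 5) * 5
    if group not in family._levels[family._anchors[0]]:
        raise ValueError(
            f"life table family {family.name!r} does not cover age group "
            f"{group}-{group + 4} (age {age})"
        )
    values = [family._levels[a][group] for a in family._anchors]
    return float(np.interp(e0, family._anchors, values))


def annual_survival(p5x: float) -> float:
    """One-year survival from a 5-year survival probability.

    The fifth root spreads survival evenly across the five-year interval.
    """
    if not (0.0 < p5x <= 1.0):
        raise ValueError(f"5-year survival probability must be in (0, 1], got {p5x}")
    return p5x ** (1.0 / 5.0)


@dataclass
class AssumptionSet:
    """Everything the engines need besides the service history itself."""

    methods: Mapping[str, MethodSpec]
    demography: DemographicSeries
    life_table: LifeTableFamily
    median_age_sterilisation: float
    cpr_basis: str = "all-women"

    def __post_init__(self) -> None:
        if isinstance(self.methods, Sequence):
            self.methods = {m.name: m for m in self.methods}
        for name, spec in self.methods.items():
            if name != spec.name:
                raise ValueError(f"method key {name!r} does not match spec name {spec.name!r}")
        if not (15 <= self.median_age_sterilisation < MAX_REPRODUCTIVE_AGE):
            raise ValueError(
                f"median_age_sterilisation must lie in [15, {MAX_REPRODUCTIVE_AGE}), "
                f"got {self.median_age_sterilisation}"
            )
        if self.cpr_basis not in ("all-women", "in-union"):
            raise ValueError(
                f"cpr_basis must be 'all-women' or 'in-union', got {self.cpr_basis!r}"
            )

    def method(self, name: str) -> MethodSpec:
        try:
            return self.methods[name]
        except KeyError:
            known = ", ".join(sorted(self.methods))
            raise KeyError(f"unknown method {name!r}; known methods: {known}") from None

    @property
    def lapm_names(self) -> list[str]:
        return [n for n, m in self.methods.items() if m.is_lapm]

    @property
    def shortterm_names(self) -> list[str]:
        return [n for n, m in self.methods.items() if m.category == SHORT_TERM]

    def denominator(self, year: int) -> float:
        """CPR denominator for ``year``: WRA, or in-union WRA."""
        wra = self.demography.wra(year)
        if self.cpr_basis == "in-union":
            return wra * self.demography.prop_in_union(year)
        return wra

    def sterilisation_annual_survival(self, age: float, year: int) -> float:
        """One-year survival of a sterilisation cohort of median ``age`` in ``year``."""
        p5x = survival_5px(self.life_table, self.demography.e0(year), age)
        return annual_survival(p5x)
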