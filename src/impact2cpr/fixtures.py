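"""Synthetic inputs: service histories, assumption sets, client profiles.

The generator emulates the structure of a growing national family-planning
programme — a years x methods table of service counts expanding steeply
from a small base, a sub-Saharan-scale demographic backdrop, and an
exit-interview client profile — so every other module is exercisable
without any external data.  Defaults mirror the shape of the standard
Madagascar worked example: the measured 2011 client profile
(22.4% adopters / 49.2% continuers / 28.4% provider changers) applied to
all years, ~35% annual service growth (an eightfold user increase over a
seven-year trend), a WRA population of ~4.5 million growing 2.8% a year,
and female life expectancy rising from 62 years.  Statistical realism of
any specific country programme is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .assumptions import AssumptionSet, DemographicSeries
from .cpr_engine import ClientProfile
from .datasets import (
    default_median_age_sterilisation,
    default_method_specs,
    synthetic_life_table,
)
from .user_estimation import ServiceHistory

__all__ = ["FixtureParams", "generate_service_history", "generate_assumption_set", "toy_example"]

#: Service units in the first history year, per method (before growth/noise).
_DEFAULT_BASE_UNITS: dict[str, float] = {
    "iud_10yr": 200.0,
    "implant_5yr": 150.0,
    "implant_3yr": 400.0,
    "female_sterilisation": 60.0,
    "male_sterilisation": 10.0,
    "pill": 6000.0,
    "injectable_3mo": 2000.0,
    "condom": 12000.0,
}


@dataclass(frozen=True)
class FixtureParams:
    """Knobs of the synthetic-data generator (all with study-shaped defaults)."""

    seed: int = 0
    start_year: int = 1996
    n_years: int = 16
    base_units: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_BASE_UNITS)
    )
    growth: float = 0.35  # annual multiplicative service growth
    noise_sd: float = 0.10  # lognormal sd around the growth trend
    profile: tuple[float, float, float] = (0.224, 0.492, 0.284)
    wra_start: float = 4_500_000.0
    wra_growth: float = 0.028
    prop_in_union: float = 0.70
    e0_start: float = 62.0
    e0_slope: float = 0.3  # years of life expectancy gained per calendar year
    life_table_family: str = "synthetic-general"
    median_age_sterilisation: float | None = None  # None -> bundled default
    cpr_basis: str = "all-women"
    demography_margin: int = 10  # extra projected years past the history

    def __post_init__(self) -> None:
        if self.n_years < 1:
            raise ValueError("n_years must be >= 1")
        if self.growth <= -1 or self.wra_growth <= -1:
            raise ValueError("growth rates must exceed -1")
        if any(u < 0 for u in self.base_units.values()):
            raise ValueError("base_units must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def generate_service_history(params: FixtureParams) -> ServiceHistory:
    """Seeded multi-year, multi-method service history.

    ``units[m, t] = base_m * (1 + growth)^t * LogNormal(0, noise_sd)``,
    rounded to whole commodities/services.  The history starts well before
    any plausible baseline year so pre-existing cohorts exist.
    """
    rng = np.random.default_rng(params.seed)
    records = []
    for t in range(params.n_years):
        year = params.start_year + t
        for method, base in params.base_units.items():
            if base == 0:
                continue
            noise = rng.lognormal(mean=0.0, sigma=params.noise_sd) if params.noise_sd else 1.0
            units = round(base * (1.0 + params.growth) ** t * noise)
            records.append((year, method, float(units)))
    return ServiceHistory.from_records(records)


def generate_assumption_set(params: FixtureParams) -> AssumptionSet:
    """Internally consistent methods + demography + life table."""
    horizon = params.n_years + params.demography_margin
    records = {
        params.start_year
        + t: (
            params.wra_start * (1.0 + params.wra_growth) ** t,
            params.prop_in_union,
            params.e0_start + params.e0_slope * t,
        )
        for t in range(horizon)
    }
    median_age = (
        default_median_age_sterilisation()
        if params.median_age_sterilisation is None
        else params.median_age_sterilisation
    )
    return AssumptionSet(
        methods=default_method_specs(),
        demography=DemographicSeries.from_records(records),
        life_table=synthetic_life_table(params.life_table_family),
        median_age_sterilisation=median_age,
        cpr_basis=params.cpr_basis,
    )


def toy_example() -> tuple[ServiceHistory, AssumptionSet, ClientProfile]:
    """Small documentation fixture: the default shape at 1/100 service scale.

    Deterministic (seed 0); its expected trend output is committed as a
    regression snapshot in the test suite.
    """
    params = FixtureParams()
    params = replace(
        params, base_units={m: u / 100.0 for m, u in params.base_units.items()}
    )
    history = generate_service_history(params)
    assumptions = generate_assumption_set(params)
    profile = ClientProfile.constant(*params.profile)
    return history, assumptions, profile
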