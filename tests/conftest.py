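"""Shared fixtures: small hand-built assumption sets and random mini-cases.

``make_random_case`` builds a complete random configuration twice over: once
as package objects and once as the plain-dict inputs the independent
reference oracles consume, so engine-vs-oracle comparisons never share code
paths.
"""

from __future__ import annotations

import numpy as np
import pytest

from impact2cpr import (
    AssumptionSet,
    ClientProfile,
    DemographicSeries,
    LifeTableFamily,
    MethodSpec,
    ServiceHistory,
)

CONSTANT_ANNUAL_SURVIVAL = 0.998


def flat_life_table(annual: float = CONSTANT_ANNUAL_SURVIVAL) -> LifeTableFamily:
    """Life table giving the same one-year survival at every age and e0."""
    p5x = annual**5
    groups = {g: p5x for g in range(15, 55, 5)}
    return LifeTableFamily("flat", {50.0: dict(groups), 80.0: dict(groups)})


def constant_demography(
    years, wra: float = 1_000_000.0, in_union: float = 0.7, e0: float = 60.0
) -> DemographicSeries:
    return DemographicSeries.from_records({y: (wra, in_union, e0) for y in years})


@pytest.fixture
def la5() -> MethodSpec:
    """Five-year long-acting method with the worked-example CCR table."""
    return MethodSpec(
        name="la5",
        category="long-acting",
        max_duration=5,
        ccr_table=(1.0, 0.8, 0.6, 0.4, 0.2, 0.0),
        cyp_factor=3.0,
    )


@pytest.fixture
def simple_assumptions(la5) -> AssumptionSet:
    """Minimal method mix over a flat demographic/mortality backdrop."""
    methods = [
        la5,
        MethodSpec(name="ster", category="permanent", cyp_factor=10.0),
        MethodSpec(name="pill", category="short-term", units_per_year=13.0, cyp_factor=1 / 15),
        MethodSpec(name="condom", category="short-term", units_per_year=120.0, cyp_factor=1 / 120),
    ]
    return AssumptionSet(
        methods=methods,
        demography=constant_demography(range(1995, 2031)),
        life_table=flat_life_table(),
        median_age_sterilisation=40.0,
        cpr_basis="all-women",
    )


def random_ccr_table(rng: np.random.Generator, max_duration: int) -> tuple[float, ...]:
    drops = rng.uniform(0.02, 0.3, size=max_duration)
    table = [1.0]
    for d in drops:
        table.append(max(0.0, table[-1] - d))
    return tuple(table)


def make_random_case(seed: int):
    """A full random mini-configuration, as package objects and plain dicts.

    Returns ``(history, assumptions, profile, y_start, y_end, exclude, ref)``
    where ``ref`` holds the plain-dict mirror for the reference oracles.
    """
    rng = np.random.default_rng(seed)
    y_hist_start = 2000
    n_hist = 8
    y_start = 2004
    y_end = 2007

    max_dur = int(rng.integers(3, 7))
    ccr = random_ccr_table(rng, max_dur)
    units_py = float(rng.uniform(4, 20))
    methods = {
        "la": MethodSpec(name="la", category="long-acting", max_duration=max_dur, ccr_table=ccr),
        "ster": MethodSpec(name="ster", category="permanent"),
        "st": MethodSpec(name="st", category="short-term", units_per_year=units_py),
        "condom": MethodSpec(name="condom", category="short-term", units_per_year=120.0),
    }
    median_age = float(rng.integers(30, 46))

    demo_years = range(y_hist_start, y_end + 2)
    wra0 = float(rng.uniform(5e5, 5e6))
    g = float(rng.uniform(0.0, 0.04))
    e0_0 = float(rng.uniform(52, 72))
    slope = float(rng.uniform(0.0, 0.5))
    in_union = float(rng.uniform(0.5, 0.9))
    demography = {
        y: (wra0 * (1 + g) ** (y - y_hist_start), in_union, e0_0 + slope * (y - y_hist_start))
        for y in demo_years
    }

    anchors = (50.0, 70.0)
    life_levels = {
        a: {
            grp: float(rng.uniform(0.90, 0.999))
            for grp in range(15, 55, 5)
        }
        for a in anchors
    }
    # higher e0 anchor must not be less survivable, for monotonicity checks
    for grp in range(15, 55, 5):
        lo, hi = life_levels[50.0][grp], life_levels[70.0][grp]
        if hi < lo:
            life_levels[50.0][grp], life_levels[70.0][grp] = hi, lo

    entries = {}
    for y in range(y_hist_start, y_hist_start + n_hist):
        for name in methods:
            if rng.random() < 0.15:
                continue  # sparse history
            scale = 50 if methods[name].category != "short-term" else 800
            entries[(y, name)] = float(np.round(rng.uniform(0, scale)))
    history = ServiceHistory(entries)

    a = float(rng.uniform(0.0, 0.6))
    c = float(rng.uniform(0.0, 1.0 - a))
    profile_triple = (a, c, 1.0 - a - c)
    profile = ClientProfile.constant(*profile_triple)

    cpr_basis = "in-union" if rng.random() < 0.5 else "all-women"
    assumptions = AssumptionSet(
        methods=methods,
        demography=DemographicSeries.from_records(demography),
        life_table=LifeTableFamily("rand", life_levels),
        median_age_sterilisation=median_age,
        cpr_basis=cpr_basis,
    )
    exclude = frozenset({"condom"})

    ref = {
        "services": dict(history._entries),
        "methods": {
            "la": {"category": "long-acting", "ccr": list(ccr)},
            "ster": {"category": "permanent"},
            "st": {"category": "short-term", "units_per_year": units_py},
            "condom": {"category": "short-term", "units_per_year": 120.0},
        },
        "demography": demography,
        "life_levels": life_levels,
        "median_age": median_age,
        "profile": profile_triple,
        "cpr_basis": cpr_basis,
    }
    return history, assumptions, profile, y_start, y_end, exclude, ref
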