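"""Independent straight-line reference implementations used as test oracles.

Everything here is deliberately plain Python over plain dicts — no numpy,
no imports from the package under test — written directly from the model
procedure: brute-force linear interpolation, a double loop over every
(cohort, calendar-year) pair, and a literal transcription of the eight
yearly accounting steps.
"""

from __future__ import annotations

REF_MAX_AGE = 49


def ref_interp(x: float, xs: list[float], ys: list[float]) -> float:
    """Piecewise-linear interpolation, clamped outside the range."""
    if x <= xs[0]:
        return ys[0]
    if x >= xs[-1]:
        return ys[-1]
    for i in range(len(xs) - 1):
        if xs[i] <= x <= xs[i + 1]:
            frac = (x - xs[i]) / (xs[i + 1] - xs[i])
            return ys[i] + frac * (ys[i + 1] - ys[i])
    raise AssertionError("unreachable")


def ref_5px(life_levels: dict, e0: float, age: float) -> float:
    """life_levels: {e0_anchor: {age_group_start: p5x}}."""
    group = int(age // 5) * 5
    anchors = sorted(life_levels)
    return ref_interp(e0, anchors, [life_levels[a][group] for a in anchors])


def ref_e0(demography: dict, year: int) -> float:
    """demography: {year: (wra, prop_in_union, e0)}; clamped linear in year."""
    years = sorted(demography)
    return ref_interp(year, [float(y) for y in years], [demography[y][2] for y in years])


def ref_lapm_trajectory(services: float, ccr: list[float]) -> list[float]:
    """Year-by-year users of one IUD/implant cohort (offsets 0..max-1)."""
    return [services * (ccr[n] + ccr[n + 1]) / 2.0 for n in range(len(ccr) - 1)]


def ref_ster_trajectory(
    services: float,
    start_year: int,
    median_age: float,
    demography: dict,
    life_levels: dict,
) -> list[float]:
    """Recursive survival until the cohort's median age passes 49."""
    traj = []
    level = services
    age = int(median_age)
    n = 0
    while age + n <= REF_MAX_AGE:
        p5x = ref_5px(life_levels, ref_e0(demography, start_year + n), age + n)
        level = level * p5x ** (1.0 / 5.0)
        traj.append(level)
        n += 1
    return traj


def ref_cohort_users(
    services: dict,
    methods: dict,
    year: int,
    median_age: float,
    demography: dict,
    life_levels: dict,
    exclude: set,
    max_provision_year: int | None = None,
) -> float:
    """Double loop over every (LAPM cohort, calendar year) pair."""
    total = 0.0
    for (py, name), units in services.items():
        if name in exclude or units <= 0:
            continue
        if max_provision_year is not None and py > max_provision_year:
            continue
        spec = methods[name]
        if spec["category"] == "long-acting":
            traj = ref_lapm_trajectory(units, spec["ccr"])
        elif spec["category"] == "permanent":
            traj = ref_ster_trajectory(units, py, median_age, demography, life_levels)
        else:
            continue
        n = year - py
        if 0 <= n < len(traj):
            total += traj[n]
    return total


def ref_shortterm_users(services: dict, methods: dict, year: int, exclude: set) -> float:
    total = 0.0
    for (py, name), units in services.items():
        if py != year or name in exclude:
            continue
        spec = methods[name]
        if spec["category"] == "short-term":
            total += units / spec["units_per_year"]
    return total


def ref_total_users(
    services, methods, year, median_age, demography, life_levels, exclude
) -> float:
    return ref_cohort_users(
        services, methods, year, median_age, demography, life_levels, exclude
    ) + ref_shortterm_users(services, methods, year, exclude)


def ref_first_year_users(
    services, methods, year, median_age, demography, life_levels, exclude
) -> dict:
    """New users created by year's services, per method."""
    out = {}
    for (py, name), units in services.items():
        if py != year or name in exclude or units <= 0:
            continue
        spec = methods[name]
        if spec["category"] == "long-acting":
            out[name] = units * (spec["ccr"][0] + spec["ccr"][1]) / 2.0
        elif spec["category"] == "permanent":
            p5x = ref_5px(life_levels, ref_e0(demography, year), int(median_age))
            out[name] = units * p5x ** (1.0 / 5.0)
        else:
            out[name] = units / spec["units_per_year"]
    return out


def ref_trend(
    services: dict,
    methods: dict,
    demography: dict,
    life_levels: dict,
    median_age: float,
    profile,
    y_start: int,
    y_end: int,
    exclude: set,
    cpr_basis: str = "all-women",
) -> dict:
    """Literal transcription of the eight yearly steps.

    ``services``: {(year, method): units}; ``profile``: (a, c, p) triple or
    {year: (a, c, p)}.  Returns baseline numbers and one row dict per year.
    """

    def denom(year):
        wra, in_union, _ = demography[year]
        return wra * in_union if cpr_basis == "in-union" else wra

    def prof(year):
        return profile[year] if isinstance(profile, dict) else profile

    y0 = y_start - 1
    baseline_users = ref_total_users(
        services, methods, y0, median_age, demography, life_levels, exclude
    )
    baseline_contribution = baseline_users / denom(y0)

    # counted cohorts created inside the trend: (provision year, method, fraction)
    counted = []
    rows = []
    previous_total = baseline_users
    for y in range(y_start, y_end + 1):
        # step 2: cohorts provided at or before the baseline year
        pre_existing = ref_cohort_users(
            services, methods, y, median_age, demography, life_levels, exclude,
            max_provision_year=y0,
        )
        # step 6 (from earlier years): counted cohorts at offset >= 1
        existing = 0.0
        for (py, name, fraction) in counted:
            units = services.get((py, name), 0.0)
            spec = methods[name]
            if spec["category"] == "long-acting":
                traj = ref_lapm_trajectory(units, spec["ccr"])
            else:
                traj = ref_ster_trajectory(units, py, median_age, demography, life_levels)
            n = y - py
            if 1 <= n < len(traj):
                existing += fraction * traj[n]
        # step 3
        new_by_method = ref_first_year_users(
            services, methods, y, median_age, demography, life_levels, exclude
        )
        new_users = sum(new_by_method.values())
        # step 4
        needed = previous_total - pre_existing - existing
        if needed < 0:
            needed = 0.0
        a, c, _p = prof(y)
        continuers = new_users * c
        adopters = new_users * a
        if continuers >= needed:
            maintain, increase = needed, adopters
        elif continuers + adopters <= needed:
            maintain, increase = continuers + adopters, 0.0
        else:
            maintain, increase = needed, adopters - (needed - continuers)
        # step 5
        fraction = (maintain + increase) / new_users if new_users > 0 else 0.0
        for name in new_by_method:
            if methods[name]["category"] in ("long-acting", "permanent") and fraction > 0:
                counted.append((y, name, fraction))
        # step 7
        total = pre_existing + existing + maintain + increase
        # step 8
        total_pct = total / denom(y)
        rows.append(
            {
                "year": y,
                "pre_existing": pre_existing,
                "existing": existing,
                "maintain": maintain,
                "increase": increase,
                "new_users": new_users,
                "counting_fraction": fraction,
                "total_users_in_cpr": total,
                "total_pct_contribution": total_pct,
                "pct_point_increase": total_pct - baseline_contribution,
            }
        )
        previous_total = total
    return {
        "baseline_users": baseline_users,
        "baseline_contribution": baseline_contribution,
        "years": rows,
    }
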