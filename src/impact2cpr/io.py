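"""Readers and writers for all tabular inputs and outputs.

Everything tabular is CSV; configuration is YAML or JSON.  Method names in
input files are matched case-insensitively through a canonical alias table,
since field data files name the same method many ways ("IUD-10yr",
"Copper T", ...).  All years are calendar years (integers); the model has
annual resolution only.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .assumptions import (
    AssumptionSet,
    DemographicSeries,
    LifeTableFamily,
    MethodSpec,
)
from .cpr_engine import ClientProfile, TrendResult
from .user_estimation import CohortMatrix, ServiceHistory, UserEstimates

__all__ = [
    "canonical_method_name",
    "read_service_history",
    "write_service_history",
    "load_assumption_set",
    "save_assumption_set",
    "write_trend_result",
    "write_user_estimates",
    "write_cohort_matrix",
    "RunConfig",
    "load_run_config",
    "file_sha256",
]

logger = logging.getLogger(__name__)

#: Aliases -> canonical method names (applied after lowercasing and
#: normalising separators to underscores).
METHOD_ALIASES: dict[str, str] = {
    "iud": "iud_10yr",
    "copper_t": "iud_10yr",
    "copper_t_380a": "iud_10yr",
    "iud_10_yr": "iud_10yr",
    "iud_5_yr": "iud_5yr",
    "implant": "implant_3yr",
    "implanon": "implant_3yr",
    "jadelle": "implant_5yr",
    "implant_3_yr": "implant_3yr",
    "implant_4_yr": "implant_4yr",
    "implant_5_yr": "implant_5yr",
    "tubal_ligation": "female_sterilisation",
    "female_sterilization": "female_sterilisation",
    "vasectomy": "male_sterilisation",
    "male_sterilization": "male_sterilisation",
    "pills": "pill",
    "oral_pill": "pill",
    "oc": "pill",
    "injectable": "injectable_3mo",
    "injectables": "injectable_3mo",
    "injection": "injectable_3mo",
    "depo": "injectable_3mo",
    "condoms": "condom",
    "male_condom": "condom",
}


def canonical_method_name(name: str) -> str:
    """Normalise a method label: lowercase, separators to ``_``, aliases."""
    key = re.sub(r"[\s\-/]+", "_", str(name).strip().lower())
    return METHOD_ALIASES.get(key, key)


def _parse_units(value, row: int) -> float:
    """Parse a units cell, tolerating thousands separators ("1,234")."""
    if isinstance(value, str):
        value = value.replace(",", "").strip()
    try:
        units = float(value)
    except (TypeError, ValueError):
        raise ValueError(f"row {row}: cannot parse units value {value!r}") from None
    if units < 0:
        raise ValueError(f"row {row}: negative units ({units})")
    return units


def read_service_history(path: str | Path) -> ServiceHistory:
    """Read a service history CSV with columns year, method, units."""
    path = Path(path)
    frame = pd.read_csv(path, dtype=str)
    frame.columns = [c.strip().lower() for c in frame.columns]
    expected = ["year", "method", "units"]
    if sorted(frame.columns) != sorted(expected):
        raise ValueError(
            f"{path.name}: expected columns {expected}, found {list(frame.columns)}"
        )
    entries: dict[tuple[int, str], float] = {}
    n_blank = 0
    for i, row in enumerate(frame.itertuples(index=False), start=2):  # 1 = header
        try:
            year = int(str(row.year).strip())
        except ValueError:
            raise ValueError(f"{path.name} row {i}: cannot parse year {row.year!r}") from None
        method = canonical_method_name(row.method)
        if pd.isna(row.units) or str(row.units).strip() == "":
            n_blank += 1
            continue
        units = _parse_units(row.units, i)
        if (year, method) in entries:
            raise ValueError(f"{path.name} row {i}: duplicate entry for ({year}, {method!r})")
        entries[(year, method)] = units
    if n_blank:
        logger.warning(
            "%s: %d blank units cells treated as zero services", path.name, n_blank
        )
    return ServiceHistory(entries)


def write_service_history(history: ServiceHistory, path: str | Path) -> None:
    history.to_frame().to_csv(path, index=False)


# -- assumption sets ---------------------------------------------------------


def load_assumption_set(config_path: str | Path) -> AssumptionSet:
    """Load an assumption set from a YAML/JSON config plus CSV data files.

    The config names a demography CSV (year, wra, prop_in_union, e0), a
    life-table CSV (family, e0_level, age_group_start, p5x) with the family
    to use, and per-method blocks, long-acting ones pointing at a CCR CSV
    (year_offset, ccr).  Relative file paths resolve against the config.
    """
    config_path = Path(config_path)
    config = yaml.safe_load(config_path.read_text())
    root = config_path.parent

    demo = pd.read_csv(root / config["demography_file"]).set_index("year")
    demography = DemographicSeries(demo)

    lt_conf = config["life_table"]
    lt_frame = pd.read_csv(root / lt_conf["file"])
    family_name = lt_conf["family"]
    sub = lt_frame[lt_frame["family"] == family_name]
    if sub.empty:
        known = ", ".join(sorted(lt_frame["family"].unique()))
        raise ValueError(
            f"life table family {family_name!r} not in {lt_conf['file']}; found: {known}"
        )
    levels: dict[float, dict[int, float]] = {}
    for (anchor,), group in sub.groupby(["e0_level"]):
        levels[float(anchor)] = dict(
            zip(group["age_group_start"].astype(int), group["p5x"].astype(float))
        )
    life_table = LifeTableFamily(family_name, levels)

    methods: dict[str, MethodSpec] = {}
    for entry in config["methods"]:
        entry = dict(entry)
        ccr_file = entry.pop("ccr_file", None)
        if ccr_file is not None:
            table = pd.read_csv(root / ccr_file).sort_values("year_offset")
            entry["ccr_table"] = tuple(table["ccr"].astype(float))
        spec = MethodSpec(**entry)
        methods[spec.name] = spec

    return AssumptionSet(
        methods=methods,
        demography=demography,
        life_table=life_table,
        median_age_sterilisation=float(config["median_age_sterilisation"]),
        cpr_basis=config.get("cpr_basis", "all-women"),
    )


def save_assumption_set(
    assumptions: AssumptionSet, directory: str | Path, name: str = "assumptions.yaml"
) -> Path:
    """Write an assumption set as config + CSVs; returns the config path.

    ``load_assumption_set`` on the result reproduces the set exactly.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    demo = assumptions.demography.to_frame()
    demo.index.name = "year"
    demo.to_csv(directory / "demography.csv")

    assumptions.life_table.to_frame().to_csv(directory / "life_tables.csv", index=False)

    method_entries = []
    for spec in assumptions.methods.values():
        entry: dict = {"name": spec.name, "category": spec.category}
        if spec.ccr_table is not None:
            ccr_file = f"ccr_{spec.name}.csv"
            pd.DataFrame(
                {"year_offset": range(len(spec.ccr_table)), "ccr": spec.ccr_table}
            ).to_csv(directory / ccr_file, index=False)
            entry["max_duration"] = spec.max_duration
            entry["ccr_file"] = ccr_file
        if spec.units_per_year is not None:
            entry["units_per_year"] = spec.units_per_year
        if spec.cyp_factor is not None:
            entry["cyp_factor"] = spec.cyp_factor
        method_entries.append(entry)

    config = {
        "cpr_basis": assumptions.cpr_basis,
        "median_age_sterilisation": assumptions.median_age_sterilisation,
        "demography_file": "demography.csv",
        "life_table": {"family": assumptions.life_table.name, "file": "life_tables.csv"},
        "methods": method_entries,
    }
    out = directory / name
    out.write_text(yaml.safe_dump(config, sort_keys=False))
    return out


# -- results -----------------------------------------------------------------


def write_trend_result(trend: TrendResult, path: str | Path) -> None:
    """One row per trend year with the full decomposition."""
    trend.to_frame().to_csv(path)


def write_user_estimates(
    estimates: UserEstimates, assumptions: AssumptionSet, path: str | Path
) -> None:
    """Long format: year, method, users, category."""
    frame = estimates.to_long_frame()
    frame["category"] = [assumptions.method(m).category for m in frame["method"]]
    frame.to_csv(path, index=False)


def write_cohort_matrix(
    matrix: CohortMatrix, assumptions: AssumptionSet, path: str | Path
) -> None:
    """Long format: year, method, users, category (one row per cohort-year)."""
    frame = matrix.to_frame()
    frame["category"] = [assumptions.method(m).category for m in frame["method"]]
    frame.to_csv(path, index=False)


# -- run configuration -------------------------------------------------------


@dataclass
class RunConfig:
    """Paths and switches of one engine run (or sweep)."""

    history_file: Path
    assumptions_file: Path
    y_start: int
    y_end: int
    profile: ClientProfile
    exclude_condoms: bool = True
    output_dir: Path = Path("impact2cpr_out")
    log_level: str = "INFO"
    scenarios: list[tuple[str, ClientProfile]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.y_start > self.y_end:
            raise ValueError(f"y_start {self.y_start} must not exceed y_end {self.y_end}")
        for attr in ("history_file", "assumptions_file"):
            p = Path(getattr(self, attr))
            setattr(self, attr, p)
            if not p.exists():
                raise FileNotFoundError(f"{attr} does not exist: {p}")

    @property
    def exclude(self) -> frozenset[str]:
        return frozenset({"condom"}) if self.exclude_condoms else frozenset()


def _parse_profile(block) -> ClientProfile:
    """A profile block: a single triple or a per-year mapping of triples."""

    def triple(d) -> tuple[float, float, float]:
        return (
            float(d["pct_adopters"]),
            float(d["pct_continuers"]),
            float(d["pct_provider_changers"]),
        )

    if isinstance(block, dict) and "pct_adopters" in block:
        return ClientProfile(triple(block))
    return ClientProfile({int(y): triple(d) for y, d in dict(block).items()})


def load_run_config(path: str | Path) -> RunConfig:
    path = Path(path)
    if path.suffix.lower() == ".json":
        config = json.loads(path.read_text())
    else:
        config = yaml.safe_load(path.read_text())
    root = path.parent

    def resolve(p: str) -> Path:
        p = Path(p)
        return p if p.is_absolute() else root / p

    scenarios = [
        (s["label"], _parse_profile(s["profile"]))
        for s in config.get("scenarios", [])
    ]
    return RunConfig(
        history_file=resolve(config["history_file"]),
        assumptions_file=resolve(config["assumptions_file"]),
        y_start=int(config["y_start"]),
        y_end=int(config["y_end"]),
        profile=_parse_profile(config["profile"]),
        exclude_condoms=bool(config.get("exclude_condoms", True)),
        output_dir=resolve(config.get("output_dir", "impact2cpr_out")),
        log_level=str(config.get("log_level", "INFO")),
        scenarios=scenarios,
    )


def file_sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
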