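"""Bundled default data.

* Default method specifications with editable CCR tables and CYP factors
  (``data/default_methods.yaml`` + one CSV per CCR table).  The pill and
  10-year IUD figures follow the published USAID CYP conventions; the rest
  are illustrative defaults that a programme should replace with its own
  current assumption set.
* Synthetic model life-table anchor families
  (``data/life_tables_synthetic.csv``): constructed stand-ins with the
  shape of the standard Coale-Demeny / UN families (5px per 5-year age
  group at a handful of e0 anchor levels), NOT the published tables.
* The published Impact 2 user-category estimates for Marie Stopes
  Madagascar, 2005-2011, condoms excluded — the standard worked example of
  this methodology — used as reference data for consistency checks.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd
import yaml

from .assumptions import LifeTableFamily, MethodSpec

__all__ = [
    "default_method_specs",
    "synthetic_life_table",
    "load_published_madagascar_estimates",
    "MADAGASCAR_LAPM_SERVICES_2011",
]

#: LAPM service deliveries recorded by Marie Stopes Madagascar in 2011,
#: published alongside the user estimates; the modelled LAPM user number for
#: the same year (175,283) is more than double this service count because
#: cohorts from earlier years continue.
MADAGASCAR_LAPM_SERVICES_2011 = 67_111


def _data_dir():
    return resources.files(__package__) / "data"


def default_method_specs() -> dict[str, MethodSpec]:
    """The bundled default contraceptive method set, keyed by name."""
    root = _data_dir()
    config = yaml.safe_load((root / "default_methods.yaml").read_text())
    specs: dict[str, MethodSpec] = {}
    for entry in config["methods"]:
        entry = dict(entry)
        ccr_file = entry.pop("ccr_file", None)
        if ccr_file is not None:
            with (root / ccr_file).open() as fh:
                table = pd.read_csv(fh)
            table = table.sort_values("year_offset")
            entry["ccr_table"] = tuple(table["ccr"].astype(float))
        spec = MethodSpec(**entry)
        specs[spec.name] = spec
    return specs


def default_median_age_sterilisation() -> float:
    root = _data_dir()
    config = yaml.safe_load((root / "default_methods.yaml").read_text())
    return float(config["median_age_sterilisation"])


def life_table_frame() -> pd.DataFrame:
    with (_data_dir() / "life_tables_synthetic.csv").open() as fh:
        return pd.read_csv(fh)


def synthetic_life_table(family: str = "synthetic-general") -> LifeTableFamily:
    """One of the bundled synthetic life-table families."""
    frame = life_table_frame()
    sub = frame[frame["family"] == family]
    if sub.empty:
        known = ", ".join(sorted(frame["family"].unique()))
        raise KeyError(f"unknown life table family {family!r}; bundled: {known}")
    levels: dict[float, dict[int, float]] = {}
    for (anchor,), group in sub.groupby(["e0_level"]):
        levels[float(anchor)] = dict(
            zip(group["age_group_start"].astype(int), group["p5x"].astype(float))
        )
    return LifeTableFamily(family, levels)


def load_published_madagascar_estimates() -> pd.DataFrame:
    """Published per-year user-category estimates, Madagascar 2005-2011.

    Columns: total_users, lapm_users, short_term_users, users_served,
    adopters_served, adopters_increasing_cpr; index is the calendar year.
    These are published model outputs, bundled as reference data — they are
    not recomputed here (the underlying per-method service history and
    country assumption set are not in the public record).
    """
    with (_data_dir() / "madagascar_published_estimates.csv").open() as fh:
        frame = pd.read_csv(fh)
    return frame.set_index("year")
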