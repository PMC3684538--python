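"""Client-profile sensitivity sweeps.

The increasing-CPR metric leans heavily on the client profile, which is
often measured in a single exit-interview round and proxied across a whole
trend.  A sweep re-runs the full engine under alternative profiles
(typically a lower- and a higher-adopter variant around the measured one)
on otherwise identical inputs, so the spread of the resulting
percentage-point curves bounds the profile uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .assumptions import AssumptionSet
from .cpr_engine import ClientProfile, TrendResult, run_trend
from .user_estimation import DEFAULT_EXCLUDE, ServiceHistory

__all__ = ["ProfileScenario", "SweepResult", "profile_sweep"]


@dataclass(frozen=True)
class ProfileScenario:
    """A labelled client profile to run the engine under."""

    label: str
    profile: ClientProfile


@dataclass
class SweepResult:
    """Aligned per-scenario trend results."""

    trends: dict[str, TrendResult]

    def tidy(self) -> pd.DataFrame:
        """Long frame (scenario, year, pct_point_increase), ready to plot."""
        rows = [
            {
                "scenario": label,
                "year": yr.year,
                "pct_point_increase": 100.0 * yr.pct_point_increase,
            }
            for label, trend in self.trends.items()
            for yr in trend.years
        ]
        return pd.DataFrame(rows, columns=["scenario", "year", "pct_point_increase"])

    @property
    def cumulative(self) -> dict[str, float]:
        """Final-year percentage-point increase per scenario."""
        return {
            label: 100.0 * trend.cumulative_pct_point_increase
            for label, trend in self.trends.items()
        }


def profile_sweep(
    history: ServiceHistory,
    assumptions: AssumptionSet,
    scenarios: list[ProfileScenario],
    y_start: int,
    y_end: int,
    exclude: frozenset[str] = DEFAULT_EXCLUDE,
) -> SweepResult:
    """Run the full engine once per scenario on identical inputs.

    Sweeps deliberately re-run everything rather than perturbing
    intermediate results: correctness over speed at desk scale.
    """
    if not scenarios:
        raise ValueError("at least one scenario is required")
    labels = [s.label for s in scenarios]
    if len(set(labels)) != len(labels):
        raise ValueError("scenario labels must be unique")
    return SweepResult(
        {
            s.label: run_trend(history, assumptions, s.profile, y_start, y_end, exclude)
            for s in scenarios
        }
    )
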