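"""Annual microplastic intake estimation and Monte Carlo uncertainty.

The point estimate is the deterministic product

    intake = (weekly consumption / 7) * concentration * exposure days,

with the concentration in items per gram and the exposure frequency in
consumption days per year (52/156/260 for one, three, five days a week).
Two consumption rates are carried: the canned-fish rate (MICF estimates)
and the overall fish rate (MIF estimates).

Uncertainty is propagated by Monte Carlo under a normal assumption,
truncated at zero by default (negative intakes are unphysical), reporting
the empirical mean and 5th/95th percentiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import isfinite
from typing import Sequence

import numpy as np
from scipy import stats

from .types import (
    BrandConcentration,
    ConsumptionScenario,
    IntakeEstimate,
    ValidationError,
    EXPOSURE_FREQUENCIES,
)

__all__ = [
    "MonteCarloConfig",
    "default_scenarios",
    "daily_rate",
    "intake",
    "monte_carlo_intake",
    "intake_table",
]

#: Canned-fish and overall fish consumption for the surveyed population,
#: grams per person per week.
CANNED_FISH_G_PER_WEEK = 0.54
FISH_G_PER_WEEK = 16.84


@dataclass(frozen=True)
class MonteCarloConfig:
    """Settings for the intake uncertainty simulation."""

    iterations: int = 10_000
    distribution: str = "normal"
    truncate_at_zero: bool = True
    seed: int = 20230118
    percentiles: tuple[float, float] = (5.0, 95.0)

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValidationError("iterations must be >= 1")
        if self.distribution != "normal":
            raise ValidationError(
                f"unsupported distribution {self.distribution!r}"
            )
        if not all(0.0 < p < 100.0 for p in self.percentiles):
            raise ValidationError("percentiles must lie in (0, 100)")


def default_scenarios() -> list[ConsumptionScenario]:
    """The six standard scenarios: two rates x three frequencies."""
    return [
        ConsumptionScenario(label, rate, days)
        for label, rate in (
            ("canned_fish", CANNED_FISH_G_PER_WEEK),
            ("fish", FISH_G_PER_WEEK),
        )
        for days in EXPOSURE_FREQUENCIES
    ]


def daily_rate(scenario: ConsumptionScenario) -> float:
    """Consumption in g/person/day (weekly rate / 7)."""
    return scenario.weekly_rate_g / 7.0


def intake(
    concentration_per_g: float, scenario: ConsumptionScenario
) -> float:
    """Annual intake in items/person/year for one scenario.

    ``concentration_per_g`` is the corrected concentration in items per
    gram (a per-100 g value divided by 100).
    """
    if concentration_per_g < 0:
        raise ValidationError("concentration must be non-negative")
    return (
        daily_rate(scenario)
        * concentration_per_g
        * scenario.exposure_days_per_year
    )


def monte_carlo_intake(
    mean: float,
    spread: float,
    config: MonteCarloConfig,
    *,
    code: str = "grand",
    scenario: ConsumptionScenario | None = None,
) -> IntakeEstimate:
    """Simulate intake uncertainty around a point estimate.

    Draws ``config.iterations`` samples from Normal(mean, spread) — the
    zero-truncated variant when ``truncate_at_zero`` is set — and reports
    the empirical mean and the configured percentiles. Runs are
    reproducible under a fixed ``config.seed``.
    """
    if not (isfinite(mean) and isfinite(spread)):
        raise ValidationError("Monte Carlo parameters must be finite")
    if spread < 0:
        raise ValidationError("spread must be non-negative")
    if scenario is None:
        scenario = ConsumptionScenario("fish", FISH_G_PER_WEEK, 52)
    if spread == 0.0:
        point = max(mean, 0.0) if config.truncate_at_zero else mean
        return IntakeEstimate(
            code=code,
            scenario=scenario,
            point_items_per_year=max(mean, 0.0),
            mc_mean=point,
            mc_p5=point,
            mc_p95=point,
        )
    rng = np.random.default_rng(config.seed)
    if config.truncate_at_zero:
        a = (0.0 - mean) / spread
        samples = stats.truncnorm.rvs(
            a, np.inf, loc=mean, scale=spread,
            size=config.iterations, random_state=rng,
        )
    else:
        samples = rng.normal(mean, spread, size=config.iterations)
    lo, hi = np.percentile(samples, config.percentiles)
    return IntakeEstimate(
        code=code,
        scenario=scenario,
        point_items_per_year=max(mean, 0.0),
        mc_mean=float(np.mean(samples)),
        mc_p5=float(lo),
        mc_p95=float(hi),
    )


def intake_table(
    brands: Sequence[BrandConcentration],
    scenarios: Sequence[ConsumptionScenario] | None = None,
) -> list[IntakeEstimate]:
    """Point intake estimates for every brand under every scenario.

    Uses each brand's corrected concentration as given (no extra rounding);
    feed display-rounded concentrations to reproduce a published table
    cell-for-cell.
    """
    if scenarios is None:
        scenarios = default_scenarios()
    estimates = []
    for brand in brands:
        if brand.corrected_mean_per100g is None:
            raise ValidationError(
                f"{brand.code}: corrected concentration missing"
            )
        conc_per_g = brand.corrected_mean_per100g / 100.0
        for scenario in scenarios:
            estimates.append(
                IntakeEstimate(
                    code=brand.code,
                    scenario=scenario,
                    point_items_per_year=intake(conc_per_g, scenario),
                )
            )
    return estimates
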