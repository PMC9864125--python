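"""Model/results surface for a canned-fish microplastic survey.

:class:`CannedFishSurvey` holds the survey data (per-can counts, product
metadata, particle attributes) together with the correction constants;
``fit()`` runs the estimation — per-brand concentrations, verification
scaling, blank-subtracted grand mean — and returns a
:class:`SurveyResults` carrying the estimates and their standard errors,
with intake tables, Monte Carlo uncertainty, composition summaries and
the inferential stage hanging off the results object.

Example
-------
>>> from canmp import CannedFishSurvey, simulate
>>> tables = simulate.generate_survey(simulate.GeneratorConfig(seed=7))
>>> res = CannedFishSurvey.from_tables(tables).fit()
>>> print(res.summary())                            # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import mean, stdev
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import composition as comp
from . import corrections, intake as intake_mod, stats as stats_mod
from .simulate import SurveyTables
from .types import (
    BrandConcentration,
    CanObservation,
    ConsumptionScenario,
    CorrectionConstants,
    IntakeEstimate,
    ParticleRecord,
    ProductRecord,
    ValidationError,
)
from . import io as io_mod

__all__ = ["CannedFishSurvey", "SurveyResults", "constants_from_data"]


def constants_from_data(
    particles: Sequence[ParticleRecord],
    blank_counts: Sequence[int],
) -> CorrectionConstants:
    """Estimate correction constants from analyzed particles and blanks."""
    analyzed = [p for p in particles if p.verified != "not_analyzed"]
    verified = [p for p in analyzed if p.verified == "verified_mp"]
    if not analyzed:
        raise ValidationError("no analyzed particles to estimate the rate")
    if not blank_counts:
        raise ValidationError("no blank observations supplied")
    return CorrectionConstants(
        n_analyzed=len(analyzed),
        n_verified=len(verified),
        blank_particles=int(sum(blank_counts)),
        blank_units=len(blank_counts),
    )


class CannedFishSurvey:
    """A microplastic survey model: data plus correction constants.

    Parameters
    ----------
    observations
        Per-can particle counts, three replicate cans per brand in the
        reference design.
    products
        Optional product metadata; required for the grouped inferential
        stage (ANOVA factors, weight-abundance correlation).
    particles
        Optional particle-level attributes; required for composition
        summaries.
    constants
        Verification and blank constants. Defaults to the reference
        survey's (64/79 verified, 2 particles over 3 dishes).
    blank_mode
        ``"standard"`` subtracts the per-dish blank rate from the per-100 g
        grand mean; ``"unit_consistent"`` rescales it to per-100 g first.
    """

    def __init__(
        self,
        observations: Sequence[CanObservation],
        products: Sequence[ProductRecord] | None = None,
        particles: Sequence[ParticleRecord] | None = None,
        constants: CorrectionConstants | None = None,
        *,
        blank_mode: corrections.BlankMode = "standard",
    ) -> None:
        if not observations:
            raise ValidationError("a survey needs at least one observation")
        self.observations = list(observations)
        self.products = list(products) if products is not None else None
        self.particles = list(particles) if particles is not None else None
        self.constants = (
            constants if constants is not None else CorrectionConstants()
        )
        self.blank_mode = blank_mode

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_csv(
        cls,
        observations_path,
        products_path=None,
        particles_path=None,
        constants: CorrectionConstants | None = None,
        **kwargs,
    ) -> "CannedFishSurvey":
        return cls(
            io_mod.read_observation_table(observations_path),
            products=io_mod.read_product_table(products_path)
            if products_path
            else None,
            particles=io_mod.read_particle_table(particles_path)
            if particles_path
            else None,
            constants=constants,
            **kwargs,
        )

    @classmethod
    def from_tables(
        cls,
        tables: SurveyTables,
        constants: CorrectionConstants | None = None,
        blank_counts: Sequence[int] | None = None,
        **kwargs,
    ) -> "CannedFishSurvey":
        """Build from a synthetic :class:`~canmp.simulate.SurveyTables`.

        When ``constants`` is omitted and ``blank_counts`` are given, the
        verification and blank constants are estimated from the synthetic
        particles and blank dishes — the same route a real survey takes.
        """
        if constants is None and blank_counts is not None:
            constants = constants_from_data(tables.particles, blank_counts)
        return cls(
            tables.observations,
            products=tables.products,
            particles=tables.particles,
            constants=constants,
            **kwargs,
        )

    # -- estimation -------------------------------------------------------

    def fit(self) -> "SurveyResults":
        """Estimate per-brand and grand corrected concentrations."""
        rate = corrections.verification_rate(self.constants)
        blank = corrections.blank_rate(self.constants)
        by_code: dict[str, list[CanObservation]] = {}
        for obs in self.observations:
            by_code.setdefault(obs.code, []).append(obs)
        brands = [
            corrections.correct_brand(
                corrections.brand_concentration(group), rate
            )
            for group in by_code.values()
        ]
        masses = {obs.subsample_mass_g for obs in self.observations}
        grand = corrections.grand_mean(
            brands,
            rate,
            blank,
            blank_mode=self.blank_mode,
            subsample_mass_g=masses.pop() if len(masses) == 1 else 50.0,
        )
        return SurveyResults(model=self, brands=brands, grand=grand,
                             verification_rate=rate, blank_rate=blank)


@dataclass
class SurveyResults:
    """Fitted survey estimates with uncertainty and downstream analyses."""

    model: CannedFishSurvey
    brands: list[BrandConcentration]
    grand: BrandConcentration
    verification_rate: float
    blank_rate: float

    # -- core accessors ---------------------------------------------------

    @property
    def params(self) -> pd.Series:
        """Corrected per-brand concentrations (MPs/100 g)."""
        return pd.Series(
            {b.code: b.corrected_mean_per100g for b in self.brands},
            name="corrected_mean_per100g",
        )

    @property
    def bse(self) -> pd.Series:
        """Standard errors of the corrected brand concentrations."""
        return pd.Series(
            {b.code: b.std_error_per100g for b in self.brands},
            name="std_error_per100g",
        )

    def concentration_frame(self) -> pd.DataFrame:
        rows = [
            {
                "code": b.code,
                "raw_mean_per100g": b.raw_mean_per100g,
                "corrected_mean_per100g": b.corrected_mean_per100g,
                "std_error_per100g": b.std_error_per100g,
                "n_replicates": b.n_replicates,
            }
            for b in [*self.brands, self.grand]
        ]
        return pd.DataFrame(rows).set_index("code")

    def per_can_values(self) -> pd.DataFrame:
        """Per-can abundances (MPs/100 g), joined to product metadata."""
        prods = {
            p.code: p for p in (self.model.products or [])
        }
        rows = []
        for obs in self.model.observations:
            product = prods.get(obs.code)
            rows.append(
                {
                    "code": obs.code,
                    "replicate": obs.replicate,
                    "per100g": obs.particle_count
                    / obs.subsample_mass_g
                    * 100.0,
                    "producer": obs.code.split("-", 1)[0],
                    "package_type": product.package_type if product else None,
                    "oil_type": (product.additive_oil or "none").lower()
                    if product
                    else None,
                    "water_usage": (
                        any(
                            "water" in a.lower()
                            for a in product.other_additives
                        )
                        if product
                        else None
                    ),
                    "species": product.species if product else None,
                    "product_weight_g": product.product_weight_g
                    if product
                    else None,
                }
            )
        return pd.DataFrame(rows)

    # -- intake -----------------------------------------------------------

    def intake_table(
        self,
        scenarios: Sequence[ConsumptionScenario] | None = None,
        include_grand: bool = True,
    ) -> pd.DataFrame:
        """Point intake estimates (items/person/year), wide by scenario."""
        brands = [*self.brands, self.grand] if include_grand else self.brands
        estimates = intake_mod.intake_table(brands, scenarios)
        frame = pd.DataFrame(
            {
                "code": [e.code for e in estimates],
                "scenario": [e.scenario.label for e in estimates],
                "days": [e.scenario.exposure_days_per_year for e in estimates],
                "items_per_year": [e.point_items_per_year for e in estimates],
            }
        )
        wide = frame.pivot_table(
            index="code",
            columns=["scenario", "days"],
            values="items_per_year",
            sort=False,
        )
        return wide.reindex([b.code for b in brands])

    def monte_carlo(
        self,
        config: intake_mod.MonteCarloConfig | None = None,
        scenarios: Sequence[ConsumptionScenario] | None = None,
    ) -> list[IntakeEstimate]:
        """Per-scenario pooled Monte Carlo uncertainty of the intake.

        For each scenario the simulated distribution is Normal(m, s) with
        ``m`` the intake at the grand corrected concentration and ``s`` the
        standard deviation of per-brand intakes (the brand-level SE times
        sqrt(n_brands)), truncated at zero by default.
        """
        if config is None:
            config = intake_mod.MonteCarloConfig()
        if scenarios is None:
            scenarios = intake_mod.default_scenarios()
        results = []
        for offset, scenario in enumerate(scenarios):
            values = [
                intake_mod.intake(
                    b.corrected_mean_per100g / 100.0, scenario
                )
                for b in self.brands
            ]
            spread = stdev(values) if len(values) > 1 else 0.0
            point = intake_mod.intake(
                self.grand.corrected_mean_per100g / 100.0, scenario
            )
            sub = intake_mod.MonteCarloConfig(
                iterations=config.iterations,
                distribution=config.distribution,
                truncate_at_zero=config.truncate_at_zero,
                seed=config.seed + offset,
                percentiles=config.percentiles,
            )
            results.append(
                intake_mod.monte_carlo_intake(
                    point, spread, sub, code="grand", scenario=scenario
                )
            )
        return results

    # -- composition ------------------------------------------------------

    def composition(self, dimension: str) -> comp.CompositionSummary:
        if self.model.particles is None:
            raise ValidationError("no particle table attached to the survey")
        return comp.summarize(self.model.particles, dimension)

    # -- inferential stage ------------------------------------------------

    def grouped_values(
        self, factor: str, level: str = "can"
    ) -> stats_mod.GroupedValues:
        """Abundances grouped by a survey factor.

        ``level="can"`` uses per-can values (n = cans); ``level="brand"``
        aggregates to per-brand means first. Replicate cans of a brand
        share the brand's contamination level, so the per-can analysis is
        anticonservative for factors that vary only between brands; the
        brand level restores exchangeability within groups.
        """
        if self.model.products is None:
            raise ValidationError(
                "product metadata is required for grouped analyses"
            )
        frame = self.per_can_values()
        if factor not in frame.columns:
            raise ValidationError(f"unknown grouping factor {factor!r}")
        if level == "brand":
            frame = (
                frame.groupby(["code", factor], dropna=True, as_index=False)
                ["per100g"].mean()
            )
        elif level != "can":
            raise ValidationError(f"unknown aggregation level {level!r}")
        groups = {
            str(label): list(sub["per100g"])
            for label, sub in frame.groupby(factor, dropna=True)
        }
        return stats_mod.GroupedValues(factor=factor, groups=groups)

    def anova(
        self, factor: str, level: str = "can", **kwargs
    ) -> stats_mod.AnovaResult:
        return stats_mod.one_way_anova(
            self.grouped_values(factor, level=level), **kwargs
        )

    def normality(self) -> stats_mod.NormalityResult:
        frame = self.per_can_values()
        return stats_mod.normality_tests(
            stats_mod.log_transform(frame["per100g"])
        )

    def pearson_weight_abundance(self) -> tuple[float, float]:
        frame = self.per_can_values().dropna(subset=["product_weight_g"])
        return stats_mod.pearson_weight_abundance(
            frame["product_weight_g"], frame["per100g"]
        )

    # -- presentation -----------------------------------------------------

    def plot_intake_distribution(
        self,
        estimate: IntakeEstimate,
        config: intake_mod.MonteCarloConfig | None = None,
        ax=None,
    ):
        """Histogram of the simulated intake distribution for one scenario."""
        import matplotlib.pyplot as plt

        if config is None:
            config = intake_mod.MonteCarloConfig()
        if ax is None:
            _, ax = plt.subplots()
        rng = np.random.default_rng(config.seed)
        spread = (
            (estimate.mc_p95 - estimate.mc_p5) / 3.29
            if estimate.mc_p95 is not None
            else 0.0
        )
        samples = rng.normal(
            estimate.point_items_per_year, max(spread, 1e-12),
            size=config.iterations,
        )
        samples = samples[samples >= 0]
        ax.hist(samples, bins=50, color="steelblue", alpha=0.8)
        ax.set_xlabel("items/person/year")
        ax.set_ylabel("frequency")
        ax.set_title(
            f"{estimate.scenario.label}, "
            f"{estimate.scenario.exposure_days_per_year} days/year"
        )
        return ax

    def summary(self) -> str:
        """Human-readable estimation summary."""
        lines = [
            "Canned-fish microplastic survey",
            "=" * 47,
            f"brands: {len(self.brands)}    "
            f"cans: {len(self.model.observations)}",
            f"verification rate: {self.verification_rate:.4f} "
            f"({self.verification_rate * 100:.0f}%)",
            f"blank rate: {self.blank_rate:.2f} items/dish "
            f"(mode: {self.model.blank_mode})",
            "",
            f"grand raw mean:       "
            f"{self.grand.raw_mean_per100g:6.2f} MPs/100 g",
            f"grand corrected mean: "
            f"{self.grand.corrected_mean_per100g:6.2f} "
            f"± {self.grand.std_error_per100g:.2f} MPs/100 g",
            "",
            self.concentration_frame().round(2).to_string(),
        ]
        return "\n".join(lines)
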