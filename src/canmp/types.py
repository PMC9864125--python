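"""Domain types for canned-fish microplastic surveys.

All records are plain dataclasses with eager validation so that malformed
survey files fail at read time, not deep inside the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "PACKAGE_TYPES",
    "PARTICLE_SHAPES",
    "VERIFICATION_STATES",
    "EXPOSURE_FREQUENCIES",
    "ProductRecord",
    "ParticleRecord",
    "CanObservation",
    "BrandConcentration",
    "CorrectionConstants",
    "ConsumptionScenario",
    "IntakeEstimate",
    "ValidationError",
]

#: Closed vocabulary for packaging after normalization.
PACKAGE_TYPES = frozenset(
    {"can", "can_bpa_free", "aluminum", "composite_cpp", "glass"}
)
PARTICLE_SHAPES = frozenset({"fiber", "fragment"})
VERIFICATION_STATES = frozenset({"verified_mp", "rejected", "not_analyzed"})
#: Consumption days per year for one, three and five meals a week.
EXPOSURE_FREQUENCIES = (52, 156, 260)


class ValidationError(ValueError):
    """A record or table violates the survey data contract."""


@dataclass(frozen=True)
class ProductRecord:
    """One canned product: code, species, additives, weight and packaging.

    The brand code has a producer-brand-product structure (``D-C-1``): the
    letters before the first hyphen identify the producer. ``package_type``
    is the normalized vocabulary; the label as printed on the source table
    is preserved in ``package_label_raw``.
    """

    code: str
    producer: str
    species: str
    additive_oil: str | None
    other_additives: tuple[str, ...]
    product_weight_g: float
    package_type: str
    party_no: str = ""
    package_label_raw: str = ""

    def __post_init__(self) -> None:
        if self.product_weight_g <= 0:
            raise ValidationError(
                f"{self.code}: product weight must be positive, "
                f"got {self.product_weight_g}"
            )
        expected = self.code.split("-", 1)[0]
        if self.producer != expected:
            raise ValidationError(
                f"{self.code}: producer {self.producer!r} does not match the "
                f"code prefix {expected!r}"
            )
        if self.package_type not in PACKAGE_TYPES:
            raise ValidationError(
                f"{self.code}: unknown package type {self.package_type!r}"
            )
        if not self.package_label_raw:
            object.__setattr__(self, "package_label_raw", self.package_type)


@dataclass(frozen=True)
class ParticleRecord:
    """One detected particle with its morphology and verification status."""

    sample_id: str
    shape: str
    color: str
    size_mm: float
    polymer: str = "unknown"
    verified: str = "not_analyzed"

    def __post_init__(self) -> None:
        if self.shape not in PARTICLE_SHAPES:
            raise ValidationError(f"unknown particle shape {self.shape!r}")
        if self.verified not in VERIFICATION_STATES:
            raise ValidationError(
                f"unknown verification state {self.verified!r}"
            )
        if not self.size_mm > 0:
            raise ValidationError(
                f"particle size must be positive, got {self.size_mm}"
            )
        if self.polymer != "unknown" and self.verified == "not_analyzed":
            raise ValidationError(
                f"particle in {self.sample_id}: polymer {self.polymer!r} "
                "assigned without spectroscopic analysis"
            )


@dataclass(frozen=True)
class CanObservation:
    """Particle count for one replicate can (one digested subsample)."""

    code: str
    replicate: int
    subsample_mass_g: float
    particle_count: int

    def __post_init__(self) -> None:
        if self.subsample_mass_g <= 0:
            raise ValidationError(
                f"{self.code} r{self.replicate}: subsample mass must be "
                f"positive, got {self.subsample_mass_g}"
            )
        if self.particle_count < 0:
            raise ValidationError(
                f"{self.code} r{self.replicate}: negative particle count"
            )


@dataclass(frozen=True)
class BrandConcentration:
    """Raw and corrected microplastic concentration for one brand.

    Concentrations are in MPs per 100 g of fish flesh; ``std_error_per100g``
    is the standard error over replicate cans (scaled by the verification
    rate once the correction is applied).
    """

    code: str
    raw_mean_per100g: float
    corrected_mean_per100g: float | None = None
    std_error_per100g: float | None = None
    n_replicates: int | None = None

    def __post_init__(self) -> None:
        if self.raw_mean_per100g < 0:
            raise ValidationError(
                f"{self.code}: negative raw concentration"
            )
        if (
            self.corrected_mean_per100g is not None
            and self.corrected_mean_per100g < 0
        ):
            raise ValidationError(
                f"{self.code}: negative corrected concentration"
            )
        if self.std_error_per100g is not None and self.std_error_per100g < 0:
            raise ValidationError(f"{self.code}: negative standard error")

    def with_corrected(
        self, corrected: float, std_error: float | None = None
    ) -> "BrandConcentration":
        return replace(
            self,
            corrected_mean_per100g=corrected,
            std_error_per100g=std_error
            if std_error is not None
            else self.std_error_per100g,
        )


@dataclass(frozen=True)
class CorrectionConstants:
    """Constants for the two-step count correction.

    ``n_verified / n_analyzed`` is the spectroscopic verification rate
    (fraction of counted particles confirmed as synthetic polymer);
    ``blank_particles / blank_units`` is the procedural-blank background in
    items per control dish.
    """

    n_analyzed: int = 79
    n_verified: int = 64
    blank_particles: int = 2
    blank_units: int = 3

    def __post_init__(self) -> None:
        if not 0 <= self.n_verified <= self.n_analyzed:
            raise ValidationError(
                f"verified count {self.n_verified} outside "
                f"[0, {self.n_analyzed}]"
            )
        if self.blank_units < 1:
            raise ValidationError("at least one blank unit is required")
        if self.blank_particles < 0:
            raise ValidationError("negative blank particle count")


@dataclass(frozen=True)
class ConsumptionScenario:
    """A consumption rate paired with an exposure frequency.

    ``weekly_rate_g`` is grams of product eaten per person per week (the
    canned-fish rate or the overall fish rate); ``exposure_days_per_year``
    is the assumed number of consumption days (52/156/260 for one, three,
    five days a week).
    """

    label: str
    weekly_rate_g: float
    exposure_days_per_year: int

    def __post_init__(self) -> None:
        if self.weekly_rate_g <= 0:
            raise ValidationError("weekly consumption rate must be positive")
        if self.exposure_days_per_year not in EXPOSURE_FREQUENCIES:
            raise ValidationError(
                f"unsupported exposure frequency "
                f"{self.exposure_days_per_year}; expected one of "
                f"{EXPOSURE_FREQUENCIES}"
            )


@dataclass(frozen=True)
class IntakeEstimate:
    """Annual microplastic intake: point estimate and Monte Carlo summary."""

    code: str
    scenario: ConsumptionScenario
    point_items_per_year: float
    mc_mean: float | None = None
    mc_p5: float | None = None
    mc_p95: float | None = None

    def __post_init__(self) -> None:
        if self.point_items_per_year < 0:
            raise ValidationError(f"{self.code}: negative intake estimate")
        if (
            self.mc_p5 is not None
            and self.mc_mean is not None
            and self.mc_p95 is not None
            and not (self.mc_p5 <= self.mc_mean <= self.mc_p95)
        ):
            raise ValidationError(
                f"{self.code}: Monte Carlo percentiles out of order "
                f"({self.mc_p5}, {self.mc_mean}, {self.mc_p95})"
            )
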