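"""Synthetic market-basket survey generator.

Emulates the sampling design of a canned-fish microplastic survey: brands
nested in producers, three replicate cans per brand, a 50 g digested
subsample per can. Per-can particle counts are Poisson at the can level —
the minimal model for particle counts, and one that makes laboratory
background additive. Each counted particle receives a shape, color, size
and a latent true-microplastic label; a random subsample is "analyzed"
(spectroscopy in the real protocol) and true microplastics among them are
marked verified.

Defaults mirror the reference survey: 7 producers x ~5 brands, per-100 g
Poisson intensities spanning 1-17, background at 0.67 items per dish, a
64/79 probability that a counted particle is truly plastic, a 30% analysis
fraction, and shape/color/polymer/size distributions matching the printed
composition summaries. Particle sizes are log-normal truncated to the
printed per-shape ranges (0.06-5.14 mm fragments, 0.27-5.89 mm fibers).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .types import (
    CanObservation,
    ParticleRecord,
    ProductRecord,
    ValidationError,
)

__all__ = ["GeneratorConfig", "SurveyTables", "generate_survey",
           "generate_blanks"]

_SHAPE_PROBS = {"fragment": 0.573, "fiber": 0.427}
_COLOR_PROBS = {
    "blue": 0.348,
    "black": 0.273,
    "white": 0.119,
    "transparent": 0.106,
    "other": 0.154,
}
# Polymer draws are shape-conditional, using the integer counts behind the
# printed per-shape composition blocks (11 fibers, 53 fragments).
_FIBER_POLYMER_COUNTS = {
    "Chitin": 2,
    "Poly(vinyl acetate)": 2,
    "Polyamide - Nylon 6, 6": 2,
    "Cellulose": 1,
    "Ethylene-vinyl acetate": 1,
    "Polyacrylonitrile": 1,
    "Polypropylene": 1,
    "Polyvinylidene chloride": 1,
}
_FRAGMENT_POLYMER_COUNTS = {
    "Polyolefin": 14,
    "Poly(methacrylic acid methyl ester)": 6,
    "Polyacrylonitrile": 6,
    "Polyethylene Terephthalate": 5,
    "Polyethylene": 4,
    "Polypropylene": 4,
    "Polystyrene": 4,
    "Polyamide - Nylon 6, 6": 3,
    "Polyvinylidene chloride": 3,
    "Epoxy": 2,
    "Poly(vinyl acetate)": 2,
}
# Log-normal size parameters (log-mm) and truncation ranges per shape.
_SIZE_PARAMS = {
    "fragment": {"mu": -0.5, "sigma": 0.9, "range_mm": (0.06, 5.14)},
    "fiber": {"mu": 0.0, "sigma": 0.8, "range_mm": (0.27, 5.89)},
}

_SPECIES = ("Tuna", "Skipjack", "Yellowfin Tuna", "Mackerel", "Salmon",
            "Blacksea Anchovy")
_OILS = ("Sunflower oil", "Olive oil", "Canola oil", None)
_PACKAGES = ("can", "can", "can", "can_bpa_free", "aluminum",
             "composite_cpp", "glass")
_WEIGHTS = (75.0, 80.0, 100.0, 110.0, 120.0, 160.0, 185.0)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-design parameters for the synthetic survey."""

    n_producers: int = 7
    brands_per_producer: int = 5
    replicates_per_brand: int = 3
    subsample_mass_g: float = 50.0
    brand_lambda_range: tuple[float, float] = (1.0, 17.0)
    producer_effect_sd: float = 0.5
    blank_rate_per_petri: float = 2.0 / 3.0
    n_blank_units: int = 3
    verification_true_mp_prob: float = 64.0 / 79.0
    analysis_fraction: float = 0.30
    shape_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(_SHAPE_PROBS)
    )
    color_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(_COLOR_PROBS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.brand_lambda_range
        if not (0 < lo <= hi):
            raise ValidationError("lambda bounds must be positive and ordered")
        if not 0.0 <= self.verification_true_mp_prob <= 1.0:
            raise ValidationError("true-MP probability outside [0, 1]")
        if not 0.0 <= self.analysis_fraction <= 1.0:
            raise ValidationError("analysis fraction outside [0, 1]")
        if self.blank_rate_per_petri < 0 or self.producer_effect_sd < 0:
            raise ValidationError("rates and spreads must be non-negative")
        if min(self.n_producers, self.brands_per_producer,
               self.replicates_per_brand) < 1:
            raise ValidationError("design counts must be >= 1")
        for name, probs in (("shape", self.shape_probs),
                            ("color", self.color_probs)):
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-6 or any(p < 0 for p in probs.values()):
                raise ValidationError(
                    f"{name} probabilities must be non-negative and sum to 1"
                )


@dataclass(frozen=True)
class SurveyTables:
    """A complete synthetic survey plus its generating ground truth."""

    products: list[ProductRecord]
    observations: list[CanObservation]
    particles: list[ParticleRecord]
    truth: dict


def _draw_categorical(rng: np.random.Generator, probs: Mapping[str, float],
                      size: int) -> np.ndarray:
    labels = list(probs)
    weights = np.array([probs[k] for k in labels], dtype=float)
    weights = weights / weights.sum()
    return rng.choice(labels, size=size, p=weights)


def _draw_sizes(rng: np.random.Generator, shape: str, size: int
                ) -> np.ndarray:
    params = _SIZE_PARAMS[shape]
    lo, hi = params["range_mm"]
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.lognormal(params["mu"], params["sigma"],
                             size=2 * (size - filled) + 8)
        keep = draw[(draw >= lo) & (draw <= hi)]
        take = min(keep.size, size - filled)
        out[filled:filled + take] = keep[:take]
        filled += take
    return out


def generate_survey(config: GeneratorConfig) -> SurveyTables:
    """Draw a full synthetic survey under ``config``.

    Brand intensities (MPs per 100 g) are uniform over
    ``brand_lambda_range`` and multiplied by a per-producer log-normal
    effect; per-can counts are Poisson at the subsample scale with
    additive Poisson background at ``blank_rate_per_petri``. Deterministic
    under a fixed ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    products: list[ProductRecord] = []
    observations: list[CanObservation] = []
    particles: list[ParticleRecord] = []
    brand_lambdas: dict[str, float] = {}
    producer_effects: dict[str, float] = {}

    mass_factor = config.subsample_mass_g / 100.0
    for p_idx in range(config.n_producers):
        producer = _producer_letters(p_idx)
        effect = (
            rng.normal(0.0, config.producer_effect_sd)
            if config.producer_effect_sd > 0
            else 0.0
        )
        producer_effects[producer] = float(np.exp(effect))
        for b_idx in range(config.brands_per_producer):
            code = f"{producer}-B{b_idx + 1}-1"
            lam = float(
                rng.uniform(*config.brand_lambda_range)
                * producer_effects[producer]
            )
            brand_lambdas[code] = lam
            products.append(
                ProductRecord(
                    code=code,
                    producer=producer,
                    species=str(rng.choice(_SPECIES)),
                    additive_oil=_OILS[rng.integers(len(_OILS))],
                    other_additives=("Salt",)
                    if rng.random() < 0.5
                    else ("Water", "Salt"),
                    product_weight_g=float(rng.choice(_WEIGHTS)),
                    package_type=str(rng.choice(_PACKAGES)),
                )
            )
            for rep in range(1, config.replicates_per_brand + 1):
                sample_count = int(rng.poisson(lam * mass_factor))
                background = (
                    int(rng.poisson(config.blank_rate_per_petri))
                    if config.blank_rate_per_petri > 0
                    else 0
                )
                count = sample_count + background
                observations.append(
                    CanObservation(
                        code=code,
                        replicate=rep,
                        subsample_mass_g=config.subsample_mass_g,
                        particle_count=count,
                    )
                )
                particles.extend(
                    _draw_particles(rng, config, f"{code}:r{rep}", count)
                )

    particles = _assign_verification(rng, config, particles)
    truth = {
        "config": config,
        "brand_lambdas": brand_lambdas,
        "producer_effects": producer_effects,
        "expected_raw_per_can_per100g": {
            code: lam + config.blank_rate_per_petri / mass_factor
            for code, lam in brand_lambdas.items()
        },
    }
    return SurveyTables(products, observations, particles, truth)


def _producer_letters(index: int) -> str:
    letters = ""
    index += 1
    while index:
        index, rem = divmod(index - 1, 26)
        letters = chr(65 + rem) + letters
    return letters


def _draw_particles(rng, config, sample_id, count):
    if count == 0:
        return []
    shapes = _draw_categorical(rng, config.shape_probs, count)
    colors = _draw_categorical(rng, config.color_probs, count)
    records = []
    for shape, color in zip(shapes, colors):
        shape = str(shape)
        size = float(_draw_sizes(rng, shape, 1)[0])
        records.append(
            ParticleRecord(
                sample_id=sample_id, shape=shape, color=str(color),
                size_mm=size,
            )
        )
    return records


def _assign_verification(rng, config, particles):
    """Mark a random analysis subsample; true MPs in it become verified.

    The latent true-MP label is independent of shape by default; polymer
    identity (shape-conditional, matching the printed composition blocks)
    is revealed only for verified particles.
    """
    n = len(particles)
    if n == 0:
        return particles
    analyzed = rng.random(n) < config.analysis_fraction
    is_mp = rng.random(n) < config.verification_true_mp_prob
    out = []
    for particle, a, mp in zip(particles, analyzed, is_mp):
        if not a:
            out.append(particle)
            continue
        if mp:
            counts = (
                _FIBER_POLYMER_COUNTS
                if particle.shape == "fiber"
                else _FRAGMENT_POLYMER_COUNTS
            )
            total = sum(counts.values())
            polymer = str(
                _draw_categorical(
                    rng, {k: v / total for k, v in counts.items()}, 1
                )[0]
            )
            out.append(
                ParticleRecord(
                    sample_id=particle.sample_id,
                    shape=particle.shape,
                    color=particle.color,
                    size_mm=particle.size_mm,
                    polymer=polymer,
                    verified="verified_mp",
                )
            )
        else:
            out.append(
                ParticleRecord(
                    sample_id=particle.sample_id,
                    shape=particle.shape,
                    color=particle.color,
                    size_mm=particle.size_mm,
                    polymer="unknown",
                    verified="rejected",
                )
            )
    return out


def generate_blanks(
    config: GeneratorConfig, n_units: int | None = None
) -> pd.DataFrame:
    """Poisson background counts for the procedural control dishes."""
    rng = np.random.default_rng(config.seed + 1)
    n = config.n_blank_units if n_units is None else n_units
    counts = (
        rng.poisson(config.blank_rate_per_petri, size=n)
        if config.blank_rate_per_petri > 0
        else np.zeros(n, dtype=int)
    )
    return pd.DataFrame(
        {"dish_id": [f"blank-{i + 1}" for i in range(n)],
         "particle_count": counts.astype(int)}
    )
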