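"""Shape, color, polymer and size-class composition summaries.

Includes an integer-count reconstruction: published composition tables
print percentages rounded to two decimals, and because the underlying
totals are small the integer counts behind them can be recovered exactly
by searching for the smallest denominator consistent with every printed
share.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

from .types import ParticleRecord, ValidationError
from .util import round_half_up

__all__ = [
    "SIZE_CLASSES",
    "NATURAL_POLYMERS",
    "SizeClass",
    "CompositionSummary",
    "classify_size",
    "summarize",
    "reconstruct_counts",
    "combined_polymer_shares",
]


@dataclass(frozen=True)
class SizeClass:
    """A plastic-debris size class with (lower, upper] boundaries in mm."""

    label: str
    lower_mm: float
    upper_mm: float


#: Debris size scheme: nanoplastic < 1 um <= microplastic <= 5 mm <
#: mesoplastic <= 20 mm < macroplastic <= 100 mm < megaplastic. Classes are
#: upper-inclusive, so exactly 5 mm is still a microplastic.
SIZE_CLASSES = (
    SizeClass("nanoplastic", 0.0, 0.001),
    SizeClass("microplastic", 0.001, 5.0),
    SizeClass("mesoplastic", 5.0, 20.0),
    SizeClass("macroplastic", 20.0, 100.0),
    SizeClass("megaplastic", 100.0, float("inf")),
)

#: Biogenic polymers reported alongside plastics in spectroscopy tables;
#: they are flagged non-plastic but retained in composition summaries.
NATURAL_POLYMERS = frozenset({"cellulose", "chitin"})


@dataclass(frozen=True)
class CompositionSummary:
    """Percentage shares over one dimension of particle attributes."""

    dimension: str
    shares: Mapping[str, float]
    n: int

    def __post_init__(self) -> None:
        total = sum(self.shares.values())
        if self.shares and abs(total - 100.0) > 0.1:
            raise ValidationError(
                f"{self.dimension} shares sum to {total}, not 100"
            )
        if any(v < 0 for v in self.shares.values()):
            raise ValidationError(f"{self.dimension}: negative share")


def classify_size(size_mm: float) -> str:
    """Assign a positive Feret diameter (mm) to its debris size class.

    The class partition is upper-inclusive: the nanoplastic/microplastic
    boundary sits below 1 um, and a particle of exactly 5 mm counts as
    microplastic while 5.89 mm (the largest fiber observed in the reference
    survey) is mesoplastic.
    """
    if not size_mm > 0:
        raise ValidationError(f"size must be positive, got {size_mm}")
    for cls in SIZE_CLASSES:
        if size_mm <= cls.upper_mm:
            return cls.label
    raise AssertionError("unreachable: classes cover (0, inf)")


def _dimension_value(particle: ParticleRecord, dimension: str) -> str | None:
    if dimension == "shape":
        return particle.shape
    if dimension == "color":
        return particle.color
    if dimension == "size_class":
        return classify_size(particle.size_mm)
    if dimension == "polymer":
        # Polymer identity only exists for spectroscopically confirmed
        # particles; rejected and unanalyzed particles have no defined value.
        if particle.verified != "verified_mp" or particle.polymer == "unknown":
            return None
        return particle.polymer
    raise ValueError(f"unknown composition dimension {dimension!r}")


def summarize(
    particles: Sequence[ParticleRecord], dimension: str
) -> CompositionSummary:
    """Percentage of particles per label along one attribute dimension.

    Particles without a defined value for the dimension (e.g. unanalyzed
    particles when summarizing polymers) are excluded from the denominator.
    """
    if not particles:
        raise ValidationError("cannot summarize an empty particle list")
    values = [
        v
        for p in particles
        if (v := _dimension_value(p, dimension)) is not None
    ]
    if not values:
        raise ValidationError(
            f"no particle has a defined {dimension!r} value"
        )
    counts = Counter(values)
    n = len(values)
    return CompositionSummary(
        dimension=dimension,
        shares={label: 100.0 * k / n for label, k in counts.items()},
        n=n,
    )


def reconstruct_counts(
    shares: Mapping[str, float], total_hint: int | None = None
) -> dict[str, int]:
    """Recover integer counts behind printed 2-decimal percentages.

    Finds the smallest total ``n`` (at most ``total_hint`` when given, else
    1000) such that each share corresponds to an integer count ``k`` with
    ``round(100 k / n, 2)`` equal to the printed value and the counts sum
    to ``n``. Raises with the nearest misses when no total is consistent.
    """
    total = sum(shares.values())
    if abs(total - 100.0) > 0.5:
        raise ValidationError(f"shares sum to {total}, not ~100")
    limit = total_hint if total_hint is not None else 1000
    near_misses: list[tuple[int, float]] = []
    for n in range(1, limit + 1):
        counts: dict[str, int] = {}
        deviation = 0.0
        for label, pct in shares.items():
            k = round(pct * n / 100.0)
            if k < 1 and pct > 0:
                k = 1
            err = abs(round_half_up(100.0 * k / n) - round_half_up(pct))
            deviation = max(deviation, err)
            counts[label] = k
        if deviation < 0.005 and sum(counts.values()) == n:
            return counts
        near_misses.append((n, deviation))
    near_misses.sort(key=lambda item: item[1])
    detail = ", ".join(f"n={n} (off by {d:.2f})" for n, d in near_misses[:3])
    raise ValidationError(
        f"no integer counts up to n={limit} reproduce the printed shares; "
        f"nearest: {detail}"
    )


def combined_polymer_shares(
    fiber_counts: Mapping[str, int],
    fragment_counts: Mapping[str, int],
    expected_total: int | None = None,
) -> CompositionSummary:
    """Merge per-shape polymer counts into overall percentage shares.

    Typically fed the outputs of :func:`reconstruct_counts` for the fiber
    and fragment blocks of a printed composition table; ``expected_total``
    guards against reconstructions inconsistent with the published number
    of verified particles.
    """
    merged: Counter[str] = Counter(fiber_counts)
    merged.update(fragment_counts)
    n = sum(merged.values())
    if expected_total is not None and n != expected_total:
        raise ValidationError(
            f"combined counts total {n}, expected {expected_total}"
        )
    return CompositionSummary(
        dimension="polymer",
        shares={label: 100.0 * k / n for label, k in merged.items()},
        n=n,
    )
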