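"""Inferential statistics on replicate-level abundances.

Per-can concentrations are counts, so they are right-skewed; the analysis
log-transforms them (log(x+1), admitting zero counts) before normality
checks and one-way ANOVA across grouping factors (producer, package type,
oil type, water usage, species). A Pearson correlation relates product
weight to abundance.

Normality is checked two ways: Shapiro-Wilk, and the Lilliefors variant of
the Kolmogorov-Smirnov test (the plain KS test is miscalibrated when the
normal parameters are estimated from the same data).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors

from .types import ValidationError

__all__ = [
    "GroupedValues",
    "NormalityResult",
    "AnovaResult",
    "log_transform",
    "normality_tests",
    "one_way_anova",
    "pearson_weight_abundance",
]

GROUPING_FACTORS = (
    "producer",
    "package_type",
    "oil_type",
    "water_usage",
    "species",
)


@dataclass(frozen=True)
class GroupedValues:
    """Per-can abundances grouped by one survey factor."""

    factor: str
    groups: Mapping[str, Sequence[float]]

    def __post_init__(self) -> None:
        if len(self.groups) < 2:
            raise ValidationError(
                f"{self.factor}: at least two groups required"
            )
        for label, values in self.groups.items():
            arr = np.asarray(values, dtype=float)
            if arr.size == 0 or not np.all(np.isfinite(arr)):
                raise ValidationError(
                    f"{self.factor}/{label}: empty or non-finite values"
                )


@dataclass(frozen=True)
class NormalityResult:
    ks_statistic: float
    ks_pvalue: float
    shapiro_statistic: float
    shapiro_pvalue: float
    non_normal: bool
    alpha: float = 0.05


@dataclass(frozen=True)
class AnovaResult:
    factor: str
    f_statistic: float
    pvalue: float
    df_between: int
    df_within: int
    n_groups_used: int
    dropped_groups: tuple[str, ...] = ()

    @property
    def significant(self) -> bool:
        return self.pvalue < 0.05


def log_transform(values: Sequence[float]) -> np.ndarray:
    """log(x + 1) transform; order-preserving and defined at zero counts."""
    arr = np.asarray(values, dtype=float)
    if np.any(arr < 0):
        raise ValidationError("log transform requires non-negative values")
    return np.log1p(arr)


def normality_tests(
    values: Sequence[float], alpha: float = 0.05
) -> NormalityResult:
    """Kolmogorov-Smirnov (Lilliefors) and Shapiro-Wilk normality checks.

    Flags the sample non-normal when either test rejects at ``alpha``.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 3:
        raise ValidationError("normality tests require n >= 3")
    if np.ptp(arr) == 0:
        raise ValidationError(
            "normality tests undefined for a constant sample"
        )
    ks_stat, ks_p = lilliefors(arr, dist="norm")
    with warnings.catch_warnings():
        # Shapiro-Wilk p-values above n=5000 are approximate; fine here.
        warnings.simplefilter("ignore")
        sw_stat, sw_p = sps.shapiro(arr)
    return NormalityResult(
        ks_statistic=float(ks_stat),
        ks_pvalue=float(ks_p),
        shapiro_statistic=float(sw_stat),
        shapiro_pvalue=float(sw_p),
        non_normal=bool(ks_p < alpha or sw_p < alpha),
        alpha=alpha,
    )


def one_way_anova(
    grouped: GroupedValues, *, transform: bool = True
) -> AnovaResult:
    """Classical one-way ANOVA across the factor's groups.

    Values are log(x+1)-transformed by default. Groups with a single
    observation carry no within-group information and are dropped with a
    warning; at least two usable groups must remain.
    """
    usable: dict[str, np.ndarray] = {}
    dropped: list[str] = []
    for label, values in grouped.groups.items():
        arr = np.asarray(values, dtype=float)
        if arr.size < 2:
            dropped.append(label)
        else:
            usable[label] = log_transform(arr) if transform else arr
    if dropped:
        warnings.warn(
            f"{grouped.factor}: dropping single-observation groups "
            f"{sorted(dropped)}",
            UserWarning,
            stacklevel=2,
        )
    if len(usable) < 2:
        raise ValidationError(
            f"{grouped.factor}: fewer than two usable groups for ANOVA"
        )
    samples = list(usable.values())
    f_stat, pvalue = sps.f_oneway(*samples)
    n_total = sum(len(s) for s in samples)
    return AnovaResult(
        factor=grouped.factor,
        f_statistic=float(f_stat),
        pvalue=float(pvalue),
        df_between=len(samples) - 1,
        df_within=n_total - len(samples),
        n_groups_used=len(samples),
        dropped_groups=tuple(sorted(dropped)),
    )


def pearson_weight_abundance(
    weights: Sequence[float], abundances: Sequence[float]
) -> tuple[float, float]:
    """Pearson correlation between sample weight and MP abundance."""
    w = np.asarray(weights, dtype=float)
    a = np.asarray(abundances, dtype=float)
    if w.shape != a.shape:
        raise ValidationError("weight and abundance vectors differ in length")
    if w.size < 3:
        raise ValidationError("Pearson correlation requires n >= 3")
    if np.ptp(w) == 0 or np.ptp(a) == 0:
        raise ValidationError(
            "Pearson correlation undefined for zero-variance input"
        )
    result = sps.pearsonr(w, a)
    return float(result.statistic), float(result.pvalue)
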