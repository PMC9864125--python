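"""CSV readers/writers and packaged reference tables.

Interchange schemas (UTF-8, "." decimal separator):

* ``products.csv`` — code, party_no, species, additive_oil, other_additives,
  product_weight_g, package_type
* ``observations.csv`` — code, replicate, subsample_mass_g, particle_count
* ``particles.csv`` — sample_id, shape, color, size_mm, polymer, verified
* ``concentrations.csv`` — code, raw_mean_per100g, corrected_mean_per100g,
  std_error_per100g

The packaged reference tables transcribe the printed survey of 33 Turkish
canned-fish products: product metadata, per-brand concentrations with the
six intake columns, and polymer shares by particle shape.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .types import (
    BrandConcentration,
    CanObservation,
    ParticleRecord,
    ProductRecord,
    ValidationError,
)

__all__ = [
    "normalize_package_label",
    "read_product_table",
    "read_observation_table",
    "read_particle_table",
    "read_concentration_table",
    "write_product_table",
    "write_observation_table",
    "write_particle_table",
    "write_concentration_table",
    "load_reference_products",
    "load_reference_concentrations",
    "load_reference_intake_table",
    "load_reference_polymer_shares",
    "load_constants",
    "is_tuna_type",
]

# Normalization of printed packaging labels to the closed vocabulary; the
# source table spells aluminium both ways.
_PACKAGE_LABELS = {
    "can": "can",
    "can (bpa free)": "can_bpa_free",
    "can (bpa-free)": "can_bpa_free",
    "aluminum": "aluminum",
    "aluminium": "aluminum",
    "c/pp": "composite_cpp",
    "glass": "glass",
    # already-normalized labels round-trip unchanged
    "can_bpa_free": "can_bpa_free",
    "composite_cpp": "composite_cpp",
}

#: Species labels tallied as "tuna" in the printed product summary. Skipjack
#: is marketed (and was evidently counted) as tuna; yellowfin rows carry
#: their own label and are not part of the printed n = 23 tally.
TUNA_TYPE_SPECIES = frozenset({"tuna", "skipjack"})


def normalize_package_label(label: str) -> str:
    """Map a printed packaging label onto the closed vocabulary."""
    try:
        return _PACKAGE_LABELS[label.strip().lower()]
    except KeyError:
        raise ValidationError(f"unknown package label {label!r}") from None


def is_tuna_type(species: str) -> bool:
    return species.strip().lower() in TUNA_TYPE_SPECIES


def _read_csv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValidationError(
            f"{path.name}: missing required columns {missing}"
        )
    return frame


def _number(raw: str, *, row: str, column: str) -> float:
    try:
        return float(raw)
    except ValueError:
        raise ValidationError(
            f"row {row!r}, column {column!r}: cannot parse number {raw!r}"
        ) from None


def _split_additives(raw: str) -> tuple[str, ...]:
    if not raw or raw.strip().lower() in {"none", ""}:
        return ()
    return tuple(part.strip() for part in raw.split(",") if part.strip())


def read_product_table(path: str | Path) -> list[ProductRecord]:
    """Read product metadata, normalizing the packaging vocabulary."""
    frame = _read_csv(
        path,
        ["code", "species", "additive_oil", "product_weight_g", "package_type"],
    )
    records: list[ProductRecord] = []
    seen: set[str] = set()
    for _, row in frame.iterrows():
        code = row["code"].strip()
        if code in seen:
            raise ValidationError(f"duplicate product code {code!r}")
        seen.add(code)
        raw_label = row["package_type"]
        try:
            package = normalize_package_label(raw_label)
        except ValidationError as exc:
            raise ValidationError(f"row {code!r}: {exc}") from None
        oil = row["additive_oil"].strip()
        records.append(
            ProductRecord(
                code=code,
                producer=code.split("-", 1)[0],
                species=row["species"].strip(),
                additive_oil=None if oil.lower() in {"", "none"} else oil,
                other_additives=_split_additives(
                    row.get("other_additives", "")
                ),
                product_weight_g=_number(
                    row["product_weight_g"], row=code, column="product_weight_g"
                ),
                package_type=package,
                party_no=row.get("party_no", "").strip(),
                package_label_raw=raw_label.strip(),
            )
        )
    return records


def read_observation_table(path: str | Path) -> list[CanObservation]:
    """Read per-can particle counts (one row per replicate can)."""
    frame = _read_csv(
        path, ["code", "replicate", "subsample_mass_g", "particle_count"]
    )
    records = []
    for _, row in frame.iterrows():
        code = row["code"].strip()
        records.append(
            CanObservation(
                code=code,
                replicate=int(
                    _number(row["replicate"], row=code, column="replicate")
                ),
                subsample_mass_g=_number(
                    row["subsample_mass_g"], row=code, column="subsample_mass_g"
                ),
                particle_count=int(
                    _number(
                        row["particle_count"], row=code, column="particle_count"
                    )
                ),
            )
        )
    _check_replicates(records)
    return records


def _check_replicates(records: Iterable[CanObservation]) -> None:
    by_code: dict[str, list[int]] = {}
    for rec in records:
        by_code.setdefault(rec.code, []).append(rec.replicate)
    for code, reps in by_code.items():
        if sorted(reps) != list(range(1, len(reps) + 1)):
            raise ValidationError(
                f"{code}: replicates must be consecutive from 1, got {reps}"
            )


def read_particle_table(path: str | Path) -> list[ParticleRecord]:
    frame = _read_csv(
        path, ["sample_id", "shape", "color", "size_mm", "polymer", "verified"]
    )
    return [
        ParticleRecord(
            sample_id=row["sample_id"].strip(),
            shape=row["shape"].strip().lower(),
            color=row["color"].strip().lower(),
            size_mm=_number(
                row["size_mm"], row=row["sample_id"], column="size_mm"
            ),
            polymer=row["polymer"].strip() or "unknown",
            verified=row["verified"].strip().lower(),
        )
        for _, row in frame.iterrows()
    ]


def read_concentration_table(path: str | Path) -> list[BrandConcentration]:
    frame = _read_csv(path, ["code", "raw_mean_per100g"])
    records = []
    for _, row in frame.iterrows():
        code = row["code"].strip()

        def optional(column: str) -> float | None:
            value = row.get(column, "")
            return (
                _number(value, row=code, column=column)
                if str(value).strip()
                else None
            )

        n_reps = row.get("n_replicates", "")
        records.append(
            BrandConcentration(
                code=code,
                raw_mean_per100g=_number(
                    row["raw_mean_per100g"], row=code, column="raw_mean_per100g"
                ),
                corrected_mean_per100g=optional("corrected_mean_per100g"),
                std_error_per100g=optional("std_error_per100g"),
                n_replicates=int(float(n_reps)) if str(n_reps).strip() else None,
            )
        )
    return records


def write_product_table(
    records: Sequence[ProductRecord], path: str | Path
) -> None:
    pd.DataFrame(
        {
            "code": [r.code for r in records],
            "party_no": [r.party_no for r in records],
            "species": [r.species for r in records],
            "additive_oil": [r.additive_oil or "None" for r in records],
            "other_additives": [
                ", ".join(r.other_additives) for r in records
            ],
            "product_weight_g": [r.product_weight_g for r in records],
            "package_type": [r.package_label_raw or r.package_type
                             for r in records],
        }
    ).to_csv(path, index=False)


def write_observation_table(
    records: Sequence[CanObservation], path: str | Path
) -> None:
    pd.DataFrame(
        {
            "code": [r.code for r in records],
            "replicate": [r.replicate for r in records],
            "subsample_mass_g": [r.subsample_mass_g for r in records],
            "particle_count": [r.particle_count for r in records],
        }
    ).to_csv(path, index=False)


def write_particle_table(
    records: Sequence[ParticleRecord], path: str | Path
) -> None:
    pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "shape": [r.shape for r in records],
            "color": [r.color for r in records],
            "size_mm": [r.size_mm for r in records],
            "polymer": [r.polymer for r in records],
            "verified": [r.verified for r in records],
        }
    ).to_csv(path, index=False)


def write_concentration_table(
    records: Sequence[BrandConcentration], path: str | Path
) -> None:
    def fmt(value: float | None) -> str:
        return "" if value is None else repr(float(value))

    pd.DataFrame(
        {
            "code": [r.code for r in records],
            "raw_mean_per100g": [repr(float(r.raw_mean_per100g))
                                 for r in records],
            "corrected_mean_per100g": [
                fmt(r.corrected_mean_per100g) for r in records
            ],
            "std_error_per100g": [fmt(r.std_error_per100g) for r in records],
            "n_replicates": [
                "" if r.n_replicates is None else r.n_replicates
                for r in records
            ],
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Packaged reference tables


def _data_path(name: str) -> Path:
    return Path(resources.files("canmp").joinpath("data", name))


def load_reference_products() -> list[ProductRecord]:
    """The 33 surveyed products with printed metadata."""
    return read_product_table(_data_path("products.csv"))


def load_reference_concentrations(
    include_grand: bool = False,
) -> list[BrandConcentration]:
    """Printed per-brand raw/corrected concentrations (MPs per 100 g)."""
    records = read_concentration_table(_data_path("concentrations.csv"))
    if not include_grand:
        records = [r for r in records if r.code != "grand"]
    return records


def load_reference_intake_table() -> pd.DataFrame:
    """The full printed concentration/intake table, grand row included."""
    frame = pd.read_csv(_data_path("concentrations.csv"))
    return frame.set_index("code")


def load_reference_polymer_shares() -> pd.DataFrame:
    """Printed polymer shares (%) by particle shape, plus the total block."""
    return pd.read_csv(_data_path("polymer_shares.csv"))


def load_constants() -> dict:
    """Scalar study constants (correction, consumption, Monte Carlo)."""
    with open(_data_path("constants.yaml"), encoding="utf-8") as handle:
        return yaml.safe_load(handle)
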