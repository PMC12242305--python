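"""Deterministic δ13C corrections.

Two corrections make bone-collagen δ13C comparable across specimens and eras:

1. **Lipid normalization.**  Lipids are depleted in 13C relative to protein;
   collagen with C:N above ~3.3 carries a lipid bias.  The arithmetic
   normalization ``δ13C_normalized = δ13C_raw − 3.32 + 0.99 × C:N`` estimates
   the lipid-free value and is applied to *every* specimen, flagged or not.

2. **Oceanic Suess correction.**  Anthropogenic CO2 has progressively depleted
   δ13C of surface-ocean dissolved inorganic carbon since ~1850.  A specimen
   collected in year ``y`` in a region with per-year decline constant ``a``
   (≤ 0 ‰) is corrected by the factor ``a × exp((y − 1850) × 0.027)``; the
   (negative) factor is subtracted, shifting values toward zero so that
   specimens of all eras are referenced to a common pre-industrial baseline.
   The regional ``a`` is the accumulated surface-water Suess effect divided by
   the 140-year span from 1850 to 1990.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .data_model import (
    RegionParams,
    SourceDistribution,
    SpecimenRecord,
    _round_half_away,
    resolve_region_code,
    resolve_year,
)

__all__ = [
    "SuessConstants",
    "LIPID_INTERCEPT",
    "LIPID_SLOPE",
    "normalize_lipid",
    "suess_factor",
    "apply_suess",
    "derive_a_value",
    "mean_total_cse",
    "correct_records",
    "correct_sources_to_era",
]

#: Lipid-normalization constants (protein-lipid mass-balance fit).
LIPID_INTERCEPT = -3.32
LIPID_SLOPE = 0.99


@dataclass(frozen=True)
class SuessConstants:
    """Constants of the exponential Suess-effect model.

    ``onset_year`` anchors the industrial era (1850); ``exponent_rate`` is the
    fitted exponential growth rate of the global surface-ocean δ13C decline
    (0.027 yr⁻¹); ``normalization_span`` is the 1850–1990 span (140 yr) used
    to convert an accumulated regional Suess effect into a per-year a-value.
    """

    onset_year: int = 1850
    exponent_rate: float = 0.027
    normalization_span: int = 140

    def __post_init__(self) -> None:
        if not self.exponent_rate > 0:
            raise ValueError("exponent_rate must be positive")
        if self.normalization_span <= 0:
            raise ValueError("normalization_span must be positive")


DEFAULT_CONSTANTS = SuessConstants()


def normalize_lipid(d13c_raw: float, cn_ratio: float) -> float:
    """Lipid-normalize a raw δ13C value given the specimen's C:N ratio.

    ``δ13C_normalized = δ13C_raw − 3.32 + 0.99 × C:N``; at C:N ≈ 3.354 the
    correction is zero, above it the value shifts up (toward less negative).
    """
    if not (math.isfinite(d13c_raw) and math.isfinite(cn_ratio)):
        raise ValueError("non-finite input to lipid normalization")
    if cn_ratio <= 0:
        raise ValueError("C:N ratio must be positive")
    return d13c_raw + LIPID_INTERCEPT + LIPID_SLOPE * cn_ratio


def suess_factor(
    a_value: float, year: int, constants: SuessConstants = DEFAULT_CONSTANTS
) -> float:
    """Suess-effect correction factor (‰, ≤ 0) for one region and year.

    Zero before the industrial onset; ``a × exp((year − onset) × rate)``
    afterwards, so the magnitude grows exponentially toward the present.
    """
    if a_value > 0:
        raise ValueError("a-value must be ≤ 0 (Suess effect is a depletion)")
    if year > 2100:
        raise ValueError(f"implausible collection year {year}")
    if year < constants.onset_year:
        return 0.0
    return a_value * math.exp((year - constants.onset_year) * constants.exponent_rate)


def apply_suess(
    record: SpecimenRecord,
    region: RegionParams,
    constants: SuessConstants = DEFAULT_CONSTANTS,
) -> SpecimenRecord:
    """Return a copy of ``record`` with the Suess-corrected δ13C filled in.

    The (negative) factor is subtracted from the normalized value, so
    corrected values move toward zero; adding the factor back recovers the
    normalized value exactly.
    """
    if record.d13c_normalized is None:
        raise ValueError(f"{record.specimen_id}: lipid normalization has not run")
    year = resolve_year(record.year_spec)
    factor = suess_factor(region.a_value, year, constants)
    return replace(record, d13c_se=record.d13c_normalized - factor)


def derive_a_value(
    total_cse: float, constants: SuessConstants = DEFAULT_CONSTANTS
) -> float:
    """Per-year δ13C decline constant from an accumulated regional Suess effect.

    ``a = total_cse / 140`` rounded half-away-from-zero to 4 decimal places.
    """
    if total_cse > 0:
        raise ValueError("accumulated Suess effect must be ≤ 0")
    return _round_half_away(total_cse / constants.normalization_span, 4)


def mean_total_cse(point_estimates: Sequence[float]) -> float:
    """Arithmetic mean of surface-water accumulated-Suess point estimates."""
    if len(point_estimates) == 0:
        raise ValueError("no point estimates supplied")
    return float(sum(point_estimates) / len(point_estimates))


# --------------------------------------------------------------------------
# pipeline helpers


def correct_records(
    records: Iterable[SpecimenRecord],
    regions: dict[str, RegionParams],
    constants: SuessConstants = DEFAULT_CONSTANTS,
    aliases: dict | None = None,
) -> list[SpecimenRecord]:
    """Lipid-normalize (where raw values exist) then Suess-correct records.

    Records that already carry ``d13c_normalized`` (e.g. the packaged
    reference table) skip the lipid step.
    """
    out = []
    for rec in records:
        if rec.d13c_normalized is None:
            if rec.d13c_raw is None or rec.cn_ratio is None:
                raise ValueError(
                    f"{rec.specimen_id}: need raw δ13C and C:N to normalize"
                )
            rec = replace(
                rec, d13c_normalized=normalize_lipid(rec.d13c_raw, rec.cn_ratio)
            )
        code = resolve_region_code(rec.region, aliases)
        try:
            region = regions[code]
        except KeyError:
            raise KeyError(
                f"{rec.specimen_id}: region code {code!r} not in "
                f"{sorted(regions)}"
            ) from None
        out.append(apply_suess(rec, region, constants))
    return out


def correct_sources_to_era(
    sources: Iterable[SourceDistribution],
    regions: dict[str, RegionParams],
    specimen_year: int,
    source_reference_year: int = 2005,
    constants: SuessConstants = DEFAULT_CONSTANTS,
    aliases: dict | None = None,
) -> list[SourceDistribution]:
    """Suess-correct modern prey-source δ13C back to a specimen's era.

    Modern sources are more 13C-depleted than the specimen-era ocean; the
    accumulated factor difference between the source collection year and the
    specimen year is subtracted from each source mean (a negative difference,
    so source δ13C shifts up toward the historical baseline).
    """
    out = []
    for src in sources:
        code = src.region_code or resolve_region_code(src.region_label, aliases)
        a = regions[code].a_value
        shift = suess_factor(a, source_reference_year, constants) - suess_factor(
            a, specimen_year, constants
        )
        out.append(
            SourceDistribution(
                source_id=src.source_id,
                region_label=src.region_label,
                n=src.n,
                mu_d13c=src.mu_d13c - shift,
                sd_d13c=src.sd_d13c,
                mu_d15n=src.mu_d15n,
                sd_d15n=src.sd_d15n,
                region_code=code,
                consumer=src.consumer,
            )
        )
    return out
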