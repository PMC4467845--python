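"""Estimated daily intake of metals from fish and TDI screening.

For each location the mean concentration of each metal over the detected
replicates is converted to an estimated daily intake per kg body weight,

    EDI = C_metal * W / m      [ug per kg body weight per day]

with C_metal the mean concentration (mg/kg dry weight), W the daily fish
consumption (g/day) and m the adult body mass (kg); mg/kg x g = ug makes
the units resolve without an explicit factor.  EDIs are then screened
against the tolerable-daily-intake registry.

Non-detects are excluded from location means by default (the convention
under which published survey averages reproduce); zero- and half-LOD
substitution are available as options.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._errors import ValidationError
from .reference import ExposureParams, TDIEntry

__all__ = [
    "MetalRecord",
    "EDIRow",
    "location_mean_concentration",
    "estimated_daily_intake",
    "tdi_screen",
    "edi_table",
]

#: Non-detect handling strategies for location means.
NONDETECT_STRATEGIES = ("exclude", "zero", "half_lod")


@dataclass(frozen=True)
class MetalRecord:
    """Concentration of one element in one replicate; None marks a non-detect."""

    sample_code: str
    location: str
    element: str
    concentration_mg_per_kg: float | None

    def __post_init__(self) -> None:
        c = self.concentration_mg_per_kg
        if c is not None and (not math.isfinite(c) or c < 0):
            raise ValidationError(
                f"{self.sample_code}/{self.element}: concentration must be >= 0, got {c}"
            )

    @property
    def detected(self) -> bool:
        return self.concentration_mg_per_kg is not None


@dataclass(frozen=True)
class EDIRow:
    """Estimated daily intake of one element at one location, with screening."""

    location: str
    element: str
    mean_concentration_mg_per_kg: float
    edi_ug_per_kg_day: float
    tdi_ug_per_kg_day: float | None = None
    ratio: float | None = None
    flag: str = "no_tdi"  # below_tdi | exceeds_tdi | no_tdi


def location_mean_concentration(
    records: Sequence[MetalRecord],
    nondetect: str = "exclude",
    detection_limit_mg_per_kg: float = 0.0002,
) -> float | None:
    """Mean concentration over the replicates of one location and element.

    Returns None when every replicate is a non-detect (no EDI is then
    computed).  ``nondetect`` chooses the censoring rule: "exclude"
    (default) drops non-detects, "zero" and "half_lod" substitute 0 and
    half the detection limit respectively.
    """
    if not records:
        raise ValidationError("no records given")
    if nondetect not in NONDETECT_STRATEGIES:
        raise ValidationError(
            f"unknown non-detect strategy {nondetect!r}; expected {NONDETECT_STRATEGIES}"
        )
    keys = {(r.location, r.element) for r in records}
    if len(keys) > 1:
        raise ValidationError(f"records mix locations/elements: {sorted(keys)}")
    values: list[float] = []
    for rec in records:
        if rec.detected:
            values.append(rec.concentration_mg_per_kg)  # type: ignore[arg-type]
        elif nondetect == "zero":
            values.append(0.0)
        elif nondetect == "half_lod":
            values.append(detection_limit_mg_per_kg / 2.0)
    if not values:
        return None
    return sum(values) / len(values)


def estimated_daily_intake(
    mean_concentration_mg_per_kg: float, params: ExposureParams
) -> float:
    """EDI in ug per kg body weight per day from a mean concentration."""
    if mean_concentration_mg_per_kg < 0:
        raise ValidationError(
            f"concentration must be >= 0, got {mean_concentration_mg_per_kg}"
        )
    if params.body_mass_kg <= 0:
        raise ValidationError(f"body mass must be > 0, got {params.body_mass_kg}")
    return mean_concentration_mg_per_kg * params.daily_food_mass_g / params.body_mass_kg


def tdi_screen(
    edi_rows: Iterable[EDIRow], registry: Iterable[TDIEntry] | Mapping[str, TDIEntry]
) -> list[EDIRow]:
    """Annotate EDI rows with the TDI, the EDI/TDI ratio and a flag.

    A ratio of exactly 1 is classified ``below_tdi`` (the boundary is
    inclusive); elements absent from the registry are flagged ``no_tdi``.
    """
    if isinstance(registry, Mapping):
        by_element = dict(registry)
    else:
        by_element = {e.element: e for e in registry}
    out = []
    for row in edi_rows:
        entry = by_element.get(row.element)
        if entry is None:
            out.append(
                EDIRow(
                    row.location,
                    row.element,
                    row.mean_concentration_mg_per_kg,
                    row.edi_ug_per_kg_day,
                    None,
                    None,
                    "no_tdi",
                )
            )
            continue
        ratio = row.edi_ug_per_kg_day / entry.tdi_ug_per_kg_day
        flag = "below_tdi" if ratio <= 1.0 else "exceeds_tdi"
        out.append(
            EDIRow(
                row.location,
                row.element,
                row.mean_concentration_mg_per_kg,
                row.edi_ug_per_kg_day,
                entry.tdi_ug_per_kg_day,
                ratio,
                flag,
            )
        )
    return out


def edi_table(
    records: Sequence[MetalRecord],
    params: ExposureParams,
    registry: Iterable[TDIEntry] | Mapping[str, TDIEntry] = (),
    nondetect: str = "exclude",
    elements: Sequence[str] | None = None,
) -> pd.DataFrame:
    """EDI/TDI screening table over all locations and elements present.

    Location/element pairs where every replicate is a non-detect are
    omitted (no intake estimate is possible).  ``elements`` restricts the
    table to a subset, preserving the given order.
    """
    grouped: dict[tuple[str, str], list[MetalRecord]] = {}
    for rec in records:
        grouped.setdefault((rec.location, rec.element), []).append(rec)

    rows: list[EDIRow] = []
    for (location, element), group in grouped.items():
        if elements is not None and element not in elements:
            continue
        mean = location_mean_concentration(group, nondetect=nondetect)
        if mean is None:
            continue
        edi = estimated_daily_intake(mean, params)
        rows.append(EDIRow(location, element, mean, edi))
    rows = tdi_screen(rows, registry)
    if elements is not None:
        order = {el: i for i, el in enumerate(elements)}
        rows.sort(key=lambda r: (order.get(r.element, len(order)), r.location))
    frame = pd.DataFrame(
        [
            {
                "location": r.location,
                "element": r.element,
                "mean_concentration_mg_per_kg": r.mean_concentration_mg_per_kg,
                "edi_ug_per_kg_day": r.edi_ug_per_kg_day,
                "tdi_ug_per_kg_day": r.tdi_ug_per_kg_day,
                "ratio": r.ratio,
                "flag": r.flag,
            }
            for r in rows
        ]
    )
    return frame
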