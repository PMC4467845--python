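"""Ingestion dose and lifetime cancer risk from radionuclide activities in fish.

The computation chain, per sample and per parent chain:

* daily intake          D_int = A_s * A_if / 365          [Bq/day]
* annual effective dose D_eff = A_s * A_if * D_cf * 1e6   [uSv/y]
* total effective dose          sum of D_eff over chains  [uSv/y]
* lifetime cancer risk  LCR   = D_int * 365 * A_ls * R_c  [dimensionless]

where A_s is the activity concentration (Bq/kg dry weight), A_if the
annual per-capita fish intake (kg/y), D_cf the ingestion dose conversion
factor (Sv/Bq), A_ls the reference lifespan (y) and R_c the mortality
risk coefficient (per Bq).  The annual radionuclide intake entering the
risk equation is D_int * 365 = A_s * A_if, so dose and risk are mutually
consistent by construction.

Water samples are carried through reports but excluded from the dose and
risk chain, which models the fish-consumption pathway only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._errors import ValidationError
from .reference import CHAINS, ExposureParams, ReferenceBundle
from .rounding import round_half_up, round_sig_figs
from .spectrometry import ActivityMeasurement

__all__ = [
    "SampleRecord",
    "daily_intake",
    "annual_effective_dose",
    "total_effective_dose",
    "lifetime_cancer_risk",
    "dose_risk_table",
    "aggregate",
    "dose_risk_report",
]


@dataclass(frozen=True)
class SampleRecord:
    """One measured replicate: a fish or water sample with its activities."""

    sample_code: str
    location: str
    matrix: str  # "fish" or "water"
    activities: Mapping[str, ActivityMeasurement] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.matrix not in ("fish", "water"):
            raise ValidationError(
                f"matrix must be 'fish' or 'water', got {self.matrix!r}"
            )
        for chain in self.activities:
            if chain not in CHAINS:
                raise ValidationError(
                    f"sample {self.sample_code}: unknown chain {chain!r}"
                )


def daily_intake(activity_bq_per_kg: float, params: ExposureParams) -> float:
    """Daily radionuclide intake (Bq/day) from the activity concentration.

    Equivalent to A_s * A_p * F_c / (M_p * 365) when the per-capita
    intake is derived from production statistics.
    """
    if activity_bq_per_kg < 0:
        raise ValidationError(f"activity must be >= 0, got {activity_bq_per_kg}")
    return activity_bq_per_kg * params.intake_kg_per_year / params.days_per_year


def annual_effective_dose(
    activity_bq_per_kg: float,
    params: ExposureParams,
    dose_coefficient_sv_per_bq: float,
) -> float:
    """Committed effective dose from one year's intake, in microsieverts."""
    if activity_bq_per_kg < 0:
        raise ValidationError(f"activity must be >= 0, got {activity_bq_per_kg}")
    if dose_coefficient_sv_per_bq <= 0:
        raise ValidationError(
            f"dose coefficient must be > 0, got {dose_coefficient_sv_per_bq}"
        )
    return activity_bq_per_kg * params.intake_kg_per_year * dose_coefficient_sv_per_bq * 1e6


def total_effective_dose(per_chain_doses: Mapping[str, float]) -> float:
    """Total committed dose: plain sum of the per-chain doses (uSv/y)."""
    if not per_chain_doses:
        raise ValidationError("no per-chain doses to total")
    return float(sum(per_chain_doses.values()))


def lifetime_cancer_risk(
    daily_intake_bq: float,
    params: ExposureParams,
    risk_coefficient_per_bq: float,
) -> float:
    """Lifetime mortality risk: annual intake x lifespan x risk coefficient."""
    if daily_intake_bq < 0:
        raise ValidationError(f"daily intake must be >= 0, got {daily_intake_bq}")
    if risk_coefficient_per_bq <= 0:
        raise ValidationError(
            f"risk coefficient must be > 0, got {risk_coefficient_per_bq}"
        )
    annual_intake_bq = daily_intake_bq * params.days_per_year
    return annual_intake_bq * params.lifespan_y * risk_coefficient_per_bq


def _chain_cols(prefix: str) -> list[str]:
    return [f"{prefix}_{chain}" for chain in CHAINS]


def dose_risk_table(
    records: Sequence[SampleRecord],
    bundle: ReferenceBundle,
) -> pd.DataFrame:
    """Per-sample daily intake, effective dose, total dose and LCR.

    Only fish samples enter the table; water records are ignored here.
    Columns: ``daily_intake_<chain>`` (Bq/d), ``effective_dose_<chain>``
    (uSv/y), ``total_effective_dose`` (uSv/y), ``lcr_<chain>``.
    """
    params = bundle.params
    rows = []
    for rec in records:
        if rec.matrix != "fish":
            continue
        if not rec.activities:
            raise ValidationError(
                f"fish sample {rec.sample_code} has no activities for the dose pipeline"
            )
        row: dict[str, object] = {"sample_code": rec.sample_code, "location": rec.location}
        doses: dict[str, float] = {}
        for chain, meas in rec.activities.items():
            if chain not in bundle.dose_coefficients_sv_per_bq:
                raise ValidationError(f"no dose coefficient for chain {chain!r}")
            if chain not in bundle.risk_coefficients_per_bq:
                raise ValidationError(f"no risk coefficient for chain {chain!r}")
            d_int = daily_intake(meas.value, params)
            d_eff = annual_effective_dose(
                meas.value, params, bundle.dose_coefficients_sv_per_bq[chain]
            )
            lcr = lifetime_cancer_risk(
                d_int, params, bundle.risk_coefficients_per_bq[chain]
            )
            row[f"daily_intake_{chain}"] = d_int
            row[f"effective_dose_{chain}"] = d_eff
            row[f"lcr_{chain}"] = lcr
            doses[chain] = d_eff
        row["total_effective_dose"] = total_effective_dose(doses)
        rows.append(row)
    if not rows:
        raise ValidationError("no fish samples in input")
    columns = (
        ["sample_code", "location"]
        + _chain_cols("daily_intake")
        + _chain_cols("effective_dose")
        + ["total_effective_dose"]
        + _chain_cols("lcr")
    )
    frame = pd.DataFrame(rows)
    return frame.reindex(columns=[c for c in columns if c in frame.columns])


#: Display precision of the printed survey tables: decimal places per
#: column kind ("sig" entries are significant figures).
TABLE_DISPLAY_PRECISION = {
    "daily_intake": 2,
    "effective_dose": 4,  # significant figures
    "total_effective_dose": 1,
    "lcr": 2,  # significant figures
}


def _display_round(frame: pd.DataFrame) -> pd.DataFrame:
    out = frame.copy()
    for col in out.columns:
        if col.startswith("daily_intake"):
            out[col] = out[col].map(lambda v: round_half_up(v, 2))
        elif col.startswith("effective_dose") or col == "total_effective_dose":
            # printed with 4 significant figures (1 d.p. above 100)
            out[col] = out[col].map(lambda v: round_sig_figs(v, 4))
        elif col.startswith("lcr"):
            out[col] = out[col].map(lambda v: round_sig_figs(v, 2))
    return out


def aggregate(
    frame: pd.DataFrame,
    by: str | None = "location",
    display_rounding: bool = False,
) -> pd.DataFrame:
    """Arithmetic means of every numeric column, per group or overall.

    With ``display_rounding=True`` the per-sample values are first
    rounded half-up to the printed table precision, mirroring how the
    summary rows of the published tables were computed from their
    displayed entries.  Uncertainty columns, when present, are averaged
    like any other column.
    """
    if frame.empty:
        raise ValidationError("cannot aggregate an empty table")
    numeric = frame.select_dtypes(include=[np.number]).columns
    work = _display_round(frame) if display_rounding else frame
    if by is None:
        return work[numeric].mean().to_frame().T
    if by not in frame.columns:
        raise ValidationError(f"grouping column {by!r} not present")
    grouped = work.groupby(by, sort=False)[list(numeric)].mean().reset_index()
    return grouped


def dose_risk_report(
    records: Sequence[SampleRecord],
    bundle: ReferenceBundle,
    display_rounding: bool = False,
) -> pd.DataFrame:
    """Dose/risk table with location-mean and overall-mean summary rows.

    The overall row is the mean over all fish samples.  Summary rows are
    labelled ``Mean (<location>)`` and ``Over all mean``.
    """
    table = dose_risk_table(records, bundle)
    loc_means = aggregate(table, by="location", display_rounding=display_rounding)
    loc_means.insert(0, "sample_code", "Mean (" + loc_means["location"] + ")")
    overall = aggregate(table, by=None, display_rounding=display_rounding)
    overall.insert(0, "location", "")
    overall.insert(0, "sample_code", "Over all mean")
    return pd.concat([table, loc_means, overall], ignore_index=True)
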