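"""CSV readers/writers, report assembly and pipeline orchestration.

Table schemas (comma-separated, UTF-8, "." decimal separator, empty cell
or "-" = missing; scientific notation accepted on read):

* activity table:   sample_code, location, matrix, nuclide,
                    activity_Bq_per_kg, uncertainty_Bq_per_kg
* metal table:      sample_code, location, element, concentration_mg_per_kg
* peak table:       sample_code, location, progeny_nuclide, energy_keV,
                    net_counts, net_counts_unc, background_counts,
                    live_time_s, sample_mass_kg
* efficiency table: energy_keV, efficiency, rel_unc
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from ._errors import SchemaError, ValidationError
from .dose import SampleRecord, dose_risk_report
from .metals import MetalRecord, edi_table
from .reference import CHAINS, ReferenceBundle, default_bundle
from .spectrometry import (
    ActivityMeasurement,
    EfficiencyCurve,
    EfficiencyPoint,
    PeakMeasurement,
    fit_efficiency,
    quantify_sample,
)
from .stats import oneway_anova, tukey_hsd

logger = logging.getLogger("seadose")

__all__ = [
    "read_activity_table",
    "write_activity_table",
    "read_metal_table",
    "write_metal_table",
    "read_peak_table",
    "read_efficiency_table",
    "records_from_frame",
    "frame_from_records",
    "RiskReport",
    "run_pipeline",
    "significance_report",
]

_ACTIVITY_COLUMNS = [
    "sample_code",
    "location",
    "matrix",
    "nuclide",
    "activity_Bq_per_kg",
    "uncertainty_Bq_per_kg",
]
_METAL_COLUMNS = ["sample_code", "location", "element", "concentration_mg_per_kg"]
_PEAK_COLUMNS = [
    "sample_code",
    "location",
    "progeny_nuclide",
    "energy_keV",
    "net_counts",
    "net_counts_unc",
    "background_counts",
    "live_time_s",
    "sample_mass_kg",
]
_EFFICIENCY_COLUMNS = ["energy_keV", "efficiency", "rel_unc"]


def _check_columns(frame: pd.DataFrame, expected: Sequence[str], path: object) -> None:
    missing = [c for c in expected if c not in frame.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing column(s) {missing}; expected columns {list(expected)}"
        )


def _missing(value: object) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and np.isnan(value):
        return True
    return isinstance(value, str) and value.strip() in ("", "-")


def records_from_frame(frame: pd.DataFrame, source: object = "<frame>") -> list[SampleRecord]:
    """Build sample records from a long-format activity table."""
    _check_columns(frame, _ACTIVITY_COLUMNS, source)
    records: dict[str, dict[str, Any]] = {}
    for idx, row in frame.iterrows():
        nuclide = str(row["nuclide"]).strip()
        if nuclide not in CHAINS:
            raise SchemaError(
                f"{source} row {idx}: unknown nuclide {nuclide!r}; expected one of {CHAINS}"
            )
        code = str(row["sample_code"]).strip()
        entry = records.setdefault(
            code,
            {
                "location": str(row["location"]).strip(),
                "matrix": str(row["matrix"]).strip(),
                "activities": {},
            },
        )
        if _missing(row["activity_Bq_per_kg"]):
            logger.warning(
                "sample %s: missing %s activity, measurement skipped", code, nuclide
            )
            continue
        value = float(row["activity_Bq_per_kg"])
        if value < 0:
            raise SchemaError(f"{source} row {idx}: negative activity {value}")
        unc = 0.0 if _missing(row["uncertainty_Bq_per_kg"]) else float(row["uncertainty_Bq_per_kg"])
        entry["activities"][nuclide] = ActivityMeasurement(
            parent_chain=nuclide, value=value, uncertainty=unc
        )
    return [
        SampleRecord(
            sample_code=code,
            location=entry["location"],
            matrix=entry["matrix"],
            activities=entry["activities"],
        )
        for code, entry in records.items()
    ]


def read_activity_table(path: str | Path) -> list[SampleRecord]:
    """Read a long-format activity CSV into sample records."""
    frame = pd.read_csv(
        path, dtype={"sample_code": str}, keep_default_na=True,
        float_precision="round_trip",
    )
    return records_from_frame(frame, source=path)


def frame_from_records(records: Sequence[SampleRecord]) -> pd.DataFrame:
    """Long-format activity table from sample records (lossless round trip)."""
    rows = []
    for rec in records:
        for chain in CHAINS:
            meas = rec.activities.get(chain)
            if meas is None:
                continue
            rows.append(
                {
                    "sample_code": rec.sample_code,
                    "location": rec.location,
                    "matrix": rec.matrix,
                    "nuclide": chain,
                    "activity_Bq_per_kg": meas.value,
                    "uncertainty_Bq_per_kg": meas.uncertainty,
                }
            )
    return pd.DataFrame(rows, columns=_ACTIVITY_COLUMNS)


def write_activity_table(records: Sequence[SampleRecord], path: str | Path) -> None:
    frame_from_records(records).to_csv(path, index=False, float_format="%.17g")


def read_metal_table(path: str | Path) -> list[MetalRecord]:
    """Read a metal concentration CSV; empty cells and '-' are non-detects."""
    frame = pd.read_csv(
        path, dtype={"sample_code": str}, keep_default_na=True,
        float_precision="round_trip",
    )
    _check_columns(frame, _METAL_COLUMNS, path)
    records = []
    for idx, row in frame.iterrows():
        raw = row["concentration_mg_per_kg"]
        conc = None if _missing(raw) else float(raw)
        if conc is not None and conc < 0:
            raise SchemaError(f"{path} row {idx}: negative concentration {conc}")
        records.append(
            MetalRecord(
                sample_code=str(row["sample_code"]).strip(),
                location=str(row["location"]).strip(),
                element=str(row["element"]).strip(),
                concentration_mg_per_kg=conc,
            )
        )
    return records


def write_metal_table(records: Sequence[MetalRecord], path: str | Path) -> None:
    frame = pd.DataFrame(
        [
            {
                "sample_code": r.sample_code,
                "location": r.location,
                "element": r.element,
                "concentration_mg_per_kg": r.concentration_mg_per_kg,
            }
            for r in records
        ],
        columns=_METAL_COLUMNS,
    )
    frame.to_csv(path, index=False, float_format="%.17g")


def read_peak_table(
    path: str | Path, bundle: ReferenceBundle | None = None
) -> list[PeakMeasurement]:
    """Read a peak-area CSV, matching each row to a registered gamma line.

    Lines are matched by progeny nuclide and energy (within 1 keV).
    """
    if bundle is None:
        bundle = default_bundle()
    frame = pd.read_csv(path, dtype={"sample_code": str}, float_precision="round_trip")
    _check_columns(frame, _PEAK_COLUMNS, path)
    peaks = []
    for idx, row in frame.iterrows():
        progeny = str(row["progeny_nuclide"]).strip()
        energy = float(row["energy_keV"])
        matches = [
            ln
            for ln in bundle.gamma_lines
            if ln.progeny_nuclide == progeny and abs(ln.energy_kev - energy) < 1.0
        ]
        if not matches:
            raise SchemaError(
                f"{path} row {idx}: no registered gamma line for {progeny!r} at {energy} keV"
            )
        peaks.append(
            PeakMeasurement(
                line=matches[0],
                net_counts=float(row["net_counts"]),
                net_counts_uncertainty=float(row["net_counts_unc"]),
                background_counts=float(row["background_counts"]),
                live_time_s=float(row["live_time_s"]),
                sample_mass_kg=float(row["sample_mass_kg"]),
                sample_code=str(row["sample_code"]).strip(),
            )
        )
    return peaks


def read_efficiency_table(path: str | Path) -> list[EfficiencyPoint]:
    frame = pd.read_csv(path)
    _check_columns(frame, _EFFICIENCY_COLUMNS, path)
    return [
        EfficiencyPoint(
            energy_kev=float(row["energy_keV"]),
            efficiency=float(row["efficiency"]),
            rel_uncertainty=0.0 if _missing(row["rel_unc"]) else float(row["rel_unc"]),
        )
        for _, row in frame.iterrows()
    ]


def peaks_to_records(
    peaks: Sequence[PeakMeasurement],
    curve: EfficiencyCurve,
    bundle: ReferenceBundle | None = None,
    locations: Mapping[str, str] | None = None,
    allow_extrapolation: bool = False,
) -> tuple[list[SampleRecord], list[str]]:
    """Quantify grouped peaks into sample records; returns (records, warnings)."""
    by_sample: dict[str, list[PeakMeasurement]] = {}
    for p in peaks:
        by_sample.setdefault(p.sample_code, []).append(p)
    warnings: list[str] = []
    records = []
    for code, sample_peaks in by_sample.items():
        activities = quantify_sample(
            sample_peaks, curve, allow_extrapolation=allow_extrapolation
        )
        for chain, meas in activities.items():
            if meas.below_mda:
                warnings.append(
                    f"sample {code}: {chain} activity {meas.value:.4g} Bq/kg below "
                    f"MDA {meas.mda:.4g} Bq/kg"
                )
        matrix = "water" if code.startswith("Wa") else "fish"
        records.append(
            SampleRecord(
                sample_code=code,
                location=(locations or {}).get(code, ""),
                matrix=matrix,
                activities=activities,
            )
        )
    for w in warnings:
        logger.warning("%s", w)
    return records, warnings


def significance_report(
    records: Sequence[SampleRecord], alpha: float = 0.05, matrix: str = "fish"
) -> dict[str, Any]:
    """Per-nuclide one-way ANOVA and Tukey HSD across locations."""
    out: dict[str, Any] = {}
    for chain in CHAINS:
        groups: dict[str, list[float]] = {}
        for rec in records:
            if rec.matrix != matrix or chain not in rec.activities:
                continue
            groups.setdefault(rec.location, []).append(rec.activities[chain].value)
        if len(groups) < 2 or any(len(v) < 2 for v in groups.values()):
            continue
        anova = oneway_anova(groups)
        tukey = tukey_hsd(groups, alpha=alpha)
        out[chain] = {
            "f_statistic": anova.f_statistic,
            "df": [anova.df_between, anova.df_within],
            "p_value": anova.p_value,
            "significant": bool(anova.p_value < alpha),
            "group_means": anova.group_means,
            "tukey": [
                {
                    "pair": [c.group_a, c.group_b],
                    "mean_difference": c.mean_difference,
                    "critical_difference": c.critical_difference,
                    "significant": c.significant,
                }
                for c in tukey.pairwise
            ],
        }
    return out


@dataclass
class RiskReport:
    """Complete pipeline output: tables plus metadata and warnings."""

    metadata: dict[str, Any]
    activity: pd.DataFrame
    dose_risk: pd.DataFrame
    metals_edi: pd.DataFrame | None
    statistics: dict[str, Any]
    warnings: list[str] = field(default_factory=list)

    def to_json(self, include_timestamps: bool = True) -> str:
        meta = dict(self.metadata)
        if not include_timestamps:
            meta.pop("timestamp", None)
        payload = {
            "metadata": meta,
            "activity": self.activity.to_dict(orient="records"),
            "dose_risk": self.dose_risk.to_dict(orient="records"),
            "metals_edi": (
                None if self.metals_edi is None else self.metals_edi.to_dict(orient="records")
            ),
            "statistics": self.statistics,
            "warnings": self.warnings,
        }
        return json.dumps(payload, indent=2, default=_json_default)


def _json_default(obj: object):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and np.isnan(obj):
        return None
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def _config_hash(bundle: ReferenceBundle) -> str:
    blob = repr(
        (
            bundle.params,
            sorted(bundle.dose_coefficients_sv_per_bq.items()),
            sorted(bundle.risk_coefficients_per_bq.items()),
            tuple(bundle.tdi),
            bundle.gamma_lines,
        )
    ).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(
    activity_records: Sequence[SampleRecord],
    metal_records: Sequence[MetalRecord] | None = None,
    bundle: ReferenceBundle | None = None,
    alpha: float = 0.05,
    display_rounding: bool = False,
    seed: int | None = None,
    timestamp: str | None = None,
) -> RiskReport:
    """Run the full measurement-to-risk chain and assemble the report.

    Deterministic given inputs: the only non-pure content is the optional
    metadata timestamp, which callers may omit or fix.
    """
    if bundle is None:
        bundle = default_bundle()
    warnings: list[str] = []
    for rec in activity_records:
        for chain, meas in rec.activities.items():
            if meas.below_mda:
                warnings.append(
                    f"sample {rec.sample_code}: {chain} value below MDA enters means"
                )
    dose_frame = dose_risk_report(
        activity_records, bundle, display_rounding=display_rounding
    )
    edi_frame = None
    if metal_records:
        edi_frame = edi_table(
            metal_records, bundle.params, registry=bundle.tdi_by_element
        )
        for _, row in edi_frame.iterrows():
            if row["flag"] == "no_tdi":
                warnings.append(
                    f"element {row['element']} ({row['location']}): no TDI registered"
                )
    stats = significance_report(activity_records, alpha=alpha)
    metadata: dict[str, Any] = {"config_hash": _config_hash(bundle)}
    if seed is not None:
        metadata["seed"] = seed
    if timestamp is not None:
        metadata["timestamp"] = timestamp
    for w in warnings:
        logger.warning("%s", w)
    return RiskReport(
        metadata=metadata,
        activity=frame_from_records(activity_records),
        dose_risk=dose_frame,
        metals_edi=edi_frame,
        statistics=stats,
        warnings=warnings,
    )
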