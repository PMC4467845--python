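"""Nuclear decay data, dose/risk coefficients, TDI registry and exposure defaults.

The default values describe the assessment of natural radioactivity
(Ra-226, Th-232, K-40) and trace metals in marine fish landed on the west
coast of Peninsular Malaysia: ingestion dose conversion factors, USEPA
mortality risk coefficients, tolerable daily intakes for the screened
metals, the characteristic gamma lines used for quantification under
secular equilibrium, and the population/consumption parameters of the
exposure scenario.  Every value can be overridden key-by-key from a YAML
or JSON configuration file via :func:`load_reference_bundle`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Mapping

import yaml

from ._errors import ConfigError, ValidationError

__all__ = [
    "CHAINS",
    "GammaLine",
    "ExposureParams",
    "TDIEntry",
    "ReferenceBundle",
    "default_gamma_lines",
    "default_bundle",
    "load_reference_bundle",
    "derive_per_capita_intake",
    "TL208_CHAIN_BRANCH",
]

#: Parent decay chains quantified by the pipeline.
CHAINS = ("Ra-226", "Th-232", "K-40")

#: Branch of the Th-232 chain that feeds Tl-208 (Bi-212 -> Tl-208, 35.94%).
TL208_CHAIN_BRANCH = 0.3594


@dataclass(frozen=True)
class GammaLine:
    """One characteristic gamma line of a progeny nuclide.

    Under secular equilibrium the activity of the progeny equals the
    activity of its long-lived parent, so a progeny line quantifies the
    parent chain.  ``primary`` marks the strong, interference-free lines
    actually used for quantification; the remaining lines are carried for
    completeness.  ``branching_factor`` multiplies the emission intensity
    for progeny fed through a partial decay branch (default 1.0).
    """

    progeny_nuclide: str
    parent_chain: str
    energy_kev: float
    intensity: float
    primary: bool = False
    branching_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.parent_chain not in CHAINS:
            raise ValidationError(
                f"unknown parent chain {self.parent_chain!r}; expected one of {CHAINS}"
            )
        if not 0.0 < self.intensity <= 1.0:
            raise ValidationError(
                f"gamma intensity must be in (0, 1], got {self.intensity}"
            )
        if self.energy_kev <= 0:
            raise ValidationError(f"gamma energy must be positive, got {self.energy_kev}")
        if not 0.0 < self.branching_factor <= 1.0:
            raise ValidationError(
                f"branching factor must be in (0, 1], got {self.branching_factor}"
            )

    @property
    def effective_intensity(self) -> float:
        """Photons per parent decay: emission intensity times branch factor."""
        return self.intensity * self.branching_factor


# Decay data (NNDC NuDat): energies in keV, intensities as fractions.
# Primary lines are the strong, independent lines used for quantification.
_GAMMA_LINE_DATA = [
    # progeny, chain, energy, intensity, primary
    ("Pb-214", "Ra-226", 295.2228, 0.1842, False),
    ("Pb-214", "Ra-226", 351.9321, 0.3560, True),
    ("Bi-214", "Ra-226", 609.320, 0.4549, True),
    ("Bi-214", "Ra-226", 1120.294, 0.1492, False),
    ("Bi-214", "Ra-226", 1764.491, 0.1530, False),
    ("Pb-212", "Th-232", 238.632, 0.4360, True),
    ("Tl-208", "Th-232", 510.77, 0.2260, False),
    ("Tl-208", "Th-232", 583.187, 0.8500, True),
    ("Tl-208", "Th-232", 860.557, 0.1250, False),
    ("Ac-228", "Th-232", 338.320, 0.1127, False),
    ("Ac-228", "Th-232", 911.204, 0.2580, True),
    ("Ac-228", "Th-232", 968.971, 0.1580, False),
    ("K-40", "K-40", 1460.822, 0.1066, True),
]


def default_gamma_lines(tl208_chain_branching: bool = False) -> list[GammaLine]:
    """Return the built-in gamma-line registry.

    Parameters
    ----------
    tl208_chain_branching:
        When True, Tl-208 lines carry the Bi-212 -> Tl-208 chain branch
        (0.3594) as their branching factor, for chain-consistent
        quantification.  The default treats the tabulated intensities as
        already expressing photons per parent decay, i.e. branch factor 1.
    """
    lines = []
    for progeny, chain, energy, intensity, primary in _GAMMA_LINE_DATA:
        branch = TL208_CHAIN_BRANCH if (tl208_chain_branching and progeny == "Tl-208") else 1.0
        lines.append(
            GammaLine(
                progeny_nuclide=progeny,
                parent_chain=chain,
                energy_kev=energy,
                intensity=intensity,
                primary=primary,
                branching_factor=branch,
            )
        )
    return lines


@dataclass(frozen=True)
class ExposureParams:
    """Population, production and consumption parameters of the exposure scenario.

    Defaults describe Peninsular Malaysia, 2012: annual marine fish
    landings of 1,472,240 short tons (1 short ton = 907.188 kg), an adult
    population of 19.15 million, 68% of the catch actually consumed
    (after wastage and export), a per-capita seafish consumption of
    47.4 kg/y, a 130 g/day average fish meal, a 70 kg adult reference
    body mass and a 70 y reference lifespan.

    ``per_capita_intake_kg_y`` is the annual mass of fish consumed per
    person used in the dose and risk equations.  The default carries the
    published rounded figure (47.4); set it to ``None`` to derive it from
    the production, conversion, consumed-fraction and population fields
    (which yields 47.43 and shifts last printed digits of the doses).
    """

    annual_production_short_tons: float = 1_472_240.0
    short_ton_kg: float = 907.188
    consumed_fraction: float = 0.68
    population: float = 19.15e6
    per_capita_intake_kg_y: float | None = 47.4
    body_mass_kg: float = 70.0
    daily_food_mass_g: float = 130.0
    lifespan_y: float = 70.0
    days_per_year: float = 365.0

    def __post_init__(self) -> None:
        positive = {
            "annual_production_short_tons": self.annual_production_short_tons,
            "short_ton_kg": self.short_ton_kg,
            "population": self.population,
            "body_mass_kg": self.body_mass_kg,
            "daily_food_mass_g": self.daily_food_mass_g,
            "lifespan_y": self.lifespan_y,
            "days_per_year": self.days_per_year,
        }
        for key, value in positive.items():
            if not (isinstance(value, (int, float)) and math.isfinite(value) and value > 0):
                raise ValidationError(f"exposure parameter {key!r} must be > 0, got {value!r}")
        if not 0.0 <= self.consumed_fraction <= 1.0:
            raise ValidationError(
                f"consumed_fraction must be in [0, 1], got {self.consumed_fraction}"
            )
        if self.per_capita_intake_kg_y is not None and self.per_capita_intake_kg_y <= 0:
            raise ValidationError(
                f"per_capita_intake_kg_y must be > 0 or None, got {self.per_capita_intake_kg_y}"
            )

    @property
    def intake_kg_per_year(self) -> float:
        """Annual per-capita fish intake: the override if set, else derived."""
        if self.per_capita_intake_kg_y is not None:
            return self.per_capita_intake_kg_y
        return derive_per_capita_intake(self)


def derive_per_capita_intake(params: ExposureParams) -> float:
    """Per-capita annual fish intake (kg/y) from production statistics.

    intake = production [short tons] x kg/short ton x consumed fraction / population
    """
    if params.population == 0:
        raise ValidationError("population must be nonzero to derive per-capita intake")
    return (
        params.annual_production_short_tons
        * params.short_ton_kg
        * params.consumed_fraction
        / params.population
    )


@dataclass(frozen=True)
class TDIEntry:
    """Tolerable daily intake of a metal, in micrograms per kg body weight per day."""

    element: str
    tdi_ug_per_kg_day: float
    source_label: str = ""

    def __post_init__(self) -> None:
        if self.tdi_ug_per_kg_day <= 0:
            raise ValidationError(
                f"TDI for {self.element} must be > 0, got {self.tdi_ug_per_kg_day}"
            )


# Ingestion dose conversion factors, Sv per Bq (ICRP-based compilation).
_DEFAULT_DOSE_COEFFS = {"Ra-226": 2.8e-7, "Th-232": 2.3e-7, "K-40": 6.2e-9}

# USEPA mortality risk coefficients, per Bq ingested.
_DEFAULT_RISK_COEFFS = {"Ra-226": 9.56e-9, "Th-232": 2.45e-9, "K-40": 5.89e-10}

# Tolerable daily intakes, ug per kg body weight per day.
_DEFAULT_TDI = [
    ("Al", 143.0, "Nutrition ATC (2014)"),
    ("Cr", 143.0, "Health Canada (2007)"),
    ("Mn", 157.0, "Zhuang et al. (2009)"),
    ("Co", 20.0, "Health Canada (2007)"),
    ("Cu", 142.0, "Zhuang et al. (2009)"),
    ("As", 2.14, "Nutrition ATC (2014)"),
    ("Hg", 0.57, "Nutrition ATC (2014)"),
    ("Pb", 3.60, "Antoine et al. (2012)"),
]


@dataclass(frozen=True)
class ReferenceBundle:
    """Validated bundle of all reference data the pipeline consumes."""

    gamma_lines: tuple[GammaLine, ...]
    dose_coefficients_sv_per_bq: Mapping[str, float]
    risk_coefficients_per_bq: Mapping[str, float]
    tdi: tuple[TDIEntry, ...]
    params: ExposureParams

    def __post_init__(self) -> None:
        for name, table in (
            ("dose_coefficients_sv_per_bq", self.dose_coefficients_sv_per_bq),
            ("risk_coefficients_per_bq", self.risk_coefficients_per_bq),
        ):
            for chain, value in table.items():
                if chain not in CHAINS:
                    raise ValidationError(f"{name}: unknown chain {chain!r}")
                if not (math.isfinite(value) and value > 0):
                    raise ValidationError(f"{name}[{chain}] must be > 0, got {value}")
        chains_with_primary = {ln.parent_chain for ln in self.gamma_lines if ln.primary}
        missing = set(ln.parent_chain for ln in self.gamma_lines) - chains_with_primary
        if missing:
            raise ValidationError(
                f"every parent chain needs at least one primary line; missing for {sorted(missing)}"
            )

    @property
    def tdi_by_element(self) -> dict[str, TDIEntry]:
        return {entry.element: entry for entry in self.tdi}

    def primary_lines(self, chain: str | None = None) -> list[GammaLine]:
        lines = [ln for ln in self.gamma_lines if ln.primary]
        if chain is not None:
            lines = [ln for ln in lines if ln.parent_chain == chain]
        return lines


def default_bundle(tl208_chain_branching: bool = False) -> ReferenceBundle:
    """The built-in reference bundle with all default values."""
    return ReferenceBundle(
        gamma_lines=tuple(default_gamma_lines(tl208_chain_branching)),
        dose_coefficients_sv_per_bq=dict(_DEFAULT_DOSE_COEFFS),
        risk_coefficients_per_bq=dict(_DEFAULT_RISK_COEFFS),
        tdi=tuple(TDIEntry(el, v, src) for el, v, src in _DEFAULT_TDI),
        params=ExposureParams(),
    )


_EXPOSURE_KEYS = {
    "annual_production_short_tons",
    "short_ton_kg",
    "consumed_fraction",
    "population",
    "per_capita_intake_kg_y",
    "body_mass_kg",
    "daily_food_mass_g",
    "lifespan_y",
    "days_per_year",
}


def _read_config(path: str | Path) -> dict[str, Any]:
    path = Path(path)
    text = path.read_text()
    try:
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
    except (yaml.YAMLError, json.JSONDecodeError) as exc:
        raise ConfigError(f"could not parse config file {path}: {exc}") from exc
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ConfigError(f"config file {path} must contain a mapping at top level")
    return data


def load_reference_bundle(
    config_path: str | Path | None = None,
    overrides: Mapping[str, Any] | None = None,
) -> ReferenceBundle:
    """Load the reference bundle, applying config-file and in-memory overrides.

    The configuration dialect mirrors the bundle structure; units are
    carried in the key names::

        exposure:
          lifespan_y: 80
        dose_coefficients_sv_per_bq:
          Ra-226: 2.8e-7
        risk_coefficients_per_bq:
          K-40: 5.89e-10
        tdi_ug_per_kg_day:
          As: 2.14
        options:
          tl208_chain_branching: false

    Unknown keys raise :class:`ConfigError` naming the offending key.
    """
    config: dict[str, Any] = {}
    if config_path is not None:
        config = _read_config(config_path)
    if overrides:
        for section, vals in overrides.items():
            if isinstance(vals, Mapping):
                config.setdefault(section, {})
                config[section].update(vals)
            else:
                config[section] = vals

    known_sections = {
        "exposure",
        "dose_coefficients_sv_per_bq",
        "risk_coefficients_per_bq",
        "tdi_ug_per_kg_day",
        "options",
    }
    unknown = set(config) - known_sections
    if unknown:
        raise ConfigError(
            f"unknown config section(s) {sorted(unknown)}; expected {sorted(known_sections)}"
        )

    options = config.get("options", {}) or {}
    if not isinstance(options, Mapping):
        raise ConfigError("config section 'options' must be a mapping")
    unknown_opts = set(options) - {"tl208_chain_branching"}
    if unknown_opts:
        raise ConfigError(f"unknown option key(s) {sorted(unknown_opts)}")
    bundle = default_bundle(bool(options.get("tl208_chain_branching", False)))

    exposure = config.get("exposure", {}) or {}
    if not isinstance(exposure, Mapping):
        raise ConfigError("config section 'exposure' must be a mapping")
    unknown_exp = set(exposure) - _EXPOSURE_KEYS
    if unknown_exp:
        raise ConfigError(
            f"unknown exposure key(s) {sorted(unknown_exp)}; expected {sorted(_EXPOSURE_KEYS)}"
        )
    try:
        params = replace(bundle.params, **dict(exposure))
    except ValidationError as exc:
        raise ConfigError(f"invalid exposure parameter: {exc}") from exc

    dose = dict(bundle.dose_coefficients_sv_per_bq)
    for chain, value in (config.get("dose_coefficients_sv_per_bq", {}) or {}).items():
        dose[chain] = value
    risk = dict(bundle.risk_coefficients_per_bq)
    for chain, value in (config.get("risk_coefficients_per_bq", {}) or {}).items():
        risk[chain] = value

    tdi_entries = {e.element: e for e in bundle.tdi}
    for element, value in (config.get("tdi_ug_per_kg_day", {}) or {}).items():
        try:
            tdi_entries[element] = TDIEntry(element, float(value), "user config")
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid TDI for {element!r}: {value!r}") from exc
        except ValidationError as exc:
            raise ConfigError(str(exc)) from exc

    try:
        return ReferenceBundle(
            gamma_lines=bundle.gamma_lines,
            dose_coefficients_sv_per_bq=dose,
            risk_coefficients_per_bq=risk,
            tdi=tuple(tdi_entries.values()),
            params=params,
        )
    except ValidationError as exc:
        raise ConfigError(str(exc)) from exc
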