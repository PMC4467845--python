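"""HPGe gamma-spectrometry quantification.

Converts net peak areas into parent-chain activity concentrations under
the secular-equilibrium assumption: the activity of a short-lived progeny
equals that of its long-lived parent, so each strong progeny line yields
an independent estimate of the parent activity

    A = N / (t * eps(E) * P_gamma * b * m)          [Bq/kg dry weight]

with N the net counts, t the live time, eps the full-energy-peak
efficiency at the line energy, P_gamma the emission intensity, b the
chain branching factor and m the dry sample mass.  Detection capability
is screened with the Currie decision criterion at 95% confidence, and
per-line estimates are pooled by inverse-variance weighting.

Uncertainties are combined in quadrature from four independent
components: counting statistics (per peak), detection efficiency (4%),
sample mass (1.5%) and emission intensity (1%); each is overridable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from ._errors import ValidationError
from .reference import GammaLine

__all__ = [
    "EfficiencyPoint",
    "EfficiencyCurve",
    "PeakMeasurement",
    "ActivityMeasurement",
    "UncertaintyBudget",
    "DEFAULT_BUDGET",
    "fit_efficiency",
    "line_activity",
    "minimum_detectable_activity",
    "propagate_uncertainty",
    "combine_lines",
    "quantify_sample",
]


@dataclass(frozen=True)
class EfficiencyPoint:
    """One calibration point: full-energy-peak efficiency at a given energy."""

    energy_kev: float
    efficiency: float
    rel_uncertainty: float = 0.0

    def __post_init__(self) -> None:
        if self.energy_kev <= 0:
            raise ValidationError(f"calibration energy must be > 0, got {self.energy_kev}")
        if not 0.0 < self.efficiency < 1.0:
            raise ValidationError(
                f"efficiency must be in (0, 1), got {self.efficiency} at {self.energy_kev} keV"
            )


@dataclass(frozen=True)
class EfficiencyCurve:
    """Polynomial efficiency curve fitted in ln(efficiency) vs ln(energy) space.

    ``coefficients`` are ascending powers of ln(E/keV).  Evaluation outside
    the calibration energy range raises unless extrapolation is explicitly
    allowed.
    """

    coefficients: tuple[float, ...]
    energy_range_kev: tuple[float, float]
    fit_residual: float = 0.0

    @property
    def fit_order(self) -> int:
        return len(self.coefficients) - 1

    def efficiency(self, energy_kev: float, allow_extrapolation: bool = False) -> float:
        if energy_kev <= 0:
            raise ValidationError(f"energy must be > 0, got {energy_kev}")
        lo, hi = self.energy_range_kev
        if not allow_extrapolation and not (lo <= energy_kev <= hi):
            raise ValidationError(
                f"{energy_kev} keV outside calibration range [{lo}, {hi}] keV; "
                "pass allow_extrapolation=True to override"
            )
        ln_eff = float(np.polynomial.polynomial.polyval(math.log(energy_kev), self.coefficients))
        return math.exp(ln_eff)

    def covers(self, energy_kev: float) -> bool:
        lo, hi = self.energy_range_kev
        return lo <= energy_kev <= hi


def fit_efficiency(points: Sequence[EfficiencyPoint], order: int = 4) -> EfficiencyCurve:
    """Least-squares polynomial fit of ln(efficiency) against ln(energy).

    Requires at least ``order + 1`` distinct calibration energies.  The
    reported residual is the root-mean-square misfit in ln-efficiency.
    """
    if order < 0:
        raise ValidationError(f"fit order must be >= 0, got {order}")
    energies = np.array([p.energy_kev for p in points], dtype=float)
    if len(np.unique(energies)) < order + 1:
        raise ValidationError(
            f"need at least {order + 1} distinct calibration energies for order {order}, "
            f"got {len(np.unique(energies))}"
        )
    x = np.log(energies)
    y = np.log(np.array([p.efficiency for p in points], dtype=float))
    coeffs = np.polynomial.polynomial.polyfit(x, y, order)
    resid = float(np.sqrt(np.mean((np.polynomial.polynomial.polyval(x, coeffs) - y) ** 2)))
    return EfficiencyCurve(
        coefficients=tuple(float(c) for c in coeffs),
        energy_range_kev=(float(energies.min()), float(energies.max())),
        fit_residual=resid,
    )


@dataclass(frozen=True)
class PeakMeasurement:
    """Net peak area of one gamma line in one sample spectrum."""

    line: GammaLine
    net_counts: float
    net_counts_uncertainty: float
    background_counts: float
    live_time_s: float
    sample_mass_kg: float
    sample_code: str = ""

    def __post_init__(self) -> None:
        if self.live_time_s <= 0:
            raise ValidationError(f"live time must be > 0, got {self.live_time_s}")
        if self.sample_mass_kg <= 0:
            raise ValidationError(f"sample mass must be > 0, got {self.sample_mass_kg}")
        if self.net_counts < 0:
            raise ValidationError(f"net counts must be >= 0, got {self.net_counts}")
        if self.background_counts < 0:
            raise ValidationError(
                f"background counts must be >= 0, got {self.background_counts}"
            )


@dataclass(frozen=True)
class UncertaintyBudget:
    """Relative (1-sigma) uncertainty components added in quadrature.

    Counting statistics are taken per peak from the measurement itself;
    the systematic components default to 4% (efficiency), 1.5% (mass) and
    1% (emission intensity).
    """

    efficiency: float = 0.04
    mass: float = 0.015
    intensity: float = 0.01
    extra: tuple[float, ...] = ()

    def combined(self, counting_rel: float) -> float:
        return propagate_uncertainty(
            [counting_rel, self.efficiency, self.mass, self.intensity, *self.extra]
        )


DEFAULT_BUDGET = UncertaintyBudget()


def propagate_uncertainty(relative_components: Iterable[float]) -> float:
    """Combine independent relative uncertainties in quadrature.

    Returns sqrt(sum of squares); the empty list gives 0.
    """
    comps = [float(c) for c in relative_components]
    if any(c < 0 for c in comps):
        raise ValidationError("uncertainty components must be >= 0")
    return math.sqrt(sum(c * c for c in comps))


def line_activity(
    peak: PeakMeasurement,
    curve: EfficiencyCurve,
    budget: UncertaintyBudget = DEFAULT_BUDGET,
    allow_extrapolation: bool = False,
) -> tuple[float, float]:
    """Activity concentration (Bq/kg) and 1-sigma uncertainty from one peak."""
    eff = curve.efficiency(peak.line.energy_kev, allow_extrapolation=allow_extrapolation)
    if eff <= 0:
        raise ValidationError(
            f"non-positive efficiency {eff} at {peak.line.energy_kev} keV"
        )
    denom = (
        peak.live_time_s * eff * peak.line.effective_intensity * peak.sample_mass_kg
    )
    activity = peak.net_counts / denom
    counting_rel = (
        peak.net_counts_uncertainty / peak.net_counts if peak.net_counts > 0 else 0.0
    )
    return activity, activity * budget.combined(counting_rel)


def minimum_detectable_activity(
    background_counts: float,
    efficiency: float,
    intensity: float,
    live_time_s: float,
    mass_kg: float,
    branching_factor: float = 1.0,
) -> float:
    """Currie minimum detectable activity at 95% confidence, in Bq/kg.

    MDA = (2.71 + 4.65 sqrt(B)) / (t * eps * P_gamma * b * m)
    """
    if background_counts < 0:
        raise ValidationError(f"background counts must be >= 0, got {background_counts}")
    for name, value in (
        ("efficiency", efficiency),
        ("intensity", intensity),
        ("live_time_s", live_time_s),
        ("mass_kg", mass_kg),
        ("branching_factor", branching_factor),
    ):
        if value <= 0:
            raise ValidationError(f"{name} must be > 0, got {value}")
    return (2.71 + 4.65 * math.sqrt(background_counts)) / (
        live_time_s * efficiency * intensity * branching_factor * mass_kg
    )


def combine_lines(
    line_activities: Sequence[tuple[float, float]],
    method: str = "inverse_variance",
) -> tuple[float, float]:
    """Pool per-line activity estimates of one parent chain.

    ``inverse_variance`` (default) weights each line by 1/sigma^2, the
    standard pooling rule for independent estimates of a common value;
    ``mean`` takes the unweighted mean (for inputs without uncertainties)
    with the uncertainty propagated as the RMS/n of the inputs.
    """
    if not line_activities:
        raise ValidationError("cannot combine an empty set of line activities")
    values = np.array([v for v, _ in line_activities], dtype=float)
    sigmas = np.array([u for _, u in line_activities], dtype=float)
    if method == "mean":
        n = len(values)
        return float(values.mean()), float(np.sqrt(np.sum(sigmas**2)) / n)
    if method != "inverse_variance":
        raise ValidationError(f"unknown combination method {method!r}")
    if np.any(sigmas <= 0):
        raise ValidationError(
            "inverse-variance weighting needs positive uncertainties; "
            "use method='mean' otherwise"
        )
    weights = 1.0 / sigmas**2
    value = float(np.sum(weights * values) / np.sum(weights))
    return value, float(math.sqrt(1.0 / np.sum(weights)))


@dataclass(frozen=True)
class ActivityMeasurement:
    """Pooled activity concentration of one parent chain in one sample."""

    parent_chain: str
    value: float
    uncertainty: float
    mda: float = 0.0
    contributing_lines: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValidationError(f"activity must be >= 0, got {self.value}")
        if self.uncertainty < 0:
            raise ValidationError(f"uncertainty must be >= 0, got {self.uncertainty}")

    @property
    def below_mda(self) -> bool:
        return self.value < self.mda


def quantify_sample(
    peaks: Sequence[PeakMeasurement],
    curve: EfficiencyCurve,
    budget: UncertaintyBudget = DEFAULT_BUDGET,
    primary_only: bool = True,
    method: str = "inverse_variance",
    allow_extrapolation: bool = False,
) -> dict[str, ActivityMeasurement]:
    """Quantify all parent chains present in a sample's peak list.

    By default only primary (strong, independent) lines enter the
    combination.  The reported MDA per chain is the best (smallest)
    line-level Currie MDA among the contributing lines.
    """
    by_chain: dict[str, list[PeakMeasurement]] = {}
    for peak in peaks:
        if primary_only and not peak.line.primary:
            continue
        by_chain.setdefault(peak.line.parent_chain, []).append(peak)

    result: dict[str, ActivityMeasurement] = {}
    for chain, chain_peaks in by_chain.items():
        estimates = [
            line_activity(p, curve, budget, allow_extrapolation=allow_extrapolation)
            for p in chain_peaks
        ]
        value, unc = combine_lines(estimates, method=method)
        mdas = [
            minimum_detectable_activity(
                p.background_counts,
                curve.efficiency(p.line.energy_kev, allow_extrapolation=allow_extrapolation),
                p.line.intensity,
                p.live_time_s,
                p.sample_mass_kg,
                p.line.branching_factor,
            )
            for p in chain_peaks
        ]
        labels = tuple(
            f"{p.line.progeny_nuclide}@{p.line.energy_kev:g}keV" for p in chain_peaks
        )
        result[chain] = ActivityMeasurement(
            parent_chain=chain,
            value=max(value, 0.0),
            uncertainty=unc,
            mda=min(mdas),
            contributing_lines=labels,
        )
    return result
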