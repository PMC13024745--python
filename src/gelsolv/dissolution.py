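"""Dissolution and supersaturation analytics.

Covers the bookkeeping of paddle-apparatus release tests in which aliquots
are withdrawn at each timepoint and replaced with fresh medium: the mass
removed in earlier aliquots must be added back when converting sampled
concentrations to cumulative release,

    A_n = C_n · V + v · Σ_{i<n} C_i      (µg; reported in mg),

with V the vessel volume, v the aliquot volume and C_i the sampled
concentrations. This is the unique mass-consistent accounting for
sample-and-replace protocols: at every timepoint A_n equals the drug mass
currently in the vessel plus everything removed before.

Supersaturation ("spring-plateau") behaviour is summarised by fold
enhancements over a reference profile at requested times, C_max and its
time, and the trapezoidal area under the concentration curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np

from .errors import MissingTimepointError, ValidationError

__all__ = [
    "DissolutionProtocol",
    "ConcentrationSeries",
    "ReleaseProfile",
    "SupersaturationMetrics",
    "cumulative_release",
    "enhancement_ratio",
    "supersaturation_metrics",
    "profile_summary",
]


@dataclass(frozen=True)
class DissolutionProtocol:
    """Sample-and-replace dissolution protocol descriptor.

    vessel_volume and aliquot_volume in mL, dose in mg of drug;
    temperature (°C), stir_rpm and medium are annotations.
    """

    vessel_volume: float
    aliquot_volume: float
    dose: float
    temperature: float = 37.0
    stir_rpm: float = 100.0
    medium: str = "deionized water"

    def __post_init__(self):
        if self.dose <= 0:
            raise ValidationError("dose must be > 0 mg")
        if self.aliquot_volume < 0:
            raise ValidationError("aliquot_volume must be >= 0 mL")
        if self.vessel_volume <= self.aliquot_volume:
            raise ValidationError(
                "vessel_volume must exceed aliquot_volume "
                f"({self.vessel_volume} mL <= {self.aliquot_volume} mL)"
            )


@dataclass(frozen=True)
class ConcentrationSeries:
    """Sampled medium concentrations: times in min, concentrations in µg/mL."""

    times: np.ndarray
    concentrations: np.ndarray
    label: str = ""

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        if t.ndim != 1 or t.shape != c.shape or t.size < 2:
            raise ValidationError(
                "times and concentrations must be equal-length 1-D arrays "
                "with at least 2 points"
            )
        if t[0] < 0 or np.any(np.diff(t) <= 0):
            raise ValidationError("times must be strictly increasing and start >= 0")
        if np.any(c < 0):
            raise ValidationError("concentrations must be >= 0")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concentrations", c)

    def at(self, time: float) -> float:
        """Concentration at an exactly matching sampled time (no interpolation)."""
        idx = np.nonzero(np.isclose(self.times, time, rtol=0.0, atol=1e-9))[0]
        if idx.size == 0:
            raise MissingTimepointError(
                f"time {time} min was not sampled in series {self.label!r}"
            )
        return float(self.concentrations[idx[0]])


@dataclass(frozen=True)
class ReleaseProfile:
    """Withdrawal-corrected cumulative release over time."""

    times: np.ndarray
    cumulative_amount: np.ndarray  # mg
    cumulative_percent: np.ndarray  # % of dose

    def percent_at(self, time: float) -> float:
        idx = np.nonzero(np.isclose(self.times, time, rtol=0.0, atol=1e-9))[0]
        if idx.size == 0:
            raise MissingTimepointError(f"time {time} min not in release profile")
        return float(self.cumulative_percent[idx[0]])


@dataclass(frozen=True)
class SupersaturationMetrics:
    """Per-time folds against a reference plus profile-level summaries."""

    at_times: tuple[float, ...]
    concentrations: tuple[float, ...]
    reference_concentrations: tuple[float, ...]
    folds: tuple[float, ...]
    c_max: float
    t_max: float
    auc: float  # µg·min/mL, trapezoidal


def cumulative_release(
    protocol: DissolutionProtocol, series: ConcentrationSeries
) -> ReleaseProfile:
    """Convert sampled concentrations to cumulative released drug.

    Applies the sample-and-replace correction A_n = C_n·V + v·Σ_{i<n} C_i
    (µg/mL × mL → µg, reported as mg) and expresses it as % of dose. With
    aliquot_volume = 0 this reduces to the naive C·V conversion. Percentages
    above 100 are possible only through measurement noise and are flagged
    with a warning.
    """
    c = series.concentrations
    removed_before = np.concatenate(([0.0], np.cumsum(c)[:-1]))
    amount_ug = c * protocol.vessel_volume + protocol.aliquot_volume * removed_before
    amount_mg = amount_ug / 1000.0
    percent = 100.0 * amount_mg / protocol.dose
    if np.any(percent > 100.0 + 1e-9):
        warnings.warn(
            f"cumulative release exceeds 100% of dose (max {percent.max():.2f}%); "
            "likely measurement noise",
            stacklevel=2,
        )
    return ReleaseProfile(
        times=series.times.copy(),
        cumulative_amount=amount_mg,
        cumulative_percent=percent,
    )


def enhancement_ratio(
    value_sample: float, value_reference: float, decimals: int = 2
) -> float:
    """Fold enhancement value_sample / value_reference, rounded half-up.

    Half-up rounding to ``decimals`` matches the conventional presentation
    of solubility and supersaturation fold values.
    """
    if value_reference <= 0:
        raise ValidationError("reference value must be > 0")
    if value_sample < 0:
        raise ValidationError("sample value must be >= 0")
    ratio = value_sample / value_reference
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(ratio)).quantize(quantum, rounding=ROUND_HALF_UP))


def supersaturation_metrics(
    series: ConcentrationSeries,
    reference_series: ConcentrationSeries,
    at_times: Sequence[float],
    decimals: int = 2,
) -> SupersaturationMetrics:
    """Fold enhancements at requested times plus C_max, t_max and AUC.

    Requested times must be sampled exactly in both series (no
    interpolation); folds go through :func:`enhancement_ratio`.
    """
    concs, refs, folds = [], [], []
    for t in at_times:
        c = series.at(t)
        r = reference_series.at(t)
        concs.append(c)
        refs.append(r)
        folds.append(enhancement_ratio(c, r, decimals=decimals))
    i_max = int(np.argmax(series.concentrations))
    auc = float(np.trapezoid(series.concentrations, series.times))
    return SupersaturationMetrics(
        at_times=tuple(float(t) for t in at_times),
        concentrations=tuple(concs),
        reference_concentrations=tuple(refs),
        folds=tuple(folds),
        c_max=float(series.concentrations[i_max]),
        t_max=float(series.times[i_max]),
        auc=auc,
    )


def profile_summary(
    profile: ReleaseProfile, at_times: Sequence[float]
) -> dict[float, float]:
    """Percent released at each requested time (exact-match lookup)."""
    return {float(t): profile.percent_at(t) for t in at_times}
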