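"""Synthetic phase-solubility and dissolution data with known ground truth.

Every analysis stage in gelsolv can be exercised without external data:
the generators here draw from the same models the estimators assume (plus
multiplicative assay noise), and emit the generating parameters alongside,
so parameter-recovery and round-trip tests have an exact oracle.

Noise model: recorded values are mean·(1 + ε) with ε ~ Normal(0, noise_cv)
truncated at −0.99, reflecting concentration assays whose error scales with
signal while never producing negative readings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .dissolution import ConcentrationSeries, DissolutionProtocol
from .errors import ValidationError
from .phase_solubility import (
    PhaseSolubilityDataset,
    detect_breakpoint,
    predict_with_aggregation,
)

__all__ = [
    "PhaseSolSimConfig",
    "DissolutionSimConfig",
    "PhaseSolTruth",
    "DissolutionTruth",
    "default_ligand_grid",
    "sink_protocol",
    "nonsink_protocol",
    "gen_phase_solubility",
    "gen_dissolution",
]


def default_ligand_grid() -> np.ndarray:
    """Doubling grid 0.0488…25 mM (10 points), the shape of a typical
    phase-solubility study spanning a linear region up to ~6.25 mM plus a
    deviated high-concentration tail."""
    return 25.0 / 2.0 ** np.arange(9, -1, -1)


def sink_protocol() -> DissolutionProtocol:
    """Paddle sink-condition protocol: 900 mL medium, 2 mL aliquots,
    2.1 mg dose, 37 °C, 100 rpm."""
    return DissolutionProtocol(vessel_volume=900.0, aliquot_volume=2.0, dose=2.1)


def nonsink_protocol() -> DissolutionProtocol:
    """Non-sink supersaturation protocol: 200 mL medium, 2 mL aliquots,
    80 mg dose, 37 °C, 100 rpm."""
    return DissolutionProtocol(vessel_volume=200.0, aliquot_volume=2.0, dose=80.0)


@dataclass(frozen=True)
class PhaseSolSimConfig:
    """Generating parameters for a phase-solubility diagram.

    K11 (mM⁻¹) and S0 (mM) set the linear law; beta (mM⁻¹) switches on the
    A_N aggregation deviation (0 = pure A_L); noise_cv is the multiplicative
    assay coefficient of variation of a single measurement, and each
    reported point is the mean of ``replicates`` independent measurements
    (triplicate assays being the usual bench protocol). Defaults:
    K11 = 1.5 mM⁻¹, S0 = 0.033 mM (an 11.77 µg/mL intrinsic solubility at
    356.41 g/mol), 5% single-measurement noise, triplicates.
    """

    K11: float = 1.5
    S0: float = 0.033
    ligand_grid: np.ndarray = field(default_factory=default_ligand_grid)
    noise_cv: float = 0.05
    beta: float = 0.0
    replicates: int = 3
    seed: int = 0

    def __post_init__(self):
        grid = np.asarray(self.ligand_grid, dtype=float)
        if grid.ndim != 1 or grid.size < 3 or np.any(np.diff(grid) <= 0):
            raise ValidationError("ligand_grid must be strictly increasing, >= 3 pts")
        if min(self.K11, self.S0, self.noise_cv, self.beta) < 0 or np.any(grid < 0):
            raise ValidationError("simulation parameters must be non-negative")
        if int(self.replicates) != self.replicates or self.replicates < 1:
            raise ValidationError("replicates must be a positive integer")
        object.__setattr__(self, "ligand_grid", grid)


@dataclass(frozen=True)
class PhaseSolTruth:
    """Ground truth emitted with a simulated diagram."""

    K11: float
    S0: float
    beta: float
    noiseless: np.ndarray
    diagram_class: str
    breakpoint: float  # detect_breakpoint applied to the noiseless means


@dataclass(frozen=True)
class DissolutionSimConfig:
    """First-order approach to a plateau under sample-and-replace dilution.

    Between samples C(t) relaxes toward C_inf (µg/mL) with rate k (min⁻¹);
    at each sample time the recorded concentration is perturbed by assay
    noise and the vessel is diluted by the replaced aliquot. The kinetic
    form is a stand-in that exercises the release accounting, not a
    mechanistic dissolution model.
    """

    protocol: DissolutionProtocol = field(default_factory=sink_protocol)
    C_inf: float | None = None  # default: dose fully dissolved in the vessel
    k: float = 0.074
    sample_times: Sequence[float] = (5, 10, 15, 20, 30, 45, 60, 90, 120)
    noise_cv: float = 0.0
    seed: int = 0

    def __post_init__(self):
        t = np.asarray(self.sample_times, dtype=float)
        if t.ndim != 1 or t.size < 2 or t[0] <= 0 or np.any(np.diff(t) <= 0):
            raise ValidationError(
                "sample_times must be strictly increasing, > 0, with >= 2 points"
            )
        c_inf = (
            1000.0 * self.protocol.dose / self.protocol.vessel_volume
            if self.C_inf is None
            else self.C_inf
        )
        if c_inf < 0 or self.k < 0 or self.noise_cv < 0:
            raise ValidationError("C_inf, k and noise_cv must be non-negative")
        object.__setattr__(self, "sample_times", t)
        object.__setattr__(self, "C_inf", float(c_inf))


@dataclass(frozen=True)
class DissolutionTruth:
    """Exact dissolved-mass trajectory underlying a simulated run."""

    times: np.ndarray
    noiseless_concentrations: np.ndarray  # pre-dilution, µg/mL
    cumulative_mg: np.ndarray
    cumulative_percent: np.ndarray


def _truncated_noise(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    if cv == 0:
        return np.zeros(size)
    eps = rng.normal(0.0, cv, size=size)
    return np.maximum(eps, -0.99)


def gen_phase_solubility(
    cfg: PhaseSolSimConfig,
) -> tuple[PhaseSolubilityDataset, PhaseSolTruth]:
    """Simulate a phase-solubility diagram with known K₁:₁, S0 and β.

    The noiseless means come from :func:`predict_with_aggregation`;
    observations multiply them by (1 + ε). The emitted truth includes the
    breakpoint/class the detector reports on the noiseless means — the
    reference against which noisy-data detection is judged.
    """
    rng = np.random.default_rng(cfg.seed)
    mean = predict_with_aggregation(cfg.K11, cfg.S0, cfg.beta, cfg.ligand_grid)
    # each reported point averages `replicates` single measurements
    eps = np.stack(
        [_truncated_noise(rng, cfg.noise_cv, mean.size) for _ in range(cfg.replicates)]
    ).mean(axis=0)
    observed = mean * (1.0 + eps)
    dataset = PhaseSolubilityDataset(
        ligand_total=cfg.ligand_grid.copy(),
        drug_total=observed,
        intrinsic_solubility=cfg.S0,
        temperature=37.0,
    )
    if cfg.beta == 0 or mean.size < 5:
        bp, cls = float(cfg.ligand_grid[-1]), "A_L"
    else:
        noiseless_ds = PhaseSolubilityDataset(
            ligand_total=cfg.ligand_grid.copy(),
            drug_total=mean,
            intrinsic_solubility=cfg.S0,
        )
        bp, cls = detect_breakpoint(noiseless_ds)
    truth = PhaseSolTruth(
        K11=cfg.K11,
        S0=cfg.S0,
        beta=cfg.beta,
        noiseless=mean,
        diagram_class=cls,
        breakpoint=bp,
    )
    return dataset, truth


def gen_dissolution(
    cfg: DissolutionSimConfig,
) -> tuple[ConcentrationSeries, DissolutionTruth]:
    """Forward-simulate a sample-and-replace dissolution run.

    Between samples the vessel concentration follows
    C(t) = C_prev + (C_inf − C_prev)(1 − e^{−kΔt}), except that newly
    dissolved mass can never exceed the undissolved remainder of the dose
    (the solid reservoir is finite, so the true release is capped at 100%).
    At each sample time the pre-dilution concentration is recorded (noise
    on the record only, never on the state), the withdrawn mass C·v is
    tallied, and the vessel is diluted by (V − v)/V. Dissolved mass is
    tracked exactly, so the emitted truth is the actual cumulative released
    fraction — the oracle for
    :func:`gelsolv.dissolution.cumulative_release`.
    """
    rng = np.random.default_rng(cfg.seed)
    V, v = cfg.protocol.vessel_volume, cfg.protocol.aliquot_volume
    dose_ug = cfg.protocol.dose * 1000.0
    c = 0.0  # vessel concentration, µg/mL
    t_prev = 0.0
    dissolved_ug = 0.0
    noiseless, cumulative = [], []
    for t in cfg.sample_times:
        delta_ug = (cfg.C_inf - c) * (1.0 - np.exp(-cfg.k * (t - t_prev))) * V
        delta_ug = min(max(delta_ug, 0.0), dose_ug - dissolved_ug)
        dissolved_ug += delta_ug
        c_new = c + delta_ug / V
        noiseless.append(c_new)
        cumulative.append(dissolved_ug)
        c = c_new * (V - v) / V  # replace aliquot with fresh medium
        t_prev = t
    noiseless = np.asarray(noiseless)
    recorded = noiseless * (1.0 + _truncated_noise(rng, cfg.noise_cv, noiseless.size))
    cumulative_ug = np.asarray(cumulative)
    series = ConcentrationSeries(
        times=np.asarray(cfg.sample_times, dtype=float),
        concentrations=recorded,
        label=f"simulated (k={cfg.k}/min, C_inf={cfg.C_inf:g} ug/mL)",
    )
    truth = DissolutionTruth(
        times=np.asarray(cfg.sample_times, dtype=float),
        noiseless_concentrations=noiseless,
        cumulative_mg=cumulative_ug / 1000.0,
        cumulative_percent=100.0 * cumulative_ug / dose_ug,
    )
    return series, truth
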