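"""1:1 complexation phase-solubility analysis (Higuchi–Connors).

A drug D of intrinsic solubility S0 dissolves in the presence of a ligand L
that forms a soluble 1:1 complex with equilibrium constant

    K₁:₁ = [DL] / ([D][L]),

with mass balances [D]_T = [D] + [DL] and [L]_T = [L] + [DL]. While excess
solid drug is present, [D] is pinned at S0 and the total drug solubility is
linear in total ligand:

    S_T(L_T) = S0 + (K·S0 / (1 + K·S0)) · L_T,

the classical A_L phase-solubility diagram: intercept S0, slope strictly
inside (0, 1) for any K, S0 > 0, and

    K₁:₁ = slope / (S0 · (1 − slope)).

At high ligand concentration the diagram may bend below this line (an A_N
negative deviation). Here that is modelled by ligand self-aggregation
reducing the effective free-ligand pool, L_eff = L_T / (1 + β·L_T), which is
substituted for L_T in the linear law. All concentrations are mM, K₁:₁ and
β are mM⁻¹.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import stats

from .errors import InsufficientDataError, ValidationError

__all__ = [
    "PhaseSolubilityDataset",
    "Speciation",
    "ComplexationFit",
    "BreakpointResult",
    "predict_total_solubility",
    "predict_with_aggregation",
    "solve_speciation",
    "detect_breakpoint",
    "fit_K11",
]

#: Relative shortfall below the extrapolated linear law that counts as a
#: systematic A_N deviation (see detect_breakpoint).
DEVIATION_TOL = 0.15

#: One-sided z-score for the extrapolation-uncertainty part of the
#: breakpoint margin (~99.5% one-sided normal quantile).
DEVIATION_Z = 2.58


@dataclass(frozen=True)
class PhaseSolubilityDataset:
    """Equilibrium drug solubility vs total ligand concentration, in mM.

    ``ligand_intrinsic`` (the ligand's own intrinsic solubility) is stored
    for completeness but enters no computation.
    """

    ligand_total: np.ndarray
    drug_total: np.ndarray
    intrinsic_solubility: float
    temperature: float | None = None
    ligand_intrinsic: float | None = None

    def __post_init__(self):
        lt = np.asarray(self.ligand_total, dtype=float)
        dt = np.asarray(self.drug_total, dtype=float)
        if lt.ndim != 1 or lt.shape != dt.shape or lt.size < 3:
            raise ValidationError(
                "ligand_total and drug_total must be equal-length 1-D arrays "
                "with at least 3 points"
            )
        if np.any(lt < 0) or np.any(dt < 0):
            raise ValidationError("concentrations must be non-negative")
        if np.any(np.diff(lt) <= 0):
            raise ValidationError("ligand_total must be strictly increasing")
        if self.intrinsic_solubility < 0:
            raise ValidationError("intrinsic solubility must be >= 0")
        object.__setattr__(self, "ligand_total", lt)
        object.__setattr__(self, "drug_total", dt)

    def __len__(self) -> int:
        return self.ligand_total.size


@dataclass(frozen=True)
class Speciation:
    """Free and complexed species at equilibrium, mM."""

    free_drug: float
    free_ligand: float
    complex_conc: float

    def __post_init__(self):
        if min(self.free_drug, self.free_ligand, self.complex_conc) < 0:
            raise ValidationError("species concentrations must be >= 0")


@dataclass(frozen=True)
class ComplexationFit:
    """Least-squares A-type diagram fit and the inverted K₁:₁ (mM⁻¹)."""

    K11: float
    slope: float
    intercept: float
    linear_range: tuple[float, float]
    r_squared: float
    diagram_class: str
    n_points: int

    def __post_init__(self):
        if not 0 < self.slope < 1:
            raise ValidationError("slope must lie in (0, 1) for a 1:1 model")
        if self.K11 < 0:
            raise ValidationError("K11 must be >= 0")


class BreakpointResult(NamedTuple):
    breakpoint: float
    diagram_class: str


def _validate_nonneg(**kwargs: float) -> None:
    for name, v in kwargs.items():
        if v < 0 or not math.isfinite(v):
            raise ValidationError(f"{name} must be finite and >= 0, got {v}")


def predict_total_solubility(K11: float, S0: float, ligand_total):
    """Total drug solubility S_T = S0 + [K·S0/(1 + K·S0)]·L_T (all mM).

    Scalar in, scalar out; arrays broadcast. Returns S0 at L_T = 0 and is
    linear and strictly increasing in L_T whenever K11·S0 > 0.
    """
    _validate_nonneg(K11=K11, S0=S0)
    lt = np.asarray(ligand_total, dtype=float)
    if np.any(lt < 0):
        raise ValidationError("ligand_total must be >= 0")
    slope = K11 * S0 / (1.0 + K11 * S0)
    out = S0 + slope * lt
    return float(out) if np.isscalar(ligand_total) else out


def predict_with_aggregation(K11: float, S0: float, beta: float, ligand_total):
    """A_N-type prediction: ligand self-aggregation caps the free-ligand pool.

    The effective ligand L_eff = L_T/(1 + β·L_T) replaces L_T in the linear
    law; β = 0 recovers :func:`predict_total_solubility` exactly, and any
    β > 0 gives a strictly concave, everywhere-lower curve.
    """
    _validate_nonneg(K11=K11, S0=S0, beta=beta)
    lt = np.asarray(ligand_total, dtype=float)
    if np.any(lt < 0):
        raise ValidationError("ligand_total must be >= 0")
    l_eff = lt / (1.0 + beta * lt)
    out = predict_total_solubility(K11, S0, l_eff)
    return float(out) if np.isscalar(ligand_total) else out


def solve_speciation(K11: float, drug_total: float, ligand_total: float) -> Speciation:
    """Solve the 1:1 equilibrium for the species concentrations.

    The complex concentration C is the physically admissible root of
    K·(D_T − C)·(L_T − C) = C in [0, min(D_T, L_T)]; the quadratic is solved
    in the numerically stable product form to avoid cancellation when the
    complexed fraction is small.
    """
    _validate_nonneg(K11=K11, drug_total=drug_total, ligand_total=ligand_total)
    if K11 == 0 or drug_total == 0 or ligand_total == 0:
        c = 0.0
    else:
        # K C^2 - (K(D+L)+1) C + K D L = 0; smaller root is admissible.
        b = K11 * (drug_total + ligand_total) + 1.0
        disc = b * b - 4.0 * K11 * K11 * drug_total * ligand_total
        c = 2.0 * K11 * drug_total * ligand_total / (b + math.sqrt(disc))
        c = min(c, drug_total, ligand_total)
    return Speciation(
        free_drug=drug_total - c, free_ligand=ligand_total - c, complex_conc=c
    )


def _ols(x: np.ndarray, y: np.ndarray):
    res = stats.linregress(x, y)
    return res.slope, res.intercept, res.rvalue**2


def detect_breakpoint(
    data: PhaseSolubilityDataset,
    deviation_tol: float = DEVIATION_TOL,
    z: float = DEVIATION_Z,
    min_below: int = 3,
    min_above: int = 2,
) -> BreakpointResult:
    """Locate the onset of A_N negative deviation by grid search.

    Candidate breakpoints are the observed ligand concentrations. For each
    candidate (with at least ``min_below`` points at or below it and
    ``min_above`` above), a line anchored at the model-fixed intercept
    (0, S0) is fitted to the points below — the A-type law pins the
    intercept at the intrinsic solubility, and anchoring keeps chance tilt
    of a short low-concentration fit from being amplified by extrapolation.
    The candidate qualifies when every point above falls below the
    extrapolated line (one-sided sign criterion) *and* the first
    ``min_above`` points above fall short by more than
    max(``deviation_tol``·prediction, ``z``·SE of the extrapolated
    prediction) — a relative margin floor plus a one-sided significance
    test, so that neither assay noise nor fit uncertainty fires the sign
    test early on a smoothly curving diagram. The smallest qualifying
    candidate wins (earliest onset); if none qualifies the diagram is A_L
    with breakpoint at the largest observed ligand concentration.

    A monotone-decreasing tail (B-type behaviour, outside the A-type model)
    still classifies as A_N but emits a warning.
    """
    if min_below < 2 or min_above < 1:
        raise ValidationError("min_below must be >= 2 and min_above >= 1")
    if len(data) < 5:
        raise InsufficientDataError(
            f"breakpoint detection needs >= 5 points, got {len(data)}"
        )
    lt, dt = data.ligand_total, data.drug_total
    s0 = data.intrinsic_solubility
    n = lt.size
    for j in range(min_below - 1, n - min_above):
        x, y = lt[: j + 1], dt[: j + 1]
        sxx = float(np.sum(x * x))
        slope = float(np.sum(x * (y - s0))) / sxx
        pred_above = s0 + slope * lt[j + 1 :]
        resid = dt[j + 1 :] - pred_above
        dof = x.size - 1  # one fitted parameter (anchored slope)
        s_e = math.sqrt(float(np.sum((y - (s0 + slope * x)) ** 2)) / dof)
        se_pred = s_e * np.sqrt(1.0 + lt[j + 1 :] ** 2 / sxx)
        margin = np.maximum(deviation_tol * np.abs(pred_above), z * se_pred)
        if np.all(resid < 0) and np.all(resid[:min_above] < -margin[:min_above]):
            tail = dt[j + 1 :]
            if tail.size >= 2 and np.all(np.diff(tail) < 0):
                warnings.warn(
                    "drug solubility decreases beyond the breakpoint; "
                    "B-type diagram suspected (outside the A-type model)",
                    stacklevel=2,
                )
            return BreakpointResult(float(lt[j]), "A_N")
    return BreakpointResult(float(lt[-1]), "A_L")


def fit_K11(
    data: PhaseSolubilityDataset,
    linear_range: tuple[float, float] | None = None,
    s0_from_intercept: bool = False,
) -> ComplexationFit:
    """Estimate K₁:₁ from the linear portion of a phase-solubility diagram.

    Ordinary least squares of S_T on L_T within ``linear_range`` (default:
    up to the detected breakpoint when the dataset has >= 5 points). The
    constant inverts the slope via K = slope/(S0·(1 − slope)) with S0 the
    measured intrinsic solubility — the model fixes the intercept there —
    unless ``s0_from_intercept`` asks for the regression intercept instead.
    """
    if linear_range is None:
        if len(data) >= 5:
            bp, diagram_class = detect_breakpoint(data)
            linear_range = (float(data.ligand_total[0]), bp)
        else:
            linear_range = (float(data.ligand_total[0]), float(data.ligand_total[-1]))
            diagram_class = "A_L"
    else:
        lo, hi = linear_range
        if lo > hi:
            raise ValidationError("linear_range must be (low, high) with low <= high")
        if lo < data.ligand_total[0] or hi > data.ligand_total[-1]:
            raise ValidationError("linear_range must lie within the data range")
        diagram_class = "A_N" if hi < data.ligand_total[-1] else "A_L"
    lo, hi = linear_range
    mask = (data.ligand_total >= lo) & (data.ligand_total <= hi)
    if mask.sum() < 3:
        raise InsufficientDataError(
            f"need >= 3 points inside the linear range, got {int(mask.sum())}"
        )
    slope, intercept, r2 = _ols(data.ligand_total[mask], data.drug_total[mask])
    if slope <= 0:
        raise ValidationError("no solubilization trend: slope <= 0")
    if slope >= 1:
        raise ValidationError("slope inconsistent with 1:1 model: slope >= 1")
    S0 = intercept if s0_from_intercept else data.intrinsic_solubility
    if S0 <= 0:
        raise ValidationError("intrinsic solubility must be > 0 to invert the slope")
    K11 = slope / (S0 * (1.0 - slope))
    return ComplexationFit(
        K11=K11,
        slope=slope,
        intercept=intercept,
        linear_range=(float(lo), float(hi)),
        r_squared=r2,
        diagram_class=diagram_class,
        n_points=int(mask.sum()),
    )
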