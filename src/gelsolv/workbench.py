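"""Configuration, CSV/JSON I/O and the reproduce-report glue.

Molar masses are configuration constants in :data:`MOLAR_MASSES`, never
inferred; shipped reference observations for the sulindac–meglumine system
live in ``data/reference_values.json`` and feed the ``reproduce`` report
and the analysis drivers.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

from .dissolution import ConcentrationSeries, DissolutionProtocol, enhancement_ratio
from .errors import SchemaError, ValidationError
from .hsp import (
    compute_hansen,
    meglumine_composition,
    miscibility_screen,
    sulindac_composition,
)
from .phase_solubility import PhaseSolubilityDataset
from .units import convert_units

__all__ = [
    "MOLAR_MASSES",
    "reference_values",
    "read_phase_solubility_csv",
    "read_concentration_series_csv",
    "read_protocol_json",
    "CheckResult",
    "Report",
    "reproduce_report",
]

#: Molar-mass registry (g/mol) for the shipped fixture compounds.
MOLAR_MASSES: dict[str, float] = {"sulindac": 356.41, "meglumine": 195.21}


def reference_values() -> dict:
    """Published observations for the sulindac–meglumine system."""
    with resources.files("gelsolv.data").joinpath("reference_values.json").open() as fh:
        return json.load(fh)


def _read_table(path, required: Sequence[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, comment="#")
    except (pd.errors.ParserError, pd.errors.EmptyDataError, UnicodeDecodeError) as exc:
        raise SchemaError(f"{path}: unreadable CSV ({exc})") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")
    for col in required:
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
        if len(bad) and df[col].dtype == object and col != "label":
            raise SchemaError(f"{path}, row {bad[0] + 2}: non-numeric value in {col!r}")
    return df


def read_phase_solubility_csv(
    path,
    intrinsic_solubility: float,
    units: str = "mM",
    molar_mass: float | None = None,
    temperature: float | None = None,
) -> PhaseSolubilityDataset:
    """Read ``ligand_mM,drug_solubility`` CSV into a dataset in mM.

    ``units`` applies to the drug-solubility column *and* to
    ``intrinsic_solubility``; µg/mL input requires ``molar_mass`` (g/mol).
    """
    df = _read_table(path, ("ligand_mM", "drug_solubility"))
    drug = df["drug_solubility"].astype(float).to_numpy()
    s0 = intrinsic_solubility
    if units.strip().lower() != "mm":
        drug = np.array([convert_units(v, units, "mM", molar_mass) for v in drug])
        s0 = convert_units(s0, units, "mM", molar_mass)
    return PhaseSolubilityDataset(
        ligand_total=df["ligand_mM"].astype(float).to_numpy(),
        drug_total=drug,
        intrinsic_solubility=s0,
        temperature=temperature,
    )


def read_concentration_series_csv(path) -> dict[str, ConcentrationSeries]:
    """Read long-format ``time_min,conc_ug_per_ml[,label]`` into series."""
    df = _read_table(path, ("time_min", "conc_ug_per_ml"))
    if "label" not in df.columns:
        df = df.assign(label="")
    out = {}
    for label, grp in df.groupby("label", sort=False):
        grp = grp.sort_values("time_min")
        out[str(label)] = ConcentrationSeries(
            times=grp["time_min"].astype(float).to_numpy(),
            concentrations=grp["conc_ug_per_ml"].astype(float).to_numpy(),
            label=str(label),
        )
    return out


def read_protocol_json(path) -> DissolutionProtocol:
    """Read a protocol descriptor ``{vessel_ml, aliquot_ml, dose_mg, ...}``."""
    with open(path) as fh:
        cfg = json.load(fh)
    try:
        return DissolutionProtocol(
            vessel_volume=float(cfg["vessel_ml"]),
            aliquot_volume=float(cfg["aliquot_ml"]),
            dose=float(cfg["dose_mg"]),
            temperature=float(cfg.get("temp_c", 37.0)),
            stir_rpm=float(cfg.get("rpm", 100.0)),
            medium=str(cfg.get("medium", "deionized water")),
        )
    except KeyError as exc:
        raise SchemaError(f"{path}: missing protocol key {exc}") from None


def builtin_protocol(name: str) -> DissolutionProtocol:
    """Shipped protocol presets: ``sink`` (900 mL) or ``nonsink`` (200 mL)."""
    files = {"sink": "protocol_paddle900.json", "nonsink": "protocol_nonsink200.json"}
    if name not in files:
        raise ValidationError(f"unknown protocol preset {name!r}; use sink|nonsink")
    with resources.as_file(
        resources.files("gelsolv.data").joinpath(files[name])
    ) as p:
        return read_protocol_json(p)


@dataclass(frozen=True)
class CheckResult:
    """One reproduce-report line: computed vs expected at a tolerance."""

    id: str
    description: str
    computed: float
    expected: float
    tolerance: float

    @property
    def passed(self) -> bool:
        return abs(self.computed - self.expected) <= self.tolerance

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "description": self.description,
            "computed": self.computed,
            "expected": self.expected,
            "tolerance": self.tolerance,
            "pass": self.passed,
        }


@dataclass(frozen=True)
class Report:
    checks: tuple[CheckResult, ...]
    environment: dict

    @property
    def overall_pass(self) -> bool:
        return all(c.passed for c in self.checks)

    def to_dict(self) -> dict:
        return {
            "checks": [c.to_dict() for c in self.checks],
            "environment": self.environment,
            "overall_pass": self.overall_pass,
        }


def reproduce_report() -> Report:
    """Recompute the desk-reproducible study numbers from shipped fixtures.

    Covers the Δδ miscibility screen from the published δ values, the
    group-contribution δ of both fixture molecules (±5%, since the study's
    contribution table is not public), and the solubility/supersaturation
    fold enhancements from the published concentrations.
    """
    ref = reference_values()
    d_sul, d_meg = (
        ref["delta_total_mpa_sqrt"]["sulindac"],
        ref["delta_total_mpa_sqrt"]["meglumine"],
    )
    screen = miscibility_screen(d_sul, d_meg)
    sol = ref["apparent_solubility_ug_per_ml"]
    sup = ref["supersaturation_720min_ug_per_ml"]
    hsp_sul = compute_hansen(sulindac_composition())
    hsp_meg = compute_hansen(meglumine_composition())
    checks = (
        CheckResult(
            "miscibility-delta-diff",
            "|delta(SUL) - delta(MEG)| from published delta values, MPa^0.5",
            screen.delta_diff,
            ref["delta_diff_mpa_sqrt"],
            0.005,
        ),
        CheckResult(
            "miscibility-verdict",
            "delta-diff below the 7 MPa^0.5 cutoff (1 = miscible)",
            1.0 if screen.verdict == "miscible" else 0.0,
            1.0,
            0.0,
        ),
        CheckResult(
            "hansen-delta-sulindac",
            "group-contribution total delta of sulindac, MPa^0.5 (+/-5%)",
            hsp_sul.delta_total,
            d_sul,
            0.05 * d_sul,
        ),
        CheckResult(
            "hansen-delta-meglumine",
            "group-contribution total delta of meglumine, MPa^0.5 (+/-5%)",
            hsp_meg.delta_total,
            d_meg,
            0.05 * d_meg,
        ),
        CheckResult(
            "enhancement-fold-pm",
            "apparent-solubility fold, physical mixture vs crystalline",
            enhancement_ratio(sol["physical_mixture"], sol["crystalline"]),
            ref["enhancement_fold"]["physical_mixture"],
            0.005,
        ),
        CheckResult(
            "enhancement-fold-hydrogel",
            "apparent-solubility fold, hydrogel vs crystalline "
            "(printed-precision tolerance; the published figure truncates)",
            enhancement_ratio(sol["hydrogel"], sol["crystalline"]),
            ref["enhancement_fold"]["hydrogel"],
            0.01,
        ),
        CheckResult(
            "supersaturation-fold-crystalline",
            "720 min concentration fold, hydrogel vs crystalline",
            enhancement_ratio(sup["hydrogel"], sup["crystalline"]),
            ref["supersaturation_fold_720min"]["vs_crystalline"],
            0.005,
        ),
        CheckResult(
            "supersaturation-fold-pm",
            "720 min concentration fold, hydrogel vs physical mixture",
            enhancement_ratio(sup["hydrogel"], sup["physical_mixture"]),
            ref["supersaturation_fold_720min"]["vs_physical_mixture"],
            0.005,
        ),
    )
    env = {
        "python": platform.python_version(),
        "gelsolv": _version(),
        "numpy": np.__version__,
    }
    return Report(checks=checks, environment=env)


def _version() -> str:
    from importlib.metadata import PackageNotFoundError, version

    try:
        return version("gelsolv")
    except PackageNotFoundError:
        return "unknown"
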