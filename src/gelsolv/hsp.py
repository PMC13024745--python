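"""Group-contribution Hansen solubility parameters and miscibility screening.

The total solubility parameter δ (MPa^0.5) of a molecule is split into
dispersion, polar and hydrogen-bonding components,

    δ² = δd² + δp² + δh²,

each estimated additively from tabulated per-functional-group increments
(Hoftyzer–van Krevelen molar attraction constants with Fedors volume
increments):

    δd = Σ nᵢ F_dᵢ / V,   δp = sqrt(Σ nᵢ F_pᵢ²) / V,   δh = sqrt(Σ nᵢ E_hᵢ / V),

with V = Σ nᵢ Vᵢ the additive molar volume (cm³/mol), F in
MPa^0.5·cm³/mol, and E_h in J/mol (1 J/cm³ = 1 MPa, so the units close).

Two components are screened as miscible when the difference of their
total parameters, Δδ, is below 7 MPa^0.5 — the conventional cutoff for
drug–excipient compatibility.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from os import PathLike
from typing import IO, Iterable, Mapping, Union

from .errors import SchemaError, UnknownGroupError, ValidationError

__all__ = [
    "GroupContribution",
    "GroupContributionTable",
    "GroupComposition",
    "HansenParameters",
    "MiscibilityResult",
    "MISCIBILITY_THRESHOLD",
    "load_group_table",
    "load_composition",
    "default_group_table",
    "sulindac_composition",
    "meglumine_composition",
    "compute_hansen",
    "miscibility_screen",
]

#: Conventional Δδ cutoff for predicted miscibility, MPa^0.5.
MISCIBILITY_THRESHOLD = 7.0

_TABLE_COLUMNS = ("name", "F_d", "F_p", "E_h", "V")
_COMPOSITION_COLUMNS = ("group", "count")


@dataclass(frozen=True)
class GroupContribution:
    """Per-group increments: F_d/F_p (MPa^0.5 cm³/mol), E_h (J/mol), V (cm³/mol).

    V may be negative for branch carbons (Fedors convention) but never zero;
    F_d may be negative only for the quaternary carbon, F_p and E_h are
    non-negative.
    """

    name: str
    F_d: float
    F_p: float
    E_h: float
    V: float

    def __post_init__(self):
        if not self.name:
            raise ValidationError("group name must be non-empty")
        if self.V == 0 or not math.isfinite(self.V):
            raise ValidationError(
                f"group {self.name!r}: molar-volume increment must be nonzero"
            )
        if self.F_p < 0 or self.E_h < 0:
            raise ValidationError(
                f"group {self.name!r}: F_p and E_h must be non-negative"
            )


class GroupContributionTable(Mapping[str, GroupContribution]):
    """An ordered, name-unique collection of :class:`GroupContribution` rows."""

    def __init__(self, rows: Iterable[GroupContribution], table_id: str = "custom"):
        self.table_id = table_id
        self._rows: dict[str, GroupContribution] = {}
        for row in rows:
            if row.name in self._rows:
                raise SchemaError(f"duplicate group name in table: {row.name!r}")
            self._rows[row.name] = row
        if not self._rows:
            raise SchemaError("contribution table is empty")

    def __getitem__(self, name: str) -> GroupContribution:
        return self._rows[name]

    def __iter__(self):
        return iter(self._rows)

    def __len__(self) -> int:
        return len(self._rows)

    def __repr__(self) -> str:
        return f"GroupContributionTable({self.table_id!r}, {len(self)} groups)"


@dataclass(frozen=True)
class GroupComposition:
    """A molecule expressed as occurrence counts of contribution-table groups."""

    molecule_name: str
    groups: Mapping[str, int]
    table_id: str = "hoftyzer-van-krevelen/fedors"

    def __post_init__(self):
        counts = dict(self.groups)
        for name, n in counts.items():
            if int(n) != n or n < 0:
                raise ValidationError(
                    f"{self.molecule_name}: count for group {name!r} must be a "
                    f"non-negative integer, got {n!r}"
                )
        if not any(n >= 1 for n in counts.values()):
            raise ValidationError(
                f"{self.molecule_name}: composition needs at least one group "
                "with count >= 1"
            )
        object.__setattr__(self, "groups", counts)


@dataclass(frozen=True)
class HansenParameters:
    """Hansen components and total, MPa^0.5, plus the additive molar volume."""

    delta_d: float
    delta_p: float
    delta_h: float
    delta_total: float
    molar_volume: float

    def __post_init__(self):
        for label, v in (
            ("delta_d", self.delta_d),
            ("delta_p", self.delta_p),
            ("delta_h", self.delta_h),
            ("delta_total", self.delta_total),
        ):
            if v < 0 or not math.isfinite(v):
                raise ValidationError(f"{label} must be finite and >= 0, got {v}")
        quad = math.sqrt(self.delta_d**2 + self.delta_p**2 + self.delta_h**2)
        if abs(self.delta_total - quad) > 1e-9 * max(1.0, quad):
            raise ValidationError(
                "delta_total must satisfy the quadrature identity "
                f"(got {self.delta_total}, components give {quad})"
            )


@dataclass(frozen=True)
class MiscibilityResult:
    """Outcome of a Δδ screen between two components."""

    delta_a: float
    delta_b: float
    delta_diff: float
    threshold: float
    verdict: str = field(init=False)

    def __post_init__(self):
        if self.threshold < 0:
            raise ValidationError("miscibility threshold must be >= 0")
        if abs(self.delta_diff - abs(self.delta_a - self.delta_b)) > 1e-12:
            raise ValidationError("delta_diff must equal |delta_a - delta_b|")
        object.__setattr__(
            self,
            "verdict",
            "miscible" if self.delta_diff < self.threshold else "immiscibility-risk",
        )


def _read_csv_rows(source) -> tuple[list[dict], list[str], str]:
    """Read a CSV (path or open handle), skipping full-line # comments."""
    if hasattr(source, "read"):
        text, name = source.read(), getattr(source, "name", "<stream>")
    else:
        with open(source, "r", encoding="utf-8") as fh:
            text = fh.read()
        name = str(source)
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.lstrip().startswith("#")]
    if not lines:
        raise SchemaError(f"{name}: no data rows")
    reader = csv.DictReader(lines)
    return list(reader), [c.strip() for c in reader.fieldnames or []], name


def load_group_table(
    source: Union[str, PathLike, IO[str]], table_id: str | None = None
) -> GroupContributionTable:
    """Load a contribution table from CSV with header ``name,F_d,F_p,E_h,V``.

    Duplicate group names and zero molar-volume increments are rejected with
    an error naming the offending row.
    """
    rows, header, name = _read_csv_rows(source)
    missing = [c for c in _TABLE_COLUMNS if c not in header]
    if missing:
        raise SchemaError(f"{name}: missing column(s) {', '.join(missing)}")
    contributions = []
    for i, row in enumerate(rows, start=2):
        try:
            contributions.append(
                GroupContribution(
                    name=row["name"].strip(),
                    F_d=float(row["F_d"]),
                    F_p=float(row["F_p"]),
                    E_h=float(row["E_h"]),
                    V=float(row["V"]),
                )
            )
        except (TypeError, ValueError) as exc:
            if isinstance(exc, ValidationError):
                raise ValidationError(f"{name}, row {i}: {exc}") from None
            raise SchemaError(f"{name}, row {i}: non-numeric value ({exc})") from None
    return GroupContributionTable(contributions, table_id=table_id or name)


def load_composition(
    source: Union[str, PathLike, IO[str]],
    molecule_name: str | None = None,
    table_id: str = "hoftyzer-van-krevelen/fedors",
) -> GroupComposition:
    """Load a composition from CSV with header ``group,count``."""
    rows, header, name = _read_csv_rows(source)
    missing = [c for c in _COMPOSITION_COLUMNS if c not in header]
    if missing:
        raise SchemaError(f"{name}: missing column(s) {', '.join(missing)}")
    groups: dict[str, int] = {}
    for i, row in enumerate(rows, start=2):
        gname = row["group"].strip()
        if gname in groups:
            raise SchemaError(f"{name}, row {i}: duplicate group {gname!r}")
        try:
            groups[gname] = int(row["count"])
        except (TypeError, ValueError):
            raise SchemaError(f"{name}, row {i}: non-integer count") from None
    return GroupComposition(
        molecule_name=molecule_name or name, groups=groups, table_id=table_id
    )


def _data_path(filename: str):
    return resources.files("gelsolv.data").joinpath(filename)


@lru_cache(maxsize=1)
def default_group_table() -> GroupContributionTable:
    """The built-in Hoftyzer–van Krevelen + Fedors table."""
    with resources.as_file(_data_path("group_contributions.csv")) as p:
        return load_group_table(p, table_id="hoftyzer-van-krevelen/fedors")


@lru_cache(maxsize=1)
def sulindac_composition() -> GroupComposition:
    """Shipped fragmentation of sulindac for the default table."""
    with resources.as_file(_data_path("sulindac_groups.csv")) as p:
        return load_composition(p, molecule_name="sulindac")


@lru_cache(maxsize=1)
def meglumine_composition() -> GroupComposition:
    """Shipped fragmentation of meglumine for the default table."""
    with resources.as_file(_data_path("meglumine_groups.csv")) as p:
        return load_composition(p, molecule_name="meglumine")


def compute_hansen(
    comp: GroupComposition, table: GroupContributionTable | None = None
) -> HansenParameters:
    """Evaluate the group-contribution Hansen parameters of a composition.

    Each group is weighted by its occurrence count; the polar component sums
    squared increments (so it is *not* invariant under duplication of the
    whole molecule, unlike δd and δh, whose numerator and denominator scale
    together).
    """
    table = table if table is not None else default_group_table()
    unknown = [g for g in comp.groups if g not in table]
    if unknown:
        raise UnknownGroupError(unknown)
    active = {g: n for g, n in comp.groups.items() if n > 0}
    V = sum(n * table[g].V for g, n in active.items())
    if V <= 0:
        raise ValidationError(
            f"{comp.molecule_name}: total molar volume must be positive, got {V}"
        )
    sum_fd = sum(n * table[g].F_d for g, n in active.items())
    sum_fp2 = sum(n * table[g].F_p ** 2 for g, n in active.items())
    sum_eh = sum(n * table[g].E_h for g, n in active.items())
    delta_d = sum_fd / V
    delta_p = math.sqrt(sum_fp2) / V
    delta_h = math.sqrt(sum_eh / V)
    if delta_d < 0:
        raise ValidationError(
            f"{comp.molecule_name}: negative dispersion component ({delta_d:.3f}); "
            "check the fragmentation"
        )
    total = math.sqrt(delta_d**2 + delta_p**2 + delta_h**2)
    return HansenParameters(delta_d, delta_p, delta_h, total, V)


def miscibility_screen(
    a: HansenParameters | float,
    b: HansenParameters | float,
    threshold: float = MISCIBILITY_THRESHOLD,
) -> MiscibilityResult:
    """Screen two components for miscibility by Δδ = |δ_a − δ_b|.

    Accepts :class:`HansenParameters` or bare total-δ values (MPa^0.5); the
    verdict is ``"miscible"`` iff Δδ is strictly below ``threshold``.
    """
    if threshold < 0:
        raise ValidationError("miscibility threshold must be >= 0")
    da = a.delta_total if isinstance(a, HansenParameters) else float(a)
    db = b.delta_total if isinstance(b, HansenParameters) else float(b)
    if not (math.isfinite(da) and math.isfinite(db)):
        raise ValidationError("solubility parameters must be finite")
    return MiscibilityResult(
        delta_a=da, delta_b=db, delta_diff=abs(da - db), threshold=threshold
    )
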