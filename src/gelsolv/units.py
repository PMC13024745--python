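"""Unit conversions bridging assay units (µg/mL) and model units (mM).

All equilibrium math in :mod:`gelsolv.phase_solubility` is carried out in
millimolar; dissolution assays report µg/mL. The bridge requires a molar
mass (g/mol), which is always supplied explicitly — never inferred.
"""

from __future__ import annotations

from .errors import ValidationError

#: Canonical spellings for the supported units.
_ALIASES = {
    "ug/ml": "ug/mL",
    "µg/ml": "ug/mL",
    "μg/ml": "ug/mL",
    "mm": "mM",
    "mg": "mg",
    "ug": "ug",
    "µg": "ug",
    "μg": "ug",
}


def _canon(units: str) -> str:
    key = units.strip().lower()
    if key not in _ALIASES:
        raise ValidationError(f"unsupported units: {units!r}")
    return _ALIASES[key]


def convert_units(
    value: float,
    from_units: str,
    to_units: str,
    molar_mass: float | None = None,
) -> float:
    """Convert ``value`` between supported unit pairs.

    Supported pairs: µg/mL ↔ mM (requires ``molar_mass`` in g/mol) and
    mg ↔ µg. Round-tripping is the identity to floating precision.

    Parameters
    ----------
    value:
        Non-negative quantity to convert.
    from_units, to_units:
        Unit labels; ``"ug/mL"`` (µ spellings accepted), ``"mM"``,
        ``"mg"``, ``"ug"``.
    molar_mass:
        Molar mass in g/mol, required for the concentration pair.
    """
    if value < 0:
        raise ValidationError(f"cannot convert negative quantity {value}")
    src, dst = _canon(from_units), _canon(to_units)
    if src == dst:
        return value
    if {src, dst} == {"ug/mL", "mM"}:
        if molar_mass is None or molar_mass <= 0:
            raise ValidationError(
                "µg/mL ↔ mM conversion requires a positive molar mass (g/mol)"
            )
        # 1 µg/mL = 1 mg/L; (mg/L) / (g/mol) = mmol/L = mM
        return value / molar_mass if src == "ug/mL" else value * molar_mass
    if {src, dst} == {"mg", "ug"}:
        return value * 1000.0 if src == "mg" else value / 1000.0
    raise ValidationError(f"unsupported conversion: {from_units!r} -> {to_units!r}")
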