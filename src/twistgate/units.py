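"""Physical constants and unit conversion.

Internal units throughout the package: length nm, energy kJ/mol,
force kJ mol^-1 nm^-1, charge e, angle rad, time ps, torque kJ/mol.
Forces are converted to pN only at reporting boundaries.
"""

from __future__ import annotations

from .errors import UnitError

#: Coulomb prefactor 1/(4 pi eps0) in kJ mol^-1 nm e^-2 (MD convention).
KE_COULOMB = 138.935458

#: 1 kJ mol^-1 nm^-1 expressed in piconewton (divide by Avogadro's number).
KJ_MOL_NM_TO_PN = 1.66054

_FORCE_UNITS = {"kJ/mol/nm", "pN"}


def convert_force(value: float, from_unit: str, to_unit: str) -> float:
    """Convert a force (or force magnitude) between kJ/mol/nm and pN.

    Accepts scalars or numpy arrays; the conversion is a single
    multiplicative constant, kept here so every module agrees on it.
    """
    for u in (from_unit, to_unit):
        if u not in _FORCE_UNITS:
            raise UnitError(f"unknown force unit {u!r}; expected one of {sorted(_FORCE_UNITS)}")
    if from_unit == to_unit:
        return value
    if from_unit == "kJ/mol/nm":  # -> pN
        return value * KJ_MOL_NM_TO_PN
    return value / KJ_MOL_NM_TO_PN
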