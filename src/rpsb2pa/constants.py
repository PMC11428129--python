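"""Physical constants and unit conversions.

All internal computation in this package runs in Hartree atomic units;
conversion to eV, Debye and Göppert-Mayer (GM) units happens only at the
I/O boundary. Constants are CODATA 2018 values, frozen at import time.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class PhysicalConstants:
    """CODATA 2018 constants used by the 2PA conversion machinery.

    Attributes
    ----------
    alpha : fine-structure constant (dimensionless)
    a0_cm : Bohr radius in cm
    c_cm_per_s : speed of light in cm/s
    hartree_ev : Hartree energy in eV
    au_dipole_debye : one atomic unit of electric dipole moment in Debye
    gm_cm4s : one Göppert-Mayer unit in cm^4 s / photon
    """

    alpha: float = 7.2973525693e-3
    a0_cm: float = 5.29177210903e-9
    c_cm_per_s: float = 2.99792458e10
    hartree_ev: float = 27.211386245988
    au_dipole_debye: float = 2.5417464731
    gm_cm4s: float = 1e-50


CODATA = PhysicalConstants()

#: supported multiplicative unit conversions, (from, to) -> factor
_CONVERSIONS = {
    ("eV", "hartree"): 1.0 / CODATA.hartree_ev,
    ("hartree", "eV"): CODATA.hartree_ev,
    ("D", "au"): 1.0 / CODATA.au_dipole_debye,
    ("au", "D"): CODATA.au_dipole_debye,
    ("cm4s", "GM"): 1.0 / CODATA.gm_cm4s,
    ("GM", "cm4s"): CODATA.gm_cm4s,
}


def convert_units(value: float, unit_from: str, unit_to: str) -> float:
    """Convert ``value`` between supported unit pairs.

    Supported: eV<->hartree, D<->au (dipole), cm4s<->GM.
    Identity conversions (same token) are allowed for any known token.
    """
    if unit_from == unit_to:
        known = {u for pair in _CONVERSIONS for u in pair}
        if unit_from not in known:
            raise ValueError(f"unknown unit token {unit_from!r}")
        return value
    try:
        factor = _CONVERSIONS[(unit_from, unit_to)]
    except KeyError:
        raise ValueError(
            f"unsupported unit conversion {unit_from!r} -> {unit_to!r}"
        ) from None
    return value * factor


def constants_table() -> str:
    """Render the constants as a documented plain-text table (audit trail)."""
    c = CODATA
    lines = [
        "# Physical constants (CODATA 2018) used by rpsb2pa",
        "# name                 value                  unit",
        f"alpha                  {c.alpha:.10e}   dimensionless (fine-structure constant)",
        f"a0                     {c.a0_cm:.10e}   cm (Bohr radius)",
        f"c                      {c.c_cm_per_s:.10e}   cm/s (speed of light)",
        f"hartree                {c.hartree_ev:.12f}   eV",
        f"au_dipole              {c.au_dipole_debye:.10f}   Debye per atomic unit",
        f"GM                     {c.gm_cm4s:.1e}   cm^4 s / photon",
    ]
    return "\n".join(lines) + "\n"
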