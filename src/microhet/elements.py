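"""Default per-element Van-der-Waals radii and atomic masses.

Radii are in picometres (Bondi-style values; Ar 188 pm, Cl 175 pm), masses in
unified atomic mass units.  Both tables can be overridden per observation.
"""

from __future__ import annotations

VDW_RADIUS_PM: dict[str, float] = {
    "H": 120.0,
    "He": 140.0,
    "Li": 182.0,
    "B": 192.0,
    "C": 170.0,
    "N": 155.0,
    "O": 152.0,
    "F": 147.0,
    "Ne": 154.0,
    "Na": 227.0,
    "Mg": 173.0,
    "Si": 210.0,
    "P": 180.0,
    "S": 180.0,
    "Cl": 175.0,
    "Ar": 188.0,
    "K": 275.0,
    "Br": 185.0,
    "Kr": 202.0,
    "I": 198.0,
    "Xe": 216.0,
}

ATOMIC_MASS_U: dict[str, float] = {
    "H": 1.008,
    "He": 4.0026,
    "Li": 6.94,
    "B": 10.81,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998,
    "Ne": 20.180,
    "Na": 22.990,
    "Mg": 24.305,
    "Si": 28.085,
    "P": 30.974,
    "S": 32.06,
    "Cl": 35.45,
    "Ar": 39.948,
    "K": 39.098,
    "Br": 79.904,
    "Kr": 83.798,
    "I": 126.904,
    "Xe": 131.293,
}


def vdw_radius(symbol: str) -> float:
    """Default Van-der-Waals radius in pm; raises for unknown elements."""
    try:
        return VDW_RADIUS_PM[symbol]
    except KeyError:
        raise KeyError(
            f"no default Van-der-Waals radius for element {symbol!r}; "
            "provide an explicit per-site radius"
        ) from None


def atomic_mass(symbol: str) -> float:
    try:
        return ATOMIC_MASS_U[symbol]
    except KeyError:
        raise KeyError(
            f"no default atomic mass for element {symbol!r}; provide explicit masses"
        ) from None
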