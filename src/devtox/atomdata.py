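"""Atomic property tables for weighted 2D descriptors.

Values follow the standard descriptor-literature tables: atomic mass
(u), polarizability (Å³), van der Waals volume (Å³) and Sanderson
electronegativity.  Weighting schemes use each property scaled relative
to carbon, so carbon always carries weight 1.
"""

from __future__ import annotations

TABLE_VERSION = "2024.1"

# element -> (mass, polarizability, vdw_volume, sanderson_en)
_PROPERTIES: dict[str, tuple[float, float, float, float]] = {
    "H": (1.008, 0.667, 6.709, 2.592),
    "B": (10.811, 3.030, 17.875, 2.275),
    "C": (12.011, 1.760, 22.449, 2.746),
    "N": (14.007, 1.100, 15.599, 3.194),
    "O": (15.999, 0.802, 11.494, 3.654),
    "F": (18.998, 0.557, 9.203, 4.000),
    "Al": (26.982, 6.800, 36.511, 1.714),
    "Si": (28.086, 5.380, 31.976, 2.138),
    "P": (30.974, 3.630, 26.522, 2.515),
    "S": (32.066, 2.900, 24.429, 2.957),
    "Cl": (35.453, 2.180, 23.228, 3.475),
    "Fe": (55.845, 8.400, 41.052, 2.000),
    "Co": (58.933, 7.500, 35.041, 2.000),
    "Ni": (58.693, 6.800, 17.157, 2.000),
    "Cu": (63.546, 6.100, 11.494, 2.033),
    "Zn": (65.39, 7.100, 38.351, 2.223),
    "As": (74.922, 4.310, 29.289, 2.816),
    "Se": (78.96, 3.770, 28.731, 3.014),
    "Br": (79.904, 3.050, 31.059, 3.219),
    "Sn": (118.710, 7.700, 45.830, 2.298),
    "I": (126.904, 5.350, 38.792, 2.778),
    "Hg": (200.59, 5.700, 19.160, 2.195),
    "Pb": (207.2, 6.800, 43.623, 2.291),
}

_SCHEME_INDEX = {"mass": 0, "polarizability": 1, "vdw_volume": 2, "electronegativity": 3}

#: one-letter scheme codes used in descriptor symbols (BEHm1, GATS1p, ...)
SCHEME_CODES = {
    "m": "mass",
    "p": "polarizability",
    "v": "vdw_volume",
    "e": "electronegativity",
}


class UnknownElementError(KeyError):
    """Raised when an atom has no entry in the property table."""


def atomic_property(symbol: str, scheme: str) -> float:
    """Raw atomic property value for an element under a weighting scheme."""
    try:
        row = _PROPERTIES[symbol]
    except KeyError:
        raise UnknownElementError(
            f"no {scheme} value tabulated for element {symbol!r}"
        ) from None
    return row[_SCHEME_INDEX[scheme]]


def carbon_scaled(symbol: str, scheme: str) -> float:
    """Atomic property scaled relative to carbon (carbon -> 1.0)."""
    return atomic_property(symbol, scheme) / atomic_property("C", scheme)
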