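"""Isotope masses and natural abundances (IUPAC 2013 representative values).

Values are pinned here rather than taken from a third-party library so that
computed m/z and natural-abundance distributions are stable across library
upgrades. Only the elements occurring in the derivatized acid panel are
listed (C, H, N, O, S kept for headroom).
"""

from __future__ import annotations

# mass of a proton (Da), for [M+H]+ adducts
PROTON_MASS = 1.007276466621

# per element: list of (isotope mass in Da, fractional abundance),
# sorted by increasing mass; abundances sum to 1
ISOTOPES: dict[str, list[tuple[float, float]]] = {
    "H": [(1.0078250319, 0.999885), (2.0141017781, 0.000115)],
    "C": [(12.0, 0.9893), (13.0033548351, 0.0107)],
    "N": [(14.0030740052, 0.99636), (15.0001088989, 0.00364)],
    "O": [
        (15.9949146221, 0.99757),
        (16.9991315, 0.00038),
        (17.9991604, 0.00205),
    ],
    "S": [
        (31.97207069, 0.9499),
        (32.97145850, 0.0075),
        (33.96786683, 0.0425),
        (35.96708088, 0.0001),
    ],
}

# monoisotopic (lightest-isotope) masses, Da
MONOISOTOPIC_MASS: dict[str, float] = {el: iso[0][0] for el, iso in ISOTOPES.items()}

# heavy-isotope labels supported in formulas: symbol -> (element, isotope index)
HEAVY_ISOTOPES: dict[str, tuple[str, int]] = {
    "2H": ("H", 1),
    "13C": ("C", 1),
}


def heavy_mass(symbol: str) -> float:
    """Exact mass of a fixed heavy isotope such as ``13C`` or ``2H``."""
    element, idx = HEAVY_ISOTOPES[symbol]
    return ISOTOPES[element][idx][0]
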