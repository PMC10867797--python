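"""Elemental-formula arithmetic and aggregated isotopologue distributions.

Formulas carry two layers of isotope information:

* ``counts`` — total atoms per element (a deuterium counts as an H here);
* ``fixed_heavy`` — how many of those atoms are pinned to a heavy isotope
  (``13C``, ``2H``), e.g. from a deuterated internal standard or a 13C
  tracer label. Fixed atoms contribute their exact heavy mass and no
  natural-abundance variability.

Distributions are aggregated by nominal mass shift (unit resolution), which
is the correct model for a triple-quadrupole instrument: a 13C and a 15N
substitution land in the same +1 channel and are not resolved.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .isotopes import HEAVY_ISOTOPES, ISOTOPES, MONOISOTOPIC_MASS, heavy_mass


class FormulaError(ValueError):
    """Raised for malformed formula strings or invalid isotope annotations."""


_TOKEN = re.compile(r"\[(\d+[A-Z][a-z]?)\](\d*)|([A-Z][a-z]?)(\d*)|(.)")


@dataclass(frozen=True)
class ElementalFormula:
    """Element->count map with optional fixed heavy-isotope annotations."""

    counts: dict[str, int] = field(default_factory=dict)
    fixed_heavy: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for el, n in self.counts.items():
            if el not in ISOTOPES:
                raise FormulaError(f"unknown element symbol: {el!r}")
            if n < 0:
                raise FormulaError(f"negative count for {el}: {n}")
        for sym, n in self.fixed_heavy.items():
            if sym not in HEAVY_ISOTOPES:
                raise FormulaError(f"unsupported heavy isotope: {sym!r}")
            if n < 0:
                raise FormulaError(f"negative heavy count for {sym}: {n}")
            element = HEAVY_ISOTOPES[sym][0]
            if n > self.counts.get(element, 0):
                raise FormulaError(
                    f"{sym} count {n} exceeds total {element} atoms "
                    f"({self.counts.get(element, 0)})"
                )

    # -- arithmetic -------------------------------------------------------

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        counts = dict(self.counts)
        for el, n in other.counts.items():
            counts[el] = counts.get(el, 0) + n
        heavy = dict(self.fixed_heavy)
        for sym, n in other.fixed_heavy.items():
            heavy[sym] = heavy.get(sym, 0) + n
        return ElementalFormula(counts, heavy)

    def __sub__(self, other: "ElementalFormula") -> "ElementalFormula":
        counts = dict(self.counts)
        for el, n in other.counts.items():
            counts[el] = counts.get(el, 0) - n
        heavy = dict(self.fixed_heavy)
        for sym, n in other.fixed_heavy.items():
            heavy[sym] = heavy.get(sym, 0) - n
        counts = {el: n for el, n in counts.items() if n != 0}
        heavy = {s: n for s, n in heavy.items() if n != 0}
        return ElementalFormula(counts, heavy)

    def scale(self, k: int) -> "ElementalFormula":
        return ElementalFormula(
            {el: n * k for el, n in self.counts.items()},
            {s: n * k for s, n in self.fixed_heavy.items()},
        )

    def with_fixed(self, symbol: str, n: int) -> "ElementalFormula":
        """Return a copy with ``n`` additional atoms pinned to ``symbol``."""
        heavy = dict(self.fixed_heavy)
        heavy[symbol] = heavy.get(symbol, 0) + n
        return ElementalFormula(dict(self.counts), heavy)

    # -- properties -------------------------------------------------------

    def monoisotopic_mass(self) -> float:
        """Exact mass with light isotopes everywhere except fixed heavies."""
        mass = 0.0
        light = self.light_counts()
        for el, n in light.items():
            mass += n * MONOISOTOPIC_MASS[el]
        for sym, n in self.fixed_heavy.items():
            mass += n * heavy_mass(sym)
        return mass

    def light_counts(self) -> dict[str, int]:
        """Atoms per element that are free to vary naturally."""
        light = dict(self.counts)
        for sym, n in self.fixed_heavy.items():
            element = HEAVY_ISOTOPES[sym][0]
            light[element] = light.get(element, 0) - n
        return {el: n for el, n in light.items() if n > 0}

    def hill(self) -> str:
        """Canonical Hill-notation string, heavy annotations appended.

        Element counts are printed net of fixed heavy atoms so that the
        string parses back to the identical formula.
        """
        parts: list[str] = []
        counts = self.light_counts()
        for el in ("C", "H"):
            if counts.get(el):
                n = counts.pop(el)
                parts.append(el + (str(n) if n > 1 else ""))
        for el in sorted(counts):
            if counts[el]:
                parts.append(el + (str(counts[el]) if counts[el] > 1 else ""))
        for sym in sorted(self.fixed_heavy):
            n = self.fixed_heavy[sym]
            if n:
                parts.append(f"[{sym}]" + (str(n) if n > 1 else ""))
        return "".join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.hill()


def parse_formula(text: str) -> ElementalFormula:
    """Parse Hill-notation text with optional ``[2H]n`` / ``[13C]n`` markers.

    ``"C2H4O2"`` is plain acetic acid; ``"C2H[2H]3O2"`` is the d3-acetyl
    skeleton (total H = 4, of which 3 are deuterium). Round-trips through
    :meth:`ElementalFormula.hill`.
    """
    if not text or not text.strip():
        raise FormulaError("empty formula string")
    counts: dict[str, int] = {}
    heavy: dict[str, int] = {}
    for m in _TOKEN.finditer(text.strip()):
        iso, iso_n, el, el_n, bad = m.groups()
        if bad is not None:
            raise FormulaError(f"malformed token {bad!r} in {text!r}")
        if iso is not None:
            if iso not in HEAVY_ISOTOPES:
                raise FormulaError(f"unsupported isotope marker [{iso}] in {text!r}")
            n = int(iso_n) if iso_n else 1
            heavy[iso] = heavy.get(iso, 0) + n
            element = HEAVY_ISOTOPES[iso][0]
            counts[element] = counts.get(element, 0) + n
        else:
            if el not in ISOTOPES:
                raise FormulaError(f"unknown element symbol {el!r} in {text!r}")
            n = int(el_n) if el_n else 1
            counts[el] = counts.get(el, 0) + n
    return ElementalFormula(counts, heavy)


def natural_isotopologue_distribution(
    formula: ElementalFormula, n_peaks: int
) -> np.ndarray:
    """First ``n_peaks + 1`` terms of the nominal-mass isotopologue pattern.

    Element patterns (abundance vs. integer mass shift) are raised to their
    atom counts and convolved across elements; the full, untruncated
    expansion sums to 1. Fixed heavy atoms are excluded from the expansion —
    their mass shift is already part of the species' monoisotopic mass.
    """
    if n_peaks < 0:
        raise ValueError("n_peaks must be >= 0")
    dist = np.array([1.0])
    for el, n in formula.light_counts().items():
        base = _element_shift_pattern(el)
        dist = np.convolve(dist, _poly_power(base, n))
    out = np.zeros(n_peaks + 1)
    m = min(len(dist), n_peaks + 1)
    out[:m] = dist[:m]
    return out


def _element_shift_pattern(element: str) -> np.ndarray:
    isotopes = ISOTOPES[element]
    base_mass = isotopes[0][0]
    size = round(isotopes[-1][0] - base_mass) + 1
    pattern = np.zeros(size)
    for mass, abundance in isotopes:
        pattern[round(mass - base_mass)] += abundance
    return pattern


def _poly_power(pattern: np.ndarray, n: int) -> np.ndarray:
    """``pattern`` convolved with itself ``n`` times (binary exponentiation)."""
    result = np.array([1.0])
    square = pattern
    while n > 0:
        if n & 1:
            result = np.convolve(result, square)
        square = np.convolve(square, square)
        n >>= 1
    return result
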