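"""dMRM transition-table construction and retention-time scheduling.

Every analyte gets one quantifier transition (product = protonated
2-picolylamine, m/z 109, unless the registry overrides it) and at most one
qualifier. Isotopologue expansion adds one quantifier channel per possible
13C label count k = 0..n_acid_carbons; the 109 product contains no acid
carbons, so it is label-invariant, while water-loss qualifiers shift with
the precursor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .formula import parse_formula
from .isotopes import PROTON_MASS
from .registry import (
    RUN_LENGTH_MIN,
    WATER_MONO_MASS,
    Panel,
    PanelEntry,
    derivatize,
    label_isotopologue,
    precursor_mz,
)

#: protonated 2-picolylamine, the panel-wide quantifier product ion
PICOLYLAMINE_H_MZ = round(parse_formula("C6H8N2").monoisotopic_mass() + PROTON_MASS)

#: default scheduling half-width, minutes (window = rt ± half-width)
DEFAULT_WINDOW_HALF_WIDTH = 0.5

TRANSITION_COLUMNS = [
    "analyte",
    "isotopologue_k",
    "precursor_mz",
    "product_mz",
    "role",
    "ce_eV",
    "rt_min",
    "rt_window_min",
]


@dataclass(frozen=True)
class Transition:
    """One scheduled MRM channel."""

    analyte: str
    isotopologue_k: int
    precursor_mz: float  # nominal, Da
    product_mz: float  # nominal, Da
    role: str  # "quantifier" | "qualifier"
    ce: float  # eV
    rt_center: float  # minutes
    rt_window: float = 2 * DEFAULT_WINDOW_HALF_WIDTH  # minutes

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.analyte, self.isotopologue_k, self.role)

    @property
    def window(self) -> tuple[float, float]:
        half = self.rt_window / 2
        return (max(0.0, self.rt_center - half), min(RUN_LENGTH_MIN, self.rt_center + half))


@dataclass
class DMRMSchedule:
    """Transition list plus the concurrency profile of its RT windows."""

    transitions: list[Transition] = field(default_factory=list)

    @property
    def max_concurrency(self) -> int:
        """Largest number of simultaneously acquired transitions."""
        events: list[tuple[float, int]] = []
        for t in self.transitions:
            lo, hi = t.window
            events.append((lo, 1))
            events.append((hi, -1))
        # close windows before opening new ones at the same instant
        events.sort(key=lambda e: (e[0], e[1]))
        best = cur = 0
        for _, delta in events:
            cur += delta
            best = max(best, cur)
        return best

    def find(self, analyte: str, k: int = 0, role: str = "quantifier") -> Transition:
        for t in self.transitions:
            if t.key == (analyte, k, role):
                return t
        raise KeyError(f"no transition for {(analyte, k, role)}")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "analyte": t.analyte,
                "isotopologue_k": t.isotopologue_k,
                "precursor_mz": t.precursor_mz,
                "product_mz": t.product_mz,
                "role": t.role,
                "ce_eV": t.ce,
                "rt_min": t.rt_center,
                "rt_window_min": t.rt_window,
            }
            for t in self.transitions
        ]
        return pd.DataFrame(rows, columns=TRANSITION_COLUMNS)


def _entry_transitions(entry: PanelEntry, k: int, window: float) -> list[Transition]:
    exact, nominal = precursor_mz(label_isotopologue(entry, k))
    quant_product = (
        entry.quantifier_mz if entry.quantifier_mz is not None else PICOLYLAMINE_H_MZ
    )
    out = [
        Transition(
            analyte=entry.name,
            isotopologue_k=k,
            precursor_mz=float(nominal),
            product_mz=float(quant_product),
            role="quantifier",
            ce=entry.ce_quant,
            rt_center=entry.rt_min,
            rt_window=window,
        )
    ]
    rule = entry.qualifier_rule
    qualifier_mz: Optional[float] = None
    if rule.kind == "water_loss":
        qualifier_mz = float(round(exact - WATER_MONO_MASS))
    elif rule.kind == "fixed_mz" and k == 0:
        # fixed fragments have unknown acid-carbon content; not expanded
        qualifier_mz = float(rule.mz)
    if qualifier_mz is not None:
        out.append(
            Transition(
                analyte=entry.name,
                isotopologue_k=k,
                precursor_mz=float(nominal),
                product_mz=qualifier_mz,
                role="qualifier",
                ce=entry.ce_qual,
                rt_center=entry.rt_min,
                rt_window=window,
            )
        )
    return out


def build_panel_transitions(
    panel: Panel | Sequence[PanelEntry],
    window_half_width: float = DEFAULT_WINDOW_HALF_WIDTH,
) -> list[Transition]:
    """Unlabeled (k = 0) quantifier + qualifier table for the whole panel."""
    out: list[Transition] = []
    for entry in panel:
        out.extend(_entry_transitions(entry, 0, 2 * window_half_width))
    return out


def expand_isotopologue_transitions(
    panel: Panel,
    analytes: Iterable[str],
    window_half_width: float = DEFAULT_WINDOW_HALF_WIDTH,
) -> list[Transition]:
    """All-k transition channels for the selected analytes.

    Produces n_acid_carbons + 1 quantifier channels per analyte with the
    precursor shifted one nominal mass unit per label.
    """
    out: list[Transition] = []
    for name in analytes:
        entry = panel[name]  # raises KeyError if absent
        for k in range(entry.n_acid_carbons + 1):
            out.extend(_entry_transitions(entry, k, 2 * window_half_width))
    return out


def schedule_from_frame(df: pd.DataFrame) -> DMRMSchedule:
    """Rebuild a schedule from a transition CSV written by ``to_frame``."""
    transitions = [
        Transition(
            analyte=row["analyte"],
            isotopologue_k=int(row["isotopologue_k"]),
            precursor_mz=float(row["precursor_mz"]),
            product_mz=float(row["product_mz"]),
            role=row["role"],
            ce=float(row["ce_eV"]),
            rt_center=float(row["rt_min"]),
            rt_window=float(row["rt_window_min"]),
        )
        for _, row in df.iterrows()
    ]
    return DMRMSchedule(transitions=transitions)


def schedule_dmrm(
    transitions: Sequence[Transition],
    window_half_width: Optional[float] = None,
) -> DMRMSchedule:
    """Wrap a transition list in a schedule with a concurrency report.

    If ``window_half_width`` is given, every transition's window is reset
    to rt ± half-width (clipped to the run length by the window property).
    """
    ts = list(transitions)
    if window_half_width is not None:
        ts = [
            Transition(
                analyte=t.analyte,
                isotopologue_k=t.isotopologue_k,
                precursor_mz=t.precursor_mz,
                product_mz=t.product_mz,
                role=t.role,
                ce=t.ce,
                rt_center=t.rt_center,
                rt_window=2 * window_half_width,
            )
            for t in ts
        ]
    return DMRMSchedule(transitions=ts)
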