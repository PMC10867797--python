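"""Analyte panel registry and 2-picolylamine derivatization chemistry.

Each carboxyl group is converted to the 2-picolylamine (2-PA) amide:
the derivative gains C6H8N2 and loses H2O per derivatized site. For
deuterated standards the carboxyl O-D is exchangeable and leaves with the
condensation water, so exactly one fixed deuterium is dropped per
derivatized site that carries one (e.g. CD3COOD keeps three of its four
deuteriums). MRM quantitation then monitors the protonated derivative
([M+H]+) fragmenting — for most analytes — to protonated 2-PA at m/z 109.
"""

from __future__ import annotations

import math
from importlib import resources
from pathlib import Path
from typing import Literal, Optional, Union

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from .formula import ElementalFormula, parse_formula
from .isotopes import PROTON_MASS, heavy_mass

# neutral gained/lost per derivatized carboxyl site
PICOLYLAMINE = parse_formula("C6H8N2")
WATER = parse_formula("H2O")
WATER_MONO_MASS = WATER.monoisotopic_mass()  # 18.0106 Da

#: total LC run length, minutes (includes re-equilibration)
RUN_LENGTH_MIN = 17.0


class RegistryError(ValueError):
    """Raised when a panel entry is chemically or structurally invalid."""


class QualifierRule(BaseModel):
    """How the confirming (qualifier) transition is derived.

    ``water_loss`` qualifiers sit at precursor − H2O and therefore shift
    with 13C labeling; ``fixed_mz`` qualifiers are instrument-optimized
    fragments taken verbatim from the registry; ``none`` omits the
    qualifier (low-abundance analytes with a single usable fragment).
    """

    kind: Literal["fixed_mz", "water_loss", "none"]
    mz: Optional[float] = None

    @model_validator(mode="after")
    def _check_mz(self) -> "QualifierRule":
        if self.kind == "fixed_mz" and self.mz is None:
            raise ValueError("fixed_mz qualifier requires an m/z value")
        return self


class PanelEntry(BaseModel):
    """One analyte (or internal standard) of the acid panel."""

    name: str
    acid_formula: str
    n_carboxyl: int = Field(ge=1, default=1)
    n_acid_carbons: int = Field(ge=1)
    exchangeable_deuterium: int = Field(ge=0, default=0)
    rt_min: float = Field(gt=0)
    ce_quant: float
    ce_qual: Optional[float] = None
    quantifier_mz: Optional[float] = None  # override; default is 2-PA·H+ 109
    qualifier_rule: QualifierRule = QualifierRule(kind="none")
    cal_range: Optional[tuple[float, float]] = None  # μg/mL
    internal_standard: str = "self"
    is_stock_ugml: Optional[float] = None  # set only for the IS compounds

    @field_validator("cal_range")
    @classmethod
    def _range_ordered(cls, v):
        if v is not None and not v[0] < v[1]:
            raise ValueError(f"cal_range low must be < high, got {v}")
        return v

    @model_validator(mode="after")
    def _chemistry_consistent(self) -> "PanelEntry":
        f = self.formula()
        if self.n_carboxyl * 2 > f.counts.get("O", 0):
            raise RegistryError(
                f"{self.name}: {self.n_carboxyl} carboxyl sites need "
                f"{2 * self.n_carboxyl} O, formula has {f.counts.get('O', 0)}"
            )
        if self.n_acid_carbons > f.counts.get("C", 0):
            raise RegistryError(
                f"{self.name}: n_acid_carbons exceeds carbon count"
            )
        if self.qualifier_rule.kind != "none" and self.ce_qual is None:
            raise RegistryError(f"{self.name}: qualifier defined without CE")
        return self

    @property
    def is_internal_standard(self) -> bool:
        return self.is_stock_ugml is not None

    def formula(self) -> ElementalFormula:
        return parse_formula(self.acid_formula)


def derivatize(entry: PanelEntry) -> ElementalFormula:
    """Formula of the fully 2-PA-derivatized analyte.

    Adds C6H8N2 and removes H2O per carboxyl site. One fixed deuterium per
    derivatized site is converted back to ordinary hydrogen bookkeeping
    before the condensation (the carboxyl O-D leaves with the water).
    """
    f = entry.formula()
    d_lost = min(entry.exchangeable_deuterium, entry.n_carboxyl)
    if d_lost:
        heavy = dict(f.fixed_heavy)
        heavy["2H"] = heavy.get("2H", 0) - d_lost
        if heavy["2H"] < 0:
            raise RegistryError(
                f"{entry.name}: exchangeable_deuterium exceeds fixed 2H"
            )
        f = ElementalFormula(dict(f.counts), {k: v for k, v in heavy.items() if v})
    return f + PICOLYLAMINE.scale(entry.n_carboxyl) - WATER.scale(entry.n_carboxyl)


def precursor_mz(derivative: ElementalFormula) -> tuple[float, int]:
    """``(exact, nominal)`` m/z of the protonated derivative [M+H]+."""
    exact = derivative.monoisotopic_mass() + PROTON_MASS
    return exact, round(exact)


def label_isotopologue(entry: PanelEntry, k: int) -> ElementalFormula:
    """Derivative with ``k`` 13C fixed in the acid-moiety carbons.

    The 2-PA reagent is always unlabeled, so labels never exceed the acid's
    own carbon count.
    """
    if not 0 <= k <= entry.n_acid_carbons:
        raise RegistryError(
            f"{entry.name}: label count {k} outside 0..{entry.n_acid_carbons}"
        )
    derivative = derivatize(entry)
    if k == 0:
        return derivative
    return derivative.with_fixed("13C", k)


C13_SHIFT = heavy_mass("13C") - 12.0  # 1.00336 Da per label


class Panel:
    """Ordered collection of panel entries with name lookup."""

    def __init__(self, entries: list[PanelEntry]):
        self.entries = list(entries)
        self._by_name = {e.name: e for e in self.entries}
        if len(self._by_name) != len(self.entries):
            raise RegistryError("duplicate analyte names in panel")
        for e in self.entries:
            is_name = e.internal_standard
            if is_name != "self":
                target = self._by_name.get(is_name)
                if target is None or not target.is_internal_standard:
                    raise RegistryError(
                        f"{e.name}: internal standard {is_name!r} does not "
                        "resolve to an IS-flagged panel entry"
                    )

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __getitem__(self, name: str) -> PanelEntry:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"analyte {name!r} not in panel") from None

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    @property
    def analytes(self) -> list[PanelEntry]:
        return [e for e in self.entries if not e.is_internal_standard]

    @property
    def internal_standards(self) -> list[PanelEntry]:
        return [e for e in self.entries if e.is_internal_standard]

    def internal_standard_for(self, name: str) -> PanelEntry:
        entry = self[name]
        if entry.internal_standard == "self":
            return entry
        return self[entry.internal_standard]


def load_panel(path: Union[str, Path, None] = None) -> Panel:
    """Load a panel from YAML; ``None`` loads the bundled default panel."""
    if path is None:
        text = (
            resources.files("scfaquant").joinpath("data/default_panel.yaml")
        ).read_text()
    else:
        text = Path(path).read_text()
    doc = yaml.safe_load(text)
    entries = []
    for raw in doc["panel"]:
        rule = raw.get("qualifier_rule", "none")
        if isinstance(rule, (int, float)):
            raw["qualifier_rule"] = {"kind": "fixed_mz", "mz": float(rule)}
        elif isinstance(rule, str):
            raw["qualifier_rule"] = {"kind": rule}
        entries.append(PanelEntry(**raw))
    return Panel(entries)
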