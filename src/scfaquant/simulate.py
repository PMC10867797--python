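"""Synthetic dMRM chromatogram generator with known ground truth.

Peaks are exponentially modified Gaussians (EMG) — the standard model for
slightly tailing LC peaks — whose closed-form area makes every downstream
integration and quantitation step checkable against truth. The generator
reproduces the features the quantitation pipeline must cope with:

* natural-abundance isotope bleed of each labeled species into heavier
  channels (from the registry's aggregated distributions);
* a persistent acetate background signal in blanks;
* a per-sample multiplicative matrix factor applied equally to analytes
  and internal standards (exactly the effect IS-ratio calibration cancels);
* additive Gaussian detector noise on a constant baseline;
* cross-talk between isobaric analytes whose identical transitions have
  overlapping RT windows (e.g. the methylvalerate isomers at 207→109).
"""

from __future__ import annotations

import math
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy.stats import exponnorm

from .formula import natural_isotopologue_distribution
from .registry import Panel, PanelEntry, label_isotopologue
from .transitions import DMRMSchedule, Transition

#: 1:10 (v/v) IS spike → stock diluted 11-fold in the final sample
IS_DILUTION = 11.0

CHROMATOGRAM_COLUMNS = [
    "sample_id",
    "analyte",
    "isotopologue_k",
    "role",
    "time_min",
    "intensity",
]


class SimulationError(RuntimeError):
    """Raised when truth amounts cannot be represented by the schedule."""


class GroundTruthSample(BaseModel):
    """One simulated injection with its true composition."""

    sample_id: str
    role: Literal["blank", "calibrant", "sample", "spiked_sample"]
    concentrations: dict[str, dict[int, float]] = Field(default_factory=dict)
    is_concentrations: dict[str, float] = Field(default_factory=dict)
    matrix_factor: float = 1.0
    seed: int = 0

    @model_validator(mode="after")
    def _non_negative(self) -> "GroundTruthSample":
        for analyte, per_k in self.concentrations.items():
            for k, c in per_k.items():
                if c < 0:
                    raise ValueError(f"{analyte} k={k}: negative concentration")
        return self


class PeakShapeParams(BaseModel):
    """Instrument response model shared by a simulated run."""

    sigma: float = Field(gt=0, default=0.015)  # Gaussian width, min
    tau: float = Field(ge=0, default=0.006)  # exponential tail, min
    response_factors: dict[str, float] = Field(default_factory=dict)  # counts·min per μg/mL
    qualifier_rel_response: float = 0.3
    noise_sd: float = Field(ge=0, default=20.0)  # counts
    baseline: float = Field(ge=0, default=100.0)  # counts
    # environmental acetate contamination present in EVERY injection
    # (blanks exist to measure and subtract it), counts·min
    acetate_background_area: float = Field(ge=0, default=5e4)
    sampling_interval: float = Field(gt=0, default=0.01)  # min

    @classmethod
    def defaults_for_panel(cls, panel: Panel, **overrides) -> "PeakShapeParams":
        """Response factors scaled so mid-calibration-range areas ≈ 1e6."""
        rf: dict[str, float] = {}
        for entry in panel:
            if entry.cal_range is not None:
                mid = math.sqrt(entry.cal_range[0] * entry.cal_range[1])
            else:
                mid = entry.is_stock_ugml / IS_DILUTION
            rf[entry.name] = 1e6 / mid
        return cls(response_factors=rf, **overrides)


def emg_profile(
    t: np.ndarray, area: float, rt: float, sigma: float, tau: float
) -> np.ndarray:
    """EMG peak sampled at ``t`` with total (closed-form) area ``area``."""
    if tau <= 1e-9:  # pure Gaussian limit
        return (
            area / (sigma * math.sqrt(2 * math.pi))
            * np.exp(-0.5 * ((t - rt) / sigma) ** 2)
        )
    return area * exponnorm.pdf(t, tau / sigma, loc=rt, scale=sigma)


def _channel_amounts(
    panel: Panel,
    truth: dict[str, dict[int, float]],
    schedule: DMRMSchedule,
    sample_id: str = "",
) -> dict[tuple[str, int], float]:
    """Observed amount per (analyte, channel k), μg/mL equivalents.

    True species amounts are convolved with each species' own
    natural-abundance distribution, so a species with j labels puts a
    fraction p_j[d] of its amount into channel j + d.
    """
    available: dict[str, set[int]] = {}
    for tr in schedule.transitions:
        available.setdefault(tr.analyte, set()).add(tr.isotopologue_k)

    observed: dict[tuple[str, int], float] = {}
    for analyte, per_k in truth.items():
        entry = panel[analyte]
        channels = available.get(analyte, set())
        for j, amount in per_k.items():
            if amount <= 0:
                continue
            if j not in channels:
                raise SimulationError(
                    f"{sample_id}: nonzero amount for {analyte} k={j} "
                    "but the schedule has no such transition channel"
                )
            max_d = max(channels) - j
            p = natural_isotopologue_distribution(label_isotopologue(entry, j), max_d)
            for d, frac in enumerate(p):
                k = j + d
                if k in channels:
                    observed[(analyte, k)] = observed.get((analyte, k), 0.0) + amount * frac
    return observed


def _time_grid(window: tuple[float, float], dt: float) -> np.ndarray:
    i0 = math.ceil(window[0] / dt - 1e-9)
    i1 = math.floor(window[1] / dt + 1e-9)
    return np.round(np.arange(i0, i1 + 1) * dt, 6)


def simulate_chromatogram_set(
    truth: Sequence[GroundTruthSample],
    schedule: DMRMSchedule,
    shape: PeakShapeParams,
    panel: Panel,
) -> tuple[pd.DataFrame, dict]:
    """Simulate every (sample × transition) trace.

    Returns a long-format chromatogram table and a manifest dict recording
    the complete ground truth. Identical inputs (including per-sample
    seeds) produce bit-identical output.
    """
    frames: list[pd.DataFrame] = []
    for sample in truth:
        rng = np.random.default_rng(sample.seed)
        # sample composition (matrix-scaled) vs environmental contamination
        # (identical in every injection, independent of the sample matrix)
        composition: dict[str, dict[int, float]] = {
            a: dict(per_k) for a, per_k in sample.concentrations.items()
        }
        for name, conc in sample.is_concentrations.items():
            composition.setdefault(name, {})[0] = conc
        observed = _channel_amounts(panel, composition, schedule, sample.sample_id)
        background: dict[tuple[str, int], float] = {}
        has_acetate_channel = any(
            tr.analyte == "acetic acid" and tr.isotopologue_k == 0
            for tr in schedule.transitions
        )
        if (
            shape.acetate_background_area > 0
            and "acetic acid" in panel
            and has_acetate_channel
        ):
            bg_amount = shape.acetate_background_area / shape.response_factors.get(
                "acetic acid", 1e6
            )
            background = _channel_amounts(
                panel, {"acetic acid": {0: bg_amount}}, schedule, sample.sample_id
            )

        # peak area per transition, counts·min
        areas: dict[tuple[str, int, str], float] = {}
        for tr in schedule.transitions:
            key = (tr.analyte, tr.isotopologue_k)
            rf = shape.response_factors.get(tr.analyte, 1e6)
            area = rf * (
                observed.get(key, 0.0) * sample.matrix_factor
                + background.get(key, 0.0)
            )
            if tr.role == "qualifier":
                area *= shape.qualifier_rel_response
            areas[tr.key] = area

        for tr in schedule.transitions:
            t = _time_grid(tr.window, shape.sampling_interval)
            signal = np.full(t.shape, float(shape.baseline))
            # own peak plus isobaric cross-talk from identical transitions
            # whose apex falls inside this acquisition window
            for other in schedule.transitions:
                if (
                    other.precursor_mz == tr.precursor_mz
                    and other.product_mz == tr.product_mz
                    and tr.window[0] <= other.rt_center <= tr.window[1]
                ):
                    a = areas[other.key]
                    if a > 0:
                        signal += emg_profile(
                            t, a, other.rt_center, shape.sigma, shape.tau
                        )
            if shape.noise_sd > 0:
                signal += rng.normal(0.0, shape.noise_sd, size=t.shape)
            np.maximum(signal, 0.0, out=signal)
            frames.append(
                pd.DataFrame(
                    {
                        "sample_id": sample.sample_id,
                        "analyte": tr.analyte,
                        "isotopologue_k": tr.isotopologue_k,
                        "role": tr.role,
                        "time_min": t,
                        "intensity": signal,
                    }
                )
            )

    chromatograms = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=CHROMATOGRAM_COLUMNS)
    )
    manifest = {
        "schema_version": 1,
        "shape": shape.model_dump(),
        "samples": [s.model_dump() for s in truth],
    }
    return chromatograms, manifest


def default_is_concentrations(panel: Panel) -> dict[str, float]:
    """Effective in-sample IS concentrations after the 1:10 (v/v) spike."""
    return {
        e.name: e.is_stock_ugml / IS_DILUTION for e in panel.internal_standards
    }


def make_calibration_series(
    panel: Panel,
    n_levels: int,
    is_mix: Optional[dict[str, float]] = None,
    base_seed: int = 1000,
) -> list[GroundTruthSample]:
    """Pooled multi-analyte calibrants, log-spaced over each cal range.

    Level i carries every analyte at the i-th point of a geometric sequence
    spanning that analyte's own calibration range; the IS mix is present at
    its fixed effective concentration in every level.
    """
    if n_levels < 2:
        raise ValueError("need at least 2 calibration levels")
    if is_mix is None:
        is_mix = default_is_concentrations(panel)
    levels_per_analyte = {
        e.name: np.geomspace(e.cal_range[0], e.cal_range[1], n_levels)
        for e in panel.analytes
    }
    samples = []
    for i in range(n_levels):
        samples.append(
            GroundTruthSample(
                sample_id=f"cal_{i:02d}",
                role="calibrant",
                concentrations={
                    name: {0: float(levels[i])}
                    for name, levels in levels_per_analyte.items()
                },
                is_concentrations=dict(is_mix),
                seed=base_seed + i,
            )
        )
    return samples


def make_blanks(
    panel: Panel,
    n: int,
    is_mix: Optional[dict[str, float]] = None,
    base_seed: int = 2000,
) -> list[GroundTruthSample]:
    """Pseudoblanks: no analytes, IS spiked, acetate background applied."""
    if is_mix is None:
        is_mix = default_is_concentrations(panel)
    return [
        GroundTruthSample(
            sample_id=f"blank_{i:02d}",
            role="blank",
            is_concentrations=dict(is_mix),
            seed=base_seed + i,
        )
        for i in range(n)
    ]


def make_labeled_fermentation_sample(
    design: dict[str, dict[int, float]],
    totals: dict[str, float],
    sample_id: str = "fermentation",
    is_mix: Optional[dict[str, float]] = None,
    matrix_factor: float = 1.0,
    seed: int = 3000,
) -> GroundTruthSample:
    """Sample with per-analyte isotopologue fractions of a known total."""
    concentrations: dict[str, dict[int, float]] = {}
    for analyte, fractions in design.items():
        total_frac = sum(fractions.values())
        if abs(total_frac - 1.0) > 1e-9:
            raise ValueError(
                f"{analyte}: isotopologue fractions sum to {total_frac}, not 1"
            )
        total = totals[analyte]
        concentrations[analyte] = {
            int(k): total * frac for k, frac in fractions.items()
        }
    return GroundTruthSample(
        sample_id=sample_id,
        role="sample",
        concentrations=concentrations,
        is_concentrations=dict(is_mix or {}),
        matrix_factor=matrix_factor,
        seed=seed,
    )
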