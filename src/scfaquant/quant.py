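"""Calibration, validation metrics, and isotopologue correction.

Quantitation follows the external-calibration / internal-standard scheme:
the analyte-to-IS area ratio is regressed on concentration over each
analyte's calibration range (weighted least squares, 1/x by default since
the ranges span up to three orders of magnitude), and unknowns are read
off the fitted line. Signals are blank-corrected first — most importantly
for acetate, whose environmental background is substantial.

Validation metrics are the conventional ones: CV = σ/μ over replicates,
spike-in recovery = measured / (base + nominal spike), and
LOD = 3.9 · SD(blank signals) / slope.

For 13C tracer data, each labeled species bleeds into heavier channels
through natural isotope abundance. The correction walks the channels in
ascending label count and subtracts, from each channel, the bleed
predicted from every lighter (already corrected) species, scaled by that
species' distribution relative to its own monoisotopic channel. A
``monoisotopic_only`` mode subtracts only the unlabeled species'
distribution (the narrower reading of the same procedure).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import statsmodels.api as sm

from .formula import natural_isotopologue_distribution
from .registry import Panel, PanelEntry, label_isotopologue

LOD_FACTOR = 3.9  # multiplier on the blank-signal SD

Weighting = Literal["none", "1/x", "1/x2"]
CorrectionMode = Literal["cascade", "monoisotopic_only"]


class QuantError(ValueError):
    pass


@dataclass(frozen=True)
class CalibrationModel:
    """Fitted IS-ratio calibration line for one analyte."""

    analyte: str
    slope: float  # ratio per (μg/mL)
    intercept: float  # ratio
    r2: float
    weighting: Weighting
    cal_range: tuple[float, float]
    is_name: str
    lod: Optional[float] = None  # μg/mL, filled in when blanks are available

    def concentration(self, ratio: float) -> float:
        return (ratio - self.intercept) / self.slope


@dataclass
class QuantRecord:
    """Per-sample, per-channel quantitation output."""

    sample_id: str
    analyte: str
    isotopologue_k: int
    raw_area: float
    background_corrected_area: float
    is_area: float
    ratio: Optional[float]
    concentration: Optional[float]  # μg/mL
    corrected_concentration: Optional[float] = None  # post isotope correction
    flags: list[str] = field(default_factory=list)

    @property
    def flags_str(self) -> str:
        return ";".join(self.flags)


# --------------------------------------------------------------------------
# signal-level operations
# --------------------------------------------------------------------------


def background_correct(
    sample_area: float, blank_areas: Sequence[float]
) -> tuple[float, bool]:
    """Subtract the mean blank signal; floor at zero.

    Returns ``(corrected_area, clipped)`` where ``clipped`` marks areas
    that fell below the blank mean.
    """
    if len(blank_areas) == 0:
        raise QuantError("background correction requested without blanks")
    corrected = sample_area - float(np.mean(blank_areas))
    if corrected < 0:
        return 0.0, True
    return corrected, False


def fit_calibration(
    levels: Sequence[tuple[float, float]],
    analyte: str = "",
    weighting: Weighting = "1/x",
    cal_range: Optional[tuple[float, float]] = None,
    is_name: str = "",
) -> CalibrationModel:
    """Weighted least-squares fit of IS ratio on concentration.

    ``levels`` are (concentration μg/mL, analyte/IS ratio) pairs; at least
    three distinct concentrations are required.
    """
    conc = np.asarray([c for c, _ in levels], dtype=float)
    ratio = np.asarray([r for _, r in levels], dtype=float)
    if len(np.unique(conc)) < 3:
        raise QuantError(f"{analyte}: need >= 3 distinct calibration levels")
    if np.ptp(ratio) == 0:
        raise QuantError(f"{analyte}: calibration ratios have zero variance")
    if weighting == "none":
        w = np.ones_like(conc)
    elif weighting == "1/x":
        w = 1.0 / conc
    elif weighting == "1/x2":
        w = 1.0 / conc**2
    else:  # pragma: no cover - guarded by typing
        raise QuantError(f"unknown weighting {weighting!r}")
    fit = sm.WLS(ratio, sm.add_constant(conc), weights=w).fit()
    if cal_range is None:
        cal_range = (float(conc.min()), float(conc.max()))
    return CalibrationModel(
        analyte=analyte,
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r2=float(fit.rsquared),
        weighting=weighting,
        cal_range=cal_range,
        is_name=is_name,
    )


def compute_lod(blank_signals: Sequence[float], model: CalibrationModel) -> float:
    """LOD = 3.9 × sample SD of the blank signals / calibration slope.

    Signals must be in the same units the slope maps from (here: the
    analyte/IS ratio domain used throughout the pipeline).
    """
    if len(blank_signals) < 3:
        raise QuantError("need >= 3 blank signals for an LOD estimate")
    if model.slope <= 0:
        raise QuantError(f"{model.analyte}: non-positive calibration slope")
    sd = float(np.std(blank_signals, ddof=1))
    return LOD_FACTOR * sd / model.slope


def quantify(
    sample_id: str,
    analyte: str,
    isotopologue_k: int,
    raw_area: float,
    is_area: float,
    model: CalibrationModel,
    blank_areas: Sequence[float] = (),
) -> QuantRecord:
    """Blank-correct, ratio against the IS, and invert the calibration."""
    flags: list[str] = []
    if blank_areas:
        corrected, clipped = background_correct(raw_area, blank_areas)
        if clipped:
            flags.append("clipped_negative")
    else:
        corrected = raw_area
    if is_area <= 0:
        flags.append("is_missing")
        return QuantRecord(
            sample_id, analyte, isotopologue_k, raw_area, corrected,
            is_area, None, None, flags=flags,
        )
    ratio = corrected / is_area
    conc = model.concentration(ratio)
    if conc < 0:
        conc = 0.0
        flags.append("clipped_negative")
    if model.lod is not None and conc < model.lod:
        flags.append("below_lod")
    lo, hi = model.cal_range
    if conc < lo:
        flags.append("below_range")
    elif conc > hi:
        flags.append("above_range")
    return QuantRecord(
        sample_id, analyte, isotopologue_k, raw_area, corrected,
        is_area, ratio, conc, flags=flags,
    )


# --------------------------------------------------------------------------
# validation metrics
# --------------------------------------------------------------------------


def recovery_rate(
    measured_after_spike: float, base_measured: float, nominal_spike: float
) -> float:
    """measured / (base + nominal spike); 1.0 is perfect recovery."""
    if nominal_spike <= 0:
        raise QuantError("nominal spike must be positive")
    expected = base_measured + nominal_spike
    if expected <= 0:
        raise QuantError("expected post-spike concentration must be positive")
    return measured_after_spike / expected


def coefficient_of_variation(replicates: Sequence[float]) -> float:
    """Sample SD over mean of replicate concentrations."""
    x = np.asarray(replicates, dtype=float)
    if len(x) < 2:
        raise QuantError("CV needs >= 2 replicates")
    mean = float(np.mean(x))
    if mean <= 0:
        raise QuantError("CV undefined for non-positive mean")
    return float(np.std(x, ddof=1)) / mean


# --------------------------------------------------------------------------
# natural-abundance isotopologue correction
# --------------------------------------------------------------------------


def correction_matrix(entry: PanelEntry, n_channels: Optional[int] = None) -> np.ndarray:
    """Lower-triangular bleed matrix over the analyte's label channels.

    ``M[i, j]`` is the natural-abundance fraction of the j-labeled
    derivative appearing in channel ``i`` (its own distribution shifted by
    j); the diagonal holds each species' monoisotopic fraction p0.
    """
    K = entry.n_acid_carbons if n_channels is None else n_channels - 1
    M = np.zeros((K + 1, K + 1))
    for j in range(K + 1):
        p = natural_isotopologue_distribution(label_isotopologue(entry, j), K - j)
        M[j:, j] = p
    return M


def correct_natural_abundance(
    c_obs: Sequence[float],
    entry: PanelEntry,
    mode: CorrectionMode = "cascade",
) -> tuple[np.ndarray, list[int]]:
    """Remove natural-abundance bleed from observed channel concentrations.

    Channels are quantified against the unlabeled calibration curve, so a
    species contributes to heavier channels in proportion to its
    distribution relative to its own monoisotopic channel. Ascending in k:

    ``c_corr[k] = c_obs[k] − Σ_{j<k} c_corr[j] · M[k,j] / M[j,j]``

    floored at zero (clipped channel indices are returned alongside). In
    ``monoisotopic_only`` mode only the unlabeled (k = 0) species'
    distribution is subtracted.
    """
    c = np.asarray(c_obs, dtype=float)
    if np.any(c < 0):
        raise QuantError("observed isotopologue concentrations must be >= 0")
    K = len(c) - 1
    if K > entry.n_acid_carbons:
        raise QuantError(
            f"{entry.name}: {K + 1} channels but only "
            f"{entry.n_acid_carbons + 1} label configurations exist"
        )
    M = correction_matrix(entry, n_channels=K + 1)
    corr = np.zeros_like(c)
    clipped: list[int] = []
    for k in range(K + 1):
        bleed = 0.0
        sources = [0] if (mode == "monoisotopic_only" and k > 0) else range(k)
        for j in sources:
            bleed += corr[j] * M[k, j] / M[j, j]
        value = c[k] - bleed
        if value < 0:
            value = 0.0
            clipped.append(k)
        corr[k] = value
    return corr, clipped
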