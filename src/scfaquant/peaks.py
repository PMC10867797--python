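"""Baseline estimation and trapezoidal peak integration per transition.

Deliberately simple and fully deterministic: baseline from the window
flanks, apex search optionally constrained near the scheduled retention
time (which disambiguates isobaric analytes sharing a window), peak bounds
walked outward from the apex until the signal returns to 1% of the peak
height, trapezoidal area on the native sampling grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .simulate import CHROMATOGRAM_COLUMNS
from .transitions import DMRMSchedule

#: fraction of the window treated as baseline flank on each side
FLANK_FRACTION = 0.15
#: peak bound: walk from apex until intensity <= this fraction of height
BOUND_FRACTION = 0.01
#: half-width of the apex search region around an expected RT, minutes
APEX_SEARCH_HALF_WIDTH = 0.1

PEAK_COLUMNS = [
    "sample_id",
    "analyte",
    "isotopologue_k",
    "role",
    "area",
    "height",
    "apex_rt",
    "snr",
    "flags",
]


class IntegrationError(ValueError):
    """Raised for windows that cannot be integrated."""


@dataclass(frozen=True)
class Chromatogram:
    """Time/intensity trace of one transition in one sample."""

    time: np.ndarray  # minutes, strictly increasing
    intensity: np.ndarray  # counts

    def __post_init__(self) -> None:
        if len(self.time) != len(self.intensity):
            raise IntegrationError("time and intensity lengths differ")
        if len(self.time) > 1 and not np.all(np.diff(self.time) > 0):
            raise IntegrationError("time axis must be strictly increasing")


@dataclass(frozen=True)
class PeakResult:
    area: float  # counts·min, baseline-corrected
    height: float  # counts above baseline
    apex_rt: float  # minutes
    snr: float
    no_peak: bool = False
    edge_truncated: bool = False

    @property
    def flags(self) -> str:
        out = []
        if self.no_peak:
            out.append("no_peak")
        if self.edge_truncated:
            out.append("edge_truncated")
        return ";".join(out)


def _flank_values(chrom: Chromatogram, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    span = hi - lo
    mask = ((chrom.time >= lo) & (chrom.time <= lo + FLANK_FRACTION * span)) | (
        (chrom.time >= hi - FLANK_FRACTION * span) & (chrom.time <= hi)
    )
    return chrom.intensity[mask]


def estimate_baseline(chrom: Chromatogram, window: tuple[float, float]) -> float:
    """Median of the lowest-decile intensities in the window flanks."""
    flanks = _flank_values(chrom, window)
    if len(flanks) < 5:
        raise IntegrationError(
            f"only {len(flanks)} flank points in window {window}; need >= 5"
        )
    n_low = max(1, math.ceil(0.1 * len(flanks)))
    lowest = np.sort(flanks)[:n_low]
    return float(np.median(lowest))


def _flank_noise_sd(chrom: Chromatogram, window: tuple[float, float]) -> float:
    """Robust (MAD-based) noise SD of the window flanks."""
    flanks = _flank_values(chrom, window)
    mad = np.median(np.abs(flanks - np.median(flanks)))
    return float(1.4826 * mad)


def integrate_peak(
    chrom: Chromatogram,
    window: tuple[float, float],
    expected_rt: Optional[float] = None,
) -> PeakResult:
    """Integrate the (single) peak in ``window``.

    With ``expected_rt`` set, the apex is the intensity maximum within
    ±0.1 min of that time; otherwise the window-wide maximum. Apex ties
    resolve to the earliest time. Intensities are baseline-subtracted and
    floored at zero before the trapezoidal sum between the peak bounds.
    """
    lo, hi = window
    in_window = (chrom.time >= lo) & (chrom.time <= hi)
    if not np.any(in_window):
        raise IntegrationError(f"no data points in window {window}")
    t = chrom.time[in_window]
    baseline = estimate_baseline(chrom, window)
    y = np.maximum(chrom.intensity[in_window] - baseline, 0.0)

    if expected_rt is None:
        search = np.ones(len(t), dtype=bool)
    else:
        search = np.abs(t - expected_rt) <= APEX_SEARCH_HALF_WIDTH
        if not np.any(search):
            search = np.ones(len(t), dtype=bool)

    noise_sd = _flank_noise_sd(chrom, window)
    # the apex must be a genuine local maximum inside the search region —
    # a monotone flank there belongs to a neighbouring (isobaric) peak.
    # plateau_size=0 exposes plateau left edges: earliest-time tie-break.
    # width ≥ 3 samples at half prominence: single-sample noise spikes are
    # not chromatographic peaks
    candidates, props = find_peaks(
        y, prominence=max(3 * noise_sd, 1e-12), width=3, plateau_size=0
    )
    candidates = props["left_edges"][search[candidates]]
    if len(candidates) == 0:
        fallback = int(np.flatnonzero(search)[np.argmax(y[search])])
        height = float(y[fallback])
        snr = height / noise_sd if noise_sd > 0 else math.inf
        return PeakResult(0.0, height, float(t[fallback]), snr, no_peak=True)
    apex = int(candidates[np.argmax(y[candidates])])  # argmax → earliest tie
    height = float(y[apex])

    # detection height against the robust flank centre (the lowest-decile
    # area baseline sits deliberately low and would inflate noise apexes)
    flank_centre = float(np.median(_flank_values(chrom, window))) - baseline
    snr = height / noise_sd if noise_sd > 0 else math.inf
    if height <= 0 or (noise_sd > 0 and height - flank_centre < 3 * noise_sd):
        return PeakResult(0.0, height, float(t[apex]), snr, no_peak=True)

    threshold = BOUND_FRACTION * height
    left = apex
    while left > 0 and y[left] > threshold:
        left -= 1
    right = apex
    while right < len(y) - 1 and y[right] > threshold:
        right += 1
    edge_truncated = (left == 0 and y[left] > threshold) or (
        right == len(y) - 1 and y[right] > threshold
    )
    area = float(np.trapezoid(y[left : right + 1], t[left : right + 1]))
    return PeakResult(
        area=area,
        height=height,
        apex_rt=float(t[apex]),
        snr=snr,
        edge_truncated=edge_truncated,
    )


def integrate_run(
    chromatograms: pd.DataFrame, schedule: DMRMSchedule
) -> pd.DataFrame:
    """Integrate every (sample × transition) trace of a long-format table.

    Expects the simulator/instrument-export columns
    ``sample_id,analyte,isotopologue_k,role,time_min,intensity`` and
    returns one peak row per trace.
    """
    missing = set(CHROMATOGRAM_COLUMNS) - set(chromatograms.columns)
    if missing:
        raise IntegrationError(f"chromatogram table missing columns: {sorted(missing)}")
    rows = []
    by_key = {t.key: t for t in schedule.transitions}
    grouped = chromatograms.groupby(
        ["sample_id", "analyte", "isotopologue_k", "role"], sort=False
    )
    for (sample_id, analyte, k, role), grp in grouped:
        tr = by_key.get((analyte, int(k), role))
        if tr is None:
            continue
        chrom = Chromatogram(
            time=grp["time_min"].to_numpy(float),
            intensity=grp["intensity"].to_numpy(float),
        )
        res = integrate_peak(chrom, tr.window, expected_rt=tr.rt_center)
        rows.append(
            {
                "sample_id": sample_id,
                "analyte": analyte,
                "isotopologue_k": int(k),
                "role": role,
                "area": res.area,
                "height": res.height,
                "apex_rt": res.apex_rt,
                "snr": res.snr,
                "flags": res.flags,
            }
        )
    return pd.DataFrame(rows, columns=PEAK_COLUMNS)
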