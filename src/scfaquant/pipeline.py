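"""End-to-end orchestration: peak table → calibrations → quant report.

The pipeline consumes the long-format peak table (from
:func:`scfaquant.peaks.integrate_run` or an instrument export in the same
layout) plus the sample manifest describing each injection's role (blank /
calibrant / sample) and, for calibrants, the true concentrations. It fits
one IS-ratio calibration per analyte, blank-corrects every signal,
quantifies all channels against the unlabeled (k = 0) curve, and applies
the natural-abundance isotopologue correction across each analyte's label
channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .quant import (
    CalibrationModel,
    CorrectionMode,
    QuantError,
    Weighting,
    coefficient_of_variation,
    compute_lod,
    correct_natural_abundance,
    fit_calibration,
    quantify,
    recovery_rate,
)
from .registry import Panel
from .simulate import GroundTruthSample

def realize_design(config) -> tuple:
    """Turn a :class:`scfaquant.config.RunConfig` into concrete run inputs.

    Returns ``(panel, schedule, shape, samples)``; sample seeds are derived
    deterministically from the config seed.
    """
    from .registry import load_panel
    from .simulate import (
        PeakShapeParams,
        default_is_concentrations,
        make_blanks,
        make_calibration_series,
        make_labeled_fermentation_sample,
    )
    from .transitions import (
        build_panel_transitions,
        expand_isotopologue_transitions,
        schedule_dmrm,
    )

    panel = load_panel(config.panel_path)
    transitions = build_panel_transitions(panel, config.window_half_width)
    if config.labeled_analytes:
        seen = {t.key for t in transitions}
        for t in expand_isotopologue_transitions(
            panel, config.labeled_analytes, config.window_half_width
        ):
            if t.key not in seen:
                seen.add(t.key)
                transitions.append(t)
    schedule = schedule_dmrm(transitions)
    shape = PeakShapeParams.defaults_for_panel(panel, **config.shape)
    is_mix = default_is_concentrations(panel)

    samples = make_calibration_series(
        panel, config.n_calibration_levels, is_mix, base_seed=config.seed * 1000 + 1
    )
    samples += make_blanks(
        panel, config.n_blanks, is_mix, base_seed=config.seed * 1000 + 101
    )
    for i, design in enumerate(config.samples):
        seed = config.seed * 1000 + 201 + i
        if design.fractions:
            samples.append(
                make_labeled_fermentation_sample(
                    design.fractions,
                    design.totals,
                    sample_id=design.sample_id,
                    is_mix=is_mix,
                    matrix_factor=design.matrix_factor,
                    seed=seed,
                )
            )
        else:
            samples.append(
                GroundTruthSample(
                    sample_id=design.sample_id,
                    role=design.role,
                    concentrations=design.concentrations,
                    is_concentrations=is_mix,
                    matrix_factor=design.matrix_factor,
                    seed=seed,
                )
            )
    return panel, schedule, shape, samples


QUANT_COLUMNS = [
    "sample_id",
    "analyte",
    "isotopologue_k",
    "raw_area",
    "background_corrected_area",
    "is_area",
    "ratio",
    "concentration_ugml",
    "corrected_concentration_ugml",
    "flags",
]


@dataclass
class QuantRun:
    """Everything produced by one quantitation pass."""

    quant: pd.DataFrame
    calibrations: dict[str, CalibrationModel]
    blank_areas: dict[tuple[str, int], list[float]] = field(default_factory=dict)


def _quantifier_areas(peaks: pd.DataFrame) -> pd.DataFrame:
    q = peaks[peaks["role"] == "quantifier"]
    return q.set_index(["sample_id", "analyte", "isotopologue_k"])["area"]


def quantify_run(
    peaks: pd.DataFrame,
    samples: Sequence[GroundTruthSample],
    panel: Panel,
    weighting: Weighting = "1/x",
    correction_mode: CorrectionMode = "cascade",
    background_correction: bool = True,
) -> QuantRun:
    """Calibrate and quantify a full run from its peak table and manifest."""
    areas = _quantifier_areas(peaks)
    by_role: dict[str, list[GroundTruthSample]] = {}
    for s in samples:
        by_role.setdefault(s.role, []).append(s)
    calibrants = by_role.get("calibrant", [])
    blanks = by_role.get("blank", [])
    unknowns = by_role.get("sample", []) + by_role.get("spiked_sample", [])
    if not calibrants:
        raise QuantError("run contains no calibrant samples")

    def area_of(sample_id: str, analyte: str, k: int = 0) -> float:
        try:
            return float(areas.loc[(sample_id, analyte, k)])
        except KeyError:
            return 0.0

    def is_area_of(sample_id: str, analyte: str) -> float:
        is_entry = panel.internal_standard_for(analyte)
        return area_of(sample_id, is_entry.name, 0)

    # blank signal pools per channel (areas) and per analyte (ratios)
    blank_areas: dict[tuple[str, int], list[float]] = {}
    blank_ratios: dict[str, list[float]] = {}
    for b in blanks:
        if b.sample_id in areas.index.get_level_values(0):
            for (sid, analyte, k), area in areas.loc[[b.sample_id]].items():
                blank_areas.setdefault((analyte, int(k)), []).append(float(area))
        for entry in panel.analytes:
            is_area = is_area_of(b.sample_id, entry.name)
            if is_area > 0:
                blank_ratios.setdefault(entry.name, []).append(
                    area_of(b.sample_id, entry.name, 0) / is_area
                )

    # per-analyte calibration on blank-corrected IS ratios
    calibrations: dict[str, CalibrationModel] = {}
    for entry in panel.analytes:
        channel_blanks = (
            blank_areas.get((entry.name, 0), []) if background_correction else []
        )
        levels = []
        for cal in calibrants:
            conc = cal.concentrations.get(entry.name, {}).get(0)
            if conc is None:
                continue
            raw = area_of(cal.sample_id, entry.name, 0)
            corrected = raw - float(np.mean(channel_blanks)) if channel_blanks else raw
            is_area = is_area_of(cal.sample_id, entry.name)
            if is_area <= 0:
                continue
            levels.append((conc, max(corrected, 0.0) / is_area))
        model = fit_calibration(
            levels,
            analyte=entry.name,
            weighting=weighting,
            cal_range=entry.cal_range,
            is_name=panel.internal_standard_for(entry.name).name,
        )
        if len(blank_ratios.get(entry.name, [])) >= 3:
            model = CalibrationModel(
                **{**model.__dict__, "lod": compute_lod(blank_ratios[entry.name], model)}
            )
        calibrations[entry.name] = model

    # quantify every analyte channel of every unknown
    records = []
    for sample in unknowns:
        sample_channels = [
            (analyte, int(k))
            for (sid, analyte, k) in areas.index
            if sid == sample.sample_id
            and analyte in panel
            and not panel[analyte].is_internal_standard
        ]
        for analyte, k in sorted(set(sample_channels)):
            model = calibrations[analyte]
            rec = quantify(
                sample.sample_id,
                analyte,
                k,
                raw_area=area_of(sample.sample_id, analyte, k),
                is_area=is_area_of(sample.sample_id, analyte),
                model=model,
                blank_areas=(
                    blank_areas.get((analyte, k), []) if background_correction else []
                ),
            )
            records.append(rec)

    # natural-abundance correction across each analyte's channels
    by_sample_analyte: dict[tuple[str, str], list] = {}
    for rec in records:
        by_sample_analyte.setdefault((rec.sample_id, rec.analyte), []).append(rec)
    for (sid, analyte), recs in by_sample_analyte.items():
        recs.sort(key=lambda r: r.isotopologue_k)
        ks = [r.isotopologue_k for r in recs]
        if ks != list(range(len(ks))) or any(r.concentration is None for r in recs):
            for r in recs:
                r.corrected_concentration = r.concentration
            continue
        if len(recs) == 1:
            recs[0].corrected_concentration = recs[0].concentration
            continue
        corr, clipped = correct_natural_abundance(
            [r.concentration for r in recs], panel[analyte], mode=correction_mode
        )
        for r, value in zip(recs, corr):
            r.corrected_concentration = float(value)
            if r.isotopologue_k in clipped:
                r.flags.append("clipped_negative")

    quant = pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "analyte": r.analyte,
                "isotopologue_k": r.isotopologue_k,
                "raw_area": r.raw_area,
                "background_corrected_area": r.background_corrected_area,
                "is_area": r.is_area,
                "ratio": r.ratio,
                "concentration_ugml": r.concentration,
                "corrected_concentration_ugml": r.corrected_concentration,
                "flags": r.flags_str,
            }
            for r in records
        ],
        columns=QUANT_COLUMNS,
    )
    return QuantRun(quant=quant, calibrations=calibrations, blank_areas=blank_areas)


def replicate_cv(
    quant: pd.DataFrame, sample_ids: Sequence[str], isotopologue_k: int = 0
) -> dict[str, float]:
    """CV per analyte over a set of replicate injections."""
    sub = quant[
        quant["sample_id"].isin(sample_ids)
        & (quant["isotopologue_k"] == isotopologue_k)
    ]
    out = {}
    for analyte, grp in sub.groupby("analyte"):
        out[analyte] = coefficient_of_variation(
            grp["concentration_ugml"].to_numpy(float)
        )
    return out


def spike_recovery(
    quant: pd.DataFrame,
    base_sample_id: str,
    spiked_sample_id: str,
    nominal_spikes: dict[str, float],
    isotopologue_k: int = 0,
) -> dict[str, float]:
    """Spike-in recovery per analyte (1.0 = perfect)."""
    sub = quant[quant["isotopologue_k"] == isotopologue_k].set_index(
        ["sample_id", "analyte"]
    )["concentration_ugml"]
    out = {}
    for analyte, spike in nominal_spikes.items():
        base = float(sub.loc[(base_sample_id, analyte)])
        measured = float(sub.loc[(spiked_sample_id, analyte)])
        out[analyte] = recovery_rate(measured, base, spike)
    return out
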