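"""Synthetic chromatogram generator: areas, bleed, and determinism."""

import numpy as np
import pytest

from scfaquant.formula import natural_isotopologue_distribution
from scfaquant.registry import label_isotopologue
from scfaquant.simulate import (
    GroundTruthSample,
    PeakShapeParams,
    SimulationError,
    make_calibration_series,
    make_labeled_fermentation_sample,
    simulate_chromatogram_set,
)
from scfaquant.transitions import build_panel_transitions, schedule_dmrm


def _quiet_shape(panel, **overrides):
    defaults = dict(noise_sd=0.0, baseline=0.0, acetate_background_area=0.0)
    defaults.update(overrides)
    return PeakShapeParams.defaults_for_panel(panel, **defaults)


def _trace(chrom, sample_id, analyte, k=0, role="quantifier"):
    sel = chrom[
        (chrom.sample_id == sample_id)
        & (chrom.analyte == analyte)
        & (chrom.isotopologue_k == k)
        & (chrom.role == role)
    ]
    return sel["time_min"].to_numpy(), sel["intensity"].to_numpy()


def test_zero_sample_gives_zero_traces(panel):
    sched = schedule_dmrm(build_panel_transitions(panel))
    sample = GroundTruthSample(sample_id="s0", role="sample", seed=1)
    chrom, _ = simulate_chromatogram_set([sample], sched, _quiet_shape(panel), panel)
    assert (chrom["intensity"] == 0).all()


def test_noiseless_trapezoid_area_matches_closed_form(panel):
    """EMG area oracle: trapezoid on the native grid within 0.5%."""
    sched = schedule_dmrm(build_panel_transitions(panel))
    shape = _quiet_shape(panel)
    conc = 50.0
    sample = GroundTruthSample(
        sample_id="s", role="sample",
        concentrations={"butyric acid": {0: conc}}, seed=1,
    )
    chrom, _ = simulate_chromatogram_set([sample], sched, shape, panel)
    t, y = _trace(chrom, "s", "butyric acid")
    p0 = natural_isotopologue_distribution(
        label_isotopologue(panel["butyric acid"], 0), 0
    )[0]
    expected = conc * shape.response_factors["butyric acid"] * p0
    assert np.trapezoid(y, t) == pytest.approx(expected, rel=0.005)


def test_natural_abundance_bleed_ratio(panel):
    """Unlabeled acetate puts ~9.5% of its M0 signal into the k=1 channel."""
    from scfaquant.transitions import expand_isotopologue_transitions

    sched = schedule_dmrm(expand_isotopologue_transitions(panel, ["acetic acid"]))
    sample = GroundTruthSample(
        sample_id="s", role="sample",
        concentrations={"acetic acid": {0: 100.0}}, seed=1,
    )
    chrom, _ = simulate_chromatogram_set([sample], sched, _quiet_shape(panel), panel)
    t0, y0 = _trace(chrom, "s", "acetic acid", k=0)
    t1, y1 = _trace(chrom, "s", "acetic acid", k=1)
    ratio = np.trapezoid(y1, t1) / np.trapezoid(y0, t0)
    assert ratio == pytest.approx(0.095, abs=0.002)


def test_bleed_conserves_total_area(panel):
    """Channel areas sum to RF × amount × (distribution mass in channels)."""
    from scfaquant.transitions import expand_isotopologue_transitions

    sched = schedule_dmrm(expand_isotopologue_transitions(panel, ["acetic acid"]))
    shape = _quiet_shape(panel)
    sample = GroundTruthSample(
        sample_id="s", role="sample",
        concentrations={"acetic acid": {0: 100.0}}, seed=1,
    )
    chrom, _ = simulate_chromatogram_set([sample], sched, shape, panel)
    total = 0.0
    for k in range(3):
        t, y = _trace(chrom, "s", "acetic acid", k=k)
        total += np.trapezoid(y, t)
    p = natural_isotopologue_distribution(
        label_isotopologue(panel["acetic acid"], 0), 2
    )
    expected = 100.0 * shape.response_factors["acetic acid"] * p.sum()
    assert total == pytest.approx(expected, rel=0.005)


def test_identical_seed_bit_identical(panel, is_mix):
    sched = schedule_dmrm(build_panel_transitions(panel))
    shape = PeakShapeParams.defaults_for_panel(panel)
    samples = [
        GroundTruthSample(
            sample_id="s", role="sample",
            concentrations={"acetic acid": {0: 50.0}},
            is_concentrations=is_mix, seed=77,
        )
    ]
    a, _ = simulate_chromatogram_set(samples, sched, shape, panel)
    b, _ = simulate_chromatogram_set(samples, sched, shape, panel)
    assert a.equals(b)


def test_missing_channel_is_hard_error(panel):
    """Nonzero truth without a transition must not be silently dropped."""
    sched = schedule_dmrm(build_panel_transitions(panel))  # k=0 only
    sample = GroundTruthSample(
        sample_id="s", role="sample",
        concentrations={"acetic acid": {2: 10.0}}, seed=1,
    )
    with pytest.raises(SimulationError):
        simulate_chromatogram_set([sample], sched, _quiet_shape(panel), panel)


def test_blank_carries_acetate_background(panel):
    sched = schedule_dmrm(build_panel_transitions(panel))
    shape = _quiet_shape(panel, acetate_background_area=5e4)
    blank = GroundTruthSample(sample_id="b", role="blank", seed=1)
    chrom, _ = simulate_chromatogram_set([blank], sched, shape, panel)
    t, y = _trace(chrom, "b", "acetic acid")
    p0 = natural_isotopologue_distribution(
        label_isotopologue(panel["acetic acid"], 0), 0
    )[0]
    assert np.trapezoid(y, t) == pytest.approx(5e4 * p0, rel=0.005)


@pytest.mark.parametrize(
    "name,low,high",
    [("acetic acid", 5.0, 500.0), ("caproic acid", 0.001, 1.0)],
)
def test_calibration_series_spans_cal_range(panel, name, low, high):
    series = make_calibration_series(panel, 2)
    assert series[0].concentrations[name][0] == pytest.approx(low)
    assert series[-1].concentrations[name][0] == pytest.approx(high)


def test_calibration_series_is_geometric(panel):
    series = make_calibration_series(panel, 5)
    levels = [s.concentrations["acetic acid"][0] for s in series]
    ratios = np.diff(np.log(levels))
    np.testing.assert_allclose(ratios, ratios[0], rtol=1e-9)
    assert levels[0] == pytest.approx(5.0) and levels[-1] == pytest.approx(500.0)


def test_calibration_series_includes_is_mix(panel, is_mix):
    for s in make_calibration_series(panel, 3):
        assert s.is_concentrations == is_mix


def test_labeled_sample_conserves_total():
    s = make_labeled_fermentation_sample(
        {"butyric acid": {0: 0.5, 2: 0.5}}, {"butyric acid": 40.0}
    )
    assert s.concentrations["butyric acid"] == {0: 20.0, 2: 20.0}
    assert sum(s.concentrations["butyric acid"].values()) == pytest.approx(40.0)


def test_labeled_sample_pure_isotopologue():
    s = make_labeled_fermentation_sample(
        {"acetic acid": {2: 1.0}}, {"acetic acid": 100.0}
    )
    assert s.concentrations["acetic acid"] == {2: 100.0}


def test_labeled_sample_rejects_bad_fractions():
    with pytest.raises(ValueError):
        make_labeled_fermentation_sample(
            {"acetic acid": {0: 0.6, 2: 0.6}}, {"acetic acid": 10.0}
        )
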