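"""Calibration, validation metrics, and isotopologue correction."""

import numpy as np
import pytest

from scfaquant.quant import (
    CalibrationModel,
    QuantError,
    background_correct,
    coefficient_of_variation,
    compute_lod,
    correct_natural_abundance,
    correction_matrix,
    fit_calibration,
    quantify,
    recovery_rate,
)


def _model(slope=1.0, intercept=0.0, lod=None, cal_range=(0.001, 500.0)):
    return CalibrationModel(
        analyte="x", slope=slope, intercept=intercept, r2=1.0,
        weighting="none", cal_range=cal_range, is_name="is", lod=lod,
    )


# -- background correction -------------------------------------------------


def test_background_subtracts_blank_mean():
    assert background_correct(1000.0, [100.0, 120.0]) == (890.0, False)


def test_background_floors_at_zero():
    corrected, clipped = background_correct(50.0, [110.0])
    assert corrected == 0.0 and clipped


def test_background_requires_blanks():
    with pytest.raises(QuantError):
        background_correct(100.0, [])


def test_blank_self_correction_centres_at_zero():
    """Leave-one-out blank correction scatters around zero."""
    rng = np.random.default_rng(11)
    blanks = rng.normal(500.0, 20.0, size=200)
    residuals = [
        background_correct(b, np.delete(blanks, i))[0]
        - max(0.0, b - np.delete(blanks, i).mean())
        for i, b in enumerate(blanks)
    ]
    assert np.allclose(residuals, 0)
    signed = [b - np.delete(blanks, i).mean() for i, b in enumerate(blanks)]
    assert abs(np.mean(signed)) < 5.0


# -- calibration and LOD ---------------------------------------------------


def test_fit_exact_line():
    m = fit_calibration([(1, 1), (2, 2), (4, 4)])
    assert m.slope == pytest.approx(1.0)
    assert m.intercept == pytest.approx(0.0, abs=1e-12)
    assert m.r2 == pytest.approx(1.0)


@pytest.mark.parametrize("weighting", ["none", "1/x", "1/x2"])
def test_fit_weighting_recovers_true_line(weighting):
    conc = np.geomspace(0.1, 100, 6)
    m = fit_calibration([(c, 0.5 * c + 0.1) for c in conc], weighting=weighting)
    assert m.slope == pytest.approx(0.5, rel=1e-9)
    assert m.intercept == pytest.approx(0.1, rel=1e-6)


def test_fit_rejects_degenerate():
    with pytest.raises(QuantError):
        fit_calibration([(1, 1), (2, 2)])  # too few levels
    with pytest.raises(QuantError):
        fit_calibration([(1, 3), (2, 3), (4, 3)])  # zero-variance ratios


def test_lod_formula():
    blanks = [0.0, 100.0, 200.0]  # SD = 100
    m = _model(slope=2000.0)
    assert compute_lod(blanks, m) == pytest.approx(3.9 * 100.0 / 2000.0)


def test_lod_scaling_laws():
    blanks = np.array([10.0, 20.0, 30.0])
    base = compute_lod(blanks, _model(slope=2.0))
    assert compute_lod(2 * blanks, _model(slope=2.0)) == pytest.approx(2 * base)
    assert compute_lod(blanks, _model(slope=4.0)) == pytest.approx(base / 2)
    assert compute_lod([5.0, 5.0, 5.0], _model(slope=2.0)) == 0.0


def test_lod_requires_positive_slope():
    with pytest.raises(QuantError):
        compute_lod([1.0, 2.0, 3.0], _model(slope=0.0))


# -- quantify --------------------------------------------------------------


def test_quantify_identity_curve():
    rec = quantify("s", "x", 0, raw_area=150.0, is_area=100.0, model=_model())
    assert rec.ratio == pytest.approx(1.5)
    assert rec.concentration == pytest.approx(1.5)
    assert rec.flags == []


def test_quantify_flags_below_lod_and_range():
    m = _model(lod=0.5, cal_range=(1.0, 100.0))
    rec = quantify("s", "x", 0, raw_area=10.0, is_area=100.0, model=m)
    assert "below_lod" in rec.flags and "below_range" in rec.flags
    rec = quantify("s", "x", 0, raw_area=2e4, is_area=100.0, model=m)
    assert rec.flags == ["above_range"]


def test_quantify_missing_is_flagged_not_fatal():
    rec = quantify("s", "x", 0, raw_area=100.0, is_area=0.0, model=_model())
    assert rec.concentration is None and "is_missing" in rec.flags


# -- validation metrics ----------------------------------------------------


def test_recovery_examples():
    assert recovery_rate(110.0, 10.0, 100.0) == pytest.approx(1.0)
    assert recovery_rate(99.0, 0.0, 100.0) == pytest.approx(0.99)
    with pytest.raises(QuantError):
        recovery_rate(1.0, 0.0, 0.0)


def test_cv_examples():
    assert coefficient_of_variation([10.0, 10.0, 10.0]) == 0.0
    assert coefficient_of_variation([8.0, 10.0, 12.0]) == pytest.approx(0.2)
    with pytest.raises(QuantError):
        coefficient_of_variation([10.0])
    with pytest.raises(QuantError):
        coefficient_of_variation([-1.0, 1.0])


# -- natural-abundance correction -----------------------------------------


def test_correction_matrix_structure(panel):
    M = correction_matrix(panel["butyric acid"])
    assert M.shape == (5, 5)
    assert np.allclose(M, np.tril(M))  # lower triangular
    assert np.all(np.diag(M) > 0.85)  # diagonals are monoisotopic fractions
    assert np.all(M.sum(axis=0) <= 1.0 + 1e-12)
    # diagonal grows with k: fixing labels removes natural variability
    assert np.all(np.diff(np.diag(M)) > 0)


def _cascade_oracle(c_obs, M):
    """Unit-diagonal lower-triangular solve, independent of the cascade."""
    Mn = M / np.diag(M)[None, :]
    return np.linalg.solve(np.tril(Mn), np.asarray(c_obs, dtype=float))


def test_unlabeled_input_corrects_to_m0_only(panel):
    entry = panel["acetic acid"]
    M = correction_matrix(entry)
    c_obs = 100.0 * M[:, 0] / M[0, 0]  # pure unlabeled, quantified per channel
    corr, clipped = correct_natural_abundance(c_obs, entry)
    assert corr[0] == pytest.approx(100.0)
    assert np.all(np.abs(corr[1:]) < 1e-9)


def test_pure_heavy_isotopologue_untouched(panel):
    corr, clipped = correct_natural_abundance([0.0, 0.0, 50.0], panel["acetic acid"])
    np.testing.assert_allclose(corr, [0.0, 0.0, 50.0])
    assert clipped == []


def test_cascade_equals_triangular_solve(panel):
    rng = np.random.default_rng(17)
    entry = panel["valeric acid"]
    M = correction_matrix(entry)
    Mn = np.tril(M / np.diag(M)[None, :])
    for _ in range(50):
        truth = rng.uniform(0, 100, size=6)
        c_obs = Mn @ truth  # bleed-inflated observation
        corr, clipped = correct_natural_abundance(c_obs, entry)
        assert clipped == []
        np.testing.assert_allclose(corr, _cascade_oracle(c_obs, M), atol=1e-9)
        np.testing.assert_allclose(corr, truth, atol=1e-9)


def test_correction_idempotent_roundtrip(panel):
    """Re-inflating a corrected vector and correcting again is a no-op."""
    entry = panel["butyric acid"]
    M = correction_matrix(entry)
    Mn = np.tril(M / np.diag(M)[None, :])
    corr0 = np.array([30.0, 0.0, 50.0, 0.0, 5.0])
    reinflated = Mn @ corr0
    corr1, _ = correct_natural_abundance(reinflated, entry)
    np.testing.assert_allclose(corr1, corr0, atol=1e-9)


def test_correction_floors_negative_channels(panel):
    entry = panel["acetic acid"]
    # k=1 channel below the bleed predicted from k=0
    corr, clipped = correct_natural_abundance([100.0, 0.001, 0.0], entry)
    assert corr[1] == 0.0 and 1 in clipped


def test_monoisotopic_only_mode(panel):
    entry = panel["butyric acid"]
    M = correction_matrix(entry)
    c_obs = np.array([100.0, 9.7, 20.0, 2.0, 0.1])
    full, _ = correct_natural_abundance(c_obs, entry, mode="cascade")
    narrow, _ = correct_natural_abundance(c_obs, entry, mode="monoisotopic_only")
    # both subtract the unlabeled bleed from k=1 identically
    assert narrow[1] == pytest.approx(full[1])
    # but the narrow mode leaves k=3 bleed from the k=2 species in place
    assert narrow[3] > full[3]


def test_correction_rejects_invalid_input(panel):
    with pytest.raises(QuantError):
        correct_natural_abundance([-1.0, 0.0], panel["acetic acid"])
    with pytest.raises(QuantError):
        correct_natural_abundance([1.0] * 8, panel["acetic acid"])
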