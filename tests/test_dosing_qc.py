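"""Dosing precision (CV%) and linearity QC."""
import numpy as np
import pytest

import mozzipk as m
from mozzipk.datamodel import LinearityRecord


def recs(amounts, weights=None, conc=0.1):
    weights = weights or [3.4] * len(amounts)
    return [LinearityRecord(conc, a, w) for a, w in zip(amounts, weights)]


def test_cv_hand_arithmetic():
    summary = m.dosing_precision(recs([1.0, 2.0, 3.0]),
                                 normalize_by_weight=False)
    row = summary.per_concentration.iloc[0]
    assert row["mean"] == pytest.approx(2.0)
    assert row["sd"] == pytest.approx(1.0)
    assert row["cv_percent"] == pytest.approx(50.0)


def test_identical_amounts_give_zero_cv():
    summary = m.dosing_precision(recs([0.4] * 5), normalize_by_weight=False)
    assert summary.per_concentration["cv_percent"].iloc[0] == 0.0


def test_single_record_concentration_excluded_with_warning():
    records = recs([1.0, 2.0], conc=0.1) + recs([5.0], conc=0.5)
    with pytest.warns(UserWarning):
        summary = m.dosing_precision(records, normalize_by_weight=False)
    assert list(summary.per_concentration["conc_ug_ml"]) == [0.1]


def test_cv_invariant_under_rescaling():
    base = m.dosing_precision(recs([1.0, 2.0, 3.0]), False)
    scaled = m.dosing_precision(recs([7.0, 14.0, 21.0]), False)
    assert (base.per_concentration["cv_percent"].iloc[0]
            == pytest.approx(scaled.per_concentration["cv_percent"].iloc[0]))


def test_linearity_exact_line():
    records = []
    for conc in (0.01, 0.1, 1.0):
        records += recs([3.6 * conc] * 3, conc=conc)
    slope, intercept, r2 = m.dosing_linearity(records)
    assert slope == pytest.approx(3.6)
    assert intercept == pytest.approx(0.0, abs=1e-12)
    assert r2 == pytest.approx(1.0)


def test_linearity_intercept_vanishes_for_symmetric_noise():
    records = []
    for conc in (0.1, 0.5, 1.0):
        records += recs([3.6 * conc - 0.01, 3.6 * conc + 0.01], conc=conc)
    _, intercept, _ = m.dosing_linearity(records)
    assert intercept == pytest.approx(0.0, abs=1e-12)


def test_linearity_requires_two_concentrations():
    with pytest.raises(ValueError):
        m.dosing_linearity(recs([1.0, 2.0]))


def test_r2_invariant_under_affine_rescaling():
    rng = np.random.default_rng(0)
    records = []
    for conc in (0.01, 0.05, 0.1, 0.5, 1.0):
        records += recs(list(3.6 * conc * rng.lognormal(0, 0.15, 10)),
                        conc=conc)
    _, _, r2 = m.dosing_linearity(records)
    scaled = [LinearityRecord(r.blood_conc_ug_ml * 7.0, r.amount_ng * 0.2,
                              r.weight_mg) for r in records]
    _, _, r2s = m.dosing_linearity(scaled)
    assert r2 == pytest.approx(r2s)


def test_simulated_experiment_is_linear():
    """Generative model is linear in concentration.  On weight-normalised
    amounts the median R^2 over seeds stays >= 0.98; on raw amounts the
    ~18% meal-volume scatter caps R^2 near 0.95 by simple variance
    arithmetic."""
    datasets = [m.simulate_linearity_experiment(seed=s) for s in range(5)]
    r2_norm = [m.dosing_linearity(d, normalize_by_weight=True)[2]
               for d in datasets]
    r2_raw = [m.dosing_linearity(d)[2] for d in datasets]
    assert np.median(r2_norm) >= 0.98
    assert np.median(r2_raw) >= 0.92


def test_weight_normalization_reduces_dosing_cv():
    """Weight and meal size are coupled, so normalising by weight removes
    meal-volume variability in the majority of simulated experiments."""
    wins = 0
    for seed in range(40):
        records = m.simulate_linearity_experiment(seed=seed)
        raw = m.dosing_precision(records, normalize_by_weight=False)
        norm = m.dosing_precision(records, normalize_by_weight=True)
        if (norm.per_concentration["cv_percent"].median()
                < raw.per_concentration["cv_percent"].median()):
            wins += 1
    assert wins > 20


def test_simulated_cv_ranges_match_study_scale():
    """Raw amount CV near the high-teens, weight-normalised CV roughly
    halved - the pattern the dosing experiment is designed to show."""
    records = m.simulate_linearity_experiment(seed=123)
    raw = m.dosing_precision(records, False).per_concentration["cv_percent"]
    norm = m.dosing_precision(records, True).per_concentration["cv_percent"]
    assert 12.0 <= raw.median() <= 25.0
    assert 5.0 <= norm.median() <= 14.0


def test_implied_meal_volume():
    assert m.implied_meal_volume_ul(0.36, 0.1) == pytest.approx(3.6)
    with pytest.raises(ValueError):
        m.implied_meal_volume_ul(0.36, 0.0)
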