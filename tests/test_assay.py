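"""Assay-validation arithmetic and M5 BLOQ imputation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ceftripk.assay import (
    fit_calibration,
    impute_bloq,
    lod_loq,
    precision_accuracy,
    system_suitability,
)
from ceftripk.errors import DomainError, InsufficientDataError
from ceftripk.types import ConcentrationSample


def test_exact_line_recovers_slope_intercept_r():
    levels = [2.5, 5.0, 10.0, 25.0, 50.0, 100.0]
    areas = [2.0 * x + 1.0 for x in levels]
    fit = fit_calibration(levels, areas)
    assert fit.slope == pytest.approx(2.0, abs=1e-12)
    assert fit.intercept == pytest.approx(1.0, abs=1e-10)
    assert fit.r == pytest.approx(1.0, abs=1e-12)


def test_noisy_fit_matches_normal_equations_oracle():
    rng = np.random.default_rng(42)
    x = np.array([2.5, 5.0, 10.0, 25.0, 50.0, 100.0])
    y = 3.1 * x + 4.0 + rng.normal(0, 2.0, size=x.size)
    fit = fit_calibration(x, y)
    # closed-form OLS via the normal equations, computed independently
    n = x.size
    sxx = (x ** 2).sum() - x.sum() ** 2 / n
    sxy = (x * y).sum() - x.sum() * y.sum() / n
    slope = sxy / sxx
    intercept = y.mean() - slope * x.mean()
    resid = y - slope * x - intercept
    s2 = (resid ** 2).sum() / (n - 2)
    se_intercept = np.sqrt(s2 * (1.0 / n + x.mean() ** 2 / sxx))
    assert fit.slope == pytest.approx(slope, abs=1e-10)
    assert fit.intercept == pytest.approx(intercept, abs=1e-10)
    assert fit.sigma_intercept == pytest.approx(se_intercept, rel=1e-10)
    assert fit.lod == pytest.approx(3.3 * se_intercept / slope, rel=1e-10)


def test_two_point_calibration_flags_undefined_sigma():
    fit = fit_calibration([2.5, 100.0], [10.0, 400.0])
    assert fit.sigma_undefined and fit.sigma_intercept is None
    assert fit.lod is None and fit.loq is None


def test_constant_levels_rejected():
    with pytest.raises(DomainError):
        fit_calibration([5.0, 5.0, 5.0], [1.0, 2.0, 3.0])


@pytest.mark.parametrize("sigma,slope,expected", [
    (1.0, 1.0, (3.3, 10.0)),
    (0.05, 0.02, (8.25, 25.0)),
])
def test_lod_loq_formulas(sigma, slope, expected):
    assert lod_loq(sigma, slope) == pytest.approx(expected)


def test_lod_loq_rejects_nonpositive_slope():
    with pytest.raises(DomainError):
        lod_loq(1.0, 0.0)


@given(sigma=st.floats(min_value=1e-3, max_value=1e3),
       slope=st.floats(min_value=1e-3, max_value=1e3),
       scale=st.floats(min_value=1e-2, max_value=1e2))
def test_lod_loq_ratio_and_homogeneity(sigma, slope, scale):
    lod, loq = lod_loq(sigma, slope)
    assert loq / lod == pytest.approx(10.0 / 3.3, rel=1e-12)
    lod2, loq2 = lod_loq(sigma * scale, slope * scale)
    assert lod2 == pytest.approx(lod, rel=1e-9)
    assert loq2 == pytest.approx(loq, rel=1e-9)


def test_precision_identical_replicates():
    table = precision_accuracy({10.0: {1: [10.0, 10.0, 10.0]}})
    row = table.iloc[0]
    assert row["intra_day_cv_percent"] == 0.0
    assert row["recovery_percent"] == pytest.approx(100.0)


def test_precision_9_10_11():
    table = precision_accuracy({10.0: {1: [9.0, 10.0, 11.0]}})
    row = table.iloc[0]
    assert row["intra_day_cv_percent"] == pytest.approx(10.0)  # sd=1, mean=10
    assert row["recovery_percent"] == pytest.approx(100.0)


def test_inter_day_cv_matches_pooled_oracle():
    data = {
        5.0: {1: [4.8, 5.1, 5.0], 2: [5.2, 4.9, 5.1], 3: [5.0, 5.3, 4.7]},
        25.0: {1: [24.0, 25.5, 25.2], 2: [26.1, 24.8, 25.0], 3: [25.3, 24.6, 25.9]},
        80.0: {1: [79.0, 81.5, 80.2], 2: [82.0, 78.8, 80.5], 3: [80.9, 79.7, 81.1]},
    }
    table = precision_accuracy(data).set_index("nominal_ug_ml")
    for nominal, by_day in data.items():
        pooled = [v for reps in by_day.values() for v in reps]
        mean = sum(pooled) / len(pooled)
        sd = (sum((v - mean) ** 2 for v in pooled) / (len(pooled) - 1)) ** 0.5
        assert table.loc[nominal, "inter_day_cv_percent"] == pytest.approx(
            100.0 * sd / mean, rel=1e-12)
        assert table.loc[nominal, "recovery_percent"] == pytest.approx(
            100.0 * mean / nominal, rel=1e-12)


def test_precision_requires_two_replicates():
    with pytest.raises(InsufficientDataError):
        precision_accuracy({10.0: {1: [10.0]}})


def test_system_suitability_formulas():
    m = system_suitability(4.0, 0.5)
    assert m.plates == pytest.approx(1024.0)
    assert m.hetp_mm == pytest.approx(250.0 / 1024.0)  # 0.2441 mm
    sym = system_suitability(4.0, 0.5, width_at_5pct_height=0.6, front_distance=0.3)
    assert sym.tailing == pytest.approx(1.0)
    rs = system_suitability(4.0, 0.5, retention_time_2_min=5.0, peak_width_2=0.5)
    assert rs.resolution == pytest.approx(2.0)


def test_system_suitability_ordering_error():
    with pytest.raises(DomainError):
        system_suitability(4.0, 0.5, retention_time_2_min=3.0, peak_width_2=0.5)


def _samples():
    return [
        ConcentrationSample("p1", "free", 11.75, 11.75, None, bloq=True),
        ConcentrationSample("p1", "free", 23.75, 11.75, 3.0, bloq=False),
        ConcentrationSample("p1", "total", 11.75, 11.75, 14.0, bloq=False),
    ]


def test_m5_sets_bloq_to_half_lloq_and_leaves_rest():
    out = impute_bloq(_samples(), lloq=2.5)
    assert out[0].conc_ug_ml == 1.25 and out[0].imputed
    assert out[1].conc_ug_ml == 3.0 and not out[1].imputed
    assert out[2].conc_ug_ml == 14.0


def test_m5_is_idempotent_and_never_loses_samples():
    once = impute_bloq(_samples(), lloq=2.5)
    twice = impute_bloq(once, lloq=2.5)
    assert once == twice
    usable_before = sum(s.conc_ug_ml is not None for s in _samples())
    usable_after = sum(s.conc_ug_ml is not None for s in once)
    assert usable_after >= usable_before
    assert usable_after == len(once)


def test_m5_rejects_nonpositive_lloq():
    with pytest.raises(DomainError):
        impute_bloq(_samples(), lloq=0.0)
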