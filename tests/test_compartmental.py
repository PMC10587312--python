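"""Compartmental models: prediction, ML fitting, selection, diagnostics,
and %fT>MIC."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.stats import norm

from ceftripk.compartmental import (
    OneCompartment,
    TwoCompartment,
    compare_models,
    diagnostics,
    fit_model,
    information_criteria,
    predict,
    time_above_mic,
)
from ceftripk.errors import InsufficientDataError, ValidationError
from ceftripk.types import ConcentrationSample, DoseEvent, ModelFit, Regimen


def _sample(pid, t, c, analyte="total"):
    return ConcentrationSample(patient_id=pid, analyte=analyte, time_h=t,
                               time_after_last_dose_h=t, conc_ug_ml=c, bloq=False)


def test_predict_bolus_initial_concentration():
    m = OneCompartment(v_ml=10000.0, cl_ml_h=700.0)
    assert predict(m, [DoseEvent("x", 0.0, 100.0)], 0.0)[0] == pytest.approx(10.0)
    # before the first dose the prediction is defined and zero
    assert predict(m, [DoseEvent("x", 5.0, 100.0)], 1.0)[0] == 0.0


def test_two_compartment_degenerates_to_one():
    m1 = OneCompartment(v_ml=9000.0, cl_ml_h=800.0)
    m2 = TwoCompartment(v1_ml=9000.0, cl_ml_h=800.0, v2_ml=1e-8, q_ml_h=1e-8)
    doses = [DoseEvent("x", 0.0, 500.0), DoseEvent("x", 12.0, 500.0)]
    t = np.linspace(0.0, 36.0, 73)
    assert np.max(np.abs(predict(m1, doses, t) - predict(m2, doses, t))) < 1e-9


def test_multidose_prediction_matches_ode_solver():
    """Independent oracle: integrate dC/dt = -kC with bolus jumps."""
    v, cl, amt = 6500.0, 450.0, 300.0
    k = cl / v
    dose_times = [0.0, 12.0, 24.0, 36.0]
    doses = [DoseEvent("x", td, amt) for td in dose_times]
    t_eval = np.linspace(0.0, 60.0, 121)
    conc = np.zeros_like(t_eval)
    boundaries = dose_times + [float(t_eval[-1])]
    c_state = 0.0
    for t_start, t_end in zip(boundaries, boundaries[1:]):
        c_state += amt * 1000.0 / v
        last_seg = t_end == boundaries[-1]
        seg = (t_eval >= t_start) & ((t_eval <= t_end) if last_seg
                                     else (t_eval < t_end))
        sol = solve_ivp(lambda t, y: [-k * y[0]], (t_start, t_end), [c_state],
                        t_eval=t_eval[seg], rtol=1e-11, atol=1e-14)
        conc[seg] = sol.y[0]
        end = solve_ivp(lambda t, y: [-k * y[0]], (t_start, t_end), [c_state],
                        rtol=1e-12, atol=1e-15)
        c_state = float(end.y[0, -1])
    got = predict(OneCompartment(v_ml=v, cl_ml_h=cl), doses, t_eval)
    assert np.max(np.abs(got - conc)) < 1e-8


def test_fit_recovers_noise_free_troughs_exactly():
    v, cl, tau, amt = 5200.0, 310.0, 12.0, 450.0
    doses = [DoseEvent("p", j * tau, amt) for j in range(10)]
    model = OneCompartment(v_ml=v, cl_ml_h=cl)
    times = [tau - 0.25, 2 * tau - 0.25, 7 * tau - 0.25]
    conc = predict(model, doses, times)
    samples = [_sample("p", t, c) for t, c in zip(times, conc)]
    fit = fit_model(samples, doses, n_compartments=1, mode="subject", seed=0)
    assert fit.params["v_ml"] == pytest.approx(v, rel=1e-6)
    assert fit.params["cl_ml_h"] == pytest.approx(cl, rel=1e-6)
    assert fit.sigma_mult < 1e-6
    assert fit.aic == pytest.approx(fit.minus2ll + 2 * fit.k_params)
    assert fit.bic == pytest.approx(fit.minus2ll + fit.k_params * np.log(fit.n_obs))


def test_fitted_minus2ll_never_worse_than_truth():
    rng = np.random.default_rng(12)
    v, cl = 5200.0, 310.0
    doses = [DoseEvent("p", j * 12.0, 450.0) for j in range(8)]
    model = OneCompartment(v_ml=v, cl_ml_h=cl)
    times = np.array([11.75, 23.75, 47.75, 71.75, 95.75])
    conc = predict(model, doses, times) * np.exp(rng.normal(0, 0.1, times.size))
    samples = [_sample("p", float(t), float(c)) for t, c in zip(times, conc)]
    fit = fit_model(samples, doses, n_compartments=1, mode="subject", seed=0)
    # evaluate the profiled deviance at the true parameters, independently
    resid = np.log(conc) - np.log(predict(model, doses, times))
    s2 = float(resid @ resid) / times.size
    minus2ll_truth = times.size * (math.log(2 * math.pi * s2) + 1.0)
    assert fit.minus2ll <= minus2ll_truth + 1e-9


def test_scaling_doses_and_concentrations_leaves_estimates_unchanged():
    rng = np.random.default_rng(3)
    v, cl = 8000.0, 600.0
    doses = [DoseEvent("p", j * 12.0, 500.0) for j in range(6)]
    times = np.array([11.75, 23.75, 59.75])
    conc = predict(OneCompartment(v, cl), doses, times) * np.exp(
        rng.normal(0, 0.05, times.size))
    fit_a = fit_model([_sample("p", float(t), float(c)) for t, c in zip(times, conc)],
                      doses, 1, "subject", seed=5)
    scale = 3.7
    doses_s = [DoseEvent("p", d.time_h, d.amount_mg * scale) for d in doses]
    fit_b = fit_model(
        [_sample("p", float(t), float(c * scale)) for t, c in zip(times, conc)],
        doses_s, 1, "subject", seed=5)
    assert fit_b.params["v_ml"] == pytest.approx(fit_a.params["v_ml"], rel=1e-6)
    assert fit_b.params["cl_ml_h"] == pytest.approx(fit_a.params["cl_ml_h"], rel=1e-6)


def test_fit_requires_enough_observations():
    doses = [DoseEvent("p", 0.0, 500.0)]
    samples = [_sample("p", 1.0, 40.0), _sample("p", 2.0, 30.0)]
    with pytest.raises(InsufficientDataError):
        fit_model(samples, doses, n_compartments=1, mode="subject")


@pytest.mark.parametrize("minus2ll,k,n,aic_expect,bic_expect", [
    # reported population diagnostics: 1c and 2c fits of the free analyte
    (181.3514, 5, 72, 191.3514, 202.7348),
    (182.8512, 9, 72, 200.8512, 221.3412),
])
def test_information_criteria_reported_rows(minus2ll, k, n, aic_expect, bic_expect):
    aic, bic = information_criteria(minus2ll, k, n)
    assert aic == pytest.approx(aic_expect, abs=1e-9)
    assert bic == pytest.approx(bic_expect, abs=1e-3)


def test_information_criteria_k0():
    aic, bic = information_criteria(100.0, 0, 50)
    assert aic == 100.0 and bic == 100.0


def _stub_fit(aic, bic, n_obs=72):
    return ModelFit(n_compartments=1, analyte="free", mode="pooled", params={},
                    sigma_mult=0.1, minus2ll=0.0, k_params=5, n_obs=n_obs,
                    aic=aic, bic=bic)


def test_compare_models_selects_lower_aic_and_detects_tie():
    sel = compare_models(_stub_fit(191.3514, 202.7348), _stub_fit(200.8512, 221.3412))
    assert sel.selected == "1c" and sel.criteria_agree
    tie = compare_models(_stub_fit(100.0, 110.0), _stub_fit(100.0, 110.0))
    assert tie.selected == "tie"
    with pytest.raises(ValidationError):
        compare_models(_stub_fit(1.0, 2.0, n_obs=72), _stub_fit(1.0, 2.0, n_obs=70))


def test_diagnostics_blom_positions_match_hand_formula():
    fit = _stub_fit(0.0, 0.0)
    fit.weighted_residuals = [0.5, -1.2, 0.1, 1.4]
    fit.observed = fit.predicted = [1.0, 1.0, 1.0, 1.0]
    d = diagnostics(fit)
    hand = [norm.ppf((i - 0.375) / 4.25) for i in (1, 2, 3, 4)]
    assert np.allclose(d["normal_quantiles"], hand, atol=1e-12)
    assert d["sorted_std_residuals"] == sorted(fit.weighted_residuals)


def test_diagnostics_residuals_near_zero_on_perfect_fit():
    v, cl = 5200.0, 310.0
    doses = [DoseEvent("p", j * 12.0, 450.0) for j in range(10)]
    times = [11.75, 23.75, 83.75]
    conc = predict(OneCompartment(v, cl), doses, times)
    fit = fit_model([_sample("p", t, float(c)) for t, c in zip(times, conc)],
                    doses, 1, "subject", seed=0)
    assert max(abs(r) for r in fit.residuals) < 1e-8


def test_residuals_look_normal_under_multiplicative_noise():
    """Standardized residuals of a correctly specified fit pass a KS check
    against N(0,1) in at least 9 of 10 seeds."""
    from scipy.stats import kstest

    v, cl = 8000.0, 500.0
    doses = [DoseEvent("p", 0.0, 800.0)]
    times = np.linspace(0.5, 36.0, 30)
    clean = predict(OneCompartment(v, cl), doses, times)
    ok = 0
    for seed in range(10):
        rng = np.random.default_rng(900 + seed)
        conc = clean * np.exp(rng.normal(0, 0.15, times.size))
        fit = fit_model([_sample("p", float(t), float(c))
                         for t, c in zip(times, conc)], doses, 1, "subject", seed=0)
        p = kstest(fit.weighted_residuals, "norm").pvalue
        ok += p > 0.05
    assert ok >= 9


def test_ft_mic_trivial_and_derived_cases():
    # regimen whose steady-state peak (x fu) is exactly 16 mg/L, t1/2 = 4 h
    v = 10000.0
    k = math.log(2) / 4.0
    cl = k * v
    tau = 24.0
    dose = 16.0 * v / 1000.0 * (1.0 - math.exp(-k * tau))  # fu = 1
    model = OneCompartment(v_ml=v, cl_ml_h=cl)
    reg = Regimen(dose_mg=dose, interval_h=tau)
    assert time_above_mic(model, reg, 2.0) == pytest.approx(50.0, abs=1e-9)
    # trough above MIC -> 100%
    assert time_above_mic(model, reg, 0.05) == 100.0
    # peak below MIC -> 0%
    assert time_above_mic(model, reg, 20.0) == 0.0
    # non-increasing in MIC
    vals = [time_above_mic(model, reg, m) for m in (0.5, 1.0, 2.0)]
    assert vals == sorted(vals, reverse=True)


def test_ft_mic_two_compartment_matches_grid():
    m = TwoCompartment(v1_ml=4000.0, cl_ml_h=600.0, v2_ml=8000.0, q_ml_h=6000.0)
    reg = Regimen(dose_mg=800.0, interval_h=12.0)
    pct = time_above_mic(m, reg, 2.0, fu=0.3)
    # independent steady-state grid: superpose many doses, count the fraction
    _, beta, _, _ = m.macro_constants()
    n = int(np.ceil(25 * math.log(2) / beta / 12.0))
    doses = [DoseEvent("x", j * 12.0, 800.0) for j in range(n + 1)]
    grid = np.linspace(n * 12.0, (n + 1) * 12.0, 120001)
    conc = predict(m, doses, grid)
    assert pct == pytest.approx(100.0 * np.mean(0.3 * conc > 2.0), abs=0.1)
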