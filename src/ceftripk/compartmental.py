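"""One- and two-compartment IV bolus models: prediction, maximum-likelihood
fitting with multiplicative error, AIC/BIC selection, residual diagnostics
and %fT>MIC target attainment.

Error model
-----------
Observations are multiplicative: ``C_obs = C_pred * exp(eps)`` with
``eps ~ N(0, sigma^2)``, i.e. additive Gaussian error on the log scale.
For fixed structural parameters the MLE of sigma^2 is RSS/n on log
concentrations, so point estimation reduces to nonlinear least squares on
``log C``; the profiled deviance is ``-2LL = n*(log(2*pi*sigma_hat^2)+1)``.

Parameter accounting for information criteria
---------------------------------------------
``k_params`` counts structural parameters + 1 residual term for
per-subject fits, and structural + one between-subject variance term per
structural parameter + 1 residual term for pooled ("population
bookkeeping") fits: 1-compartment pooled k = 2+2+1 = 5, 2-compartment
pooled k = 4+4+1 = 9, with n the pooled observation count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats

from .errors import (
    ConvergenceError,
    DomainError,
    InsufficientDataError,
    ValidationError,
)
from .types import ConcentrationSample, DoseEvent, ModelFit, Regimen

_SIGMA2_FLOOR = 1e-20
_LOG_BOUNDS = (np.log(1e-3), np.log(1e12))


@dataclass(frozen=True)
class OneCompartment:
    """IV bolus one-compartment model; k = CL/V."""

    v_ml: float
    cl_ml_h: float

    def __post_init__(self):
        if not (self.v_ml > 0 and self.cl_ml_h > 0):
            raise DomainError("V and CL must be > 0")

    @property
    def k_per_h(self) -> float:
        return self.cl_ml_h / self.v_ml

    @property
    def n_compartments(self) -> int:
        return 1

    @property
    def n_structural(self) -> int:
        return 2


@dataclass(frozen=True)
class TwoCompartment:
    """IV bolus two-compartment model (central V1, peripheral V2, flow Q)."""

    v1_ml: float
    cl_ml_h: float
    v2_ml: float
    q_ml_h: float

    def __post_init__(self):
        for name in ("v1_ml", "cl_ml_h", "v2_ml", "q_ml_h"):
            if not getattr(self, name) > 0:
                raise DomainError(f"{name} must be > 0")

    @property
    def n_compartments(self) -> int:
        return 2

    @property
    def n_structural(self) -> int:
        return 4

    def macro_constants(self) -> Tuple[float, float, float, float]:
        """(alpha, beta, A1, B1) with A1, B1 the unit-dose (1 mg)
        coefficients in ug/mL; alpha > beta > 0."""
        k10 = self.cl_ml_h / self.v1_ml
        k12 = self.q_ml_h / self.v1_ml
        k21 = self.q_ml_h / self.v2_ml
        s = k10 + k12 + k21
        disc = math.sqrt(max(s * s - 4.0 * k10 * k21, 0.0))
        alpha = 0.5 * (s + disc)
        beta = 0.5 * (s - disc)
        unit = 1000.0 / self.v1_ml
        if disc <= 1e-300:
            return alpha, beta, unit, 0.0
        a = unit * (alpha - k21) / (alpha - beta)
        b = unit * (k21 - beta) / (alpha - beta)
        return alpha, beta, a, b


def _dose_arrays(dose_events: Sequence[DoseEvent]) -> Tuple[np.ndarray, np.ndarray]:
    return (np.asarray([d.time_h for d in dose_events], dtype=float),
            np.asarray([d.amount_mg for d in dose_events], dtype=float))


def predict(model, dose_events: Sequence[DoseEvent], t) -> np.ndarray:
    """Superposed bolus response at times ``t`` (hours); ug/mL.

    Times before the first dose return 0 (defined, not an error).
    """
    times = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(times < 0):
        raise DomainError("t must be >= 0")
    dt_, da_ = _dose_arrays(dose_events)
    conc = np.zeros_like(times)
    if isinstance(model, OneCompartment):
        k = model.k_per_h
        for td, amt in zip(dt_, da_):
            m = times >= td
            conc[m] += (amt * 1000.0 / model.v_ml) * np.exp(-k * (times[m] - td))
    elif isinstance(model, TwoCompartment):
        alpha, beta, a, b = model.macro_constants()
        for td, amt in zip(dt_, da_):
            m = times >= td
            dtm = times[m] - td
            conc[m] += amt * (a * np.exp(-alpha * dtm) + b * np.exp(-beta * dtm))
    else:
        raise ValidationError(f"unknown model type {type(model).__name__}")
    return conc


def _build_model(n_compartments: int, theta: np.ndarray):
    if n_compartments == 1:
        return OneCompartment(v_ml=theta[0], cl_ml_h=theta[1])
    return TwoCompartment(v1_ml=theta[0], cl_ml_h=theta[1],
                          v2_ml=theta[2], q_ml_h=theta[3])


def _group_by_patient(samples, dose_events):
    by_pid: Dict[str, dict] = {}
    for s in samples:
        by_pid.setdefault(s.patient_id, {"t": [], "c": []})
        if s.conc_ug_ml is None:
            raise ValidationError(
                f"sample at t={s.time_h} for {s.patient_id} has no concentration; "
                "run BLOQ imputation first")
        if s.conc_ug_ml <= 0:
            raise ValidationError("concentrations must be > 0 for log-scale fitting")
        by_pid[s.patient_id]["t"].append(s.time_h)
        by_pid[s.patient_id]["c"].append(s.conc_ug_ml)
    for pid in by_pid:
        by_pid[pid]["doses"] = [d for d in dose_events if d.patient_id == pid]
        if not by_pid[pid]["doses"]:
            raise ValidationError(f"no dose events for patient {pid}")
        by_pid[pid]["t"] = np.asarray(by_pid[pid]["t"], dtype=float)
        by_pid[pid]["c"] = np.asarray(by_pid[pid]["c"], dtype=float)
        # precompute time-since-dose matrix for vectorized prediction
        dt_, da_ = _dose_arrays(by_pid[pid]["doses"])
        dmat = by_pid[pid]["t"][:, None] - dt_[None, :]
        by_pid[pid]["dose_dt"] = np.where(dmat >= 0.0, dmat, np.inf)
        by_pid[pid]["dose_amt"] = da_
        by_pid[pid]["log_c"] = np.log(by_pid[pid]["c"])
    return by_pid


def _predict_group(theta: np.ndarray, n_compartments: int, g: dict) -> np.ndarray:
    """Superposition prediction from the cached time-since-dose matrix."""
    amt = g["dose_amt"]
    dt = g["dose_dt"]
    if n_compartments == 1:
        v, cl = theta
        return (1000.0 / v) * (amt[None, :] * np.exp(-(cl / v) * dt)).sum(axis=1)
    model = _build_model(2, theta)
    alpha, beta, a, b = model.macro_constants()
    resp = a * np.exp(-alpha * dt) + b * np.exp(-beta * dt)
    return (amt[None, :] * resp).sum(axis=1)


def _initial_theta(n_compartments, groups) -> np.ndarray:
    """Moment-style start: invert the steady-state trough relation at a
    nominal half-life of 8 h."""
    k0 = math.log(2.0) / 8.0
    vs = []
    for g in groups.values():
        doses = g["doses"]
        tau = np.median(np.diff([d.time_h for d in doses])) if len(doses) > 1 else 12.0
        amt = float(np.mean([d.amount_mg for d in doses]))
        cbar = float(np.mean(g["c"]))
        acc = math.exp(-k0 * max(tau - 0.25, 0.5)) / max(1.0 - math.exp(-k0 * tau), 1e-6)
        vs.append(max(amt * 1000.0 * acc / cbar, 1.0))
    v0 = float(np.median(vs))
    cl0 = k0 * v0
    if n_compartments == 1:
        return np.array([v0, cl0])
    return np.array([0.7 * v0, cl0, 0.7 * v0, cl0])


def _residuals_log(x, n_compartments, groups):
    theta = np.exp(x)
    res = []
    for g in groups.values():
        pred = np.maximum(_predict_group(theta, n_compartments, g), 1e-300)
        res.append(g["log_c"] - np.log(pred))
    return np.concatenate(res)


def information_criteria(minus2ll: float, k_params: int, n_obs: int) -> Tuple[float, float]:
    """AIC = -2LL + 2k; BIC = -2LL + k*ln(n)."""
    if n_obs < 1:
        raise DomainError("n_obs must be >= 1")
    if k_params < 0:
        raise DomainError("k_params must be >= 0")
    return minus2ll + 2.0 * k_params, minus2ll + k_params * math.log(n_obs)


def fit_model(samples: Sequence[ConcentrationSample],
              dose_events: Sequence[DoseEvent],
              n_compartments: int = 1,
              mode: str = "pooled",
              seed: int = 0,
              n_starts: int = 5,
              analyte: Optional[str] = None,
              tol: float = 1e-15) -> ModelFit:
    """Maximum-likelihood fit with multiplicative error.

    ``mode='pooled'`` fits one parameter vector across all patients (each
    with its own dose history); ``mode='subject'`` requires samples from a
    single patient.  Samples must be BLOQ-imputed.  Multi-start: the
    moment-based initial plus ``n_starts - 1`` log-normally jittered
    restarts with a seed-controlled generator.
    """
    if n_compartments not in (1, 2):
        raise ValidationError("n_compartments must be 1 or 2")
    if mode not in ("pooled", "subject"):
        raise ValidationError("mode must be 'pooled' or 'subject'")
    samples = list(samples)
    analytes = {s.analyte for s in samples}
    if analyte is None:
        if len(analytes) > 1:
            raise ValidationError("samples mix analytes; pass analyte= to select one")
        analyte = analytes.pop() if analytes else "total"
    else:
        samples = [s for s in samples if s.analyte == analyte]
    groups = _group_by_patient(samples, dose_events)
    if mode == "subject" and len(groups) != 1:
        raise ValidationError(f"subject mode requires one patient, got {len(groups)}")
    n_obs = sum(len(g["c"]) for g in groups.values())
    p = 2 if n_compartments == 1 else 4
    k_params = (2 * p + 1) if mode == "pooled" else (p + 1)
    min_obs = p + 1 if mode == "subject" else k_params
    if n_obs < min_obs:
        raise InsufficientDataError(
            f"{n_obs} observations < {min_obs} required for {n_compartments}c {mode} fit")

    x0 = np.log(_initial_theta(n_compartments, groups))
    rng = np.random.default_rng(seed)
    starts = [x0] + [x0 + rng.normal(0.0, 0.5, size=x0.size)
                     for _ in range(max(n_starts - 1, 0))]
    best = None
    any_success = False
    for x_start in starts:
        try:
            sol = optimize.least_squares(
                _residuals_log, x_start, args=(n_compartments, groups),
                method="trf", bounds=_LOG_BOUNDS,
                xtol=tol, ftol=tol, gtol=tol, max_nfev=2000)
        except Exception:
            continue
        any_success = any_success or sol.success
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise ConvergenceError("all optimizer starts failed")
    theta = np.exp(best.x)
    model = _build_model(n_compartments, theta)

    observed, predicted = [], []
    for g in groups.values():
        observed.extend(g["c"].tolist())
        predicted.extend(predict(model, g["doses"], g["t"]).tolist())
    obs = np.asarray(observed)
    pred = np.maximum(np.asarray(predicted), 1e-300)
    resid = np.log(obs) - np.log(pred)
    sigma2 = float(resid @ resid) / n_obs
    floored = sigma2 < _SIGMA2_FLOOR
    sigma2_eff = max(sigma2, _SIGMA2_FLOOR)
    minus2ll = n_obs * (math.log(2.0 * math.pi * sigma2_eff) + 1.0)
    aic, bic = information_criteria(minus2ll, k_params, n_obs)
    sigma = math.sqrt(sigma2_eff)

    if n_compartments == 1:
        params = {"v_ml": float(theta[0]), "cl_ml_h": float(theta[1]),
                  "k_per_h": float(theta[1] / theta[0])}
    else:
        alpha, beta, _, _ = model.macro_constants()
        params = {"v1_ml": float(theta[0]), "cl_ml_h": float(theta[1]),
                  "v2_ml": float(theta[2]), "q_ml_h": float(theta[3]),
                  "alpha_per_h": float(alpha), "beta_per_h": float(beta)}

    return ModelFit(
        n_compartments=n_compartments, analyte=analyte, mode=mode,
        params=params, sigma_mult=sigma, minus2ll=minus2ll,
        k_params=k_params, n_obs=n_obs, aic=aic, bic=bic,
        observed=obs.tolist(), predicted=pred.tolist(),
        residuals=resid.tolist(),
        weighted_residuals=(resid / sigma).tolist(),
        converged=bool(any_success), n_starts=len(starts), seed=seed,
        sigma_floored=floored,
    )


def fit_per_subject(samples, dose_events, n_compartments=1, seed=0,
                    analyte=None, n_starts=5) -> Dict[str, ModelFit]:
    """Independent per-patient fits; returns {patient_id: ModelFit}."""
    if analyte is not None:
        samples = [s for s in samples if s.analyte == analyte]
    pids = sorted({s.patient_id for s in samples}, key=lambda x: (len(x), x))
    out = {}
    for pid in pids:
        sub = [s for s in samples if s.patient_id == pid]
        dose = [d for d in dose_events if d.patient_id == pid]
        out[pid] = fit_model(sub, dose, n_compartments=n_compartments,
                             mode="subject", seed=seed, n_starts=n_starts,
                             analyte=analyte)
    return out


@dataclass
class ModelSelection:
    selected: str                 # "1c" | "2c" | "tie"
    aic_1c: float
    aic_2c: float
    bic_1c: float
    bic_2c: float
    delta_aic: float              # aic_2c - aic_1c
    delta_bic: float
    criteria_agree: bool


def compare_models(fit_1c: ModelFit, fit_2c: ModelFit) -> ModelSelection:
    """Select the model with the lower AIC; report BIC agreement."""
    if fit_1c.n_obs != fit_2c.n_obs:
        raise ValidationError(
            f"fits not comparable: n_obs {fit_1c.n_obs} vs {fit_2c.n_obs}")
    d_aic = fit_2c.aic - fit_1c.aic
    d_bic = fit_2c.bic - fit_1c.bic
    if d_aic > 0:
        selected = "1c"
    elif d_aic < 0:
        selected = "2c"
    else:
        selected = "tie"
    agree = (d_aic == 0 and d_bic == 0) or (d_aic * d_bic > 0)
    return ModelSelection(selected=selected, aic_1c=fit_1c.aic, aic_2c=fit_2c.aic,
                          bic_1c=fit_1c.bic, bic_2c=fit_2c.bic,
                          delta_aic=d_aic, delta_bic=d_bic, criteria_agree=agree)


def diagnostics(fit: ModelFit) -> dict:
    """Observed-vs-predicted pairs and a residual normal-quantile table.

    Standardized (weighted) residuals are sorted and paired with Blom
    plotting positions Phi^-1((i - 3/8)/(n + 1/4)); a Shapiro-Wilk summary
    is attached when n >= 3.
    """
    wres = np.sort(np.asarray(fit.weighted_residuals, dtype=float))
    n = wres.size
    ranks = np.arange(1, n + 1)
    blom = stats.norm.ppf((ranks - 0.375) / (n + 0.25))
    shapiro_stat = shapiro_p = None
    if n >= 3:
        sw = stats.shapiro(wres)
        shapiro_stat, shapiro_p = float(sw.statistic), float(sw.pvalue)
    return {
        "observed": list(fit.observed),
        "predicted": list(fit.predicted),
        "sorted_std_residuals": wres.tolist(),
        "normal_quantiles": blom.tolist(),
        "shapiro_stat": shapiro_stat,
        "shapiro_p": shapiro_p,
    }


def time_above_mic(model, regimen: Regimen, mic_mg_l: float, fu: float = 1.0,
                   grid_points: int = 20001) -> float:
    """Percent of the steady-state dosing interval with free conc > MIC.

    MIC in mg/L equals ug/mL numerically.  For the one-compartment model
    the closed form is used: with Css,max = (D*1000/V)/(1 - e^(-k tau)),
    %fT>MIC = 100*min(tau, ln(fu*Css,max/MIC)/k)/tau, 100% when even the
    trough stays above MIC and 0% when the peak does not reach it.  The
    two-compartment model accumulates to steady state numerically
    (burn-in 20 terminal half-lives) and integrates on a dense grid.
    """
    if mic_mg_l <= 0:
        raise DomainError("MIC must be > 0")
    if not (0.0 < fu <= 1.0):
        raise DomainError("fu must be in (0, 1]")
    tau = regimen.interval_h
    if isinstance(model, OneCompartment):
        k = model.k_per_h
        cmax = (regimen.dose_mg * 1000.0 / model.v_ml) / (1.0 - math.exp(-k * tau))
        cmin = cmax * math.exp(-k * tau)
        if fu * cmin > mic_mg_l:
            return 100.0
        if fu * cmax <= mic_mg_l:
            return 0.0
        t_above = math.log(fu * cmax / mic_mg_l) / k
        return 100.0 * min(t_above, tau) / tau
    if isinstance(model, TwoCompartment):
        _, beta, _, _ = model.macro_constants()
        t_half_terminal = math.log(2.0) / beta
        n_burn = max(int(math.ceil(20.0 * t_half_terminal / tau)), 1)
        doses = [DoseEvent("ss", j * tau, regimen.dose_mg) for j in range(n_burn + 1)]
        t0 = n_burn * tau
        grid = np.linspace(t0, t0 + tau, grid_points)
        conc = predict(model, doses, grid)
        frac = float(np.trapezoid((fu * conc > mic_mg_l).astype(float), grid) / tau)
        return 100.0 * frac
    raise ValidationError(f"unknown model type {type(model).__name__}")
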