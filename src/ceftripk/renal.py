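"""Renal-function estimation, protein-binding metrics and covariate
regressions.

eGFR uses the bedside Schwartz equation, 0.413 * height(cm) / Scr(mg/dL),
in mL/min/1.73 m^2 — the pediatric standard for this cohort.  The average
unbound fraction per patient is the clearance ratio 100*CL_total/CL_free
(free drug is the only fraction eliminated, so total clearance scales
with fu); the observed per-sample unbound fraction is 100*C_free/C_total.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence, Tuple

import numpy as np
from scipy import stats

from .errors import DomainError, InsufficientDataError, PairingError
from .types import ConcentrationSample


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r2: float
    p_value: float = float("nan")
    n: int = 0


def schwartz_egfr(height_cm: float, scr_mg_dl: float) -> float:
    """Bedside Schwartz eGFR = 0.413 * height / Scr (mL/min/1.73 m^2).

    Full precision is returned; round to 1 decimal for table parity.
    """
    if height_cm <= 0:
        raise DomainError(f"height_cm must be > 0, got {height_cm}")
    if scr_mg_dl <= 0:
        raise DomainError(f"scr_mg_dl must be > 0, got {scr_mg_dl}")
    return 0.413 * height_cm / scr_mg_dl


def unbound_fraction_avg(cl_total_ml_h: float, cl_free_ml_h: float) -> float:
    """Average unbound fraction (%) = 100 * CL_total / CL_free.

    Values above 100% are physically odd but are returned as computed
    (they flag inconsistent clearance pairs rather than being rejected).
    """
    if cl_total_ml_h <= 0:
        raise DomainError("cl_total_ml_h must be > 0")
    if cl_free_ml_h <= 0:
        raise DomainError("cl_free_ml_h must be > 0")
    return 100.0 * cl_total_ml_h / cl_free_ml_h


def unbound_fraction_observed(
    samples: Sequence[ConcentrationSample],
) -> Dict[str, Tuple[float, float]]:
    """Per-patient (min%, max%) of 100*C_free/C_total over paired times.

    Total and free samples are paired on (patient_id, time_h); a missing
    partner raises PairingError.
    """
    by_key: Dict[Tuple[str, float], Dict[str, float]] = {}
    for s in samples:
        if s.conc_ug_ml is None:
            continue
        by_key.setdefault((s.patient_id, s.time_h), {})[s.analyte] = s.conc_ug_ml
    ratios: Dict[str, list] = {}
    for (pid, t), pair in sorted(by_key.items()):
        if "total" not in pair or "free" not in pair:
            raise PairingError(f"unpaired sample for patient {pid} at t={t}")
        if pair["total"] <= 0:
            raise DomainError(f"non-positive total concentration at t={t}")
        ratios.setdefault(pid, []).append(100.0 * pair["free"] / pair["total"])
    return {pid: (min(v), max(v)) for pid, v in ratios.items()}


def regress_cl_egfr(cl_values: Sequence[float],
                    egfr_values: Sequence[float]) -> RegressionResult:
    """OLS of clearance on eGFR (the renal-elimination correlation)."""
    x = np.asarray(egfr_values, dtype=float)
    y = np.asarray(cl_values, dtype=float)
    if x.size != y.size:
        raise DomainError("cl and egfr must have equal length")
    if x.size < 3:
        raise InsufficientDataError("need >= 3 pairs")
    if np.ptp(x) == 0:
        raise DomainError("constant predictor; regression is singular")
    if np.ptp(y) == 0:
        return RegressionResult(slope=0.0, intercept=float(y[0]), r2=0.0,
                                p_value=1.0, n=int(x.size))
    res = stats.linregress(x, y)
    return RegressionResult(slope=float(res.slope), intercept=float(res.intercept),
                            r2=float(res.rvalue ** 2), p_value=float(res.pvalue),
                            n=int(x.size))


def covariate_regression(cl_values: Sequence[float],
                         covariate_values: Sequence[float],
                         transform: str = "identity") -> RegressionResult:
    """OLS of (optionally log-log transformed) clearance on a covariate,
    with an exact two-sided t-test p-value on the slope.

    ``transform='log-log'`` regresses log(CL) on log(covariate) — the
    allometric form used for body-weight effects.  A zero-variance
    response returns slope 0, r2 0, p 1 by convention.
    """
    if transform not in ("identity", "log-log"):
        raise DomainError(f"unknown transform {transform!r}")
    x = np.asarray(covariate_values, dtype=float)
    y = np.asarray(cl_values, dtype=float)
    if x.size != y.size:
        raise DomainError("unequal lengths")
    if x.size < 3:
        raise InsufficientDataError("need >= 3 pairs")
    if transform == "log-log":
        if np.any(x <= 0) or np.any(y <= 0):
            raise DomainError("log-log transform needs positive values")
        x, y = np.log(x), np.log(y)
    if np.ptp(x) == 0:
        raise DomainError("constant covariate; regression is singular")
    if np.ptp(y) == 0:
        return RegressionResult(slope=0.0, intercept=float(y[0]), r2=0.0,
                                p_value=1.0, n=int(x.size))
    res = stats.linregress(x, y)
    return RegressionResult(slope=float(res.slope), intercept=float(res.intercept),
                            r2=float(res.rvalue ** 2), p_value=float(res.pvalue),
                            n=int(x.size))
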