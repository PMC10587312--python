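"""Noncompartmental analysis of single-dose IV bolus profiles.

Produces the standard exposure set — Cmax, back-extrapolated C0, terminal
slope lambda_z and t1/2, AUC/AUMC by trapezoids, AUC extrapolated to
infinity ("AUCall"), MRT, CL = dose/AUCinf and Vss = CL*MRT.

The default integrator is linear-up/log-down (linear trapezoids on rising
or flat segments, log-trapezoids on strictly decreasing positive
segments); a plain linear method is available for comparison.  The
terminal slope is a log-linear regression over the candidate tail subsets
(last 3..m points, never including the Cmax point), keeping the subset
with the best adjusted r-squared and breaking near-ties (within 1e-4)
toward more points.
"""

from __future__ import annotations

from typing import Sequence, Tuple

import numpy as np

from .errors import DomainError, InsufficientDataError, ValidationError
from .types import NCAResult

_ADJ_R2_TIE = 1e-4


def estimate_lambda_z(times: Sequence[float],
                      conc: Sequence[float]) -> Tuple[float, int, float]:
    """Terminal elimination rate constant by best-adjusted-r2 tail fit.

    Returns (lambda_z, n_points, adj_r2).  Raises if fewer than three
    positive post-peak points exist or no candidate subset decays.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(conc, dtype=float)
    if t.size != c.size:
        raise ValidationError("times and conc must have equal length")
    if np.any(np.diff(t) <= 0):
        raise ValidationError("times must be strictly increasing")
    imax = int(np.argmax(c))
    tail_idx = np.arange(imax + 1, t.size)
    tail_idx = tail_idx[c[tail_idx] > 0]
    m = tail_idx.size
    if m < 3:
        raise InsufficientDataError(
            f"need >= 3 positive post-peak points, have {m}")
    candidates = []  # (n, adj_r2, lambda_z)
    for n in range(3, m + 1):
        idx = tail_idx[-n:]
        x, y = t[idx], np.log(c[idx])
        slope, intercept = np.polyfit(x, y, 1)
        if slope >= 0:
            continue
        resid = y - (slope * x + intercept)
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
        adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
        candidates.append((n, adj, -slope))
    if not candidates:
        raise DomainError("no decaying terminal phase found on any subset")
    best_adj = max(adj for _, adj, _ in candidates)
    n, adj, lam = max(
        (cand for cand in candidates if cand[1] >= best_adj - _ADJ_R2_TIE),
        key=lambda cand: cand[0],
    )
    return float(lam), int(n), float(adj)


def auc_aumc(times: Sequence[float], conc: Sequence[float],
             method: str = "linear-up/log-down") -> Tuple[float, float]:
    """AUC and AUMC from t[0] to t[-1] by piecewise trapezoids."""
    if method not in ("linear", "linear-up/log-down"):
        raise ValidationError(f"unknown method {method!r}")
    t = np.asarray(times, dtype=float)
    c = np.asarray(conc, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValidationError("times must be strictly increasing")
    if np.any(c < 0):
        raise ValidationError("concentrations must be >= 0")
    auc = aumc = 0.0
    for i in range(t.size - 1):
        t1, t2, c1, c2 = t[i], t[i + 1], c[i], c[i + 1]
        dt = t2 - t1
        log_down = (method == "linear-up/log-down" and 0.0 < c2 < c1)
        if log_down:
            lam = np.log(c1 / c2) / dt
            auc += (c1 - c2) / lam
            aumc += (t1 * c1 - t2 * c2) / lam + (c1 - c2) / lam ** 2
        else:
            auc += 0.5 * dt * (c1 + c2)
            aumc += 0.5 * dt * (t1 * c1 + t2 * c2)
    return float(auc), float(aumc)


def nca_profile(dose_mg: float, times: Sequence[float], conc: Sequence[float],
                method: str = "linear-up/log-down") -> NCAResult:
    """Full NCA of a single-dose IV bolus concentration-time profile.

    C0 is the exponential back-extrapolation through the first two
    positive samples; AUCinf = AUClast + Clast/lambda_z;
    MRT = (AUMClast + Clast*tlast/lambda_z + Clast/lambda_z^2) / AUCinf;
    CL = 1000*dose/AUCinf (mL/h for dose in mg); Vss = CL*MRT.
    """
    if dose_mg <= 0:
        raise DomainError(f"dose_mg must be > 0, got {dose_mg}")
    t = np.asarray(times, dtype=float)
    c = np.asarray(conc, dtype=float)
    lam, n_lam, adj_r2 = estimate_lambda_z(t, c)
    auc_last, aumc_last = auc_aumc(t, c, method=method)
    pos = np.flatnonzero(c > 0)
    if pos.size < 2:
        raise InsufficientDataError("need >= 2 positive samples for C0")
    i1, i2 = pos[0], pos[1]
    slope0 = (np.log(c[i2]) - np.log(c[i1])) / (t[i2] - t[i1])
    c0 = float(np.exp(np.log(c[i1]) - slope0 * t[i1]))
    cmax = float(c.max())
    c_last, t_last = float(c[pos[-1]]), float(t[pos[-1]])
    auc_inf = auc_last + c_last / lam
    mrt = (aumc_last + c_last * t_last / lam + c_last / lam ** 2) / auc_inf
    cl = 1000.0 * dose_mg / auc_inf
    return NCAResult(
        cmax_ug_ml=cmax, c0_ug_ml=c0, lambda_z_per_h=lam,
        t_half_h=float(np.log(2.0) / lam), auc_last=auc_last, auc_inf=auc_inf,
        aumc_last=aumc_last, mrt_h=float(mrt), cl_ml_h=float(cl),
        vss_ml=float(cl * mrt), n_lambda_points=n_lam, adj_r2=adj_r2,
        c0_below_cmax=c0 < cmax,
    )
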