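"""HPLC method-validation arithmetic and BLOQ handling.

Covers the bioanalytical-validation computations used to qualify the
ceftriaxone plasma assay (calibration linearity over 2.5-100 ug/mL, LOD =
3.3*sigma/S and LOQ = 10*sigma/S from the intercept SE and slope,
intra/inter-day precision and recovery, USP-style system-suitability
metrics) plus Beal M5 imputation of below-LLOQ concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import DomainError, InsufficientDataError, ValidationError
from .types import ConcentrationSample

#: Lowest calibration level doubles as the default LLOQ (ug/mL).
DEFAULT_LLOQ_UG_ML = 2.5


@dataclass
class CalibrationFit:
    levels_ug_ml: List[float]
    mean_peak_areas: List[float]
    slope: float
    intercept: float
    sigma_intercept: Optional[float]   # None when df == 0 (only 2 levels)
    r: float
    lod: Optional[float]
    loq: Optional[float]
    sigma_undefined: bool = False


@dataclass
class SuitabilityMetrics:
    retention_time_min: float
    peak_width: float
    plates: float
    hetp_mm: float
    tailing: Optional[float]
    resolution: Optional[float]
    column_length_mm: float = 250.0


def fit_calibration(levels: Sequence[float], areas: Sequence[float]) -> CalibrationFit:
    """OLS of peak area on nominal concentration.

    sigma is the standard error of the intercept, the quantity that feeds
    the LOD/LOQ formulas.  With exactly two points the line is exact but
    sigma is undefined (zero residual degrees of freedom); the fit is
    returned with ``sigma_undefined=True`` and no LOD/LOQ.
    """
    x = np.asarray(levels, dtype=float)
    y = np.asarray(areas, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("levels and areas must have equal length")
    if np.unique(x).size < 2:
        raise DomainError("calibration levels are constant; design is singular")
    if x.size < 2:
        raise InsufficientDataError("need >= 2 calibration points")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    intercept, slope = float(model.params[0]), float(model.params[1])
    r = float(np.corrcoef(x, y)[0, 1])
    df_resid = x.size - 2
    if df_resid < 1:
        return CalibrationFit(list(x), list(y), slope, intercept, None, r,
                              None, None, sigma_undefined=True)
    sigma = float(model.bse[0])
    lod, loq = (lod_loq(sigma, slope) if slope > 0 else (None, None))
    return CalibrationFit(list(x), list(y), slope, intercept, sigma, r, lod, loq)


def lod_loq(sigma: float, slope: float) -> Tuple[float, float]:
    """LOD = 3.3*sigma/S, LOQ = 10*sigma/S (ICH approach from the
    intercept SD and calibration slope)."""
    if slope <= 0:
        raise DomainError(f"slope must be > 0, got {slope}")
    if sigma < 0:
        raise DomainError(f"sigma must be >= 0, got {sigma}")
    return 3.3 * sigma / slope, 10.0 * sigma / slope


def precision_accuracy(
    replicates: Dict[float, Dict[object, Sequence[float]]]
) -> pd.DataFrame:
    """Intra/inter-day precision and recovery per nominal level.

    ``replicates[nominal][day]`` is the list of found concentrations for
    that level and day.  Intra-day CV% is the mean of the within-day CVs;
    inter-day CV% pools every replicate across days (sd/grand mean); both
    use the sample SD.  Recovery% = 100 * grand mean / nominal.
    """
    rows = []
    for nominal, by_day in replicates.items():
        day_cvs = []
        pooled: List[float] = []
        for day, reps in by_day.items():
            arr = np.asarray(list(reps), dtype=float)
            if arr.size < 2:
                raise InsufficientDataError(
                    f"level {nominal}, day {day}: need >= 2 replicates")
            m = arr.mean()
            if m == 0:
                raise DomainError(f"level {nominal}, day {day}: zero mean, CV undefined")
            day_cvs.append(100.0 * arr.std(ddof=1) / m)
            pooled.extend(arr.tolist())
        pooled_arr = np.asarray(pooled)
        grand = pooled_arr.mean()
        if grand == 0:
            raise DomainError(f"level {nominal}: zero grand mean")
        rows.append({
            "nominal_ug_ml": float(nominal),
            "n_days": len(by_day),
            "n_replicates": int(pooled_arr.size),
            "intra_day_cv_percent": float(np.mean(day_cvs)),
            "inter_day_cv_percent": float(100.0 * pooled_arr.std(ddof=1) / grand),
            "recovery_percent": float(100.0 * grand / float(nominal)),
        })
    return pd.DataFrame(rows)


def system_suitability(
    retention_time_min: float,
    peak_width: float,
    width_at_5pct_height: Optional[float] = None,
    front_distance: Optional[float] = None,
    retention_time_2_min: Optional[float] = None,
    peak_width_2: Optional[float] = None,
    column_length_mm: float = 250.0,
) -> SuitabilityMetrics:
    """Chromatographic run-quality metrics.

    N = 16 (tR/W)^2; HETP = L/N; tailing = W_0.05h / (2 f) (USP 5%-height
    convention); Rs = 2 (tR2 - tR1) / (W1 + W2).
    """
    if peak_width <= 0 or retention_time_min <= 0:
        raise DomainError("retention time and peak width must be > 0")
    plates = 16.0 * (retention_time_min / peak_width) ** 2
    hetp = column_length_mm / plates
    tailing = None
    if width_at_5pct_height is not None:
        if front_distance is None or front_distance <= 0 or width_at_5pct_height <= 0:
            raise DomainError("tailing needs width_at_5pct_height > 0 and front_distance > 0")
        tailing = width_at_5pct_height / (2.0 * front_distance)
    resolution = None
    if retention_time_2_min is not None:
        if peak_width_2 is None or peak_width_2 <= 0:
            raise DomainError("resolution needs peak_width_2 > 0")
        if retention_time_2_min <= retention_time_min:
            raise DomainError("second peak must elute after the first")
        resolution = 2.0 * (retention_time_2_min - retention_time_min) / (
            peak_width + peak_width_2)
    return SuitabilityMetrics(
        retention_time_min=retention_time_min, peak_width=peak_width,
        plates=plates, hetp_mm=hetp, tailing=tailing, resolution=resolution,
        column_length_mm=column_length_mm,
    )


def impute_bloq(samples: Sequence[ConcentrationSample],
                lloq: float = DEFAULT_LLOQ_UG_ML) -> List[ConcentrationSample]:
    """Beal M5 imputation: every BLOQ sample gets conc = LLOQ/2.

    Non-BLOQ samples pass through untouched; the operation is idempotent
    and never reduces the number of usable (non-missing) samples.
    """
    if lloq <= 0:
        raise DomainError(f"lloq must be > 0, got {lloq}")
    out = []
    for s in samples:
        if s.bloq:
            out.append(replace(s, conc_ug_ml=lloq / 2.0, imputed=True))
        else:
            out.append(replace(s))
    return out
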