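"""Core domain types and the units policy.

Every operation in this package uses a single unit convention:

====================  =================
quantity              unit
====================  =================
time                  hours
concentration         ug/mL (== mg/L)
volume                mL
clearance             mL/h
dose amount           mg (1 mg = 1000 ug)
eGFR                  mL/min/1.73 m^2
====================  =================

Conversions are always explicit at the call site; nothing auto-detects or
auto-converts units.  Albumin is stored as printed in the source laboratory
table (the header says g/l but the reference range 3.5-5.5 follows the g/dL
convention); the field is therefore unit-agnostic and the hypoalbuminemia
threshold is configurable where it is used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Optional

from .errors import ValidationError

#: The package-wide units policy (documentation constant).
UNITS = {
    "time": "h",
    "concentration": "ug/mL",
    "volume": "mL",
    "clearance": "mL/h",
    "dose": "mg",
    "egfr": "mL/min/1.73m2",
}

ANALYTES = ("total", "free")


class LabPair(NamedTuple):
    """A laboratory value at baseline and after treatment.

    ``after`` may be None (missing follow-up); such pairs are excluded
    pairwise from paired statistics.
    """

    baseline: float
    after: Optional[float] = None

    def validate(self, name: str, minimum: float = 0.0) -> None:
        if not math.isfinite(self.baseline) or self.baseline < minimum:
            raise ValidationError(f"{name}: baseline {self.baseline!r} invalid")
        if self.after is not None:
            if not math.isfinite(self.after) or self.after < minimum:
                raise ValidationError(f"{name}: after {self.after!r} invalid")


@dataclass
class PatientRecord:
    """Demographics and baseline/after laboratory values for one patient."""

    patient_id: str
    sex: str                      # "M" | "F"
    age_months: float             # >= 1 and < 216 (study inclusion window)
    weight_kg: float
    height_cm: float
    indication: str
    duration_days: int
    scr_mg_dl: LabPair            # serum creatinine, must be > 0
    albumin: LabPair              # as printed (see module docstring)
    bilirubin_mg_dl: LabPair
    alt_iu_l: LabPair
    ast_iu_l: LabPair

    def __post_init__(self):
        if self.sex not in ("M", "F"):
            raise ValidationError(f"sex must be M or F, got {self.sex!r}")
        if not (1.0 <= self.age_months < 216.0):
            raise ValidationError(
                f"age_months {self.age_months} outside [1, 216) for {self.patient_id}"
            )
        for name, val in (("weight_kg", self.weight_kg), ("height_cm", self.height_cm)):
            if not (val > 0 and math.isfinite(val)):
                raise ValidationError(f"{name} must be > 0, got {val}")
        if int(self.duration_days) != self.duration_days or self.duration_days < 1:
            raise ValidationError(f"duration_days must be integer >= 1, got {self.duration_days}")
        for name, pair, lo in (
            ("scr_mg_dl", self.scr_mg_dl, 1e-12),
            ("albumin", self.albumin, 1e-12),
            ("bilirubin_mg_dl", self.bilirubin_mg_dl, 0.0),
            ("alt_iu_l", self.alt_iu_l, 0.0),
            ("ast_iu_l", self.ast_iu_l, 0.0),
        ):
            if not isinstance(pair, LabPair):
                object.__setattr__(self, name, LabPair(*pair))
                pair = getattr(self, name)
            pair.validate(name, minimum=lo)


@dataclass(frozen=True)
class DoseEvent:
    """One IV bolus administration; times are hours since the patient's first dose."""

    patient_id: str
    time_h: float
    amount_mg: float

    def __post_init__(self):
        if self.time_h < 0 or not math.isfinite(self.time_h):
            raise ValidationError(f"time_h must be >= 0, got {self.time_h}")
        if not (self.amount_mg > 0 and math.isfinite(self.amount_mg)):
            raise ValidationError(f"amount_mg must be > 0, got {self.amount_mg}")


@dataclass
class ConcentrationSample:
    """One measured plasma concentration (total or free analyte).

    ``bloq`` is True iff the measured value fell below the assay LLOQ; in
    that case ``conc_ug_ml`` is None until M5 imputation sets it to LLOQ/2
    (and flips ``imputed``).
    """

    patient_id: str
    analyte: str                  # "total" | "free"
    time_h: float                 # since first dose, > 0
    time_after_last_dose_h: float
    conc_ug_ml: Optional[float]
    bloq: bool = False
    imputed: bool = False

    def __post_init__(self):
        if self.analyte not in ANALYTES:
            raise ValidationError(f"analyte must be total|free, got {self.analyte!r}")
        if not self.time_h > 0:
            raise ValidationError(f"time_h must be > 0, got {self.time_h}")
        if not self.time_after_last_dose_h > 0:
            raise ValidationError(
                f"time_after_last_dose_h must be > 0, got {self.time_after_last_dose_h}"
            )
        if self.conc_ug_ml is None:
            if not self.bloq:
                raise ValidationError("conc_ug_ml missing on a non-BLOQ sample")
        elif self.conc_ug_ml < 0 or not math.isfinite(self.conc_ug_ml):
            raise ValidationError(f"conc_ug_ml must be >= 0, got {self.conc_ug_ml}")


@dataclass(frozen=True)
class Regimen:
    """A steady-state maintenance regimen: a fixed IV bolus every ``interval_h``."""

    dose_mg: float
    interval_h: float

    def __post_init__(self):
        if self.dose_mg <= 0 or self.interval_h <= 0:
            raise ValidationError("Regimen dose and interval must be > 0")


@dataclass
class NCAResult:
    """Noncompartmental exposure metrics for a single-dose IV bolus profile."""

    cmax_ug_ml: float
    c0_ug_ml: float
    lambda_z_per_h: float
    t_half_h: float
    auc_last: float
    auc_inf: float                # reported as "AUCall"
    aumc_last: float
    mrt_h: float
    cl_ml_h: float
    vss_ml: float
    n_lambda_points: int
    adj_r2: float
    c0_below_cmax: bool = False   # back-extrapolation sanity flag


@dataclass
class ModelFit:
    """A maximum-likelihood compartmental fit with its information criteria."""

    n_compartments: int
    analyte: str
    mode: str                     # "pooled" | "subject"
    params: dict                  # structural estimates, mL / mL/h
    sigma_mult: float             # SD of log-scale (multiplicative) residuals
    minus2ll: float
    k_params: int
    n_obs: int
    aic: float
    bic: float
    observed: list = field(default_factory=list)
    predicted: list = field(default_factory=list)
    residuals: list = field(default_factory=list)           # log-scale
    weighted_residuals: list = field(default_factory=list)  # residual / sigma
    converged: bool = True
    n_starts: int = 1
    seed: int = 0
    sigma_floored: bool = False

    def to_dict(self) -> dict:
        return {
            "n_compartments": self.n_compartments,
            "analyte": self.analyte,
            "mode": self.mode,
            "params": dict(self.params),
            "sigma_mult": self.sigma_mult,
            "minus2ll": self.minus2ll,
            "k_params": self.k_params,
            "n_obs": self.n_obs,
            "aic": self.aic,
            "bic": self.bic,
            "observed": list(self.observed),
            "predicted": list(self.predicted),
            "residuals": list(self.residuals),
            "weighted_residuals": list(self.weighted_residuals),
            "converged": self.converged,
            "n_starts": self.n_starts,
            "seed": self.seed,
        }


@dataclass
class PKResult:
    """Per-patient, per-analyte PK summary (compartmental + NCA)."""

    patient_id: str
    analyte: str
    vss_ml: float
    cl_ml_h: float
    t_half_h: float
    fu_percent: Optional[float]   # 100*CL_total/CL_free; only meaningful once
    cmax_ug_ml: float
    c0_ug_ml: float
    auc_all: float                # AUC extrapolated to infinity
    aumc_last: float

RESULT_COLUMNS = [
    "patient_id", "analyte", "vss_ml", "cl_ml_h", "t_half_h", "fu_percent",
    "cmax_ug_ml", "c0_ug_ml", "auc_all", "aumc_last",
]
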