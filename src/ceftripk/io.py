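"""CSV readers and writers for the cohort tables.

Dialect: comma-separated, UTF-8, '.' decimal, header row mandatory.
Schemas::

    patients.csv  patient_id,sex,age_months,weight_kg,height_cm,indication,
                  duration_days,scr_b,scr_a,alb_b,alb_a,bili_b,bili_a,
                  alt_b,alt_a,ast_b,ast_a
    doses.csv     patient_id,time_h,amount_mg
    conc.csv      patient_id,analyte,time_h,time_after_last_dose_h,
                  conc_ug_ml,bloq

"after" laboratory cells may be blank (missing follow-up).  A blank
conc_ug_ml is only legal on a BLOQ row.
"""

from __future__ import annotations

import math
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ParseError, SchemaError, ValidationError
from .types import (
    RESULT_COLUMNS,
    ConcentrationSample,
    DoseEvent,
    LabPair,
    PatientRecord,
    PKResult,
)

PATIENT_COLUMNS = [
    "patient_id", "sex", "age_months", "weight_kg", "height_cm", "indication",
    "duration_days", "scr_b", "scr_a", "alb_b", "alb_a", "bili_b", "bili_a",
    "alt_b", "alt_a", "ast_b", "ast_a",
]
DOSE_COLUMNS = ["patient_id", "time_h", "amount_mg"]
CONC_COLUMNS = [
    "patient_id", "analyte", "time_h", "time_after_last_dose_h", "conc_ug_ml", "bloq",
]


def _check_columns(df: pd.DataFrame, required: Sequence[str], name: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing column(s) {', '.join(missing)}")


def _num(df: pd.DataFrame, col: str, name: str, allow_blank: bool = False) -> pd.Series:
    raw = df[col]
    out = pd.to_numeric(raw, errors="coerce")
    blank = raw.isna() | (raw.astype(str).str.strip() == "")
    bad = out.isna() & ~blank
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ParseError(f"{name}: non-numeric value {raw.iloc[row]!r} in column "
                         f"{col!r} at row {row}")
    if not allow_blank and blank.any():
        row = int(np.flatnonzero(blank.to_numpy())[0])
        raise ParseError(f"{name}: blank cell in column {col!r} at row {row}")
    return out


def _pair(df: pd.DataFrame, b: str, a: str, name: str) -> List[LabPair]:
    base = _num(df, b, name)
    after = _num(df, a, name, allow_blank=True)
    return [
        LabPair(float(x), None if pd.isna(y) else float(y))
        for x, y in zip(base, after)
    ]


def read_patients(path) -> List[PatientRecord]:
    df = pd.read_csv(path, dtype={"patient_id": str})
    _check_columns(df, PATIENT_COLUMNS, "patients")
    scr = _pair(df, "scr_b", "scr_a", "patients")
    alb = _pair(df, "alb_b", "alb_a", "patients")
    bili = _pair(df, "bili_b", "bili_a", "patients")
    alt = _pair(df, "alt_b", "alt_a", "patients")
    ast = _pair(df, "ast_b", "ast_a", "patients")
    age = _num(df, "age_months", "patients")
    wt = _num(df, "weight_kg", "patients")
    ht = _num(df, "height_cm", "patients")
    dur = _num(df, "duration_days", "patients")
    records = []
    for i in range(len(df)):
        records.append(PatientRecord(
            patient_id=str(df["patient_id"].iloc[i]),
            sex=str(df["sex"].iloc[i]),
            age_months=float(age.iloc[i]),
            weight_kg=float(wt.iloc[i]),
            height_cm=float(ht.iloc[i]),
            indication=str(df["indication"].iloc[i]),
            duration_days=int(dur.iloc[i]),
            scr_mg_dl=scr[i], albumin=alb[i], bilirubin_mg_dl=bili[i],
            alt_iu_l=alt[i], ast_iu_l=ast[i],
        ))
    return records


def read_doses(path) -> List[DoseEvent]:
    df = pd.read_csv(path, dtype={"patient_id": str})
    _check_columns(df, DOSE_COLUMNS, "doses")
    t = _num(df, "time_h", "doses")
    amt = _num(df, "amount_mg", "doses")
    events = [
        DoseEvent(str(p), float(ti), float(a))
        for p, ti, a in zip(df["patient_id"], t, amt)
    ]
    last: dict = {}
    for ev in events:
        prev = last.get(ev.patient_id)
        if prev is not None and ev.time_h <= prev:
            raise ValidationError(
                f"doses for patient {ev.patient_id} not strictly increasing in time_h"
            )
        last[ev.patient_id] = ev.time_h
    return events


def read_concentrations(path) -> List[ConcentrationSample]:
    df = pd.read_csv(path, dtype={"patient_id": str})
    _check_columns(df, CONC_COLUMNS, "conc")
    if len(df) == 0:
        return []
    t = _num(df, "time_h", "conc")
    tald = _num(df, "time_after_last_dose_h", "conc")
    conc = _num(df, "conc_ug_ml", "conc", allow_blank=True)
    bloq = df["bloq"].astype(str).str.strip().str.lower().isin(("true", "1", "yes"))
    samples = []
    for i in range(len(df)):
        c = conc.iloc[i]
        samples.append(ConcentrationSample(
            patient_id=str(df["patient_id"].iloc[i]),
            analyte=str(df["analyte"].iloc[i]),
            time_h=float(t.iloc[i]),
            time_after_last_dose_h=float(tald.iloc[i]),
            conc_ug_ml=None if pd.isna(c) else float(c),
            bloq=bool(bloq.iloc[i]),
        ))
    return samples


def read_cohort(patients_path, doses_path, conc_path) -> Tuple[
    List[PatientRecord], List[DoseEvent], List[ConcentrationSample]
]:
    """Read the three cohort tables and reject orphan dose/sample rows."""
    patients = read_patients(patients_path)
    doses = read_doses(doses_path)
    samples = read_concentrations(conc_path)
    ids = {p.patient_id for p in patients}
    for ev in doses:
        if ev.patient_id not in ids:
            raise ValidationError(f"dose row for unknown patient {ev.patient_id!r}")
    for s in samples:
        if s.patient_id not in ids:
            raise ValidationError(f"sample row for unknown patient {s.patient_id!r}")
    return patients, doses, samples


def _fmt(x: Optional[float]) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return ""
    return f"{x:.6g}"


def write_results(results: Sequence[PKResult], path, allow_empty: bool = False) -> None:
    """Write per-patient PK results plus median/min/max summary rows.

    Numeric cells are written at 6 significant digits; a write/read
    round-trip is the identity at that precision.
    """
    if not results and not allow_empty:
        raise ValidationError("refusing to write empty results (pass allow_empty=True)")
    rows = []
    for r in results:
        rows.append({
            "patient_id": r.patient_id, "analyte": r.analyte,
            "vss_ml": r.vss_ml, "cl_ml_h": r.cl_ml_h, "t_half_h": r.t_half_h,
            "fu_percent": r.fu_percent, "cmax_ug_ml": r.cmax_ug_ml,
            "c0_ug_ml": r.c0_ug_ml, "auc_all": r.auc_all, "aumc_last": r.aumc_last,
        })
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    numeric = [c for c in RESULT_COLUMNS if c not in ("patient_id", "analyte")]
    out = df.copy()
    for c in numeric:
        out[c] = out[c].map(_fmt)
    if len(df):
        for stat, fn in (("median", np.nanmedian), ("min", np.nanmin), ("max", np.nanmax)):
            row = {"patient_id": stat, "analyte": ""}
            for c in numeric:
                vals = pd.to_numeric(df[c], errors="coerce").to_numpy(dtype=float)
                row[c] = _fmt(float(fn(vals))) if np.isfinite(vals).any() else ""
            out.loc[len(out)] = row
    out.to_csv(path, index=False)


def read_results(path) -> pd.DataFrame:
    """Read a results.csv back, excluding summary rows."""
    df = pd.read_csv(path, dtype={"patient_id": str})
    _check_columns(df, RESULT_COLUMNS, "results")
    return df[~df["patient_id"].isin(["median", "min", "max"])].reset_index(drop=True)
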