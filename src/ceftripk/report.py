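"""Cohort summaries, paired laboratory statistics and PK/PD attainment.

Summaries report median/min/max per numeric column (the convention of the
reference study's tables; median of an even n is the midpoint of the two
central values).  Paired laboratory changes use the paired t-test with a
t-based 95% CI and the Pearson correlation between baseline and after.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .compartmental import time_above_mic
from .errors import InsufficientDataError, ValidationError
from .renal import schwartz_egfr
from .types import ModelFit, PatientRecord, PKResult, Regimen

MIC_GRID_MG_L = (0.5, 1.0, 2.0)
ATTAINMENT_THRESHOLDS = (60.0, 70.0)


@dataclass
class CohortSummary:
    n_patients: int
    numeric: pd.DataFrame         # index: column; columns: median, min, max
    indications: pd.DataFrame     # indication, count, percent


@dataclass
class PairedChange:
    lab: str
    n_pairs: int
    mean_difference: float        # baseline - after
    ci95: tuple
    p_value: float
    pearson_r: float


def _patient_frame(patients: Sequence[PatientRecord]) -> pd.DataFrame:
    rows = []
    for p in patients:
        rows.append({
            "age_months": p.age_months, "weight_kg": p.weight_kg,
            "height_cm": p.height_cm, "duration_days": p.duration_days,
            "bili_b": p.bilirubin_mg_dl.baseline, "bili_a": p.bilirubin_mg_dl.after,
            "alb_b": p.albumin.baseline, "alb_a": p.albumin.after,
            "scr_b": p.scr_mg_dl.baseline, "scr_a": p.scr_mg_dl.after,
            "alt_b": p.alt_iu_l.baseline, "alt_a": p.alt_iu_l.after,
            "ast_b": p.ast_iu_l.baseline, "ast_a": p.ast_iu_l.after,
            "egfr_b": schwartz_egfr(p.height_cm, p.scr_mg_dl.baseline),
            "egfr_a": (schwartz_egfr(p.height_cm, p.scr_mg_dl.after)
                       if p.scr_mg_dl.after is not None else np.nan),
            "indication": p.indication,
        })
    return pd.DataFrame(rows)


def summarize_cohort(patients: Sequence[PatientRecord],
                     pk_results: Optional[Sequence[PKResult]] = None) -> CohortSummary:
    """Median/min/max of every numeric column plus indication counts.

    eGFR (baseline and after) is recomputed from height and creatinine via
    the bedside Schwartz equation before summarizing.
    """
    if not patients:
        raise ValidationError("empty cohort")
    df = _patient_frame(patients)
    numeric = df.drop(columns=["indication"])
    if pk_results:
        pk = pd.DataFrame([{
            f"{r.analyte}_{name}": getattr(r, name)
            for name in ("vss_ml", "cl_ml_h", "t_half_h", "cmax_ug_ml",
                         "c0_ug_ml", "auc_all", "aumc_last")
        } | {"patient_id": r.patient_id} for r in pk_results])
        pk = pk.groupby("patient_id").first().reset_index(drop=True)
        numeric = pd.concat([numeric.reset_index(drop=True), pk], axis=1)
    summary = pd.DataFrame({
        "median": numeric.median(),
        "min": numeric.min(),
        "max": numeric.max(),
    })
    return CohortSummary(n_patients=len(patients), numeric=summary,
                         indications=indication_breakdown(patients))


def indication_breakdown(patients: Sequence[PatientRecord]) -> pd.DataFrame:
    """Counts and one-decimal percents per indication string.

    Compound indications (e.g. "Meningitis, Gastroenteritis") count as
    their own category, as in the source table.
    """
    counts: Dict[str, int] = {}
    for p in patients:
        counts[p.indication] = counts.get(p.indication, 0) + 1
    n = len(patients)
    rows = [{"indication": k, "count": v,
             "percent": round(100.0 * v / n, 1)}
            for k, v in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))]
    return pd.DataFrame(rows)


def paired_lab_change(baseline: Sequence[float], after: Sequence[float],
                      lab: str = "") -> PairedChange:
    """Paired t statistics for a before/after laboratory value.

    Pairs with a missing member are dropped.  Difference is baseline -
    after; the CI uses t_{n-1} at 95%.  Conventions: identical vectors
    give p = 1; a constant series on either side makes r undefined -> nan
    unless both vectors are equal elementwise (r = 1).
    """
    b = np.asarray(baseline, dtype=float)
    a = np.asarray(after, dtype=float)
    if b.size != a.size:
        raise ValidationError("baseline and after must have equal length")
    keep = ~(np.isnan(b) | np.isnan(a))
    b, a = b[keep], a[keep]
    n = b.size
    if n < 2:
        raise InsufficientDataError("need >= 2 complete pairs")
    diff = b - a
    mean_diff = float(diff.mean())
    sd = float(diff.std(ddof=1))
    tcrit = stats.t.ppf(0.975, n - 1)
    half = tcrit * sd / np.sqrt(n)
    if sd == 0:
        p = 1.0
    else:
        p = float(stats.ttest_rel(b, a).pvalue)
    if np.ptp(b) == 0 or np.ptp(a) == 0:
        r = 1.0 if np.array_equal(b, a) else float("nan")
    else:
        r = float(stats.pearsonr(b, a).statistic)
    return PairedChange(lab=lab, n_pairs=int(n), mean_difference=mean_diff,
                        ci95=(mean_diff - half, mean_diff + half),
                        p_value=p, pearson_r=r)


def paired_lab_report(patients: Sequence[PatientRecord],
                      labs: Iterable[str] = ("bilirubin_mg_dl", "alt_iu_l", "ast_iu_l"),
                      holm: bool = False) -> pd.DataFrame:
    """Paired before/after tests for the standard liver panel.

    Raw p-values by default (as reported in the reference study); pass
    ``holm=True`` for a Holm step-down adjustment column.
    """
    rows = []
    changes = []
    for lab in labs:
        pairs = [getattr(p, lab) for p in patients]
        b = [pr.baseline for pr in pairs if pr.after is not None]
        a = [pr.after for pr in pairs if pr.after is not None]
        changes.append(paired_lab_change(b, a, lab=lab))
    for ch in changes:
        rows.append({
            "lab": ch.lab, "n_pairs": ch.n_pairs,
            "mean_difference": ch.mean_difference,
            "ci95_lo": ch.ci95[0], "ci95_hi": ch.ci95[1],
            "p_value": ch.p_value, "pearson_r": ch.pearson_r,
        })
    df = pd.DataFrame(rows)
    if holm:
        order = np.argsort(df["p_value"].to_numpy())
        m = len(df)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * df["p_value"].iloc[idx])
            adj[idx] = min(running, 1.0)
        df["p_holm"] = adj
    return df


def attainment_report(fits: Dict[str, ModelFit],
                      regimens: Dict[str, Regimen],
                      fu: Dict[str, float],
                      mic_grid: Sequence[float] = MIC_GRID_MG_L) -> pd.DataFrame:
    """Per-patient %fT>MIC across the MIC grid with 60/70% attainment flags.

    ``fits`` are per-subject total-analyte fits; ``fu`` maps patient to
    unbound fraction (proportion).
    """
    from .compartmental import OneCompartment, TwoCompartment  # local: avoid cycle

    rows = []
    for pid, fit in fits.items():
        if fit.n_compartments == 1:
            model = OneCompartment(v_ml=fit.params["v_ml"],
                                   cl_ml_h=fit.params["cl_ml_h"])
        else:
            model = TwoCompartment(v1_ml=fit.params["v1_ml"],
                                   cl_ml_h=fit.params["cl_ml_h"],
                                   v2_ml=fit.params["v2_ml"],
                                   q_ml_h=fit.params["q_ml_h"])
        for mic in mic_grid:
            pct = time_above_mic(model, regimens[pid], mic, fu=fu[pid])
            rows.append({
                "patient_id": pid, "mic_mg_l": mic, "ft_above_mic_percent": pct,
                "attained_60": pct >= ATTAINMENT_THRESHOLDS[0],
                "attained_70": pct >= ATTAINMENT_THRESHOLDS[1],
            })
    return pd.DataFrame(rows)
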