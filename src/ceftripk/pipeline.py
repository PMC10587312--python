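"""End-to-end pipeline: simulate (or load) -> impute BLOQ -> fit 1c/2c ->
compare -> simulate fitted profiles -> NCA -> renal/binding -> summaries.

Mirrors the reference study's workflow: NCA runs on the noise-free
profile simulated from each patient's fitted one-compartment parameters,
not on the three raw troughs.  Deterministic for a fixed seed; each stage
is logged with its wall time and the input hashes.
"""

from __future__ import annotations

import hashlib
import json
import os
import time
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import io as cio
from .assay import DEFAULT_LLOQ_UG_ML, impute_bloq
from .compartmental import (
    OneCompartment,
    compare_models,
    diagnostics,
    fit_model,
    fit_per_subject,
)
from .errors import CeftripkError, ConfigError
from .nca import nca_profile
from .renal import (
    covariate_regression,
    regress_cl_egfr,
    schwartz_egfr,
    unbound_fraction_avg,
    unbound_fraction_observed,
)
from .report import attainment_report, indication_breakdown, paired_lab_report
from .synthetic import GeneratorConfig, generate_cohort, simulate_profile, write_cohort
from .types import DoseEvent, PKResult, Regimen


def _hash_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        h.update(fh.read())
    return h.hexdigest()[:12]


class _StageLog:
    def __init__(self, path):
        self.path = path
        self.lines: List[str] = []

    def add(self, stage: str, message: str) -> None:
        self.lines.append(f"{stage}: {message}")
        with open(self.path, "w") as fh:
            fh.write("\n".join(self.lines) + "\n")


def _regimen_for(doses: Sequence[DoseEvent]) -> Regimen:
    times = [d.time_h for d in doses]
    tau = float(np.median(np.diff(times))) if len(times) > 1 else 24.0
    return Regimen(dose_mg=float(np.mean([d.amount_mg for d in doses])),
                   interval_h=tau)


def run_pipeline(out_dir: str,
                 config: Optional[GeneratorConfig] = None,
                 seed: int = 0,
                 input_dir: Optional[str] = None,
                 lloq: float = DEFAULT_LLOQ_UG_ML,
                 profile_points: int = 73) -> dict:
    """Run every stage and persist artifacts under ``out_dir``.

    Either ``config`` (simulate a cohort) or ``input_dir`` (read
    patients/doses/conc CSVs) must be given.  Returns the summary dict
    that is also written to summary.json.
    """
    if (config is None) == (input_dir is None):
        raise ConfigError("provide exactly one of config (simulate) or input_dir")
    os.makedirs(out_dir, exist_ok=True)
    log = _StageLog(os.path.join(out_dir, "pipeline.log"))
    log.add("setup", f"seed={seed}")
    t0 = time.perf_counter()

    stage = "simulate" if config is not None else "load"
    try:
        if config is not None:
            patients, doses, samples, truth = generate_cohort(config)
            write_cohort(patients, doses, samples, truth, out_dir)
            lloq = config.lloq_ug_ml
        else:
            patients, doses, samples = cio.read_cohort(
                os.path.join(input_dir, "patients.csv"),
                os.path.join(input_dir, "doses.csv"),
                os.path.join(input_dir, "conc.csv"))
            for name in ("patients.csv", "doses.csv", "conc.csv"):
                log.add("load", f"{name} sha256/12={_hash_file(os.path.join(input_dir, name))}")
        log.add(stage, f"{len(patients)} patients, {len(doses)} doses, "
                       f"{len(samples)} samples ({time.perf_counter() - t0:.2f}s)")

        stage = "impute_bloq"
        n_bloq = sum(s.bloq for s in samples)
        samples = impute_bloq(samples, lloq=lloq)
        log.add(stage, f"{n_bloq} BLOQ samples set to LLOQ/2 = {lloq / 2}")

        stage = "fit"
        pooled: Dict[str, dict] = {}
        subject_fits: Dict[str, Dict[str, object]] = {}
        for analyte in ("total", "free"):
            f1 = fit_model(samples, doses, n_compartments=1, mode="pooled",
                           seed=seed, analyte=analyte, tol=1e-10)
            f2 = fit_model(samples, doses, n_compartments=2, mode="pooled",
                           seed=seed, analyte=analyte, tol=1e-10)
            sel = compare_models(f1, f2)
            pooled[analyte] = {"1c": f1, "2c": f2, "selection": sel}
            subject_fits[analyte] = fit_per_subject(
                samples, doses, n_compartments=1, seed=seed, analyte=analyte)
            log.add(stage, f"{analyte}: pooled AIC 1c={f1.aic:.4f} 2c={f2.aic:.4f} "
                           f"-> {sel.selected}")
        with open(os.path.join(out_dir, "fit.json"), "w") as fh:
            json.dump({
                analyte: {
                    "pooled_1c": pooled[analyte]["1c"].to_dict(),
                    "pooled_2c": pooled[analyte]["2c"].to_dict(),
                    "selected": pooled[analyte]["selection"].selected,
                    "diagnostics_1c": diagnostics(pooled[analyte]["1c"]),
                    "subjects": {pid: f.to_dict()
                                 for pid, f in subject_fits[analyte].items()},
                } for analyte in ("total", "free")
            }, fh, indent=2)

        stage = "nca"
        pk_results: List[PKResult] = []
        pids = sorted({p.patient_id for p in patients}, key=lambda x: (len(x), x))
        fu_avg: Dict[str, float] = {}
        for pid in pids:
            ft = subject_fits["total"].get(pid)
            ff = subject_fits["free"].get(pid)
            if ft is not None and ff is not None:
                fu_avg[pid] = unbound_fraction_avg(ft.params["cl_ml_h"],
                                                   ff.params["cl_ml_h"])
        for analyte in ("total", "free"):
            for pid in pids:
                fit = subject_fits[analyte].get(pid)
                if fit is None:
                    continue
                pt_doses = [d for d in doses if d.patient_id == pid]
                dose_mg = pt_doses[0].amount_mg
                v, cl = fit.params["v_ml"], fit.params["cl_ml_h"]
                t_half = np.log(2.0) * v / cl
                grid = np.linspace(0.0, 7.0 * t_half, profile_points)
                single = [DoseEvent(pid, 0.0, dose_mg)]
                conc = simulate_profile(v, cl, single, grid)
                res = nca_profile(dose_mg, grid, conc)
                pk_results.append(PKResult(
                    patient_id=pid, analyte=analyte, vss_ml=res.vss_ml,
                    cl_ml_h=res.cl_ml_h, t_half_h=res.t_half_h,
                    fu_percent=fu_avg.get(pid) if analyte == "total" else None,
                    cmax_ug_ml=res.cmax_ug_ml, c0_ug_ml=res.c0_ug_ml,
                    auc_all=res.auc_inf, aumc_last=res.aumc_last))
        cio.write_results(pk_results, os.path.join(out_dir, "results.csv"))
        log.add(stage, f"{len(pk_results)} patient-analyte NCA rows")

        stage = "renal_binding"
        egfr_b = {p.patient_id: schwartz_egfr(p.height_cm, p.scr_mg_dl.baseline)
                  for p in patients}
        cl_free = {pid: f.params["cl_ml_h"]
                   for pid, f in subject_fits["free"].items()}
        cl_total = {pid: f.params["cl_ml_h"]
                    for pid, f in subject_fits["total"].items()}
        common = sorted(set(cl_free) & set(egfr_b), key=lambda x: (len(x), x))
        reg_free = regress_cl_egfr([cl_free[p] for p in common],
                                   [egfr_b[p] for p in common])
        reg_total = regress_cl_egfr([cl_total[p] for p in common],
                                    [egfr_b[p] for p in common])
        weights = {p.patient_id: p.weight_kg for p in patients}
        cov = covariate_regression([cl_total[p] for p in common],
                                   [weights[p] for p in common],
                                   transform="log-log")
        try:
            fu_obs = unbound_fraction_observed(samples)
        except CeftripkError:
            fu_obs = {}
        renal = {
            "egfr_baseline": egfr_b,
            "fu_avg_percent": fu_avg,
            "fu_observed_range_percent": {k: list(v) for k, v in fu_obs.items()},
            "cl_free_vs_egfr": {"slope": reg_free.slope,
                                "intercept": reg_free.intercept, "r2": reg_free.r2},
            "cl_total_vs_egfr": {"slope": reg_total.slope,
                                 "intercept": reg_total.intercept, "r2": reg_total.r2},
            "cl_total_vs_weight_loglog": {"slope": cov.slope, "p_value": cov.p_value,
                                          "r2": cov.r2},
        }
        with open(os.path.join(out_dir, "renal.json"), "w") as fh:
            json.dump(renal, fh, indent=2)
        log.add(stage, f"CL_free~eGFR r2={reg_free.r2:.4f}")

        stage = "attainment"
        regimens = {pid: _regimen_for([d for d in doses if d.patient_id == pid])
                    for pid in pids}
        fu_prop = {pid: min(fu_avg.get(pid, 100.0) / 100.0, 1.0) for pid in pids}
        attain = attainment_report(subject_fits["total"], regimens, fu_prop)
        attain.to_csv(os.path.join(out_dir, "attainment.csv"), index=False)
        log.add(stage, f"{len(attain)} patient x MIC rows")

        stage = "summaries"
        labs = paired_lab_report(patients)
        summary = {
            "seed": seed,
            "n_patients": len(patients),
            "n_samples": len(samples),
            "n_bloq": int(n_bloq),
            "model_selection": {a: pooled[a]["selection"].selected
                                for a in ("total", "free")},
            "aic": {a: {"1c": pooled[a]["1c"].aic, "2c": pooled[a]["2c"].aic}
                    for a in ("total", "free")},
            "bic": {a: {"1c": pooled[a]["1c"].bic, "2c": pooled[a]["2c"].bic}
                    for a in ("total", "free")},
            "median_cl_total_ml_h": float(np.median(list(cl_total.values()))),
            "median_fu_percent": float(np.median(list(fu_avg.values())))
                                 if fu_avg else None,
            "egfr_median_baseline": float(np.median(list(egfr_b.values()))),
            "indications": indication_breakdown(patients).to_dict(orient="records"),
            "paired_labs": labs.to_dict(orient="records"),
            "attainment_60_all_mics_fraction": float(
                attain.groupby("patient_id")["attained_60"].all().mean()),
            "cl_free_vs_egfr_r2": reg_free.r2,
        }
        with open(os.path.join(out_dir, "summary.json"), "w") as fh:
            json.dump(summary, fh, indent=2)
        log.add("done", f"total {time.perf_counter() - t0:.2f}s")
        return summary
    except Exception as exc:
        log.add("error", f"stage {stage} failed: {exc}")
        raise
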