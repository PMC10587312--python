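#!/usr/bin/env python
"""Noncompartmental analysis of profiles simulated from the fits.

Matches the reference study's workflow: each patient's fitted
one-compartment parameters generate a noise-free single-dose profile,
which is then analyzed noncompartmentally (Cmax, C0, AUCinf, AUMC, CL,
Vss, t1/2).  Free-analyte clearance combined with total clearance gives
the average unbound fraction per patient.  Writes results/nca/.
Run steps 02-03 first (this script refits per subject from the CSVs).
"""

import os
import sys

import numpy as np
import pandas as pd

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from ceftripk.assay import impute_bloq
from ceftripk.compartmental import fit_per_subject
from ceftripk.io import read_cohort, write_results
from ceftripk.nca import nca_profile
from ceftripk.renal import unbound_fraction_avg
from ceftripk.synthetic import simulate_profile
from ceftripk.types import DoseEvent, PKResult

BASE = os.path.join(os.path.dirname(__file__), "..", "results")
IN = os.path.join(BASE, "synthetic")
OUT = os.path.join(BASE, "nca")
os.makedirs(OUT, exist_ok=True)
SEED = 42

patients, doses, samples = read_cohort(
    os.path.join(IN, "patients.csv"), os.path.join(IN, "doses.csv"),
    os.path.join(IN, "conc.csv"))
samples = impute_bloq(samples, lloq=2.5)

fits = {a: fit_per_subject(samples, doses, 1, seed=SEED, analyte=a)
        for a in ("total", "free")}
fu = {pid: unbound_fraction_avg(fits["total"][pid].params["cl_ml_h"],
                                fits["free"][pid].params["cl_ml_h"])
      for pid in fits["total"]}

results = []
for analyte in ("total", "free"):
    for pid, fit in fits[analyte].items():
        dose_mg = next(d.amount_mg for d in doses if d.patient_id == pid)
        v, cl = fit.params["v_ml"], fit.params["cl_ml_h"]
        grid = np.linspace(0.0, 7.0 * np.log(2) * v / cl, 73)
        conc = simulate_profile(v, cl, [DoseEvent(pid, 0.0, dose_mg)], grid)
        r = nca_profile(dose_mg, grid, conc)
        results.append(PKResult(
            patient_id=pid, analyte=analyte, vss_ml=r.vss_ml, cl_ml_h=r.cl_ml_h,
            t_half_h=r.t_half_h, fu_percent=fu[pid] if analyte == "total" else None,
            cmax_ug_ml=r.cmax_ug_ml, c0_ug_ml=r.c0_ug_ml, auc_all=r.auc_inf,
            aumc_last=r.aumc_last))

write_results(results, os.path.join(OUT, "results.csv"))
df = pd.DataFrame([vars(r) for r in results])
for analyte in ("total", "free"):
    sub = df[df.analyte == analyte]
    print(f"{analyte}: median CL {sub.cl_ml_h.median():.1f} mL/h, "
          f"median Vss {sub.vss_ml.median():.0f} mL, "
          f"median t1/2 {sub.t_half_h.median():.2f} h, "
          f"median AUCinf {sub.auc_all.median():.0f} h*ug/mL")
print(f"median unbound fraction {np.median(list(fu.values())):.1f}%")
print(f"wrote {os.path.abspath(OUT)}/results.csv")
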