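#!/usr/bin/env python
"""PK/PD target attainment: %fT>MIC over the EUCAST-relevant MIC window.

For each synthetic patient's fitted one-compartment model and actual
regimen, computes the percent of the steady-state dosing interval during
which free concentration exceeds MIC in {0.5, 1, 2} mg/L, with the
60%/70% efficacy-threshold flags used for time-dependent beta-lactam
killing.  Writes results/attainment.csv.  Run step 02 first.
"""

import os
import sys

import numpy as np

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from ceftripk.assay import impute_bloq
from ceftripk.compartmental import fit_per_subject
from ceftripk.io import read_cohort
from ceftripk.renal import unbound_fraction_avg
from ceftripk.report import attainment_report
from ceftripk.types import Regimen

BASE = os.path.join(os.path.dirname(__file__), "..", "results")
IN = os.path.join(BASE, "synthetic")
SEED = 42

patients, doses, samples = read_cohort(
    os.path.join(IN, "patients.csv"), os.path.join(IN, "doses.csv"),
    os.path.join(IN, "conc.csv"))
samples = impute_bloq(samples, lloq=2.5)
fits = {a: fit_per_subject(samples, doses, 1, seed=SEED, analyte=a)
        for a in ("total", "free")}

regimens, fu = {}, {}
for pid in fits["total"]:
    pt = [d for d in doses if d.patient_id == pid]
    tau = float(np.median(np.diff([d.time_h for d in pt])))
    regimens[pid] = Regimen(dose_mg=pt[0].amount_mg, interval_h=tau)
    fu[pid] = min(unbound_fraction_avg(fits["total"][pid].params["cl_ml_h"],
                                       fits["free"][pid].params["cl_ml_h"]),
                  100.0) / 100.0

table = attainment_report(fits["total"], regimens, fu)
table.to_csv(os.path.join(BASE, "attainment.csv"), index=False)

for mic in (0.5, 1.0, 2.0):
    sub = table[table.mic_mg_l == mic]
    print(f"MIC {mic:>3} mg/L: median %fT>MIC {sub.ft_above_mic_percent.median():5.1f}; "
          f"{int(sub.attained_60.sum())}/{len(sub)} patients >= 60%, "
          f"{int(sub.attained_70.sum())}/{len(sub)} >= 70%")
print(f"wrote {os.path.abspath(os.path.join(BASE, 'attainment.csv'))}")
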