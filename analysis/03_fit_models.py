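#!/usr/bin/env python
"""Fit compartmental models to the synthetic cohort of step 02.

BLOQ-imputes (Beal M5), fits pooled one- and two-compartment models per
analyte with multiplicative error, compares them by AIC/BIC, then fits
the selected one-compartment model per subject and checks recovery of
the generator's ground truth.  Writes results/fits/.
Run analysis/02_simulate_cohort.py first.
"""

import json
import os
import sys

import numpy as np
import pandas as pd

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from ceftripk.assay import impute_bloq
from ceftripk.compartmental import compare_models, diagnostics, fit_model, fit_per_subject
from ceftripk.io import read_cohort

BASE = os.path.join(os.path.dirname(__file__), "..", "results")
IN = os.path.join(BASE, "synthetic")
OUT = os.path.join(BASE, "fits")
os.makedirs(OUT, exist_ok=True)
SEED = 42

patients, doses, samples = read_cohort(
    os.path.join(IN, "patients.csv"), os.path.join(IN, "doses.csv"),
    os.path.join(IN, "conc.csv"))
samples = impute_bloq(samples, lloq=2.5)
truth = pd.DataFrame(json.load(open(os.path.join(IN, "truth.json")))["params"])

artifacts = {}
for analyte in ("total", "free"):
    f1 = fit_model(samples, doses, 1, "pooled", seed=SEED, analyte=analyte, tol=1e-10)
    f2 = fit_model(samples, doses, 2, "pooled", seed=SEED, analyte=analyte, tol=1e-10)
    sel = compare_models(f1, f2)
    print(f"{analyte}: pooled AIC 1c {f1.aic:.2f} vs 2c {f2.aic:.2f} -> "
          f"{sel.selected} selected "
          f"({'criteria agree' if sel.criteria_agree else 'AIC/BIC disagree'})")
    artifacts[analyte] = {"pooled_1c": f1.to_dict(), "pooled_2c": f2.to_dict(),
                          "selected": sel.selected,
                          "diagnostics_1c": diagnostics(f1)}

subj = fit_per_subject(samples, doses, 1, seed=SEED, analyte="total")
rows = []
for r in truth.itertuples():
    fit = subj[r.patient_id]
    rows.append({"patient_id": r.patient_id,
                 "v_ml_true": r.v_ml, "v_ml_est": fit.params["v_ml"],
                 "cl_ml_h_true": r.cl_ml_h, "cl_ml_h_est": fit.params["cl_ml_h"]})
rec = pd.DataFrame(rows)
rec["cl_rel_err_percent"] = 100 * (rec.cl_ml_h_est - rec.cl_ml_h_true) / rec.cl_ml_h_true
rec["v_rel_err_percent"] = 100 * (rec.v_ml_est - rec.v_ml_true) / rec.v_ml_true
rec.to_csv(os.path.join(OUT, "subject_recovery.csv"), index=False)
n_degenerate = int((rec.cl_rel_err_percent.abs() > 90).sum())
print(f"per-subject 1c (total, 3 troughs each): median |CL err| "
      f"{rec.cl_rel_err_percent.abs().median():.1f}%, median |V err| "
      f"{rec.v_rel_err_percent.abs().median():.1f}% at 10% assay noise; "
      f"{n_degenerate}/24 subjects weakly identified (flat-curve optimum) — "
      "the known limitation of trough-only sampling without pooling")

with open(os.path.join(OUT, "fit.json"), "w") as fh:
    json.dump(artifacts, fh, indent=2)
print(f"wrote {os.path.abspath(OUT)}")
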