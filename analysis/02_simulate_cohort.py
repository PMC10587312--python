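#!/usr/bin/env python
"""Generate the default synthetic cohort (the study's design conditions).

24 patients, 2.5 months-12 years, IV bolus 50-100 mg/kg q12-24 h for
5-21 days, three troughs per patient, total + free analytes, 10%
multiplicative assay noise, LLOQ 2.5 ug/mL.  Writes the three cohort
CSVs plus ground truth to results/synthetic/.
"""

import os
import sys

import numpy as np

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from ceftripk.synthetic import GeneratorConfig, generate_cohort, write_cohort

SEED = 42
OUT = os.path.join(os.path.dirname(__file__), "..", "results", "synthetic")

cfg = GeneratorConfig(seed=SEED)
patients, doses, samples, truth = generate_cohort(cfg)
write_cohort(patients, doses, samples, truth, OUT)
cfg.to_json(os.path.join(OUT, "config.json"))

n_bloq = sum(s.bloq for s in samples)
fu = truth.params["fu"]
print(f"seed {SEED}: {len(patients)} patients, {len(doses)} dose events, "
      f"{len(samples)} concentration samples ({n_bloq} BLOQ)")
print(f"true fu spans {100 * fu.min():.1f}-{100 * fu.max():.1f}% "
      f"(median {100 * fu.median():.1f}%)")
print(f"true CL {truth.params.cl_ml_h.min():.0f}-{truth.params.cl_ml_h.max():.0f} "
      f"mL/h; V {truth.params.v_ml.min():.0f}-{truth.params.v_ml.max():.0f} mL")
print(f"wrote cohort to {os.path.abspath(OUT)}")
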