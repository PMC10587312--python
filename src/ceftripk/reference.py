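"""Reference cohort: published per-patient data for the reanalyzed study.

The source clinical study reports, for 24 hospitalized pediatric patients
who received IV bolus ceftriaxone (50-100 mg/kg q12-24 h):

* demographics and baseline/after laboratory values (plus the eGFR columns
  the study itself computed with the bedside Schwartz equation),
* fitted per-patient PK parameters for total and free drug (Vss, CL,
  CL/eGFR, t1/2) and the derived unbound-fraction columns,
* per-patient exposure metrics (Cmax, C0, AUC to infinity, AUMC),
* population model-selection diagnostics (AIC/BIC/LogLik/-2LL) for the
  one- and two-compartment multiplicative-error fits of each analyte.

Values are stored exactly as printed and serve as *inputs* to the
reanalysis (raw concentrations were not published).  The printed
``CL/eGFR`` column's units are not stated in the source and cannot be
reproduced from the adjacent columns; it is carried verbatim with that
caveat.  The printed t1/2 columns are not consistent with ln2*Vss/CL and
are likewise carried verbatim only.
"""

from __future__ import annotations

from typing import List

import pandas as pd

from .types import LabPair, PatientRecord

# patient_id, indication, duration_days, sex, age_months, weight_kg, height_cm,
# bili_b, bili_a, alb_b, alb_a, scr_b, scr_a, alt_b, alt_a, ast_b, ast_a,
# egfr_b (as printed), egfr_a (as printed)
_DEMOGRAPHICS = [
    ("1", "Pneumonia", 14, "F", 9, 9.5, 70, 0.2, 0.28, 3.7, 3.9, 1.1, 0.5, 10, 20, 27, 35, 26.3, 57.8),
    ("2", "Meningitis", 10, "F", 2.5, 1.7, 40, 0.2, 0.25, 3.3, 3.5, 0.3, 0.4, 30, 35, 55, 68, 55.1, 41.3),
    ("3", "Urinary Tract Infection", 5, "F", 36, 17.5, 94, 0.1, 0.3, 0.87, 0.87, 0.3, 0.1, 8.4, 15, 31.8, 40, 129.4, 388.2),
    ("4", "Peritonitis", 14, "M", 108, 24, 133.5, 0.08, 0.2, 1.87, 1.4, 0.23, 0.1, 18.8, 29, 25.6, 29, 239.7, 551.4),
    ("5", "Infective Endocarditis", 21, "M", 48, 14, 103, 0.3, 0.4, 4.35, 3.74, 1.96, 1.06, 4.1, 13.8, 9.4, 37, 21.7, 40.1),
    ("6", "Meningitis", 10, "M", 144, 35, 150, 0.1, 0.2, 4.2, 4.2, 0.63, 0.5, 15, 17, 24, 28, 98.3, 123.9),
    ("7", "Pneumonia", 14, "F", 22, 11, 76, 0.2, 0.27, 4.5, 4.5, 0.38, 0.36, 14, 16, 20, 22, 82.6, 87.2),
    ("8", "Meningitis", 10, "M", 8, 9, 70, 0.1, 0.2, 4.1, 4.1, 0.5, 0.42, 15, 20, 50, 60, 57.8, 68.8),
    ("9", "Meningitis", 14, "M", 5, 7.5, 66, 0.1, 0.2, 3.0, 4.0, 0.53, 0.5, 19, 23, 40, 49, 51.4, 54.5),
    ("10", "Pneumonia", 7, "F", 26, 10.3, 77, 0.2, 0.25, 4.5, 4.5, 0.64, 0.55, 12, 17, 23, 61, 49.7, 57.8),
    ("11", "Meningitis", 10, "F", 132, 34, 145, 0.2, 0.29, 4.4, 4.4, 1.0, 0.9, 16, 18, 25, 29, 59.9, 66.5),
    ("12", "Meningitis", 10, "F", 16, 11.5, 76, 0.1, 0.22, 4.3, 4.3, 0.6, 0.4, 18, 20, 20, 21, 52.3, 78.5),
    ("13", "Gastroenteritis", 7, "M", 19, 11, 75, 0.4, 0.9, 4.32, 4.26, 0.21, 0.21, 48.8, 55, 59.9, 65, 147.5, 147.5),
    ("14", "Meningitis, Gastroenteritis", 10, "M", 5, 6.8, 66, 0.1, 0.2, 4.0, 4.2, 0.46, 0.32, 18, 25, 38, 40, 59.3, 85.2),
    ("15", "Gastroenteritis", 7, "F", 3, 6.6, 60, 0.2, 0.25, 4.5, 4.4, 0.36, 0.3, 45.1, 50, 74, 77, 68.8, 82.6),
    ("16", "Meningitis", 10, "F", 132, 15, 154, 0.2, 0.27, 4.35, 4.3, 0.64, 0.5, 51, 54, 75, 79, 99.4, 127.2),
    ("17", "Meningitis", 7, "M", 4, 5.5, 65, 0.1, 0.19, 4.55, 4.5, 0.4, 0.3, 25, 30, 36, 40, 67.1, 89.5),
    ("18", "Urinary Tract Infection", 5, "F", 60, 19, 108, 0.1, 0.15, 1.84, 2.0, 1.6, 1.2, 25, 35, 39, 45, 27.9, 37.2),
    ("19", "Pneumonia", 14, "F", 11, 12, 73, 0.2, 0.27, 3.7, 3.9, 0.6, 0.5, 15, 20, 29, 35, 50.2, 60.3),
    ("20", "Meningitis", 10, "F", 12, 13, 78, 0.28, 0.35, 3.2, 3.3, 0.5, 0.4, 39, 45, 49, 69, 64.4, 80.5),
    ("21", "Pneumonia", 14, "F", 48, 16, 107, 0.2, 0.4, 4.0, 4.2, 1.85, 1.4, 25, 29, 45, 50, 23.9, 31.6),
    ("22", "Cystitis", 7, "M", 120, 37, 158, 0.29, 0.5, 3.0, 3.2, 0.72, 0.65, 27, 30, 39, 45, 90.6, 100.4),
    ("23", "Gastroenteritis", 7, "M", 6, 8, 66, 0.2, 0.4, 3.8, 3.7, 0.35, 0.3, 42, 46, 53, 69, 77.9, 90.9),
    ("24", "Pneumonia", 14, "M", 77, 22, 116, 0.2, 0.27, 3.78, 3.9, 0.8, 0.7, 19, 25, 38, 45, 59.9, 68.4),
]

# patient_id,
# total: vss_ml, cl_ml_h, cl_over_egfr, t_half_h,
# free:  vss_ml, cl_ml_h, cl_over_egfr, t_half_h,
# fu_avg_percent, fu_obs_min_percent, fu_obs_max_percent
_PK_PARAMETERS = [
    ("1", 8363.42, 412.4198, 1.051502, 12.94588, 35460.42, 1914.46, 4.881092, 13.38733, 21.54, 18.89, 19.88),
    ("2", 1396.961, 307.3588, 1.17400, 4.529875, 2126.281, 837.1903, 3.197768, 3.405622, 36.71, 25.01, 26.3),
    ("3", 3664.44, 737.8105, 0.243197, 5.430758, 1042.449, 1321.007, 0.435431, 4.495601, 55.85, 9.51, 9.93),
    ("4", 4993.113, 518.4681, 0.065996, 6.803175, 9854.066, 1315.172, 0.167408, 5.970423, 39.42, 34.9, 35.4),
    ("5", 1101.492, 152.4519, 0.32001, 7.972266, 2531.102, 539.0499, 1.131515, 5.202838, 28.28, 23.24, 24.83),
    ("6", 9747.996, 1808.401, 0.439106, 5.165824, 3560.419, 3864.769, 0.938421, 2.442022, 46.79, 12.83, 14.48),
    ("7", 4851.421, 1188.162, 0.860485, 3.520011, 23772.12, 5026.279, 3.640109, 3.195727, 23.64, 28.11, 29.33),
    ("8", 11609.46, 335.3665, 0.400231, 24.01689, 27315.06, 1429.916, 1.706481, 5.23162, 23.45, 23.68, 25.4),
    ("9", 657.1404, 178.8306, 0.270396, 6.232549, 823.8564, 406.6213, 0.61482, 5.8837, 43.98, 24.89, 25.3),
    ("10", 4080.832, 1375.985, 1.702077, 4.722829, 18475.96, 6385.691, 7.899025, 3.757543, 21.55, 22.64, 23.68),
    ("11", 1142.602, 1040.619, 0.428128, 3.161246, 20037.39, 10895.35, 4.482532, 2.580582, 9.55, 17.49, 19.1),
    ("12", 3638.064, 125.8034, 0.140682, 21.21516, 14504.74, 543.3068, 0.607563, 19.75682, 23.16, 23.48, 24.95),
    ("13", 7049.659, 475.8978, 0.194214, 17.06646, 10415.33, 983.5143, 0.401373, 12.03742, 48.39, 51.49, 51.95),
    ("14", 13803.22, 381.1512, 0.525004, 25.04822, 25617.56, 1116.232, 1.537518, 17.82665, 34.15, 34.27, 35.07),
    ("15", 11630.04, 439.7829, 0.555145, 17.6031, 17381.07, 965.3229, 1.218543, 14.51582, 45.56, 38.31, 39.68),
    ("16", 2101.914, 227.3098, 0.082318, 12.82132, 6293.145, 1044.99, 0.378432, 7.4135, 21.75, 23.52, 24.5),
    ("17", 8900.945, 407.4808, 0.555864, 16.46693, 27100.14, 1752.388, 2.390518, 10.41533, 23.25, 27.42, 28.11),
    ("18", 10352.60, 272.33, 0.372767, 29.8707, 23989.37, 1398.963, 1.914917, 15.91113, 19.47, 20.58, 20.58),
    ("19", 198.2405, 82.17014, 0.095732, 7.44996, 93.55431, 122.2342, 0.142409, 5.381362, 67.22, 25.84, 26.79),
    ("20", 10146.69, 506.2888, 0.426887, 16.59243, 29930.87, 2137.773, 1.802503, 10.72628, 23.68, 26.53, 27.07),
    ("21", 8762.807, 341.2257, 0.596609, 24.19684, 5174.05, 1088.907, 1.903875, 5.07728, 31.34, 27.18, 28.28),
    ("22", 14234.19, 477.2572, 0.11922, 23.16377, 16007.16, 1407.156, 0.351511, 9.399338, 33.92, 49.49, 51.55),
    ("23", 10679.26, 393.1059, 0.379899, 20.70719, 7398.431, 1540.032, 1.488293, 6.157091, 25.53, 13.96, 16.56),
    ("24", 17133.47, 468.1962, 0.26766, 26.16191, 38582.27, 1194.369, 0.682801, 23.34325, 39.20, 42.0, 42.14),
]

# patient_id,
# total: cmax, c0, auc_all, aumc_last   free: cmax, c0, auc_all, aumc_last
_EXPOSURE = [
    ("1", 48.62, 78.60, 2195.50, 33886.29, 9.30, 20.09, 475.20, 6501.92),
    ("2", 23.38, 108.72, 682.19, 1396.23, 6.15, 47.52, 273.95, 365.82),
    ("3", 12.02, 84.14, 1069.15, 3165.16, 1.19, 56.60, 636.83, 312.65),
    ("4", 70.11, 155.34, 1307.15, 5013.23, 24.82, 74.53, 569.96, 1771.92),
    ("5", 52.85, 309.25, 4057.60, 14482.55, 13.12, 95.92, 1217.57, 3585.60),
    ("6", 27.60, 117.53, 782.84, 1749.28, 3.99, 79.58, 441.60, 251.04),
    ("7", 18.42, 96.26, 856.16, 2312.23, 5.33, 21.42, 201.10, 669.13),
    ("8", 49.28, 72.45, 1160.48, 9649.98, 12.52, 31.85, 400.60, 2418.27),
    ("9", 33.45, 355.86, 3924.73, 7337.57, 8.46, 168.81, 1780.62, 1854.24),
    ("10", 4.03, 47.65, 572.22, 1060.30, 0.95, 10.25, 124.13, 249.79),
    ("11", 14.44, 284.12, 1577.31, 902.96, 2.66, 25.18, 147.99, 166.51),
    ("12", 286.71, 289.92, 4921.79, 38132.49, 71.55, 73.46, 1194.11, 8988.98),
    ("13", 22.39, 118.51, 1560.98, 5663.87, 11.63, 62.44, 820.48, 2941.69),
    ("14", 14.49, 22.33, 396.49, 3491.49, 5.08, 12.31, 183.69, 1220.56),
    ("15", 14.66, 23.11, 406.18, 3528.58, 5.82, 16.18, 231.05, 1396.52),
    ("16", 33.45, 234.64, 2713.16, 7350.19, 8.18, 54.84, 638.01, 1795.96),
    ("17", 23.78, 54.69, 807.99, 5233.32, 6.68, 14.66, 219.92, 1469.35),
    ("18", 45.79, 108.60, 1743.40, 12095.41, 9.62, 35.29, 503.36, 2538.98),
    ("19", 59.33, 1210.36, 14022.68, 15618.27, 15.89, 865.38, 9708.74, 4176.34),
    ("20", 38.32, 111.63, 1677.75, 9905.46, 10.37, 30.35, 455.50, 2680.00),
    ("21", 33.76, 125.50, 1768.60, 8541.37, 9.55, 67.57, 853.00, 2414.40),
    ("22", 76.15, 179.13, 1414.54, 5014.85, 39.26, 109.92, 820.87, 2578.32),
    ("23", 20.08, 45.28, 708.67, 5050.31, 3.32, 25.49, 301.30, 826.37),
    ("24", 73.83, 116.35, 1023.40, 4452.69, 31.11, 52.38, 447.94, 1875.45),
]

# model, analyte, aic, bic, retcode, loglik, minus2ll, eps_shrinkage
_MODEL_DIAGNOSTICS = [
    ("1c", "free", 191.3514, 202.7348, 3, -90.6757, 181.3514, 0.29349),
    ("2c", "free", 200.8512, 221.3412, 3, -91.4256, 182.8512, 0.33099),
    ("1c", "total", 524.6312, 536.0145, 2, -257.316, 514.6312, 0.19803),
    ("2c", "total", 528.1524, 548.6424, 1, -255.076, 510.1524, 0.17984),
]

DEMOGRAPHIC_COLUMNS = [
    "patient_id", "indication", "duration_days", "sex", "age_months",
    "weight_kg", "height_cm", "bili_b", "bili_a", "alb_b", "alb_a",
    "scr_b", "scr_a", "alt_b", "alt_a", "ast_b", "ast_a",
    "egfr_b_reported", "egfr_a_reported",
]


def demographics() -> pd.DataFrame:
    """Demographics/laboratory table including the reported eGFR columns."""
    return pd.DataFrame(_DEMOGRAPHICS, columns=DEMOGRAPHIC_COLUMNS)


def patients() -> List[PatientRecord]:
    """The reference cohort as typed :class:`PatientRecord` objects."""
    out = []
    for row in _DEMOGRAPHICS:
        (pid, ind, dur, sex, age, wt, ht, bb, ba, alb_b, alb_a,
         sb, sa, altb, alta, astb, asta, _eb, _ea) = row
        out.append(PatientRecord(
            patient_id=pid, sex=sex, age_months=float(age), weight_kg=float(wt),
            height_cm=float(ht), indication=ind, duration_days=int(dur),
            scr_mg_dl=LabPair(sb, sa), albumin=LabPair(alb_b, alb_a),
            bilirubin_mg_dl=LabPair(bb, ba), alt_iu_l=LabPair(altb, alta),
            ast_iu_l=LabPair(astb, asta),
        ))
    return out


def pk_parameters() -> pd.DataFrame:
    """Reported compartmental/NCA parameters (wide, one row per patient)."""
    cols = [
        "patient_id",
        "vss_ml_total", "cl_ml_h_total", "cl_over_egfr_total", "t_half_h_total",
        "vss_ml_free", "cl_ml_h_free", "cl_over_egfr_free", "t_half_h_free",
        "fu_avg_percent", "fu_obs_min_percent", "fu_obs_max_percent",
    ]
    return pd.DataFrame(_PK_PARAMETERS, columns=cols)


def exposure() -> pd.DataFrame:
    """Reported exposure metrics (Cmax, C0, AUCall, AUMClast) per analyte."""
    cols = [
        "patient_id",
        "cmax_total", "c0_total", "auc_all_total", "aumc_last_total",
        "cmax_free", "c0_free", "auc_all_free", "aumc_last_free",
    ]
    return pd.DataFrame(_EXPOSURE, columns=cols)


def model_diagnostics() -> pd.DataFrame:
    """Reported population model-selection diagnostics per analyte."""
    cols = ["model", "analyte", "aic", "bic", "retcode", "loglik",
            "minus2ll", "eps_shrinkage"]
    return pd.DataFrame(_MODEL_DIAGNOSTICS, columns=cols)
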