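"""Domain-type invariants and CSV round-trips."""

import numpy as np
import pandas as pd
import pytest

from ceftripk import io as cio
from ceftripk.errors import ParseError, SchemaError, ValidationError
from ceftripk.types import (
    ConcentrationSample,
    DoseEvent,
    LabPair,
    PatientRecord,
    PKResult,
)


def _patient(**kw):
    base = dict(
        patient_id="p1", sex="F", age_months=12.0, weight_kg=10.0,
        height_cm=75.0, indication="Pneumonia", duration_days=7,
        scr_mg_dl=LabPair(0.4, 0.3), albumin=LabPair(4.0, 4.1),
        bilirubin_mg_dl=LabPair(0.2, 0.3), alt_iu_l=LabPair(20.0, 25.0),
        ast_iu_l=LabPair(30.0, 32.0),
    )
    base.update(kw)
    return PatientRecord(**base)


@pytest.mark.parametrize("kw", [
    {"age_months": 0.5},            # below inclusion window
    {"age_months": 216.0},          # adult
    {"sex": "X"},
    {"weight_kg": 0.0},
    {"duration_days": 0},
    {"scr_mg_dl": LabPair(0.0, 0.3)},
])
def test_patient_invariants_rejected(kw):
    with pytest.raises(ValidationError):
        _patient(**kw)


def test_missing_after_lab_allowed():
    p = _patient(alt_iu_l=LabPair(20.0, None))
    assert p.alt_iu_l.after is None


def test_dose_event_rejects_nonpositive_amount():
    with pytest.raises(ValidationError):
        DoseEvent("p1", 0.0, 0.0)


@pytest.mark.parametrize("kw", [
    {"time_h": 0.0},
    {"analyte": "bound"},
    {"conc_ug_ml": None, "bloq": False},   # missing value on a quantified sample
    {"conc_ug_ml": -1.0},
])
def test_sample_invariants_rejected(kw):
    base = dict(patient_id="p1", analyte="total", time_h=11.75,
                time_after_last_dose_h=11.75, conc_ug_ml=12.0, bloq=False)
    base.update(kw)
    with pytest.raises(ValidationError):
        ConcentrationSample(**base)


def _write_cohort_csvs(tmp_path, conc_rows=None, dose_rows=None):
    (tmp_path / "patients.csv").write_text(
        "patient_id,sex,age_months,weight_kg,height_cm,indication,duration_days,"
        "scr_b,scr_a,alb_b,alb_a,bili_b,bili_a,alt_b,alt_a,ast_b,ast_a\n"
        "p1,F,12,10,75,Pneumonia,7,0.4,0.3,4,4.1,0.2,0.3,20,25,30,32\n"
    )
    dose_rows = dose_rows if dose_rows is not None else ["p1,0,500", "p1,12,500"]
    (tmp_path / "doses.csv").write_text(
        "patient_id,time_h,amount_mg\n" + "\n".join(dose_rows) + "\n")
    header = "patient_id,analyte,time_h,time_after_last_dose_h,conc_ug_ml,bloq\n"
    conc_rows = conc_rows if conc_rows is not None else ["p1,total,11.75,11.75,12.5,False"]
    (tmp_path / "conc.csv").write_text(header + "\n".join(conc_rows) + "\n"
                                       if conc_rows else header)
    return (tmp_path / "patients.csv", tmp_path / "doses.csv", tmp_path / "conc.csv")


def test_read_cohort_roundtrip(tmp_path):
    paths = _write_cohort_csvs(tmp_path)
    patients, doses, samples = cio.read_cohort(*paths)
    assert len(patients) == 1 and len(doses) == 2 and len(samples) == 1
    assert samples[0].conc_ug_ml == 12.5


def test_read_cohort_empty_conc_gives_empty_list(tmp_path):
    paths = _write_cohort_csvs(tmp_path, conc_rows=[])
    _, _, samples = cio.read_cohort(*paths)
    assert samples == []


def test_missing_column_names_the_column(tmp_path):
    paths = _write_cohort_csvs(tmp_path)
    df = pd.read_csv(paths[1]).drop(columns=["amount_mg"])
    df.to_csv(paths[1], index=False)
    with pytest.raises(SchemaError, match="amount_mg"):
        cio.read_cohort(*paths)


def test_non_numeric_cell_reports_row(tmp_path):
    paths = _write_cohort_csvs(tmp_path, dose_rows=["p1,0,500", "p1,twelve,500"])
    with pytest.raises(ParseError, match="row 1"):
        cio.read_cohort(*paths)


def test_zero_dose_amount_rejected(tmp_path):
    paths = _write_cohort_csvs(tmp_path, dose_rows=["p1,0,0"])
    with pytest.raises(ValidationError):
        cio.read_cohort(*paths)


def test_orphan_sample_rejected(tmp_path):
    paths = _write_cohort_csvs(
        tmp_path, conc_rows=["p9,total,11.75,11.75,12.5,False"])
    with pytest.raises(ValidationError, match="p9"):
        cio.read_cohort(*paths)


def test_unsorted_doses_rejected(tmp_path):
    paths = _write_cohort_csvs(tmp_path, dose_rows=["p1,12,500", "p1,0,500"])
    with pytest.raises(ValidationError):
        cio.read_cohort(*paths)


def _pk_result(i):
    rng = np.random.default_rng(1000 + i)
    vals = rng.uniform(0.5, 5000.0, size=8)
    return PKResult(patient_id=str(i + 1), analyte="total", vss_ml=vals[0],
                    cl_ml_h=vals[1], t_half_h=vals[2], fu_percent=vals[3],
                    cmax_ug_ml=vals[4], c0_ug_ml=vals[5], auc_all=vals[6],
                    aumc_last=vals[7])


def test_write_results_roundtrip_6_sig_figs(tmp_path):
    results = [_pk_result(i) for i in range(24)]
    path = tmp_path / "results.csv"
    cio.write_results(results, path)
    back = cio.read_results(path)
    assert len(back) == 24
    for col, attr in [("vss_ml", "vss_ml"), ("cl_ml_h", "cl_ml_h"),
                      ("auc_all", "auc_all")]:
        orig = np.array([getattr(r, attr) for r in results])
        assert np.allclose(back[col].to_numpy(dtype=float), orig, rtol=1e-5)


def test_write_results_summary_rows_match_independent_medians(tmp_path):
    results = [_pk_result(i) for i in range(24)]
    path = tmp_path / "results.csv"
    cio.write_results(results, path)
    raw = pd.read_csv(path, dtype={"patient_id": str})
    med = raw[raw["patient_id"] == "median"]
    assert len(med) == 1
    # independent oracle: sorted-midpoint median of the original values
    vals = sorted(r.cl_ml_h for r in results)
    expected = 0.5 * (vals[11] + vals[12])
    assert float(med["cl_ml_h"].iloc[0]) == pytest.approx(expected, rel=1e-5)
    assert len(raw) == 27  # 24 data + median/min/max


def test_write_results_refuses_empty(tmp_path):
    with pytest.raises(ValidationError):
        cio.write_results([], tmp_path / "r.csv")
    cio.write_results([], tmp_path / "r.csv", allow_empty=True)
    assert (tmp_path / "r.csv").exists()
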