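import numpy as np
import pandas as pd
import pytest

from akipredict.cohort import (AdmissionRecord, CohortConfig, LabEvent,
                               apply_exclusions, compute_egfr,
                               creatinine_for_egfr, read_cohort)
from akipredict.kdigo import CreatinineSeries, detect_aki
from helpers import oracle_ckdepi


def _adm(aid="A1", pid="P1", hours=96, age=60, sex="female",
         dx=(), px=()):
    admit = pd.Timestamp("2012-03-01")
    return AdmissionRecord(aid, pid, admit, admit + pd.Timedelta(hours=hours),
                           age, sex, frozenset(dx), frozenset(px))


def _creat(aid, hours, value, admit=pd.Timestamp("2012-03-01")):
    return LabEvent(aid, "P1", "creatinine_serum", value, "umol/L",
                    admit + pd.Timedelta(hours=hours))


class TestEgfr:
    def test_worked_example(self):
        assert compute_egfr(61.9, 60, "female") == pytest.approx(94.5, abs=0.5)

    def test_sex_coefficient_direction(self):
        f = compute_egfr(61.9, 60, "female")
        m = compute_egfr(61.9, 60, "male")
        assert m > f

    def test_monotone_in_creatinine(self):
        assert compute_egfr(120, 60, "male") < compute_egfr(60, 60, "male")

    def test_oracle_agreement(self):
        rng = np.random.default_rng(3)
        for _ in range(1000):
            creat = float(rng.uniform(20, 800))
            age = float(rng.uniform(1, 95))
            sex = "female" if rng.random() < 0.5 else "male"
            assert compute_egfr(creat, age, sex) == pytest.approx(
                oracle_ckdepi(creat, age, sex), abs=0.1)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            compute_egfr(-1, 60, "male")
        with pytest.raises(ValueError):
            compute_egfr(80, 60, "other")

    def test_inverse_roundtrip(self):
        for target in (8.0, 14.0, 25.0):
            creat = creatinine_for_egfr(target, 60, "male")
            assert compute_egfr(creat, 60, "male") == pytest.approx(target,
                                                                    rel=1e-6)


class TestExclusions:
    def test_short_stay(self):
        res = apply_exclusions([_adm(hours=36)], [_creat("A1", 2, 70)], {})
        assert res.excluded == {"A1": "short_stay"}

    def test_community_aki(self):
        events = [_creat("A1", 2, 60), _creat("A1", 24, 95)]
        series = CreatinineSeries(
            "A1", np.array([e.timestamp.to_datetime64() for e in events]),
            np.array([e.value for e in events]))
        episodes = {"A1": detect_aki(series)}
        res = apply_exclusions([_adm(hours=120)], events, episodes)
        assert res.excluded == {"A1": "community_aki"}

    def test_ckd5_by_egfr(self):
        creat = creatinine_for_egfr(12.0, 60, "male")
        res = apply_exclusions([_adm(hours=96, sex="male")],
                               [_creat("A1", 2, creat)], {})
        assert res.excluded == {"A1": "ckd5"}

    def test_prior_rrt(self):
        creat = creatinine_for_egfr(25.0, 60, "male")
        res = apply_exclusions(
            [_adm(hours=96, sex="male", px=("haemodiafiltration",))],
            [_creat("A1", 2, creat)], {})
        assert res.excluded == {"A1": "prior_rrt_no_recovery"}

    def test_no_labs(self):
        res = apply_exclusions([_adm(hours=96)], [], {})
        assert res.excluded == {"A1": "no_labs"}

    def test_order_sensitivity(self):
        # satisfies short_stay AND ckd5 -> recorded as short_stay
        res = apply_exclusions(
            [_adm(hours=36, dx=("end-stage renal disease",))],
            [_creat("A1", 2, 70)], {})
        assert res.excluded == {"A1": "short_stay"}

    def test_partition_property(self, small_cohort_labeled):
        c = small_cohort_labeled
        res = apply_exclusions(c["admissions"], c["events"], c["episodes"])
        assert len(res.kept) + len(res.excluded) == len(c["admissions"])
        assert set(res.kept).isdisjoint(res.excluded)

    def test_planted_reasons_exact(self, small_cohort_labeled):
        c = small_cohort_labeled
        res = apply_exclusions(c["admissions"], c["events"], c["episodes"])
        for aid, rec in c["truth"].records.items():
            planted = rec["exclusion_reason"]
            if planted is None:
                assert aid in set(res.kept), aid
            else:
                assert res.excluded.get(aid) == planted, aid

    def test_kept_admission_clean(self):
        res = apply_exclusions([_adm(hours=96)], [_creat("A1", 2, 70)], {})
        assert res.kept == ["A1"]
        assert res.counts == {r: 0 for r in res.counts}


class TestReadCohort:
    def _write(self, tmp_path, labs_rows, adm_rows):
        labs = tmp_path / "labs.csv"
        adms = tmp_path / "admissions.csv"
        labs.write_text(
            "admission_id,patient_id,analyte,value,unit,timestamp\n"
            + "".join(labs_rows))
        adms.write_text(
            "admission_id,patient_id,admit_time,discharge_time,age_years,"
            "sex,diagnosis_codes,procedure_codes\n" + "".join(adm_rows))
        return str(labs), str(adms)

    def test_valid_rows(self, tmp_path):
        labs, adms = self._write(
            tmp_path,
            ["A1,P1,creatinine_serum,70,umol/L,2012-03-01T08:00:00\n",
             "A1,P1,sodium,140,mmol/L,2012-03-01T09:00:00\n"],
            ["A1,P1,2012-03-01T00:00:00,2012-03-05T00:00:00,60,female,,\n"])
        admissions, events, rejected = read_cohort(labs, adms)
        assert len(admissions) == 1 and len(events) == 2
        assert len(rejected) == 0

    def test_malformed_value_rejected(self, tmp_path):
        labs, adms = self._write(
            tmp_path,
            ["A1,P1,creatinine_serum,NA,umol/L,2012-03-01T08:00:00\n"],
            ["A1,P1,2012-03-01T00:00:00,2012-03-05T00:00:00,60,female,,\n"])
        _, events, rejected = read_cohort(labs, adms)
        assert len(events) == 0
        assert len(rejected) == 1
        assert rejected.iloc[0]["reject_reason"] == "non_finite_value"

    def test_orphan_admission_errors(self, tmp_path):
        labs, adms = self._write(
            tmp_path,
            ["A9,P1,creatinine_serum,70,umol/L,2012-03-01T08:00:00\n"],
            ["A1,P1,2012-03-01T00:00:00,2012-03-05T00:00:00,60,female,,\n"])
        with pytest.raises(ValueError, match="A9"):
            read_cohort(labs, adms)

    def test_missing_column_errors(self, tmp_path):
        labs = tmp_path / "labs.csv"
        labs.write_text("admission_id,analyte,value\nA1,x,1\n")
        adms = tmp_path / "admissions.csv"
        adms.write_text(
            "admission_id,patient_id,admit_time,discharge_time,age_years,"
            "sex,diagnosis_codes,procedure_codes\n"
            "A1,P1,2012-03-01T00:00:00,2012-03-05T00:00:00,60,female,,\n")
        with pytest.raises(ValueError, match="patient_id"):
            read_cohort(str(labs), str(adms))


class TestConfig:
    def test_from_yaml(self, tmp_path):
        path = tmp_path / "cohort.yaml"
        path.write_text("short_stay_hours: 24\n"
                        "eskd_diagnosis_patterns: [eskd]\n")
        cfg = CohortConfig.from_yaml(str(path))
        assert cfg.short_stay_hours == 24
        assert cfg.eskd_diagnosis_patterns == ("eskd",)
        assert cfg.egfr_ckd5_threshold == 15.0
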