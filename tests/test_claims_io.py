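"""Reading, validation, and the ordered inclusion/exclusion rules."""

import pandas as pd
import pytest

from ledd_screen import claims_io
from ledd_screen.claims_io import ClaimsSchemaError


class TestReading:
    def test_well_formed_tables_load(self, tiny_claims):
        patients_path, rx_path = tiny_claims
        bundle = claims_io.read_claims(patients_path, rx_path)
        assert len(bundle.patients) == 3
        assert len(bundle.prescriptions) == 4
        assert bundle.prescriptions["valid"].all()

    def test_missing_period_flags_row_without_dropping(self, write_csv):
        path = write_csv(
            "rx.csv",
            """
patient_id,drug_code,drug_class,prescription_date,period_days,daily_dose,single_dose
A,levodopa,pd_drug,100,NA,300,100
A,levodopa,pd_drug,130,30,300,100
""",
        )
        rx = claims_io.read_prescriptions(path)
        assert len(rx) == 2
        assert rx["valid"].tolist() == [False, True]

    def test_nonpositive_dose_flags_row(self, write_csv):
        path = write_csv(
            "rx.csv",
            """
patient_id,drug_code,drug_class,prescription_date,period_days,daily_dose,single_dose
A,levodopa,pd_drug,100,30,-5,100
""",
        )
        assert not claims_io.read_prescriptions(path)["valid"].iloc[0]

    def test_duplicate_patient_id_is_an_error(self, write_csv):
        path = write_csv(
            "patients.csv",
            """
patient_id,sex,pd_diagnosis_date,age_at_diagnosis
A,male,100,63.0
A,female,50,71.5
""",
        )
        with pytest.raises(ClaimsSchemaError, match="duplicate patient_id"):
            claims_io.read_patients(path)

    def test_bad_value_error_names_column_and_line(self, write_csv):
        path = write_csv(
            "patients.csv",
            """
patient_id,sex,pd_diagnosis_date,age_at_diagnosis
A,male,100,63.0
B,female,notaday,71.5
""",
        )
        with pytest.raises(ClaimsSchemaError, match=r"pd_diagnosis_date.*3"):
            claims_io.read_patients(path)

    def test_unparseable_prescription_date_is_an_error(self, write_csv):
        path = write_csv(
            "rx.csv",
            """
patient_id,drug_code,drug_class,prescription_date,period_days,daily_dose,single_dose
A,levodopa,pd_drug,soon,30,300,100
""",
        )
        with pytest.raises(ClaimsSchemaError, match="prescription_date"):
            claims_io.read_prescriptions(path)

    def test_unknown_sex_rejected(self, write_csv):
        path = write_csv(
            "patients.csv",
            """
patient_id,sex,pd_diagnosis_date,age_at_diagnosis
A,unknown,100,63.0
""",
        )
        with pytest.raises(ClaimsSchemaError, match="sex"):
            claims_io.read_patients(path)

    def test_missing_column_rejected(self, write_csv):
        path = write_csv("patients.csv", "patient_id,sex\nA,male")
        with pytest.raises(ClaimsSchemaError, match="pd_diagnosis_date"):
            claims_io.read_patients(path)


class TestDrugTable:
    def test_packaged_default_covers_screen_drugs(self, drug_table):
        ah = drug_table[drug_table.drug_class == "antihistamine"]
        assert len(ah) == 15
        pd_drugs = set(drug_table.loc[drug_table.drug_class == "pd_drug", "drug_code"])
        assert {"levodopa", "entacapone", "pramipexole", "selegiline"} <= pd_drugs
        factors = drug_table[drug_table.rule_type == "factor"]
        assert (factors.parameter > 0).all()

    def test_prescription_classes_assigned_from_drug_table(self, write_csv, tiny_claims):
        patients_path, rx_path = tiny_claims
        custom = write_csv(
            "drugs.csv",
            """
drug_code,name,drug_class,rule_type,parameter,generation
levodopa,Levodopa,pd_drug,factor,1.0,
pramipexole,Pramipexole,pd_drug,factor,100.0,
fexofenadine,Fexofenadine,other,none,0.0,
""",
        )
        bundle = claims_io.read_claims(patients_path, rx_path, custom)
        by_code = bundle.prescriptions.set_index("drug_code")["drug_class"]
        assert by_code.loc["fexofenadine"] == "other"

    def test_bad_rule_type_rejected(self, write_csv):
        path = write_csv(
            "drugs.csv",
            """
drug_code,name,drug_class,rule_type,parameter,generation
levodopa,Levodopa,pd_drug,magic,1.0,
""",
        )
        with pytest.raises(ClaimsSchemaError, match="rule_type"):
            claims_io.read_drug_table(path)


class TestExclusions:
    @pytest.fixture()
    def cohort(self):
        patients = pd.DataFrame(
            {
                "patient_id": ["young", "norx", "missing", "ok"],
                "sex": ["male"] * 4,
                "pd_diagnosis_date": [10, 10, 10, 10],
                "age_at_diagnosis": [39.0, 65.0, 65.0, 65.0],
            }
        )
        rx = pd.DataFrame(
            {
                "patient_id": ["young", "norx", "missing", "missing", "ok"],
                "drug_code": ["levodopa", "aspirin", "levodopa", "levodopa", "levodopa"],
                "drug_class": ["pd_drug", "other", "pd_drug", "pd_drug", "pd_drug"],
                "prescription_date": [10, 10, 10, 40, 10],
                "period_days": [30.0, 30.0, 30.0, None, 30.0],
                "daily_dose": [300.0, 1.0, 300.0, 300.0, 300.0],
                "single_dose": [100.0, 1.0, 100.0, 100.0, 100.0],
            }
        )
        return patients, rx

    def test_rules_apply_in_order_with_reconciling_log(self, cohort):
        patients, rx = cohort
        retained, log = claims_io.apply_exclusions(patients, rx)
        assert retained.patient_id.tolist() == ["ok"]
        frame = log.to_frame()
        assert frame.rule.tolist() == [
            "diagnosed_at_or_after_40",
            "has_pd_drug_or_antihistamine",
            "no_missing_prescription_fields",
        ]
        assert frame.n_removed.tolist() == [1, 1, 1]
        # running totals reconcile with input/output counts
        assert frame.n_remaining.tolist() == [3, 2, 1]
        assert log.n_input - frame.n_removed.sum() == len(retained)

    def test_one_missing_row_excludes_whole_patient(self, cohort):
        patients, rx = cohort
        retained, _ = claims_io.apply_exclusions(patients, rx)
        assert "missing" not in set(retained.patient_id)

    def test_fully_valid_patient_retained(self, cohort):
        patients, rx = cohort
        retained, log = claims_io.apply_exclusions(patients, rx)
        assert "ok" in set(retained.patient_id)
        assert log.n_remaining == 1

    def test_attrition_log_rejects_increasing_counts(self):
        log = claims_io.AttritionLog(n_input=5)
        log.record("a", 2, 3)
        with pytest.raises(ValueError):
            log.record("b", 0, 4)


def test_read_write_read_round_trip(tiny_claims, tmp_path):
    patients_path, rx_path = tiny_claims
    bundle = claims_io.read_claims(patients_path, rx_path)
    claims_io.write_claims(bundle.patients, bundle.prescriptions, tmp_path / "out")
    again = claims_io.read_claims(
        tmp_path / "out" / "patients.csv", tmp_path / "out" / "prescriptions.csv"
    )
    pd.testing.assert_frame_equal(bundle.patients, again.patients)
    pd.testing.assert_frame_equal(bundle.prescriptions, again.prescriptions)
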