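from __future__ import annotations

import sys
from pathlib import Path

import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles importable

from ledd_screen import claims_io


@pytest.fixture(scope="session")
def drug_table() -> pd.DataFrame:
    return claims_io.read_drug_table()


@pytest.fixture()
def write_csv(tmp_path):
    """Write a small table to a temp CSV and return its path."""

    def _write(name: str, text: str) -> Path:
        path = tmp_path / name
        path.write_text(text.strip() + "\n")
        return path

    return _write


@pytest.fixture()
def tiny_claims(write_csv):
    """A minimal well-formed claims pair: three patients, mixed prescriptions."""
    patients = write_csv(
        "patients.csv",
        """
patient_id,sex,pd_diagnosis_date,age_at_diagnosis
A,male,100,63.0
B,female,50,71.5
C,female,10,55.0
""",
    )
    prescriptions = write_csv(
        "prescriptions.csv",
        """
patient_id,drug_code,drug_class,prescription_date,period_days,daily_dose,single_dose
A,levodopa,pd_drug,100,30,300,100
A,fexofenadine,antihistamine,400,30,120,60
B,levodopa,pd_drug,60,30,250,80
C,pramipexole,pd_drug,20,30,1.5,0.5
""",
    )
    return patients, prescriptions
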