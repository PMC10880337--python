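"""Claims data model: reading, validation, and cohort inclusion/exclusion.

The pipeline works on two delimited-text tables plus a drug reference table:

* **patients** — one row per Parkinson's disease (PD) patient:
  ``patient_id,sex,pd_diagnosis_date,age_at_diagnosis``.  Dates are integer
  day offsets from an arbitrary study epoch (day 0); half-open intervals are
  used everywhere so coverage arithmetic is unambiguous.
* **prescriptions** — one row per dispensing event:
  ``patient_id,drug_code,drug_class,prescription_date,period_days,
  daily_dose,single_dose``.  A prescription covers the half-open interval
  ``[prescription_date, prescription_date + period_days)``.
* **drug table** — ``drug_code,name,drug_class,rule_type,parameter,generation``
  mapping codes to a class (``pd_drug`` / ``antihistamine`` / ``other``), a
  levodopa-equivalent-dose conversion rule, and (for antihistamines) the
  generation (1 or 2).

Rows with a missing or unparseable ``period_days``, ``daily_dose`` or
``single_dose`` are *flagged* (``valid == False``), never silently dropped;
the patient-level exclusion rules below decide their fate.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PATIENT_COLUMNS = ["patient_id", "sex", "pd_diagnosis_date", "age_at_diagnosis"]
PRESCRIPTION_COLUMNS = [
    "patient_id",
    "drug_code",
    "drug_class",
    "prescription_date",
    "period_days",
    "daily_dose",
    "single_dose",
]
DRUG_TABLE_COLUMNS = ["drug_code", "name", "drug_class", "rule_type", "parameter"]

VALID_SEXES = frozenset({"male", "female"})
VALID_CLASSES = frozenset({"pd_drug", "antihistamine", "other"})
VALID_RULES = frozenset({"factor", "adjunct_levodopa", "none"})

#: prescription fields whose absence flags the row as invalid
DOSE_FIELDS = ["period_days", "daily_dose", "single_dose"]


class ClaimsSchemaError(ValueError):
    """A table violates the documented CSV schema (column and line named)."""


class ClaimsBundle(NamedTuple):
    patients: pd.DataFrame
    prescriptions: pd.DataFrame
    drug_table: pd.DataFrame


@dataclass
class AttritionLog:
    """Ordered record of cohort counts removed by each exclusion rule."""

    n_input: int
    steps: list[tuple[str, int, int]] = field(default_factory=list)

    def record(self, rule: str, n_removed: int, n_remaining: int) -> None:
        if self.steps and n_remaining > self.steps[-1][2]:
            raise ValueError("attrition counts must be non-increasing")
        self.steps.append((rule, n_removed, n_remaining))
        logger.info("exclusion %-28s removed %6d, remaining %6d", rule, n_removed, n_remaining)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["rule", "n_removed", "n_remaining"])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @property
    def n_remaining(self) -> int:
        return self.steps[-1][2] if self.steps else self.n_input


def _bad_lines(raw: pd.Series, coerced: pd.Series) -> list[int]:
    """1-based file line numbers (header is line 1) where coercion failed."""
    mask = coerced.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
    return [int(i) + 2 for i in np.flatnonzero(mask.to_numpy())]


def _require_columns(df: pd.DataFrame, required: Iterable[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ClaimsSchemaError(f"{what} table is missing column(s): {', '.join(missing)}")


def read_patients(path: str | Path) -> pd.DataFrame:
    """Read and validate the patient table.

    Raises :class:`ClaimsSchemaError` on duplicate ids, unknown sex codes, or
    unparseable dates/ages, naming the offending column and line.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[""])
    _require_columns(df, PATIENT_COLUMNS, "patient")

    dup = df["patient_id"][df["patient_id"].duplicated()]
    if len(dup):
        raise ClaimsSchemaError(
            f"duplicate patient_id in patient table: {sorted(set(dup))[:5]}"
        )

    out = pd.DataFrame({"patient_id": df["patient_id"].astype(str)})
    sex = df["sex"].astype(str).str.strip().str.lower()
    bad = ~sex.isin(VALID_SEXES)
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise ClaimsSchemaError(f"column 'sex': unrecognised value at line {line}")
    out["sex"] = sex

    for col in ("pd_diagnosis_date", "age_at_diagnosis"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        lines = _bad_lines(df[col], coerced)
        if lines:
            raise ClaimsSchemaError(f"column '{col}': unparseable value at line(s) {lines[:5]}")
        if coerced.isna().any():
            line = int(np.flatnonzero(coerced.isna().to_numpy())[0]) + 2
            raise ClaimsSchemaError(f"column '{col}': missing value at line {line}")
        out[col] = coerced
    out["pd_diagnosis_date"] = out["pd_diagnosis_date"].astype(np.int64)
    out["age_at_diagnosis"] = out["age_at_diagnosis"].astype(float)
    return out


def read_prescriptions(path: str | Path) -> pd.DataFrame:
    """Read the prescription table, flagging rather than dropping bad rows.

    ``prescription_date`` must parse (it anchors all interval arithmetic);
    a missing/unparseable/non-positive value in any of ``period_days``,
    ``daily_dose`` or ``single_dose`` sets ``valid = False`` for the row.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=["", "NA", "NaN", "nan"])
    _require_columns(df, PRESCRIPTION_COLUMNS, "prescription")

    out = pd.DataFrame(
        {
            "patient_id": df["patient_id"].astype(str),
            "drug_code": df["drug_code"].astype(str),
            "drug_class": df["drug_class"].astype(str),
        }
    )
    date = pd.to_numeric(df["prescription_date"], errors="coerce")
    lines = _bad_lines(df["prescription_date"], date)
    if lines or date.isna().any():
        lines = lines or [int(np.flatnonzero(date.isna().to_numpy())[0]) + 2]
        raise ClaimsSchemaError(
            f"column 'prescription_date': unparseable/missing value at line(s) {lines[:5]}"
        )
    out["prescription_date"] = date.astype(np.int64)

    valid = pd.Series(True, index=df.index)
    for col in DOSE_FIELDS:
        coerced = pd.to_numeric(df[col], errors="coerce")
        ok = coerced.notna() & (coerced > 0)
        valid &= ok
        out[col] = coerced
    out["valid"] = valid
    n_bad = int((~valid).sum())
    if n_bad:
        logger.info("flagged %d prescription row(s) with missing/invalid dose fields", n_bad)
    return out


def read_drug_table(path: str | Path | None = None) -> pd.DataFrame:
    """Read a drug reference table; ``None`` loads the packaged default.

    The packaged default covers the nine PD drugs and fifteen antihistamines
    of the screen, with levodopa-equivalent-dose conversion rules taken from
    the standard published conversion reference (levodopa 1.0, pramipexole
    100, ropinirole 20, rasagiline 100, oral selegiline 10, amantadine 1.0,
    entacapone as 0.33 x concurrent levodopa; decarboxylase inhibitors
    contribute no levodopa equivalents).
    """
    if path is None:
        ref = importlib.resources.files("ledd_screen").joinpath("data/drug_table.csv")
        with importlib.resources.as_file(ref) as p:
            df = pd.read_csv(p, dtype={"drug_code": str})
    else:
        df = pd.read_csv(path, dtype={"drug_code": str})
    _require_columns(df, DRUG_TABLE_COLUMNS, "drug")
    bad_class = ~df["drug_class"].isin(VALID_CLASSES)
    if bad_class.any():
        line = int(np.flatnonzero(bad_class.to_numpy())[0]) + 2
        raise ClaimsSchemaError(f"column 'drug_class': unrecognised value at line {line}")
    bad_rule = ~df["rule_type"].isin(VALID_RULES)
    if bad_rule.any():
        line = int(np.flatnonzero(bad_rule.to_numpy())[0]) + 2
        raise ClaimsSchemaError(f"column 'rule_type': unrecognised value at line {line}")
    df["parameter"] = pd.to_numeric(df["parameter"], errors="raise").astype(float)
    factor_rows = df["rule_type"].isin({"factor", "adjunct_levodopa"})
    if (df.loc[factor_rows, "parameter"] <= 0).any():
        raise ClaimsSchemaError("conversion parameters must be > 0 for factor/adjunct rules")
    if "generation" in df.columns:
        df["generation"] = pd.to_numeric(df["generation"], errors="coerce").astype("Int64")
    return df


def read_claims(
    patient_file: str | Path,
    prescription_file: str | Path,
    drug_table_file: str | Path | None = None,
) -> ClaimsBundle:
    """Load and validate the three input tables as one bundle.

    Drug classes in the prescription table are *assigned from the drug
    table*, never inferred from codes; codes absent from the drug table keep
    class ``other`` and take no part in the analysis.
    """
    patients = read_patients(patient_file)
    prescriptions = read_prescriptions(prescription_file)
    drug_table = read_drug_table(drug_table_file)
    class_map = drug_table.set_index("drug_code")["drug_class"]
    prescriptions["drug_class"] = (
        prescriptions["drug_code"].map(class_map).fillna("other")
    )
    return ClaimsBundle(patients, prescriptions, drug_table)


def write_claims(
    patients: pd.DataFrame, prescriptions: pd.DataFrame, out_dir: str | Path
) -> tuple[Path, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    p_path = out_dir / "patients.csv"
    rx_path = out_dir / "prescriptions.csv"
    patients.to_csv(p_path, index=False)
    prescriptions[PRESCRIPTION_COLUMNS].to_csv(rx_path, index=False)
    return p_path, rx_path


def ensure_valid_flag(prescriptions: pd.DataFrame) -> pd.DataFrame:
    """Add the ``valid`` row flag if absent (missing/non-positive dose fields)."""
    if "valid" in prescriptions.columns:
        return prescriptions
    valid = pd.Series(True, index=prescriptions.index)
    for col in DOSE_FIELDS:
        v = pd.to_numeric(prescriptions[col], errors="coerce")
        valid &= v.notna() & (v > 0)
    return prescriptions.assign(valid=valid)


def apply_exclusions(
    patients: pd.DataFrame,
    prescriptions: pd.DataFrame,
    min_age: float = 40.0,
) -> tuple[pd.DataFrame, AttritionLog]:
    """Apply the cohort inclusion/exclusion rules, in a fixed order.

    1. keep patients diagnosed at or after ``min_age`` (default 40 years);
    2. keep patients with at least one PD-drug or antihistamine prescription;
    3. drop patients having *any* invalid prescription row (missing
       prescription period, daily dose, or single dose) — exclusion is
       patient-level, matching how claims screens quote excluded patient
       counts.

    Returns the retained patient table and an :class:`AttritionLog` whose
    running totals reconcile exactly with the input/output row counts.
    """
    prescriptions = ensure_valid_flag(prescriptions)
    log = AttritionLog(n_input=len(patients))

    keep = patients["age_at_diagnosis"] >= min_age
    patients = patients[keep]
    log.record("diagnosed_at_or_after_40", int((~keep).sum()), len(patients))

    relevant = prescriptions[prescriptions["drug_class"].isin({"pd_drug", "antihistamine"})]
    has_rx = patients["patient_id"].isin(relevant["patient_id"].unique())
    patients = patients[has_rx]
    log.record("has_pd_drug_or_antihistamine", int((~has_rx).sum()), len(patients))

    bad_patients = set(prescriptions.loc[~prescriptions["valid"], "patient_id"])
    ok = ~patients["patient_id"].isin(bad_patients)
    patients = patients[ok]
    log.record("no_missing_prescription_fields", int((~ok).sum()), len(patients))

    return patients.reset_index(drop=True), log


def subset_prescriptions(prescriptions: pd.DataFrame, patients: pd.DataFrame) -> pd.DataFrame:
    """Prescriptions belonging to the retained patients."""
    return prescriptions[prescriptions["patient_id"].isin(set(patients["patient_id"]))].reset_index(
        drop=True
    )
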