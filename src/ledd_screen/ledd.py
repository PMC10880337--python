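"""Levodopa-equivalent dose conversion and windowed daily-dose aggregation.

LED (levodopa equivalent dose) expresses a PD drug's daily dose in mg of
levodopa with equivalent clinical effect, via published conversion factors;
LEDD (levodopa equivalent daily dose) sums LEDs over a patient's concurrent
PD medications and serves here as a disease-progression surrogate.

Conversion rules come in three kinds:

``factor``
    ``LED = parameter * daily_dose`` (levodopa 1.0, pramipexole 100, ...).
``adjunct_levodopa``
    catechol-O-methyltransferase inhibitors potentiate concurrent levodopa:
    ``LED = parameter * concurrent levodopa LED`` on each covered day
    (entacapone 0.33).
``none``
    no levodopa equivalent of its own (decarboxylase inhibitors,
    antihistamines).

``ledd_window`` reports the *time-averaged daily* LEDD over a 90-day window
flanking the index date — total LED-days intersecting the window divided by
the window length — so prescriptions spanning a window edge contribute
pro-rata.  A ``cumulative=True`` switch returns the raw LED-day sum instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class UnknownDrugError(KeyError):
    """A PD-drug code has no conversion rule."""

    def __init__(self, code: str):
        super().__init__(f"no LED conversion rule for drug code '{code}'")
        self.code = code


@dataclass(frozen=True)
class ConversionRule:
    rule_type: str  # factor | adjunct_levodopa | none
    parameter: float


class LEDConversionTable:
    """drug_code -> LED conversion rule, built from a drug reference table."""

    def __init__(self, rules: dict[str, ConversionRule]):
        for code, rule in rules.items():
            if rule.rule_type in ("factor", "adjunct_levodopa") and rule.parameter <= 0:
                raise ValueError(f"conversion parameter for '{code}' must be > 0")
        self._rules = dict(rules)

    @classmethod
    def from_drug_table(cls, drug_table: pd.DataFrame) -> "LEDConversionTable":
        rules = {
            str(r.drug_code): ConversionRule(str(r.rule_type), float(r.parameter))
            for r in drug_table.itertuples()
        }
        return cls(rules)

    def __contains__(self, code: str) -> bool:
        return code in self._rules

    def rule(self, code: str) -> ConversionRule:
        try:
            return self._rules[code]
        except KeyError:
            raise UnknownDrugError(code) from None

    def factor_series(self, codes: pd.Series) -> pd.Series:
        """Multiplicative factors for ``factor`` rules, 0 for ``none``/adjunct."""
        unknown = set(codes.unique()) - set(self._rules)
        if unknown:
            raise UnknownDrugError(sorted(unknown)[0])
        return codes.map(
            {
                c: (r.parameter if r.rule_type == "factor" else 0.0)
                for c, r in self._rules.items()
            }
        )

    def adjunct_codes(self) -> list[str]:
        return [c for c, r in self._rules.items() if r.rule_type == "adjunct_levodopa"]


def led_of(daily_dose: float, drug_code: str, table: LEDConversionTable) -> float:
    """Daily LED (mg levodopa-equivalent) of one prescription record.

    Adjunct-rule drugs depend on concurrent levodopa and cannot be converted
    row-wise; use :func:`ledd_window` for those.
    """
    rule = table.rule(drug_code)
    if rule.rule_type == "factor":
        return rule.parameter * daily_dose
    if rule.rule_type == "none":
        return 0.0
    raise ValueError(
        f"'{drug_code}' converts relative to concurrent levodopa; use ledd_window"
    )


def _overlap(start, end, lo, hi):
    return np.clip(np.minimum(end, hi) - np.maximum(start, lo), 0, None)


def ledd_window(
    prescriptions: pd.DataFrame,
    index: int,
    side: str,
    table: LEDConversionTable,
    window_days: int = 90,
    cumulative: bool = False,
) -> float:
    """Time-averaged daily LEDD of one patient over one window.

    ``side='before'`` uses ``[index - window_days, index)``, ``'after'``
    uses ``[index, index + window_days)`` (half-open).  Only ``pd_drug``
    rows contribute; adjunct-rule drugs contribute ``parameter x`` the
    concurrent levodopa LED day-by-day.
    """
    if side not in ("before", "after"):
        raise ValueError("side must be 'before' or 'after'")
    lo, hi = (index - window_days, index) if side == "before" else (index, index + window_days)
    rx = prescriptions[prescriptions["drug_class"] == "pd_drug"]
    if rx.empty:
        return 0.0
    start = rx["prescription_date"].to_numpy(float)
    end = start + rx["period_days"].to_numpy(float)
    dose = rx["daily_dose"].to_numpy(float)
    factors = table.factor_series(rx["drug_code"]).to_numpy(float)
    total = float(np.sum(factors * dose * _overlap(start, end, lo, hi)))

    # adjunct drugs: LED accrues only on days also covered by levodopa
    adjuncts = set(table.adjunct_codes())
    adj = rx[rx["drug_code"].isin(adjuncts)]
    if not adj.empty:
        levo = rx[rx["drug_code"] == "levodopa"]
        for a in adj.itertuples():
            rule = table.rule(a.drug_code)
            a_lo = max(a.prescription_date, lo)
            a_hi = min(a.prescription_date + a.period_days, hi)
            if a_hi <= a_lo or levo.empty:
                continue
            ls = levo["prescription_date"].to_numpy(float)
            le = ls + levo["period_days"].to_numpy(float)
            ld = levo["daily_dose"].to_numpy(float)
            total += rule.parameter * float(np.sum(ld * _overlap(ls, le, a_lo, a_hi)))
    return total if cumulative else total / window_days


def ledd_windows_by_patient(
    prescriptions: pd.DataFrame,
    index_by_patient: pd.Series,
    table: LEDConversionTable,
    window_days: int = 90,
) -> pd.DataFrame:
    """Vectorised before/after window LEDD for many patients at once.

    ``index_by_patient`` maps patient_id -> index date.  Returns a frame
    ``patient_id, ledd_before, ledd_after, difference`` (mg/day).  Patients
    with no PD-drug coverage in a window get 0 for that side.
    """
    rx = prescriptions[prescriptions["drug_class"] == "pd_drug"].copy()
    idx = index_by_patient.rename("index_date")
    rx = rx.merge(idx, left_on="patient_id", right_index=True, how="inner")
    start = rx["prescription_date"].to_numpy(float)
    end = start + rx["period_days"].to_numpy(float)
    dose = rx["daily_dose"].to_numpy(float)
    factors = table.factor_series(rx["drug_code"]).to_numpy(float)
    anchor = rx["index_date"].to_numpy(float)

    led_days_before = factors * dose * _overlap(start, end, anchor - window_days, anchor)
    led_days_after = factors * dose * _overlap(start, end, anchor, anchor + window_days)

    # adjunct drugs (rare): fall back to the per-patient path
    adjuncts = set(table.adjunct_codes())
    adj_patients = set(rx.loc[rx["drug_code"].isin(adjuncts), "patient_id"])

    agg = (
        pd.DataFrame(
            {
                "patient_id": rx["patient_id"].to_numpy(),
                "b": led_days_before,
                "a": led_days_after,
            }
        )
        .groupby("patient_id", sort=True)
        .sum()
    )
    out = pd.DataFrame(index=index_by_patient.index)
    out.index.name = "patient_id"
    out["ledd_before"] = (agg["b"] / window_days).reindex(out.index).fillna(0.0)
    out["ledd_after"] = (agg["a"] / window_days).reindex(out.index).fillna(0.0)

    for pid in adj_patients:
        p_rx = prescriptions[prescriptions["patient_id"] == pid]
        p_idx = int(index_by_patient.loc[pid])
        out.loc[pid, "ledd_before"] = ledd_window(p_rx, p_idx, "before", table, window_days)
        out.loc[pid, "ledd_after"] = ledd_window(p_rx, p_idx, "after", table, window_days)

    out["difference"] = out["ledd_after"] - out["ledd_before"]
    return out.reset_index()


def ledd_difference(before: float, after: float) -> float:
    """Post-index minus pre-index window LEDD (mg/day)."""
    return after - before
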