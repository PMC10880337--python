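"""The per-drug screening report: increment ratios, group comparison, layout.

The screen's statistic is the *increment ratio*: for patient ``i`` with
pre-/post-index window LEDDs ``before_i`` and ``after_i``,

    ratio_i = 100 * (after_i - before_i) / before_i

and the group value is the arithmetic mean of ``ratio_i`` over the ``N``
contributing patients.  Patients with ``before_i = 0`` are excluded from the
ratio (the definition does not extend to them) and counted.  A smaller
increment ratio indicates slower apparent disease progression.  Note this
mean-of-ratios is *not* the ratio of aggregate means
``100 * (mean(after) - mean(before)) / mean(before)``; both are computed, by
distinct code paths, and reported separately.

Exposed and unexposed groups are compared with a two-tailed unpaired t-test
on the per-patient ratio lists (Welch by default, Student optional).

``run_screen`` drives the full pipeline for the overall cohort, the
first/second antihistamine-generation subgroups, and each drug: classify ->
per-unit median interval -> index dates -> pre-index covariates ->
propensity match -> window LEDDs -> increment ratios -> t-test, logging
cohort counts at every stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import claims_io, exposure, ledd, matching

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScreenParams:
    window_days: int = 90
    gap_days: int = 31
    min_duration_days: int = 31
    ratio: int = 3
    caliper: float = 0.25
    caliper_scale: str = "sd"
    ttest: str = "welch"  # welch | student
    adjust: str = "none"  # none | benjamini_hochberg
    strict: bool = True
    min_age: float = 40.0
    use_first_ever: bool = False
    analyses: tuple[str, ...] = ("overall", "generation", "drug")


@dataclass
class IncrementRatioResult:
    n: int
    per_patient_ratios: np.ndarray
    mean_ratio: float
    n_excluded_zero_baseline: int
    mean_before: float
    mean_after: float

    @property
    def aggregate_ratio(self) -> float:
        """Ratio of aggregate means — a different statistic, kept separate."""
        if self.mean_before == 0:
            return np.nan
        return 100.0 * (self.mean_after - self.mean_before) / self.mean_before


@dataclass
class ScreenResult:
    report: pd.DataFrame
    attrition: claims_io.AttritionLog
    assignments: pd.DataFrame
    balance: dict = field(default_factory=dict)


def increment_ratio(pairs: Sequence[tuple[float, float]] | np.ndarray) -> IncrementRatioResult:
    """Mean per-patient percent LEDD change over the contributing patients."""
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be (before, after) tuples")
    before, after = arr[:, 0], arr[:, 1]
    contributing = before != 0
    n_zero = int((~contributing).sum())
    before_c, after_c = before[contributing], after[contributing]
    if before_c.size == 0:
        raise ValueError("no contributing patients after zero-baseline exclusion")
    ratios = 100.0 * (after_c - before_c) / before_c
    return IncrementRatioResult(
        n=int(ratios.size),
        per_patient_ratios=ratios,
        mean_ratio=float(ratios.mean()),
        n_excluded_zero_baseline=n_zero,
        mean_before=float(before_c.mean()),
        mean_after=float(after_c.mean()),
    )


def compare_groups(
    exposed: IncrementRatioResult,
    unexposed: IncrementRatioResult,
    method: str = "welch",
) -> tuple[float, float, float]:
    """Two-sided unpaired t-test on the per-patient ratio lists.

    Returns ``(t, df, p)``.  Degenerate variance is handled explicitly:
    two identical constant samples give ``t=0, p=1``; constant samples with
    different means give ``p=0``.
    """
    if method not in ("welch", "student"):
        raise ValueError("method must be 'welch' or 'student'")
    x, y = exposed.per_patient_ratios, unexposed.per_patient_ratios
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 ratios for a t-test")
    if np.var(x) == 0 and np.var(y) == 0:
        df = float(len(x) + len(y) - 2)
        if np.mean(x) == np.mean(y):
            return 0.0, df, 1.0
        return float(np.sign(np.mean(x) - np.mean(y)) * np.inf), df, 0.0
    res = stats.ttest_ind(x, y, equal_var=(method == "student"))
    return float(res.statistic), float(res.df), float(res.pvalue)


def adjust_pvalues(report: pd.DataFrame, method: str = "none") -> pd.DataFrame:
    """Optionally append a Benjamini-Hochberg adjusted p-value column."""
    if method == "none":
        return report
    if method != "benjamini_hochberg":
        raise ValueError("method must be 'none' or 'benjamini_hochberg'")
    from statsmodels.stats.multitest import multipletests

    report = report.copy()
    mask = report["p_value"].notna()
    adjusted = pd.Series(np.nan, index=report.index)
    if mask.any():
        adjusted[mask] = multipletests(report.loc[mask, "p_value"], method="fdr_bh")[1]
    report["p_adjusted"] = adjusted
    return report


def _covariates_for(
    patients: pd.DataFrame,
    prescriptions: pd.DataFrame,
    index_by_patient: pd.Series,
    windows: pd.DataFrame,
) -> pd.DataFrame:
    """Pre-index covariate vectors: sex, age, PD-drug coverage days, LEDD."""
    rx = prescriptions[prescriptions["drug_class"] == "pd_drug"]
    rx = rx.merge(index_by_patient.rename("index_date"), left_on="patient_id", right_index=True)
    start = rx["prescription_date"].to_numpy(float)
    end = start + rx["period_days"].to_numpy(float)
    covered = np.clip(np.minimum(end, rx["index_date"].to_numpy(float)) - start, 0, None)
    period = (
        pd.DataFrame({"patient_id": rx["patient_id"], "d": covered})
        .groupby("patient_id")["d"]
        .sum()
    )
    cov = patients.set_index("patient_id").loc[index_by_patient.index]
    out = pd.DataFrame(index=index_by_patient.index)
    out["sex_male"] = (cov["sex"] == "male").astype(float)
    out["age_at_diagnosis"] = cov["age_at_diagnosis"].astype(float)
    out["levodopa_rx_period"] = period.reindex(out.index).fillna(0.0)
    out["pre_index_ledd"] = windows.set_index("patient_id")["ledd_before"].reindex(out.index)
    return out


def _unit_row(
    label: str,
    patients: pd.DataFrame,
    prescriptions: pd.DataFrame,
    assignments: pd.DataFrame,
    exposed_ids: pd.Index,
    table: ledd.LEDConversionTable,
    params: ScreenParams,
    horizon: int,
) -> tuple[dict, pd.DataFrame | None]:
    """One report row: median -> index dates -> match -> ratios -> t-test."""
    unit = assignments[
        (assignments["group"] == "unexposed")
        | assignments["patient_id"].isin(exposed_ids)
    ].copy()
    n_exposed_case = int(unit["patient_id"].isin(exposed_ids).sum())
    row = {"label": label, "exposed_case_n": n_exposed_case}
    if n_exposed_case == 0:
        row["skipped"] = "no qualifying exposed patients"
        return row, None

    dated = exposure.assign_index_dates(
        unit,
        patients,
        horizon=horizon,
        window_days=params.window_days,
        use_first_ever=params.use_first_ever,
    )
    row["median_interval_days"] = float(dated["median_interval_used"].iloc[0])
    dated = dated[dated["window_complete"]]
    exposed_flag = pd.Series(
        dated["group"].eq("exposed").to_numpy(), index=dated["patient_id"]
    )
    if not exposed_flag.any() or exposed_flag.all():
        row["skipped"] = "one group empty after window completeness filter"
        return row, None

    index_by_patient = pd.Series(
        dated["index_date"].astype(float).to_numpy(), index=dated["patient_id"]
    )
    windows = ledd.ledd_windows_by_patient(
        prescriptions, index_by_patient, table, params.window_days
    )
    covs = _covariates_for(patients, prescriptions, index_by_patient, windows)
    scores = matching.fit_propensity(covs, exposed_flag)
    cohort = matching.nearest_neighbor_match(
        scores,
        exposed_flag,
        ratio=params.ratio,
        caliper=params.caliper,
        caliper_scale=params.caliper_scale,
        strict=params.strict,
    )
    if cohort.sets.empty:
        row["skipped"] = "no matches within caliper"
        return row, None
    balance = matching.balance_table(covs, exposed_flag, cohort)

    w = windows.set_index("patient_id")
    pairs_exp = w.loc[cohort.exposed_ids, ["ledd_before", "ledd_after"]].to_numpy()
    pairs_ctl = w.loc[cohort.control_ids, ["ledd_before", "ledd_after"]].to_numpy()
    try:
        res_exp = increment_ratio(pairs_exp)
        res_ctl = increment_ratio(pairs_ctl)
        t, df_, p = compare_groups(res_exp, res_ctl, params.ttest)
    except ValueError as err:
        row["skipped"] = str(err)
        return row, balance

    row.update(
        {
            "matched_exposed_n": len(cohort.exposed_ids),
            "matched_control_n": len(cohort.control_ids),
            "unexposed_ledd_before": res_ctl.mean_before,
            "unexposed_ledd_after": res_ctl.mean_after,
            "unexposed_difference": ledd.ledd_difference(res_ctl.mean_before, res_ctl.mean_after),
            "unexposed_ratio": res_ctl.mean_ratio,
            "unexposed_aggregate_ratio": res_ctl.aggregate_ratio,
            "exposed_ledd_before": res_exp.mean_before,
            "exposed_ledd_after": res_exp.mean_after,
            "exposed_difference": ledd.ledd_difference(res_exp.mean_before, res_exp.mean_after),
            "exposed_ratio": res_exp.mean_ratio,
            "exposed_aggregate_ratio": res_exp.aggregate_ratio,
            "t_stat": t,
            "t_df": df_,
            "p_value": p,
            "n_zero_baseline": res_exp.n_excluded_zero_baseline
            + res_ctl.n_excluded_zero_baseline,
            "smd_max_before": float(balance["smd_before"].max()),
            "smd_max_after": float(balance["smd_after"].max()),
            "skipped": "",
        }
    )
    logger.info(
        "%-18s exposed n=%d matched %d:%d ratio %.3f vs %.3f p=%.4f",
        label,
        n_exposed_case,
        len(cohort.exposed_ids),
        len(cohort.control_ids),
        row["exposed_ratio"],
        row["unexposed_ratio"],
        p,
    )
    return row, balance


def run_screen(
    patients: pd.DataFrame,
    prescriptions: pd.DataFrame,
    drug_table: pd.DataFrame | None = None,
    params: ScreenParams = ScreenParams(),
) -> ScreenResult:
    """Run the full screen and return the per-drug report.

    ``analyses`` in ``params`` selects which report blocks to compute:
    ``overall`` (all antihistamines pooled), ``generation`` (first/second
    generation subgroups), ``drug`` (one row per antihistamine).  Drugs with
    zero qualifying exposed patients are reported as skipped, not failed.
    """
    if drug_table is None:
        drug_table = claims_io.read_drug_table()
    table = ledd.LEDConversionTable.from_drug_table(drug_table)
    prescriptions = claims_io.ensure_valid_flag(prescriptions)

    retained, attrition = claims_io.apply_exclusions(
        patients, prescriptions, min_age=params.min_age
    )
    rx = claims_io.subset_prescriptions(prescriptions, retained)
    horizon = int((rx["prescription_date"] + rx["period_days"].fillna(0)).max())

    ah_rx = rx[(rx["drug_class"] == "antihistamine") & rx["valid"]]
    episodes = exposure.build_episodes(ah_rx, params.gap_days, params.min_duration_days)
    assignments = exposure.classify_patients(retained, episodes)
    for g in exposure.GROUPS:
        logger.info("group %-22s n=%d", g, int((assignments["group"] == g).sum()))

    gen_map = (
        drug_table.set_index("drug_code")["generation"]
        if "generation" in drug_table.columns
        else pd.Series(dtype="Int64")
    )
    exposed_rows = assignments[assignments["group"] == "exposed"]

    units: list[tuple[str, pd.Index]] = []
    if "overall" in params.analyses:
        units.append(("overall", pd.Index(exposed_rows["patient_id"])))
    if "generation" in params.analyses:
        gens = exposed_rows["exposed_drug"].map(gen_map)
        for g, lab in [(1, "1st_generation"), (2, "2nd_generation")]:
            units.append((lab, pd.Index(exposed_rows.loc[gens == g, "patient_id"])))
    if "drug" in params.analyses:
        drugs = sorted(
            drug_table.loc[drug_table["drug_class"] == "antihistamine", "drug_code"]
        )
        for d in drugs:
            ids = pd.Index(
                exposed_rows.loc[exposed_rows["exposed_drug"] == d, "patient_id"]
            )
            units.append((d, ids))

    rows, balances = [], {}
    for label, ids in units:
        row, bal = _unit_row(
            label, retained, rx, assignments, ids, table, params, horizon
        )
        rows.append(row)
        if bal is not None:
            balances[label] = bal

    report = pd.DataFrame(rows)
    report = adjust_pvalues(report, params.adjust)
    return ScreenResult(
        report=report, attrition=attrition, assignments=assignments, balance=balances
    )


def overall_only(params: ScreenParams = ScreenParams()) -> ScreenParams:
    """Convenience: the same parameters restricted to the overall analysis."""
    return replace(params, analyses=("overall",))
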