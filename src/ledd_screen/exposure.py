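"""Exposure-episode construction, cohort classification, and index dates.

A prescription covers ``[date, date + period_days)``.  Consecutive
prescriptions of one drug merge into a single *exposure episode* when the
gap between the next start and the running coverage end is below a grace
period (default 31 days); an episode *qualifies* as exposure when its total
span strictly exceeds a minimum duration (default 31 days — "exceeding one
month").

Patients with a qualifying episode of exactly one distinct antihistamine are
*exposed* to that drug; a qualifying episode plus any prescription of a
second antihistamine excludes the patient (``multi_type``); everyone else
retained is *unexposed*.

The index date anchors the before/after dose windows: for the exposed it is
the first prescription date of the first qualifying episode (configurable to
the literal first-ever antihistamine prescription); for the unexposed it is
the PD diagnosis date plus the exposed group's median diagnosis-to-index
interval, which transfers the exposed group's timeframe onto the comparison
group.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

EPISODE_COLUMNS = ["patient_id", "drug_code", "start", "end", "duration_days", "qualifying"]
GROUPS = ("exposed", "unexposed", "excluded_multi_type", "excluded_other")


def build_episodes(
    prescriptions: pd.DataFrame,
    gap_days: int = 31,
    min_duration_days: int = 31,
) -> pd.DataFrame:
    """Merge per patient+drug prescription runs into exposure episodes.

    Gaps are measured from the running coverage end (``max`` of previous
    ``date + period``) to the next start; a gap ``< gap_days`` bridges,
    ``>= gap_days`` splits.  Overlapping prescriptions union.  Episode
    ``duration_days = end - start`` and ``qualifying = duration_days >
    min_duration_days`` (strict: a single 31-day script does not qualify).

    Input order is irrelevant (rows are sorted internally), so the result is
    order-independent and deterministic.
    """
    if gap_days < 0 or min_duration_days < 0:
        raise ValueError("gap_days and min_duration_days must be >= 0")
    rx = prescriptions
    if rx.empty:
        return pd.DataFrame(columns=EPISODE_COLUMNS)
    rx = rx.assign(_end=rx["prescription_date"] + rx["period_days"].astype(np.int64))
    rx = rx.sort_values(
        ["patient_id", "drug_code", "prescription_date", "_end"], kind="mergesort"
    )
    grp = rx.groupby(["patient_id", "drug_code"], sort=False)
    cov_end = grp["_end"].cummax()
    prev_end = cov_end.groupby([rx["patient_id"], rx["drug_code"]], sort=False).shift()
    gap = rx["prescription_date"] - prev_end
    new_episode = gap.isna() | (gap >= gap_days)
    episode_id = new_episode.cumsum()
    episodes = (
        rx.assign(_eid=episode_id, _cov=cov_end)
        .groupby(["patient_id", "drug_code", "_eid"], sort=False)
        .agg(start=("prescription_date", "min"), end=("_cov", "max"))
        .reset_index()
        .drop(columns="_eid")
    )
    episodes["duration_days"] = episodes["end"] - episodes["start"]
    episodes["qualifying"] = episodes["duration_days"] > min_duration_days
    return episodes[EPISODE_COLUMNS].reset_index(drop=True)


def classify_patients(patients: pd.DataFrame, episodes: pd.DataFrame) -> pd.DataFrame:
    """Partition retained patients into exposure groups.

    Returns one row per patient: ``patient_id, group, exposed_drug,
    first_qualifying_start, first_ah_start``.  Every retained patient lands
    in exactly one group.
    """
    out = patients[["patient_id"]].copy()
    if episodes.empty:
        out["group"] = "unexposed"
        out["exposed_drug"] = None
        out["first_qualifying_start"] = np.nan
        out["first_ah_start"] = np.nan
        return out

    per_patient = episodes.groupby("patient_id")
    n_drugs = per_patient["drug_code"].nunique()
    has_qual = per_patient["qualifying"].any()
    qual = episodes[episodes["qualifying"]]
    first_qual = qual.groupby("patient_id")["start"].min()
    first_any = per_patient["start"].min()
    qual_drug = (
        qual.sort_values(["patient_id", "start"]).groupby("patient_id")["drug_code"].first()
    )

    out = out.merge(
        pd.DataFrame(
            {
                "n_ah_drugs": n_drugs,
                "has_qualifying": has_qual,
                "first_qualifying_start": first_qual,
                "first_ah_start": first_any,
                "qual_drug": qual_drug,
            }
        ),
        left_on="patient_id",
        right_index=True,
        how="left",
    )
    out["has_qualifying"] = out["has_qualifying"].eq(True)
    out["n_ah_drugs"] = out["n_ah_drugs"].fillna(0).astype(int)
    out["group"] = np.where(
        out["has_qualifying"] & (out["n_ah_drugs"] == 1),
        "exposed",
        np.where(out["has_qualifying"], "excluded_multi_type", "unexposed"),
    )
    out["exposed_drug"] = out["qual_drug"].where(out["group"] == "exposed")
    return out[
        ["patient_id", "group", "exposed_drug", "first_qualifying_start", "first_ah_start"]
    ]


def compute_median_interval(intervals: pd.Series | np.ndarray) -> float:
    """Median diagnosis-to-index interval over exposed patients (days).

    Even counts take the mean of the two central values.  Raises on an empty
    exposed set.
    """
    arr = np.asarray(intervals, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ValueError("cannot compute a median interval from an empty exposed set")
    return float(np.median(arr))


def assign_index_dates(
    assignments: pd.DataFrame,
    patients: pd.DataFrame,
    median_interval: float | None = None,
    horizon: int | None = None,
    window_days: int = 90,
    use_first_ever: bool = False,
) -> pd.DataFrame:
    """Attach index dates and before/after window-completeness flags.

    Exposed patients anchor on their own first qualifying episode (or the
    literal first-ever antihistamine prescription when ``use_first_ever``);
    unexposed patients anchor on diagnosis + the exposed median interval
    (rounded to a whole day).  ``median_interval=None`` computes it from the
    exposed rows of ``assignments`` itself.

    ``window_complete`` is False when either 90-day window leaves the
    observed data span ``[0, horizon]``; such patients are excluded from the
    windowed analysis downstream.
    """
    out = assignments.merge(
        patients[["patient_id", "pd_diagnosis_date"]], on="patient_id", how="left"
    )
    anchor = out["first_ah_start"] if use_first_ever else out["first_qualifying_start"]
    exposed = out["group"] == "exposed"
    out["interval_days"] = np.where(exposed, anchor - out["pd_diagnosis_date"], np.nan)
    if median_interval is None:
        median_interval = compute_median_interval(out.loc[exposed, "interval_days"])
    median_interval = float(np.round(median_interval))

    index = np.where(
        exposed, anchor, out["pd_diagnosis_date"] + median_interval
    )
    index = np.where(out["group"].str.startswith("excluded"), np.nan, index)
    out["index_date"] = index
    if horizon is None:
        horizon = np.inf
    out["window_complete"] = (
        (out["index_date"] - window_days >= 0)
        & (out["index_date"] + window_days <= horizon)
        & out["index_date"].notna()
    )
    out["median_interval_used"] = median_interval
    return out
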