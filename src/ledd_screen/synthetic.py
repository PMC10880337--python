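"""Synthetic claims generator for the antihistamine/PD progression screen.

Emulates the statistical structure of a national-insurance claims extract of
Parkinson's disease (PD) patients, so that every downstream stage (episode
construction, index-date assignment, LEDD windows, propensity matching, the
increment-ratio test) is exercisable without any real data:

* each patient carries a latent levodopa-equivalent daily dose (LEDD)
  trajectory that is piecewise-constant over 90-day blocks aligned to the
  patient's (latent) index date and grows multiplicatively by a per-patient
  progression percentage per block;
* antihistamine exposure multiplies the post-index progression increment by
  ``1 - exposure_effect`` (0 = no effect, 1 = full suppression);
* exposure assignment may be confounded: the log-odds of exposure shift by
  ``confounding_strength`` per standard deviation of a latent baseline
  severity that also drives baseline LEDD (and, weakly, progression), so
  propensity matching has real work to do;
* prescriptions are dispensed in ~30-day periods; antihistamine refill gaps
  come from a mixture with mass below and above the 31-day grace period;
  a small fraction of rows has a missing dose field; a small fraction of
  patients is deliberately invalid (diagnosed before age 40).

Identical config + seed produce bit-identical tables.  The latent per-patient
truth (group, progression, increment ratio) is returned alongside the claims
tables for test assertions only.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import NamedTuple

import numpy as np
import pandas as pd

ANTIHISTAMINES = [
    "azelastine",
    "bepotastine",
    "cetirizine",
    "chlorpheniramine",
    "clemastine",
    "desloratadine",
    "dimenhydrinate",
    "ebastine",
    "fexofenadine",
    "hydroxyzine",
    "ketotifen",
    "levocetirizine",
    "loratadine",
    "mizolastine",
    "olopatadine",
]

# PD drug -> LED conversion factor used when realising trajectories as doses
PD_DRUG_FACTORS = {"levodopa": 1.0, "pramipexole": 100.0, "ropinirole": 20.0}
PD_DRUG_PROBS = {"levodopa": 0.80, "pramipexole": 0.12, "ropinirole": 0.08}

_FRACTION_FIELDS = (
    "exposure_effect",
    "exposure_prevalence",
    "multi_drug_fraction",
    "missing_field_fraction",
    "invalid_patient_fraction",
    "short_use_fraction",
    "gap_long_prob",
    "refill_skip_prob",
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Scale defaults follow the screen being emulated: pre-index LEDD around
    250 mg/day, ~9% LEDD growth per 90-day window, and a median
    diagnosis-to-first-antihistamine interval around 750 days.
    """

    n_patients: int
    seed: int = 0
    baseline_ledd_mean: float = 250.0  # mg/day, pre-index window value
    baseline_ledd_sd: float = 50.0
    progression_per_window_mean: float = 9.0  # percent per 90 days
    progression_per_window_sd: float = 15.0
    exposure_effect: float = 0.0  # fraction of the increment removed by exposure
    exposure_prevalence: float = 0.08
    confounding_strength: float = 0.0  # log-odds of exposure per SD of severity
    multi_drug_fraction: float = 0.05
    missing_field_fraction: float = 0.02  # fraction of prescription rows corrupted
    invalid_patient_fraction: float = 0.01  # deliberately aged < 40 at diagnosis
    short_use_fraction: float = 0.10  # unexposed given one sub-threshold AH script
    gap_long_prob: float = 0.2  # refill-gap mixture mass above 31 days
    gap_short_range: tuple[int, int] = (0, 20)
    gap_long_range: tuple[int, int] = (45, 120)
    interval_median_days: float = 752.0  # diagnosis -> first AH prescription
    interval_log_sd: float = 0.25
    severity_progression_corr: float = 0.0
    dose_noise_sd: float = 0.0  # optional lognormal sd on dispensed daily doses
    treatment_delay_median_days: float = 120.0  # diagnosis -> first PD drug
    treatment_delay_log_sd: float = 0.8
    treatment_delay_max_days: float = 300.0
    refill_skip_prob: float = 0.0  # chance a 30-day PD script goes unfilled
    study_horizon_days: int = 1825

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients: must be >= 1")
        for name in _FRACTION_FIELDS:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}: must be in [0, 1], got {v}")
        for name in ("baseline_ledd_sd", "progression_per_window_sd", "dose_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name}: must be >= 0")
        if self.baseline_ledd_mean <= 0:
            raise ValueError("baseline_ledd_mean: must be > 0")
        if self.study_horizon_days < 1:
            raise ValueError("study_horizon_days: must be >= 1")
        if not -1.0 <= self.severity_progression_corr <= 1.0:
            raise ValueError("severity_progression_corr: must be in [-1, 1]")


class SimulatedClaims(NamedTuple):
    patients: pd.DataFrame
    prescriptions: pd.DataFrame
    truth: pd.DataFrame


def generate_trajectory(
    baseline: float, progression_pct: float, effect: float, horizon: int
) -> np.ndarray:
    """Daily latent LEDD series: 90-day blocks growing multiplicatively.

    Block ``b`` (0-based) has constant value
    ``baseline * max(1 + progression_pct * (1 - effect) / 100, 0) ** b``;
    negative progression is allowed (dose reductions occur) and the series is
    truncated at zero.
    """
    if baseline <= 0:
        raise ValueError("baseline must be > 0")
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    g = max(1.0 + progression_pct * (1.0 - effect) / 100.0, 0.0)
    blocks = np.arange(int(np.ceil(horizon / 90)))
    values = baseline * np.power(g, blocks)
    return np.repeat(values, 90)[:horizon]


def _latent_block_value(
    offset_from_index: np.ndarray,
    baseline: np.ndarray,
    g_pre: np.ndarray,
    g_post: np.ndarray,
) -> np.ndarray:
    """Latent LEDD at given day offsets from the index date (vectorised).

    The block covering ``[-90, 0)`` equals ``baseline``; earlier blocks
    divide by the pre-index growth factor, later blocks multiply by the
    post-index factor.  Growth is constant (multiplicative) on each side of
    the index, which makes the window-averaged percent change independent of
    where a 90-day window sits relative to the block grid — the property
    that keeps the unexposed group, whose transferred index date is not
    block-aligned, exactly comparable to the exposed group under no effect.
    """
    b = np.floor_divide(offset_from_index, 90)  # block -1 is the pre-index window
    pre = baseline * np.power(np.maximum(g_pre, 0.25), (b + 1).clip(max=0))
    post = baseline * np.power(g_post, (b + 1).clip(min=0))
    return np.where(b < 0, pre, post)


def generate_population(config: SimulationConfig) -> SimulatedClaims:
    """Generate one synthetic cohort (patients, prescriptions, latent truth)."""
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    horizon = config.study_horizon_days

    pid = np.array([f"P{i:07d}" for i in range(n)])
    sex = np.where(rng.random(n) < 0.45, "male", "female")
    age = np.clip(np.round(rng.normal(68.0, 9.0, n), 1), 40.0, 95.0)
    invalid = rng.random(n) < config.invalid_patient_fraction
    age[invalid] = np.round(rng.uniform(25.0, 39.9, invalid.sum()), 1)
    dx = rng.integers(0, 366, n)

    # latent severity drives baseline LEDD, (weakly) progression, and exposure
    z = rng.standard_normal(n)
    baseline = np.maximum(config.baseline_ledd_mean + config.baseline_ledd_sd * z, 30.0)
    rho = config.severity_progression_corr
    eps = rng.standard_normal(n)
    prog = config.progression_per_window_mean + config.progression_per_window_sd * (
        rho * z + np.sqrt(1.0 - rho**2) * eps
    )

    # confounded exposure assignment (logistic in severity)
    p0 = np.clip(config.exposure_prevalence, 1e-9, 1 - 1e-9)
    logit = np.log(p0 / (1 - p0)) + config.confounding_strength * z
    exposed = rng.random(n) < 1.0 / (1.0 + np.exp(-logit))

    # diagnosis -> first antihistamine interval; clipped so that both 90-day
    # windows and the first exposure episode sit inside the observed horizon
    interval = np.exp(
        rng.normal(np.log(config.interval_median_days), config.interval_log_sd, n)
    )
    interval = np.clip(np.round(interval), 95, horizon - 225).astype(np.int64)
    # Latent trajectories are anchored at the patient's index timeframe:
    # the first antihistamine prescription for the exposed, and the common
    # transferred timeframe (diagnosis + nominal median interval) for the
    # unexposed, so baseline_ledd means "LEDD level at the index timeframe"
    # for every patient regardless of group.
    anchor_offset = np.where(exposed, interval, round(config.interval_median_days))
    index_day = dx + anchor_offset

    drug = rng.choice(ANTIHISTAMINES, n)
    multi = exposed & (rng.random(n) < config.multi_drug_fraction)

    g_pre = 1.0 + prog / 100.0
    effect = np.where(exposed, config.exposure_effect, 0.0)
    g_post = np.maximum(1.0 + prog * (1.0 - effect) / 100.0, 0.0)
    true_ratio = 100.0 * (g_post - 1.0)

    # ---- PD-drug prescriptions: ~30-day dispensing realising the trajectory,
    # starting after a treatment-initiation delay, with occasional unfilled refills
    # Initiation delay is bounded so PD treatment is established well before
    # either group's index date: the screen studies dose progression in
    # treated patients, and an initiation landing inside the pre-index
    # window would make the ratio denominator a coverage artifact.  The
    # per-patient 270-day margin covers the 90-day window, the 30-day grid
    # snap, and the sampling jitter of the transferred median index.
    delay = np.exp(
        rng.normal(np.log(config.treatment_delay_median_days), config.treatment_delay_log_sd, n)
    )
    delay_cap = np.minimum(config.treatment_delay_max_days, np.maximum(anchor_offset - 270, 0))
    delay = np.minimum(np.round(delay), delay_cap).astype(np.int64)
    # Scripts renew on a 30-day visit grid anchored at the index timeframe:
    # dose revisions happen at renewal visits, so the quarterly dose blocks
    # consist of exactly three scripts each.
    n_back = int(np.ceil(horizon / 30)) + 1
    j = np.arange(-n_back, n_back)[None, :]
    starts = index_day[:, None] + 30 * j  # (n, 2*n_back)
    keep = (starts >= (dx + delay)[:, None]) & (starts < (dx + horizon)[:, None])
    keep &= rng.random(starts.shape) >= config.refill_skip_prob
    n_rx = starts.shape[1]
    offsets = starts - index_day[:, None]
    latent = _latent_block_value(
        offsets, baseline[:, None], g_pre[:, None], g_post[:, None]
    )
    pd_drug = rng.choice(
        list(PD_DRUG_PROBS), n, p=list(PD_DRUG_PROBS.values())
    )
    factor = np.vectorize(PD_DRUG_FACTORS.get)(pd_drug).astype(float)
    noise = np.exp(rng.normal(0.0, config.dose_noise_sd, latent.shape))
    daily_dose = latent * noise / factor[:, None]

    flat = keep.ravel()
    pd_rx = pd.DataFrame(
        {
            "patient_id": np.repeat(pid, n_rx)[flat],
            "drug_code": np.repeat(pd_drug, n_rx)[flat],
            "drug_class": "pd_drug",
            "prescription_date": starts.ravel()[flat],
            "period_days": 30.0,
            "daily_dose": np.round(daily_dose.ravel()[flat], 3),
            "single_dose": np.round(daily_dose.ravel()[flat] / 3.0, 3),
        }
    )

    # ---- antihistamine prescriptions for the exposed
    ah_frames = [pd_rx]
    exp_idx = np.flatnonzero(exposed)
    if exp_idx.size:
        m = exp_idx.size
        max_rx = 6
        n_ah = rng.integers(3, max_rx + 1, m)
        periods = rng.integers(14, 31, (m, max_rx))
        periods[:, :2] = rng.integers(21, 31, (m, 2))  # first episode spans > 31 d
        long_gap = rng.random((m, max_rx)) < config.gap_long_prob
        long_gap[:, 0] = False  # keep the first two scripts in one episode
        gaps = np.where(
            long_gap,
            rng.integers(config.gap_long_range[0], config.gap_long_range[1] + 1, (m, max_rx)),
            rng.integers(config.gap_short_range[0], config.gap_short_range[1] + 1, (m, max_rx)),
        )
        step = periods + gaps
        ah_starts = index_day[exp_idx][:, None] + np.concatenate(
            [np.zeros((m, 1), dtype=np.int64), np.cumsum(step[:, :-1], axis=1)], axis=1
        )
        mask = np.arange(max_rx)[None, :] < n_ah[:, None]
        ah_dose = np.round(rng.uniform(5.0, 120.0, m), 1)
        ah_frames.append(
            pd.DataFrame(
                {
                    "patient_id": np.repeat(pid[exp_idx], max_rx)[mask.ravel()],
                    "drug_code": np.repeat(drug[exp_idx], max_rx)[mask.ravel()],
                    "drug_class": "antihistamine",
                    "prescription_date": ah_starts.ravel()[mask.ravel()],
                    "period_days": periods.ravel()[mask.ravel()].astype(float),
                    "daily_dose": np.repeat(ah_dose, max_rx)[mask.ravel()],
                    "single_dose": np.repeat(np.round(ah_dose / 2, 1), max_rx)[mask.ravel()],
                }
            )
        )
        # multi-type users: one extra prescription of a *different* antihistamine
        multi_idx = np.flatnonzero(multi)
        if multi_idx.size:
            shift = rng.integers(1, len(ANTIHISTAMINES), multi_idx.size)
            base_pos = np.searchsorted(np.array(ANTIHISTAMINES), drug[multi_idx])
            other = np.array(ANTIHISTAMINES)[(base_pos + shift) % len(ANTIHISTAMINES)]
            ah_frames.append(
                pd.DataFrame(
                    {
                        "patient_id": pid[multi_idx],
                        "drug_code": other,
                        "drug_class": "antihistamine",
                        "prescription_date": dx[multi_idx]
                        + rng.integers(100, horizon - 100, multi_idx.size),
                        "period_days": rng.integers(7, 15, multi_idx.size).astype(float),
                        "daily_dose": 10.0,
                        "single_dose": 5.0,
                    }
                )
            )

    # sub-threshold antihistamine use among the unexposed (stays unexposed)
    short_idx = np.flatnonzero(~exposed & (rng.random(n) < config.short_use_fraction))
    if short_idx.size:
        ah_frames.append(
            pd.DataFrame(
                {
                    "patient_id": pid[short_idx],
                    "drug_code": rng.choice(ANTIHISTAMINES, short_idx.size),
                    "drug_class": "antihistamine",
                    "prescription_date": dx[short_idx]
                    + rng.integers(60, horizon - 100, short_idx.size),
                    "period_days": rng.integers(3, 15, short_idx.size).astype(float),
                    "daily_dose": 10.0,
                    "single_dose": 5.0,
                }
            )
        )

    prescriptions = pd.concat(ah_frames, ignore_index=True)
    prescriptions = prescriptions.sort_values(
        ["patient_id", "drug_code", "prescription_date"], kind="mergesort"
    ).reset_index(drop=True)

    # ---- clustered missingness: record quality clusters by patient, keeping
    # the expected corrupted-ROW fraction at missing_field_fraction
    if config.missing_field_fraction > 0:
        sloppy_frac = min(5.0 * config.missing_field_fraction, 1.0)
        row_frac = config.missing_field_fraction / sloppy_frac
        sloppy = pd.Index(pid[rng.random(n) < sloppy_frac])
        candidate = prescriptions["patient_id"].isin(sloppy).to_numpy()
        corrupt = candidate & (rng.random(len(prescriptions)) < row_frac)
        which = rng.integers(0, 3, len(prescriptions))
        for k, col in enumerate(["period_days", "daily_dose", "single_dose"]):
            prescriptions.loc[corrupt & (which == k), col] = np.nan

    patients = pd.DataFrame(
        {
            "patient_id": pid,
            "sex": sex,
            "pd_diagnosis_date": dx,
            "age_at_diagnosis": age,
        }
    )
    group = np.where(multi, "multi_type", np.where(exposed, "exposed", "unexposed"))
    truth = pd.DataFrame(
        {
            "patient_id": pid,
            "true_group": group,
            "severity_z": z,
            "baseline_ledd": baseline,
            "progression_pct": prog,
            "interval_days": interval,
            "index_day": index_day,
            "assigned_drug": np.where(exposed, drug, ""),
            "true_increment_ratio": true_ratio,
        }
    )
    return SimulatedClaims(patients, prescriptions, truth)


def config_fields() -> list[str]:
    return [f.name for f in fields(SimulationConfig)]
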