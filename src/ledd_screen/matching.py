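"""Propensity-score estimation and 1:k nearest-neighbour caliper matching.

The propensity score is the modelled probability of antihistamine exposure
given the four pre-index covariates (sex, age at PD diagnosis, cumulative
levodopa prescription period, pre-index LEDD), fit by maximum-likelihood
logistic regression.  Matching is greedy nearest-neighbour without
replacement: exposed units are processed in descending score order (ties by
patient_id) and each takes its ``ratio`` nearest unexposed units by absolute
score distance, subject to a caliper expressed as a multiple of the pooled
score standard deviation (the common convention of matching software; an
absolute-probability caliper is available via ``caliper_scale``).  Strict
mode drops exposed units that cannot fill all ``ratio`` slots, so the
matched-control count is exactly ``ratio x`` the retained exposed count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

COVARIATES = ["sex_male", "age_at_diagnosis", "levodopa_rx_period", "pre_index_ledd"]


class PropensityWarning(UserWarning):
    """Separation or non-convergence in the propensity model."""


@dataclass
class MatchedCohort:
    sets: pd.DataFrame  # set_id, exposed_id, control_id, distance
    scores: pd.Series  # patient_id -> propensity score
    caliper_width: float
    dropped_exposed: list = field(default_factory=list)

    @property
    def exposed_ids(self) -> list:
        return list(self.sets["exposed_id"].unique())

    @property
    def control_ids(self) -> list:
        return list(self.sets["control_id"])


def fit_propensity(covariates: pd.DataFrame, exposed: pd.Series) -> pd.Series:
    """Exposure probability per patient from a logistic model.

    ``covariates`` is indexed by patient_id; ``exposed`` is a boolean/0-1
    series on the same index.  Zero-variance columns are dropped (an
    intercept-only model returns the exposed fraction for everyone).
    Separation or non-convergence triggers a :class:`PropensityWarning` and
    a fall back to an L2-penalised fit.
    """
    y = np.asarray(exposed, dtype=float)
    if y.min() == y.max():
        raise ValueError("propensity model needs both exposed and unexposed patients")
    X = covariates.astype(float)
    X = X.loc[:, X.std(ddof=0) > 0]
    design = sm.add_constant(X, has_constant="add")

    fallback = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = sm.Logit(y, design).fit(disp=0, maxiter=200)
            if not res.mle_retvals.get("converged", True):
                fallback = True
            params = res.params
        except Exception:
            fallback = True
            params = None
    if any("separation" in str(w.message).lower() for w in caught):
        fallback = True
    if not fallback and params is not None and not np.all(np.isfinite(params)):
        fallback = True

    if fallback:
        warnings.warn(
            "separation or non-convergence in propensity model; using penalised fit",
            PropensityWarning,
            stacklevel=2,
        )
        from sklearn.linear_model import LogisticRegression

        lr = LogisticRegression(C=1.0, max_iter=1000)
        lr.fit(design.to_numpy(), y)
        scores = lr.predict_proba(design.to_numpy())[:, 1]
    else:
        scores = res.predict(design)
    return pd.Series(np.asarray(scores, dtype=float), index=covariates.index, name="propensity")


def nearest_neighbor_match(
    scores: pd.Series,
    exposed: pd.Series,
    ratio: int = 3,
    caliper: float = 0.25,
    caliper_scale: str = "sd",
    strict: bool = True,
) -> MatchedCohort:
    """Greedy 1:``ratio`` nearest-neighbour matching without replacement.

    ``caliper_scale='sd'`` interprets ``caliper`` as a multiple of the
    pooled score standard deviation; ``'absolute'`` uses it as a raw
    probability distance.  Deterministic: ties in processing order break by
    patient_id; ties in control distance break toward the lower score, then
    lower patient_id.
    """
    if ratio < 1:
        raise ValueError("ratio must be >= 1")
    if caliper <= 0:
        raise ValueError("caliper must be > 0")
    if caliper_scale not in ("sd", "absolute"):
        raise ValueError("caliper_scale must be 'sd' or 'absolute'")
    scores = scores.astype(float)
    exposed = exposed.reindex(scores.index).astype(bool)
    width = caliper * float(scores.std(ddof=1)) if caliper_scale == "sd" else float(caliper)

    t = scores[exposed]
    t_order = np.lexsort((t.index.to_numpy(), -t.to_numpy()))
    treated = list(zip(t.index.to_numpy()[t_order], t.to_numpy()[t_order]))
    controls = scores[~exposed]
    order = np.lexsort((controls.index.to_numpy(), controls.to_numpy()))
    c_scores = controls.to_numpy()[order]
    c_ids = controls.index.to_numpy()[order]
    available = np.ones(len(c_scores), dtype=bool)

    rows = []
    dropped = []
    for set_id, (tid, ts) in enumerate(treated):
        pos = int(np.searchsorted(c_scores, ts))
        left, right = pos - 1, pos
        picked = []
        while len(picked) < ratio:
            while left >= 0 and not available[left]:
                left -= 1
            while right < len(c_scores) and not available[right]:
                right += 1
            d_left = ts - c_scores[left] if left >= 0 else np.inf
            d_right = c_scores[right] - ts if right < len(c_scores) else np.inf
            if d_left == np.inf and d_right == np.inf:
                break
            if d_left <= d_right:  # equal distance -> lower score wins
                d = d_left
                j = left
                left -= 1
            else:
                d = d_right
                j = right
                right += 1
            if d > width:
                break
            picked.append((j, d))
        if strict and len(picked) < ratio:
            dropped.append(tid)
            continue
        if not picked:
            dropped.append(tid)
            continue
        for j, d in picked:
            available[j] = False
            rows.append((set_id, tid, c_ids[j], float(d)))

    sets = pd.DataFrame(rows, columns=["set_id", "exposed_id", "control_id", "distance"])
    return MatchedCohort(sets=sets, scores=scores, caliper_width=width, dropped_exposed=dropped)


def standardized_mean_difference(x_t: np.ndarray, x_c: np.ndarray) -> float:
    """|mean difference| / pooled SD; 0 when both groups are identical constants."""
    m_t, m_c = np.mean(x_t), np.mean(x_c)
    v_t = np.var(x_t, ddof=1) if len(x_t) > 1 else 0.0
    v_c = np.var(x_c, ddof=1) if len(x_c) > 1 else 0.0
    denom = np.sqrt((v_t + v_c) / 2.0)
    if denom == 0:
        return 0.0 if m_t == m_c else np.inf
    return float(abs(m_t - m_c) / denom)


def balance_table(
    covariates: pd.DataFrame, exposed: pd.Series, cohort: MatchedCohort
) -> pd.DataFrame:
    """Pre- and post-match standardised mean differences per covariate."""
    exposed = exposed.reindex(covariates.index).astype(bool)
    matched_t = covariates.loc[cohort.exposed_ids]
    matched_c = covariates.loc[cohort.control_ids]
    rows = {}
    for col in covariates.columns:
        pre = standardized_mean_difference(
            covariates.loc[exposed, col].to_numpy(), covariates.loc[~exposed, col].to_numpy()
        )
        post = (
            standardized_mean_difference(matched_t[col].to_numpy(), matched_c[col].to_numpy())
            if len(matched_t) and len(matched_c)
            else np.nan
        )
        rows[col] = {"smd_before": pre, "smd_after": post}
    return pd.DataFrame(rows).T[["smd_before", "smd_after"]]
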