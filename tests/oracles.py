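"""Brute-force reference implementations used only by the test suite.

These deliberately avoid the vectorised code paths they check: episodes are
built on a boolean day calendar, window LEDDs by summing day by day, and the
increment ratio by a plain Python loop.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def episodes_by_calendar(
    scripts: list[tuple[int, int]], gap_days: int = 31, min_duration_days: int = 31
) -> list[tuple[int, int, bool]]:
    """Episodes for one patient+drug from (start, period) scripts.

    Marks covered days on a calendar, collapses runs, bridges gaps smaller
    than ``gap_days``, and returns (start, end, qualifying) with half-open
    ends and ``qualifying = (end - start) > min_duration_days``.
    """
    if not scripts:
        return []
    horizon = max(s + p for s, p in scripts) + 1
    covered = np.zeros(horizon, dtype=bool)
    for s, p in scripts:
        covered[s : s + p] = True
    # contiguous coverage runs
    runs = []
    d = 0
    while d < horizon:
        if covered[d]:
            e = d
            while e < horizon and covered[e]:
                e += 1
            runs.append([d, e])
            d = e
        else:
            d += 1
    # bridge runs separated by < gap_days
    merged = [runs[0]]
    for start, end in runs[1:]:
        if start - merged[-1][1] < gap_days:
            merged[-1][1] = end
        else:
            merged.append([start, end])
    return [(s, e, (e - s) > min_duration_days) for s, e in merged]


def ledd_window_by_day(
    prescriptions: pd.DataFrame,
    index: int,
    side: str,
    rules: dict[str, tuple[str, float]],
    window_days: int = 90,
) -> float:
    """Evaluate the daily LED on each window day and average.

    ``rules`` maps drug_code -> (rule_type, parameter).  Adjunct drugs
    contribute parameter x the concurrent levodopa LED on each day both are
    covered.
    """
    lo = index - window_days if side == "before" else index
    total = 0.0
    rows = list(prescriptions.itertuples())
    for day in range(lo, lo + window_days):
        levodopa_led = 0.0
        for r in rows:
            if r.drug_class != "pd_drug" or r.drug_code != "levodopa":
                continue
            if r.prescription_date <= day < r.prescription_date + r.period_days:
                levodopa_led += rules["levodopa"][1] * r.daily_dose
        for r in rows:
            if r.drug_class != "pd_drug":
                continue
            if not (r.prescription_date <= day < r.prescription_date + r.period_days):
                continue
            kind, param = rules[r.drug_code]
            if kind == "factor":
                total += param * r.daily_dose
            elif kind == "adjunct_levodopa":
                total += param * levodopa_led
    return total / window_days


def mean_percent_change(pairs) -> tuple[int, float, int]:
    """(n, mean ratio, n zero-baseline) by direct looping."""
    ratios = []
    n_zero = 0
    for before, after in pairs:
        if before == 0:
            n_zero += 1
            continue
        ratios.append(100.0 * (after - before) / before)
    return len(ratios), sum(ratios) / len(ratios), n_zero


def greedy_match_reference(
    scores: dict, exposed: dict, ratio: int, caliper_width: float
) -> list[tuple[object, object, float]]:
    """Plain-Python greedy 1:ratio caliper matching, same policy as the library.

    Exposed processed by descending score (ties: ascending id); controls by
    absolute distance (ties: lower score, then lower id); no replacement.
    """
    treated = sorted(
        [i for i, e in exposed.items() if e], key=lambda i: (-scores[i], i)
    )
    pool = {i for i, e in exposed.items() if not e}
    out = []
    for t in treated:
        cands = sorted(
            pool, key=lambda c: (abs(scores[c] - scores[t]), scores[c], c)
        )
        picked = []
        for c in cands[:ratio]:
            if abs(scores[c] - scores[t]) <= caliper_width:
                picked.append(c)
        if len(picked) < ratio:
            continue
        for c in picked:
            pool.discard(c)
            out.append((t, c, abs(scores[c] - scores[t])))
    return out
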