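#!/usr/bin/env python
"""Simulate the study cohort: confounded antihistamine exposure with a 50%
protective effect on LEDD progression.

Writes the full claims tables to scratch/cohort/ (large, regenerable) and a
compact cohort summary to results/01_cohort_summary.csv.
"""

from pathlib import Path

import pandas as pd

from ledd_screen import claims_io
from ledd_screen.synthetic import SimulationConfig, generate_population

ROOT = Path(__file__).resolve().parents[1]
SEED = 7

config = SimulationConfig(
    n_patients=5000, seed=SEED, exposure_effect=0.5, confounding_strength=0.5
)
sim = generate_population(config)

out = ROOT / "scratch" / "cohort"
claims_io.write_claims(sim.patients, sim.prescriptions, out)
sim.truth.to_csv(out / "truth.csv", index=False)

summary = (
    sim.truth.groupby("true_group")
    .agg(
        n=("patient_id", "size"),
        mean_baseline_ledd=("baseline_ledd", "mean"),
        mean_progression_pct=("progression_pct", "mean"),
        mean_true_increment_ratio=("true_increment_ratio", "mean"),
        median_interval_days=("interval_days", "median"),
    )
    .round(3)
)
(ROOT / "results").mkdir(exist_ok=True)
summary.to_csv(ROOT / "results" / "01_cohort_summary.csv")

print(f"simulated {config.n_patients} patients (seed {SEED}) -> {out}")
print(summary.to_string())
print(
    "\nLatent exposed increment ratio is ~half the unexposed ratio by "
    "construction (exposure_effect=0.5); the screen must recover this from "
    "the claims tables alone."
)
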