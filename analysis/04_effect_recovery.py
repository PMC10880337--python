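#!/usr/bin/env python
"""Effect recovery and covariate balance across repeated confounded cohorts.

Twenty cohorts (n = 5,000, exposure_effect = 0.5, confounding_strength = 0.5):
how often does the matched screen detect the protective effect, and how well
does matching repair the covariate imbalance the confounding induces?
Writes results/04_effect_recovery.csv.
"""

from pathlib import Path

import pandas as pd

from ledd_screen.screen import ScreenParams, run_screen
from ledd_screen.synthetic import SimulationConfig, generate_population

ROOT = Path(__file__).resolve().parents[1]
params = ScreenParams(analyses=("overall",))

rows = []
for seed in range(20):
    sim = generate_population(
        SimulationConfig(
            n_patients=5000, seed=seed, exposure_effect=0.5, confounding_strength=0.5
        )
    )
    r = run_screen(sim.patients, sim.prescriptions, params=params).report.iloc[0]
    rows.append(
        {
            "seed": seed,
            "exposed_ratio": round(float(r.exposed_ratio), 3),
            "unexposed_ratio": round(float(r.unexposed_ratio), 3),
            "p_value": float(r.p_value),
            "recovered": bool(r.exposed_ratio < r.unexposed_ratio and r.p_value < 0.05),
            "smd_max_before": round(float(r.smd_max_before), 3),
            "smd_max_after": round(float(r.smd_max_after), 3),
        }
    )

table = pd.DataFrame(rows)
(ROOT / "results").mkdir(exist_ok=True)
table.to_csv(ROOT / "results" / "04_effect_recovery.csv", index=False)
print(table.to_string(index=False))
print(
    f"\nRecovered in {table.recovered.sum()}/20 seeds; "
    f"max post-match SMD {table.smd_max_after.max():.3f} "
    f"(pre-match up to {table.smd_max_before.max():.3f})."
)
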