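"""Estimate growth rate and extracellular fluxes from a culture time course.

Generates a synthetic 72 h experiment (8 replicate wells sampled daily,
cell-free dishes weighed for evaporation, unconditioned medium for
degradation rates), runs the extracellular-flux stage, and compares the
estimates with the generating truth.
"""

import numpy as np
import pandas as pd

from cellflux.exflux import estimate_fluxes_from_tables
from cellflux.synth import (
    MEDIUM_SPECIES,
    default_ground_truth,
    simulate_growth_timecourse,
    simulate_medium_timecourse,
)

truth = default_ground_truth("lf", "normoxia", seed=1)
times = np.array([0.0, 24.0, 48.0, 72.0])

growth = simulate_growth_timecourse(truth, times, n_replicates=8)
conc, weights = simulate_medium_timecourse(truth, times, n_replicates=8)
blank, _ = simulate_medium_timecourse(truth, times, n_replicates=8, cell_free=True)

timecourse = pd.concat(
    [
        growth.rename(columns={"cells": "value"}).assign(condition="normoxia", analyte="cells"),
        conc.rename(columns={"conc_mM": "value", "species": "analyte"}).assign(condition="normoxia"),
    ]
)[["condition", "replicate", "time_h", "analyte", "value"]]
unconditioned = blank.rename(columns={"conc_mM": "value", "species": "analyte"}).assign(
    condition="blank"
)[["condition", "replicate", "time_h", "analyte", "value"]]

result = estimate_fluxes_from_tables(timecourse, weights, unconditioned=unconditioned)

mu_hat = result[result["quantity"] == "growth_rate"]["value"].iloc[0]
print(f"growth rate: estimated {mu_hat:.4f} /h, truth {truth.mu:.4f} /h")
print(f"{'species':8s} {'v_hat':>9s} {'v_true':>9s}   (fmol/cell/h; negative = consumption)")
for species, (rid, sign) in MEDIUM_SPECIES.items():
    row = result[(result["quantity"] == "flux") & (result["metabolite"] == species)]
    v_hat = row["value"].iloc[0]
    v_true = sign * truth.fluxes.net[rid]
    print(f"{species:8s} {v_hat:9.1f} {v_true:9.1f}")
print(
    "\nEach flux is the slope of a robust regression of medium mass against"
    "\nthe integrated cell growth; estimates track the truth to within the"
    "\n5% concentration noise of the synthetic assay."
)
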