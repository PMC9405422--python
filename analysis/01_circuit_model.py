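#!/usr/bin/env python
"""Characterise the patch/seal RC divider of cell-attached recording.

Evaluates the amplitude transfer function for the example cell
(R_seal 55.6 GOhm, R_patch 7.3 GOhm, C_patch 0.8 pF, C_elec 7 pF) and the
group-median circuit, verifies the closed form against the complex voltage
divider, and demonstrates parameter recovery by generate-and-refit.

Writes results/circuit_bode.csv and results/circuit_fit.json.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from cacc import (FrequencyResponse, PatchCircuitParams, amplitude_response,
                  complex_transfer, dc_transfer, fit_transfer, hf_transfer)

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

example = PatchCircuitParams(R_seal=55.6, R_patch=7.3, C_patch=0.8, C_elec=7.0)
median = PatchCircuitParams(R_seal=15.4, R_patch=4.9, C_patch=0.8, C_elec=7.0)

freqs = np.geomspace(0.01, 2000.0, 300)
bode = pd.DataFrame({
    "frequency_hz": freqs,
    "ar_example_cell": amplitude_response(example, freqs),
    "ar_group_median": amplitude_response(median, freqs),
})
bode.to_csv(OUT / "circuit_bode.csv", index=False)

# the two independent derivations must agree
worst = max(
    abs(abs(complex_transfer(example, f)) - amplitude_response(example, f))
    for f in freqs
)

# generate-and-refit on a noiseless 25-point table
grid = np.geomspace(0.1, 100.0, 25)
fit = fit_transfer(FrequencyResponse(grid, amplitude_response(example, grid)),
                   C_elec_fixed=7.0)

summary = {
    "example_cell": {
        "dc_transfer": round(dc_transfer(example), 4),
        "hf_transfer": round(hf_transfer(example), 4),
        "ar_0.1hz": round(float(amplitude_response(example, 0.1)), 4),
        "ar_240hz": round(float(amplitude_response(example, 240.0)), 4),
    },
    "group_median": {
        "dc_transfer": round(dc_transfer(median), 4),
        "ar_240hz_ap_band": round(float(amplitude_response(median, 240.0)), 4),
        "ar_3.9hz_psp_band": round(float(amplitude_response(median, 3.9)), 4),
    },
    "divider_vs_closed_form_max_abs_diff": float(worst),
    "refit_recovery": {k: round(v, 3) for k, v in fit.estimates.items()},
}
(OUT / "circuit_fit.json").write_text(json.dumps(summary, indent=2))

print("Example cell: DC transfer "
      f"{summary['example_cell']['dc_transfer']}, HF limit "
      f"{summary['example_cell']['hf_transfer']} "
      "(slow signals pass at ~0.9, spikes are cut to ~0.1).")
print(f"Closed form vs complex divider: max |diff| = {worst:.2e}.")
print("Generate-and-refit recovered:", summary["refit_recovery"])
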