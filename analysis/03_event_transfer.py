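#!/usr/bin/env python
"""Measure how spikes and synaptic potentials transfer into the CA channel.

Detects spontaneous PSPs (from WC, the higher-SNR channel) and step-evoked
action potentials, pairs each WC event with the simultaneous CA trace, and
summarises amplitude transfer, kinetic slowing, dominant frequencies and
amplitude-to-noise ratios.

Writes results/event_table.csv and results/event_transfer.json.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from cacc import (NeuronConfig, NoiseConfig, PatchCircuitParams,
                  StimulusProtocol, amplitude_noise_ratio,
                  amplitude_response, detect_aps_wc, detect_spsps,
                  dominant_frequency, pair_and_transfer, quietest_interval,
                  simulate_dual, simulate_membrane)

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

RATE = 5000.0
circuit = PatchCircuitParams(R_seal=15.4, R_patch=4.9, C_patch=0.8, C_elec=7.0)
noise = NoiseConfig()

# --- spontaneous PSPs at rest
psp_bundle = simulate_dual(
    simulate_membrane(NeuronConfig(), None, 120.0, RATE, seed=31),
    circuit, noise, seed=32,
)
wc, ca = psp_bundle.traces["wc"], psp_bundle.traces["ca"]
psps = detect_spsps(wc)
psp_pairs, psp_summary = pair_and_transfer(psps, ca, max_lag=50e-3)
psp_hw = float(np.median([e.half_duration for e in psps]))
anr_wc = amplitude_noise_ratio(psps, quietest_interval(wc, 1.0).sd)
anr_ca = amplitude_noise_ratio([p.ca_measurement for p in psp_pairs],
                               quietest_interval(ca, 1.0).sd)

# --- step-evoked action potentials
protocols = [StimulusProtocol(kind="step", onset=2.0 + 10 * i,
                              offset=2.5 + 10 * i, amplitude=380.0)
             for i in range(6)]
ap_bundle = simulate_dual(
    simulate_membrane(NeuronConfig(psp_rate=0.0), protocols, 62.0, RATE, seed=33),
    circuit, noise, seed=34,
)
aps = detect_aps_wc(ap_bundle.traces["wc"], resting=-81.3)
ap_pairs, ap_summary = pair_and_transfer(aps, ap_bundle.traces["ca"], max_lag=5e-3)
ap_hw = float(np.median([e.half_duration for e in aps]))

rows = []
for pairs, kind in ((psp_pairs, "PSP"), (ap_pairs, "AP")):
    for p in pairs:
        rows.append({
            "kind": kind,
            "wc_amplitude_mv": p.wc_event.amplitude,
            "ca_amplitude_mv": p.ca_measurement.amplitude,
            "wc_half_duration_ms": p.wc_event.half_duration,
            "ca_half_duration_ms": p.ca_measurement.half_duration,
            "lag_ms": p.lag,
        })
pd.DataFrame(rows).to_csv(OUT / "event_table.csv", index=False)

summary = {
    "spsp": {
        "n": psp_summary["n"],
        "transfer_median": round(psp_summary["ratio_median"], 3),
        "transfer_iqr": [round(v, 3) for v in psp_summary["ratio_iqr"]],
        "pearson_r": round(psp_summary["pearson_r"], 3),
        "half_duration_ms": round(psp_hw, 1),
        "dominant_frequency_hz": round(dominant_frequency(psp_hw), 2),
        "model_ar_at_dominant": round(
            float(amplitude_response(circuit, dominant_frequency(psp_hw))), 3),
        "amplitude_noise_ratio_wc": round(anr_wc, 1),
        "amplitude_noise_ratio_ca": round(anr_ca, 1),
    },
    "ap": {
        "n": ap_summary["n"],
        "transfer_median": round(ap_summary["ratio_median"], 3),
        "transfer_iqr": [round(v, 3) for v in ap_summary["ratio_iqr"]],
        "half_duration_ms": round(ap_hw, 2),
        "dominant_frequency_hz": round(dominant_frequency(ap_hw), 0),
        "model_ar_at_dominant": round(
            float(amplitude_response(circuit, dominant_frequency(ap_hw))), 3),
    },
}
(OUT / "event_transfer.json").write_text(json.dumps(summary, indent=2))

s = summary
print(f"sPSPs (n={s['spsp']['n']}): CA/WC amplitude transfer "
      f"{s['spsp']['transfer_median']} (IQR {s['spsp']['transfer_iqr']}), "
      f"dominant frequency {s['spsp']['dominant_frequency_hz']} Hz where the "
      f"model transfer is {s['spsp']['model_ar_at_dominant']}.")
print(f"Amplitude-to-noise: WC {s['spsp']['amplitude_noise_ratio_wc']} vs CA "
      f"{s['spsp']['amplitude_noise_ratio_ca']} — PSPs are far harder to see "
      "in the CA channel.")
print(f"APs (n={s['ap']['n']}): transfer {s['ap']['transfer_median']} at "
      f"dominant frequency {s['ap']['dominant_frequency_hz']} Hz "
      f"(model {s['ap']['model_ar_at_dominant']}); spikes are attenuated "
      "~10-fold and broadened.")
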