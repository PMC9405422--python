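#!/usr/bin/env python
"""Detect network events (GDPs and SWRs) from LFP and read out the
cell-attached membrane response.

Simulates a neonatal-CA3-like GDP session (negative field deflections,
~16 mV depolarisations, spike bursts at the field peak) and adult-CA1-like
SWR sessions (positive deflections; half the cells depolarise, half
hyperpolarise), detects events at 3 SD of the quietest episode of the
1-100 Hz band, and builds peri-event averages and spike histograms.

Writes results/network_events.csv and results/network_summary.json.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from cacc import (NetworkEventConfig, NoiseConfig, PatchCircuitParams,
                  detect_field_events, detect_mua, event_em_change,
                  peri_event, simulate_network_session)

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

RATE = 5000.0
circuit = PatchCircuitParams(R_seal=15.4, R_patch=4.9, C_patch=0.8, C_elec=7.0)
noise = NoiseConfig()

rows, summary = [], {}

# --- GDP session
gdp = simulate_network_session(NetworkEventConfig.gdp(), circuit, noise,
                               120.0, seed=51, rate=RATE)
events = detect_field_events(gdp.traces["lfp"], "negative")
ems = [event_em_change(gdp.traces["ca"], e) for e in events]
pe = peri_event(gdp.traces["ca"], events, window=0.5, bin_width=50e-3,
                ap_times=gdp.ground_truth["ap_times_s"])
centres = 0.5 * (pe.ap_bins[:-1] + pe.ap_bins[1:])
for e, em in zip(events, ems):
    rows.append({"session": "GDP", "ref_time_s": e.ref_time, "kind": e.kind,
                 "field_amplitude": e.field_amplitude, "em_change_mv": em,
                 "flagged": e.flagged})
summary["gdp"] = {
    "n_true": int(gdp.ground_truth["event_times_s"].size),
    "n_detected": len(events),
    "em_change_median_mv": round(float(np.median(ems)), 2),
    "peri_event_peak_mv": round(float(pe.mean.max()), 2),
    "ap_histogram_peak_s_from_field_ref": round(float(centres[int(np.argmax(pe.ap_hist))]), 3),
}

# --- SWR sessions: five depolarising and five hyperpolarising "cells"
swr_medians = []
for cell in range(10):
    dep = cell < 5
    s = simulate_network_session(NetworkEventConfig.swr(depolarizing=dep),
                                 circuit, noise, 60.0, seed=60 + cell, rate=RATE)
    evs = detect_field_events(s.traces["lfp"], "positive")
    ems = [event_em_change(s.traces["ca"], e) for e in evs]
    med = float(np.median(ems))
    swr_medians.append(med)
    for e, em in zip(evs, ems):
        rows.append({"session": f"SWR_cell{cell}", "ref_time_s": e.ref_time,
                     "kind": e.kind, "field_amplitude": e.field_amplitude,
                     "em_change_mv": em, "flagged": e.flagged})
summary["swr"] = {
    "n_cells": 10,
    "n_depolarizing": int(sum(m > 0 for m in swr_medians)),
    "n_hyperpolarizing": int(sum(m < 0 for m in swr_medians)),
    "median_em_change_depolarizing_mv": round(float(np.median(swr_medians[:5])), 2),
    "median_em_change_hyperpolarizing_mv": round(float(np.median(swr_medians[5:])), 2),
}

# --- MUA demonstration at full 30 kHz LFP rate
mua_sess = simulate_network_session(NetworkEventConfig.gdp(), circuit, noise,
                                    30.0, seed=71, rate=30_000.0)
mua = detect_mua(mua_sess.traces["lfp"])
summary["mua"] = {"n_true": int(mua_sess.ground_truth["mua_times_s"].size),
                  "n_detected": int(mua.size)}

pd.DataFrame(rows).to_csv(OUT / "network_events.csv", index=False)
(OUT / "network_summary.json").write_text(json.dumps(summary, indent=2))

g = summary["gdp"]
print(f"GDPs: {g['n_detected']}/{g['n_true']} events detected; CA cells "
      f"depolarise by {g['em_change_median_mv']} mV (median) and fire most "
      f"at {g['ap_histogram_peak_s_from_field_ref']} s from the field peak.")
w = summary["swr"]
print(f"SWRs: {w['n_depolarizing']}/10 cells depolarise "
      f"({w['median_em_change_depolarizing_mv']} mV) and "
      f"{w['n_hyperpolarizing']}/10 hyperpolarise "
      f"({w['median_em_change_hyperpolarizing_mv']} mV) — the heterogeneous "
      "CA1 behaviour.")
print(f"MUA at 30 kHz: {summary['mua']['n_detected']} crossings vs "
      f"{summary['mua']['n_true']} inserted spikes (3-SD rule, 1 ms dead time).")
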