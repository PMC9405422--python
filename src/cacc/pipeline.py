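"""End-to-end pipeline entry points.

``run_pipeline`` dispatches the subcommands exposed by the ``cacc`` command
line (simulate, fit-transfer, detect-events, detect-network, gaba, report),
reads/writes the package's file formats, and records parameters, seed and a
config hash so every run is reproducible.
"""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .circuit import FrequencyResponse, PatchCircuitParams, amplitude_response, fit_transfer
from .events import (amplitude_noise_ratio, detect_aps_ca, detect_aps_wc,
                     detect_spsps, dominant_frequency, pair_and_transfer)
from .gaba import fit_amplitude_vs_em, classify_polarity, reframe_ca_to_wc
from .io import read_bundle_hdf5, write_bundle_hdf5
from .network import detect_field_events, detect_mua, event_em_change, peri_event
from .processing import quietest_interval
from .synthesize import (NetworkEventConfig, NeuronConfig, NoiseConfig,
                         simulate_dual, simulate_gaba_experiment,
                         simulate_membrane, simulate_network_session)
from .traces import StimulusProtocol

KNOWN_COMMANDS = ("simulate", "fit-transfer", "detect-events", "detect-network",
                  "gaba", "report")


class PipelineError(RuntimeError):
    pass


def _config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _write_json(path: Path, payload: dict) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=2, default=float, sort_keys=True))


def _circuit_from(cfg: dict) -> PatchCircuitParams:
    return PatchCircuitParams(
        R_seal=cfg.get("R_seal", 15.4), R_patch=cfg.get("R_patch", 4.9),
        C_patch=cfg.get("C_patch", 0.8), C_elec=cfg.get("C_elec", 7.0),
    )


def _events_frame(events) -> pd.DataFrame:
    return pd.DataFrame([
        {"onset_s": e.onset, "peak_s": e.peak_time, "amplitude_mv": e.amplitude,
         "half_duration_ms": e.half_duration, "onset_to_peak_ms": e.onset_to_peak,
         "kind": e.kind, "channel": e.channel_role}
        for e in events
    ])


# ---------------------------------------------------------------------------
# subcommands


def _cmd_simulate(config: dict, seed: int, out: Path) -> dict:
    kind = config.get("session", "dual")
    rate = config.get("rate_hz", 5000.0)
    duration = config.get("duration_s", 120.0)
    neuron = NeuronConfig(**config.get("neuron", {}))
    noise = NoiseConfig(**config.get("noise", {}))
    circuit = _circuit_from(config.get("circuit", {}))
    protocols = [StimulusProtocol(**p) for p in config.get("protocols", [])]

    if kind in ("membrane", "dual"):
        bundle = simulate_membrane(neuron, protocols, duration, rate, seed)
        if kind == "dual":
            bundle = simulate_dual(bundle, circuit, noise, seed + 1)
    elif kind == "network":
        net = config.get("network", {})
        ncfg = (NetworkEventConfig.gdp() if net.get("kind", "GDP") == "GDP"
                else NetworkEventConfig.swr())
        ncfg = NetworkEventConfig(**{**ncfg.__dict__, **{k: v for k, v in net.items()}})
        bundle = simulate_network_session(ncfg, circuit, noise, duration, seed, rate=rate)
    elif kind == "gaba":
        g = config.get("gaba", {})
        bundle = simulate_gaba_experiment(
            neuron, g.get("em_levels", [-90, -80, -70, -60, -50]),
            g.get("n_stim", 10), circuit, noise, seed, rate=rate,
        )
    else:
        raise PipelineError(f"unknown session kind {kind!r}")

    out.mkdir(parents=True, exist_ok=True)
    write_bundle_hdf5(bundle, out / "bundle.h5")
    for key, val in (bundle.ground_truth or {}).items():
        arr = np.atleast_1d(np.asarray(val))
        if arr.ndim == 1:
            pd.DataFrame({key: arr}).to_csv(out / f"ground_truth_{key}.csv", index=False)
    return {"bundle": str(out / "bundle.h5"),
            "traces": sorted(bundle.traces),
            "n_ground_truth": {k: int(np.atleast_1d(v).shape[0])
                               for k, v in (bundle.ground_truth or {}).items()}}


def _cmd_fit_transfer(config: dict, seed: int, out: Path) -> dict:
    table = pd.read_csv(config["input"])
    fr = FrequencyResponse(table["frequency_hz"].to_numpy(), table["ratio"].to_numpy())
    fit = fit_transfer(fr, C_elec_fixed=config.get("C_elec", 7.0))
    grid = np.geomspace(fr.frequencies[0] / 2, fr.frequencies[-1] * 2, 200)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"frequency_hz": grid,
                  "model_ratio": amplitude_response(fit.params, grid)}
                 ).to_csv(out / "model_bode.csv", index=False)
    return {"params": fit.estimates, "residual_norm": fit.residual_norm,
            "converged": fit.converged}


def _cmd_detect_events(config: dict, seed: int, out: Path) -> dict:
    bundle = read_bundle_hdf5(config["input"])
    which = config.get("detect", ["wc_aps", "spsps"])
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {}
    all_events = []
    if "wc_aps" in which or "spsps" in which:
        try:
            wc = bundle.trace_by_role("WC")
        except KeyError as exc:
            raise PipelineError("bundle has no WC trace but WC detection requested") from exc
    if "wc_aps" in which:
        aps = detect_aps_wc(wc)
        all_events += aps
        summary["n_wc_aps"] = len(aps)
    if "spsps" in which:
        psps = detect_spsps(wc)
        all_events += psps
        summary["n_spsps"] = len(psps)
        if psps:
            noise_sd = quietest_interval(wc, 1.0).sd
            summary["spsp_amplitude_noise_ratio"] = amplitude_noise_ratio(psps, noise_sd)
            hw = float(np.median([e.half_duration for e in psps]))
            summary["spsp_dominant_frequency_hz"] = dominant_frequency(hw)
    if "ca_aps" in which:
        ca_aps = detect_aps_ca(bundle.trace_by_role("CA"))
        all_events += ca_aps
        summary["n_ca_aps"] = len(ca_aps)
    if "pair" in which and "spsps" in which and summary.get("n_spsps"):
        _, pair_summary = pair_and_transfer(
            psps, bundle.trace_by_role("CA"),
            max_lag=config.get("max_lag_s", 50e-3),
        )
        summary["psp_transfer"] = pair_summary
    _events_frame(all_events).to_csv(out / "events.csv", index=False)
    return summary


def _cmd_detect_network(config: dict, seed: int, out: Path) -> dict:
    bundle = read_bundle_hdf5(config["input"])
    lfp = bundle.trace_by_role("LFP")
    polarity = config.get("polarity", "negative")
    events = detect_field_events(lfp, polarity)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    ca = None
    try:
        ca = bundle.trace_by_role("CA")
    except KeyError:
        pass
    for ev in events:
        em = event_em_change(ca, ev) if ca is not None else float("nan")
        rows.append({"ref_time_s": ev.ref_time, "kind": ev.kind,
                     "field_amplitude": ev.field_amplitude, "em_change_mv": em})
    pd.DataFrame(rows).to_csv(out / "network_events.csv", index=False)
    summary: dict = {"n_events": len(events)}
    if events and ca is not None:
        ap_times = (bundle.ground_truth or {}).get("ap_times_s")
        pe = peri_event(ca, events, ap_times=ap_times)
        pd.DataFrame({"time_s": pe.time, "mean_mv": pe.mean, "se_mv": pe.se}
                     ).to_csv(out / "peri_event.csv", index=False)
        summary["median_em_change_mv"] = float(np.median([r["em_change_mv"] for r in rows]))
    if config.get("mua", False):
        mua = detect_mua(lfp)
        pd.DataFrame({"mua_time_s": mua}).to_csv(out / "mua_times.csv", index=False)
        summary["n_mua"] = int(mua.size)
    return summary


def _cmd_gaba(config: dict, seed: int, out: Path) -> dict:
    from .events import evoked_amplitude

    summary: dict = {}
    if "input_csv" in config:
        table = pd.read_csv(config["input_csv"])
        fit = fit_amplitude_vs_em(table["amplitude_mv"], table["em_mv"],
                                  frame=config.get("frame", "WC"))
        summary["fit"] = {"slope": fit.slope, "E_GABA": fit.E_GABA,
                          "r": fit.r, "frame": fit.frame}
        return summary
    bundle = read_bundle_hdf5(config["input"])
    gt = bundle.ground_truth or {}
    stim = float(gt.get("stim_time_s", 0.4))
    em_wc = np.asarray(gt["em_wc_levels_mv"])
    em_ca = np.asarray(gt["em_ca_levels_mv"])
    wc_amp, ca_amp = [], []
    for i in range(em_wc.size):
        wc_amp.append(evoked_amplitude(bundle.traces[f"wc_level_{i}"], stim))
        ca_amp.append(evoked_amplitude(bundle.traces[f"ca_level_{i}"], stim))
    fits = {
        "WC": fit_amplitude_vs_em(wc_amp, em_wc, frame="WC"),
        "CA": fit_amplitude_vs_em(ca_amp, em_ca, frame="CA"),
        "CA_reframed": reframe_ca_to_wc(ca_amp, em_wc),
    }
    summary["fits"] = {k: {"slope": f.slope, "E_GABA": f.E_GABA, "r": f.r}
                       for k, f in fits.items()}
    summary["polarity_wc"] = [classify_polarity(a) for a in wc_amp]
    summary["polarity_ca"] = [classify_polarity(a) for a in ca_amp]
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"em_wc_mv": em_wc, "em_ca_mv": em_ca,
                  "wc_amplitude_mv": wc_amp, "ca_amplitude_mv": ca_amp}
                 ).to_csv(out / "gaba_amplitudes.csv", index=False)
    return summary


def _cmd_report(config: dict, seed: int, out: Path) -> dict:
    src = Path(config.get("input_dir", out))
    collected = {}
    for p in sorted(src.rglob("*_summary.json")):
        collected[p.stem] = json.loads(p.read_text())
    return {"n_summaries": len(collected), "summaries": collected}


_DISPATCH = {
    "simulate": _cmd_simulate,
    "fit-transfer": _cmd_fit_transfer,
    "detect-events": _cmd_detect_events,
    "detect-network": _cmd_detect_network,
    "gaba": _cmd_gaba,
    "report": _cmd_report,
}


def run_pipeline(config: dict, seed: int = 0, out_dir="results") -> dict:
    """Run one pipeline subcommand from a config dict.

    ``config`` must contain ``"command"`` (one of ``KNOWN_COMMANDS``) plus
    command-specific inputs.  Writes machine-readable outputs under
    ``out_dir`` and returns the summary dict, which is also written as
    ``<command>_summary.json`` together with the config hash, seed and
    package version.
    """
    command = config.get("command")
    if command not in KNOWN_COMMANDS:
        raise PipelineError(f"unknown subcommand {command!r}; expected one of {KNOWN_COMMANDS}")
    for key in ("input", "input_csv"):
        if key in config and not Path(config[key]).exists():
            raise PipelineError(f"missing input file {config[key]}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary = _DISPATCH[command](config, seed, out)
    payload = {
        "command": command,
        "seed": seed,
        "config_hash": _config_hash(config),
        "version": __version__,
        "python": platform.python_version(),
        "summary": summary,
    }
    _write_json(out / f"{command}_summary.json", payload)
    return payload
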