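"""Synthetic paired-recording generator with exact ground truth.

Emulates every recording configuration the analysis pipeline consumes:

* a single-compartment leaky integrator producing whole-cell (WC) membrane
  potential with Poisson synaptic potentials and template action potentials,
* the paired cell-attached (CA) trace obtained by passing the WC signal
  through the patch/seal RC divider plus excess noise (white Gaussian and
  slow two-state "channel-gating" telegraph steps),
* local-field-potential sessions with giant-depolarizing-potential (GDP) or
  sharp-wave-ripple (SWR) deflections, multi-unit spikes and a time-locked
  CA recording,
* evoked GABA-PSP sweeps at imposed membrane potentials for reversal-
  potential analysis.

Action potentials are template insertions at threshold crossings and PSPs
are additive voltage waveforms scaled (for GABA) by driving force; there is
no conductance shunting and no Hodgkin-Huxley machinery.  That keeps the
ground truth exact, which is the point: every inserted event is listed once
in ``SessionBundle.ground_truth``.

All generators are deterministic functions of their integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .circuit import PatchCircuitParams, dc_transfer, filter_trace
from .traces import SessionBundle, StimulusProtocol, Trace

# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class NeuronConfig:
    """Parameters of the simulated neuron.

    Defaults emulate a layer-5 pyramidal cell at rest: E_rest -81.3 mV
    (the reported WC group median), membrane time constant
    R_input*C_m = 100 MOhm * 150 pF = 15 ms, spike template with 1.39 ms
    half-width so its dominant frequency (1/(3*half-width)) lands at the
    reported 240 Hz, and synaptic kinetics (rise 1 ms / decay 112 ms) whose
    half-width puts the sPSP dominant frequency near the reported 3.9 Hz.
    The 1 ms rise also gives median-amplitude events peak slopes of ~3 mV/ms,
    consistent with a population detectable by the 1 mV/ms derivative rule.
    """

    E_rest: float = -81.3          # mV
    R_input: float = 100.0         # MOhm
    C_m: float = 150.0             # pF
    ap_threshold: float = -45.0    # mV
    ap_amplitude: float = 100.0    # mV, template peak above baseline
    ap_half_width: float = 1.39e-3  # s
    ap_refractory: float = 50e-3   # s, minimum inter-spike interval
    psp_rate: float = 0.8          # Hz, Poisson event rate
    psp_amp_median: float = 3.0    # mV, log-normal median
    psp_amp_sigma: float = 0.3     # log-normal shape
    psp_rise: float = 1e-3         # s
    psp_decay: float = 112e-3      # s
    E_GABA: float = -60.0          # mV
    gaba_g_scale: float = 0.075    # mV response per mV driving force

    def __post_init__(self) -> None:
        if self.R_input <= 0 or self.C_m <= 0:
            raise ValueError("R_input and C_m must be > 0 (membrane tau must be positive)")
        if self.psp_rate < 0:
            raise ValueError("psp_rate must be >= 0")
        if self.ap_half_width <= 0 or self.psp_rise <= 0 or self.psp_decay <= self.psp_rise:
            raise ValueError("waveform time constants must be positive (decay > rise)")

    @property
    def tau_m(self) -> float:
        """Membrane time constant in seconds (MOhm * pF = microseconds)."""
        return self.R_input * self.C_m * 1e-6


@dataclass(frozen=True)
class NoiseConfig:
    """Recording-noise model.

    White-noise SDs are specified at the ``reference_rate`` acquisition
    bandwidth (50 kHz, the experimental digitisation rate) and scaled by
    sqrt(rate / reference_rate) when a session is generated at a lower rate,
    so the underlying noise *density* — and hence detector behaviour after
    band-limiting — is rate-invariant.  CA excess noise is white Gaussian at
    ``ca_excess_sd_factor`` times the WC level (the reported CA baseline SD
    is about twice the WC one) plus a slow two-state telegraph process
    emulating sporadic channel gating in the patch (default 2 mV steps at
    1 Hz switching; steps do not scale with rate).
    """

    wc_sd: float = 0.3                 # mV at reference_rate bandwidth
    ca_excess_sd_factor: float = 2.0   # dimensionless, >= 1
    telegraph_rate: float = 1.0        # Hz, state-switch rate (CA only)
    telegraph_step: float = 2.0        # mV, peak-to-peak step size
    lfp_pink_sd: float = 0.03          # LFP units (pink: not rate-scaled)
    reference_rate: float = 50_000.0   # Hz

    def __post_init__(self) -> None:
        if self.wc_sd < 0 or self.lfp_pink_sd < 0 or self.telegraph_step < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.ca_excess_sd_factor < 1:
            raise ValueError("ca_excess_sd_factor must be >= 1")
        if self.reference_rate <= 0:
            raise ValueError("reference_rate must be > 0")

    def wc_sd_at(self, rate: float) -> float:
        """Effective white WC noise SD for a trace sampled at ``rate``."""
        return self.wc_sd * np.sqrt(min(rate / self.reference_rate, 1.0))

    def ca_sd_at(self, rate: float) -> float:
        """Effective white CA excess-noise SD at ``rate``."""
        return self.ca_excess_sd_factor * self.wc_sd_at(rate)


@dataclass(frozen=True)
class NetworkEventConfig:
    """Shape and statistics of one class of network events.

    Field and membrane deflections are Gaussian-windowed humps; their
    half-widths default to the dominant-frequency readings of the events
    (1/(3*half_width): 3 Hz for GDPs, 7 Hz for SWRs).  Use :meth:`gdp` /
    :meth:`swr` for the stated study conditions.
    """

    kind: str                       # "GDP" | "SWR"
    rate: float                     # Hz
    em_deflection: float            # mV, signed, pre-filter
    em_half_width: float            # s
    field_polarity: int             # -1 (GDP at CA3) or +1 (SWR at CA1)
    field_amplitude: float          # LFP units
    field_half_width: float         # s
    ap_burst_mean: float = 3.0      # mean APs per event
    mua_per_event: float = 8.0      # mean MUA spikes per event
    mua_amplitude: float = 0.2      # LFP units, spike peak (negative-going)
    mua_background_rate: float = 20.0  # Hz (many units near the probe)
    amplitude_jitter: float = 0.1   # relative SD on per-event amplitudes

    def __post_init__(self) -> None:
        if self.kind not in ("GDP", "SWR"):
            raise ValueError("kind must be GDP or SWR")
        if self.rate < 0 or self.em_half_width <= 0 or self.field_half_width <= 0:
            raise ValueError("rate must be >= 0 and half-widths > 0")
        if self.field_polarity not in (-1, 1):
            raise ValueError("field_polarity must be -1 or +1")

    @classmethod
    def gdp(cls, rate: float = 0.3) -> "NetworkEventConfig":
        """Neonatal CA3 giant depolarizing potentials: negative field
        deflection, +16.3 mV membrane depolarization, ~3 Hz dominant freq."""
        return cls(
            kind="GDP", rate=rate, em_deflection=16.3, em_half_width=0.111,
            field_polarity=-1, field_amplitude=0.5, field_half_width=0.111,
        )

    @classmethod
    def swr(cls, rate: float = 0.3, depolarizing: bool = True) -> "NetworkEventConfig":
        """Adult CA1 sharp-wave ripples: positive field deflection, +/-1.5 mV
        membrane deflection, ~7 Hz dominant frequency."""
        return cls(
            kind="SWR", rate=rate,
            em_deflection=1.5 if depolarizing else -1.5, em_half_width=0.0476,
            field_polarity=+1, field_amplitude=0.4, field_half_width=0.0476,
            ap_burst_mean=1.0 if depolarizing else 0.0,
        )


# ---------------------------------------------------------------------------
# waveform primitives


def ap_template(rate: float, cfg: NeuronConfig) -> tuple[np.ndarray, int, float]:
    """Biphasic spike template sampled at ``rate``.

    Returns ``(waveform, peak_index, peak_amplitude)``.  The depolarizing
    lobe is a Gaussian whose FWHM equals ``cfg.ap_half_width``; a shallow
    delayed after-hyperpolarization makes the waveform biphasic.
    """
    sigma = cfg.ap_half_width / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    half_span = 8.0 * sigma + 3.0 * (3.0 * sigma)
    n_half = int(np.ceil(half_span * rate))
    t = np.arange(-n_half, n_half + 1) / rate
    w = cfg.ap_amplitude * np.exp(-(t**2) / (2 * sigma**2))
    w -= 0.12 * cfg.ap_amplitude * np.exp(-((t - 3 * sigma) ** 2) / (2 * (3 * sigma) ** 2))
    peak = int(np.argmax(w))
    return w, peak, float(w[peak])


def psp_waveform(rate: float, rise: float, decay: float, span_decays: float = 6.0) -> tuple[np.ndarray, int]:
    """Difference-of-exponentials PSP waveform, normalised to unit peak.

    Returns ``(waveform, peak_index)``; the waveform starts at its onset.
    """
    n = int(np.ceil(span_decays * decay * rate))
    t = np.arange(n) / rate
    w = np.exp(-t / decay) - np.exp(-t / rise)
    w /= w.max()
    return w, int(np.argmax(w))


def _add_at(samples: np.ndarray, idx: int, waveform: np.ndarray, offset: int = 0) -> None:
    """Add ``waveform`` into ``samples`` with waveform index ``offset``
    aligned at ``idx``, clipping at the edges."""
    start = idx - offset
    a0, a1 = max(start, 0), min(start + waveform.size, samples.size)
    if a1 <= a0:
        return
    samples[a0:a1] += waveform[a0 - start:a1 - start]


def pink_noise(n: int, sd: float, rate: float, rng: np.random.Generator,
               f_floor: float = 1.0) -> np.ndarray:
    """1/f ("pink") noise of length ``n`` scaled to the requested SD.

    The spectrum is flattened below ``f_floor`` Hz to keep finite power.
    """
    if sd == 0 or n == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / rate)
    scale = 1.0 / np.sqrt(np.maximum(f, f_floor))
    spec *= scale
    out = np.fft.irfft(spec, n=n)
    out *= sd / out.std()
    return out


def telegraph_noise(n: int, rate: float, switch_rate: float, step: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Two-state (+/- step/2) telegraph process with Poisson switching."""
    if step == 0 or switch_rate == 0 or n == 0:
        return np.zeros(n)
    duration = n / rate
    n_switch = rng.poisson(switch_rate * duration)
    switch_idx = np.sort(rng.integers(0, n, size=n_switch))
    state = rng.choice([-1.0, 1.0])
    out = np.empty(n)
    prev = 0
    for idx in switch_idx:
        out[prev:idx] = state
        state = -state
        prev = idx
    out[prev:] = state
    return out * (step / 2.0)


# ---------------------------------------------------------------------------
# simulators


def _normalize_protocols(protocol) -> list[StimulusProtocol]:
    if protocol is None:
        return []
    if isinstance(protocol, StimulusProtocol):
        return [protocol]
    return list(protocol)


def _drive_and_current(protocols, t: np.ndarray, neuron: NeuronConfig):
    """Drive potential E_drive(t) (mV) and injected current I(t) (pA)."""
    e_drive = np.full(t.size, neuron.E_rest)
    i_inj = np.zeros(t.size)
    for p in protocols:
        if p.kind == "none" or p.kind == "extracellular_pulse":
            continue
        mask = (t >= p.onset) & (t < p.offset)
        if p.kind == "step":
            i_inj[mask] += p.amplitude
        elif p.kind == "sinusoid":
            i_inj[mask] += p.amplitude * np.sin(2 * np.pi * p.frequency * (t[mask] - p.onset))
        elif p.kind == "high_K":
            # slow bath exchange: linear ramp over the first/last 20% of the window
            span = p.offset - p.onset
            ramp = 0.2 * span
            frac = np.zeros(t.size)
            frac[mask] = np.clip((t[mask] - p.onset) / ramp, 0, 1)
            washout = t >= p.offset
            frac[washout] = np.clip(1.0 - (t[washout] - p.offset) / ramp, 0, 1)
            e_drive += p.amplitude * frac
    return e_drive, i_inj


def simulate_membrane(
    neuron: NeuronConfig,
    protocol,
    duration: float,
    rate: float,
    seed: int,
) -> SessionBundle:
    """Simulate a WC membrane-potential trace with exact ground truth.

    Passive dynamics follow the leaky integrator
    dV/dt = (E_drive - V)/tau_m + I_inj R_input / tau_m (exponential-Euler
    update, exact for piecewise-constant input).  Poisson PSP waveforms are
    added as voltage events; wherever the subthreshold voltage crosses
    ``ap_threshold`` (respecting the refractory interval) a spike template is
    inserted.  The returned WC trace is noise-free; recording noise belongs
    to :func:`simulate_dual`.
    """
    n = int(round(duration * rate))
    if n > 1e8:
        raise ValueError("requested more than 1e8 samples")
    rng = np.random.default_rng(seed)
    protocols = _normalize_protocols(protocol)
    t = np.arange(n) / rate
    dt = 1.0 / rate

    e_drive, i_inj = _drive_and_current(protocols, t, neuron)
    target = e_drive + i_inj * neuron.R_input * 1e-3  # pA * MOhm = 1e-3 mV
    decay = np.exp(-dt / neuron.tau_m)
    v = np.empty(n)
    v[0] = target[0]
    # v[i+1] = target[i] + (v[i] - target[i]) * exp(-dt/tau)
    # unrolled with scipy-free recursion via lfilter would be possible; the
    # explicit loop is still cheap at desk scale but vectorise with lfilter:
    from scipy.signal import lfilter

    v = lfilter([1.0 - decay], [1.0, -decay], target, zi=[decay * target[0]])[0]

    # synaptic events (glutamatergic: fixed-kinetics, log-normal amplitude)
    psp_w, psp_peak = psp_waveform(rate, neuron.psp_rise, neuron.psp_decay)
    n_psp = rng.poisson(neuron.psp_rate * duration)
    psp_idx = np.sort(rng.integers(0, n, size=n_psp))
    psp_amps = neuron.psp_amp_median * np.exp(neuron.psp_amp_sigma * rng.standard_normal(n_psp))
    for idx, amp in zip(psp_idx, psp_amps):
        _add_at(v, int(idx), amp * psp_w)

    # spike templates at threshold crossings with refractory spacing
    ap_w, ap_peak, ap_amp = ap_template(rate, neuron)
    above = np.flatnonzero(v >= neuron.ap_threshold)
    ap_insert: list[int] = []
    refrac = int(round(neuron.ap_refractory * rate))
    next_allowed = 0
    for idx in above:
        if idx >= next_allowed:
            ap_insert.append(int(idx))
            next_allowed = idx + refrac
    for idx in ap_insert:
        _add_at(v, idx, ap_w, offset=0)  # template onset at the crossing
    ap_peak_times = (np.array(ap_insert, dtype=float) + ap_peak) / rate

    trace = Trace(samples=v, sampling_rate=rate, channel_role="WC", label="membrane")
    ground_truth = {
        "ap_times_s": ap_peak_times,
        "ap_amplitude_mv": float(ap_amp),
        "psp_times_s": psp_idx / rate,
        "psp_peak_times_s": (psp_idx + psp_peak) / rate,
        "psp_amplitudes_mv": psp_amps,
    }
    return SessionBundle(
        traces={"wc": trace},
        protocols=protocols,
        ground_truth=ground_truth,
        provenance={"generator": "simulate_membrane", "seed": seed, "rate_hz": rate},
    )


def simulate_dual(
    bundle: SessionBundle,
    circuit: PatchCircuitParams,
    noise: NoiseConfig,
    seed: int,
) -> SessionBundle:
    """Add a cell-attached trace to a WC bundle.

    The CA channel is the (noise-free) WC signal passed through the circuit
    filter, plus independent white Gaussian excess noise at
    ``ca_excess_sd_factor x wc_sd`` and telegraph steps; the WC channel gets
    its own Gaussian noise.  Over quiet segments (no telegraph switch) the
    CA/WC baseline-SD ratio therefore equals the configured factor.
    """
    try:
        wc_clean = bundle.trace_by_role("WC")
    except KeyError as exc:
        raise ValueError("bundle lacks a WC trace") from exc
    rng = np.random.default_rng(seed)
    n = wc_clean.n_samples
    rate = wc_clean.sampling_rate

    ca = filter_trace(circuit, wc_clean)
    ca_noise = noise.ca_sd_at(rate) * rng.standard_normal(n)
    ca_noise += telegraph_noise(n, rate, noise.telegraph_rate, noise.telegraph_step, rng)
    ca = ca.with_samples(ca.samples + ca_noise, label="ca")
    wc = wc_clean.with_samples(
        wc_clean.samples + noise.wc_sd_at(rate) * rng.standard_normal(n), label="wc"
    )

    traces = dict(bundle.traces)
    traces["wc"] = wc
    traces["wc_clean"] = wc_clean.with_samples(wc_clean.samples, label="wc_clean")
    traces["ca"] = ca
    provenance = dict(bundle.provenance)
    provenance.update({
        "dual_seed": seed,
        "circuit": {
            "R_seal": circuit.R_seal, "R_patch": circuit.R_patch,
            "C_patch": circuit.C_patch, "C_elec": circuit.C_elec,
        },
    })
    return SessionBundle(
        traces=traces,
        protocols=list(bundle.protocols),
        ground_truth=dict(bundle.ground_truth) if bundle.ground_truth is not None else None,
        provenance=provenance,
    )


def _gauss_pulse(rate: float, half_width: float, span_sigmas: float = 5.0) -> tuple[np.ndarray, int]:
    """Gaussian hump of unit peak with the given FWHM (s); returns (w, peak)."""
    sigma = half_width / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    n_half = int(np.ceil(span_sigmas * sigma * rate))
    t = np.arange(-n_half, n_half + 1) / rate
    return np.exp(-(t**2) / (2 * sigma**2)), n_half


def _mua_waveform(rate: float) -> np.ndarray:
    """Brief negative-going biphasic extracellular spike, unit peak, ~1 ms."""
    t = np.arange(int(np.ceil(2e-3 * rate))) / rate
    w = -np.exp(-((t - 0.4e-3) ** 2) / (2 * (0.15e-3) ** 2))
    w += 0.4 * np.exp(-((t - 0.9e-3) ** 2) / (2 * (0.3e-3) ** 2))
    return w


def simulate_network_session(
    cfg: NetworkEventConfig,
    circuit: PatchCircuitParams,
    noise: NoiseConfig,
    duration: float,
    seed: int,
    rate: float = 5000.0,
    neuron: NeuronConfig | None = None,
) -> SessionBundle:
    """LFP + CA session containing GDP- or SWR-like network events.

    The LFP is pink noise plus Gaussian-windowed field deflections of the
    configured polarity with multi-unit spikes clustered around each event
    peak.  The cell's membrane depolarizes (or hyperpolarizes) by
    ``em_deflection`` mV around the same peaks, fires ``ap_burst_mean`` APs
    per event on average near the field extremum, and is then recorded
    through the CA circuit with excess noise.  Ground truth lists event
    reference times, windows, AP and MUA times.
    """
    neuron = neuron or NeuronConfig(psp_rate=0.0)
    rng = np.random.default_rng(seed)
    n = int(round(duration * rate))
    t_grid = np.arange(n) / rate

    # --- event times: Poisson, thinned to a minimum separation.  Events
    # closer than the detector's 200 ms merge gap would be indistinguishable
    # by construction, and slice SWRs/GDPs recur at second-scale intervals,
    # so the separation floor is kept above both.
    min_sep = max(4.0 * max(cfg.em_half_width, cfg.field_half_width), 0.3)
    n_ev = rng.poisson(cfg.rate * duration)
    cand = np.sort(rng.uniform(min_sep, duration - min_sep, size=n_ev))
    ev_times: list[float] = []
    for tt in cand:
        if not ev_times or tt - ev_times[-1] >= min_sep:
            ev_times.append(float(tt))
    ev_times_arr = np.array(ev_times)

    field_w, field_peak = _gauss_pulse(rate, cfg.field_half_width)
    em_w, em_peak = _gauss_pulse(rate, cfg.em_half_width)
    mua_w = _mua_waveform(rate)

    lfp = pink_noise(n, noise.lfp_pink_sd, rate, rng)
    em = np.full(n, neuron.E_rest)
    mua_times: list[float] = []
    ap_times: list[float] = []
    ev_amp_field = np.empty(ev_times_arr.size)
    ev_amp_em = np.empty(ev_times_arr.size)
    for k, tt in enumerate(ev_times_arr):
        idx = int(round(tt * rate))
        jitter_f = 1.0 + cfg.amplitude_jitter * rng.standard_normal()
        jitter_e = 1.0 + cfg.amplitude_jitter * rng.standard_normal()
        ev_amp_field[k] = cfg.field_polarity * cfg.field_amplitude * max(jitter_f, 0.3)
        ev_amp_em[k] = cfg.em_deflection * max(jitter_e, 0.3)
        _add_at(lfp, idx, ev_amp_field[k] * field_w, offset=field_peak)
        _add_at(em, idx, ev_amp_em[k] * em_w, offset=em_peak)
        # MUA burst around the field peak
        n_mua = rng.poisson(cfg.mua_per_event)
        for tm in tt + 0.4 * cfg.field_half_width * rng.standard_normal(n_mua):
            im = int(round(tm * rate))
            amp = cfg.mua_amplitude * (1.0 + 0.3 * abs(rng.standard_normal()))
            _add_at(lfp, im, amp * mua_w)
            mua_times.append(tm)
        # APs time-locked to the event peak (depolarizing events only)
        if cfg.em_deflection > 0 and cfg.ap_burst_mean > 0:
            n_ap = rng.poisson(cfg.ap_burst_mean)
            for ta in tt + 0.3 * cfg.em_half_width * rng.standard_normal(n_ap):
                ap_times.append(float(ta))
    # background MUA
    n_bg = rng.poisson(cfg.mua_background_rate * duration)
    for tm in rng.uniform(0, duration, size=n_bg):
        _add_at(lfp, int(round(tm * rate)), cfg.mua_amplitude * mua_w)
        mua_times.append(float(tm))

    ap_w, ap_peak, _ = ap_template(rate, neuron)
    ap_times_arr = np.sort(np.array(ap_times))
    for ta in ap_times_arr:
        _add_at(em, int(round(ta * rate)) - ap_peak, ap_w)

    wc = Trace(samples=em, sampling_rate=rate, channel_role="WC", label="membrane")
    ca = filter_trace(circuit, wc)
    ca_noise = noise.ca_sd_at(rate) * rng.standard_normal(n)
    ca_noise += telegraph_noise(n, rate, noise.telegraph_rate, noise.telegraph_step, rng)
    ca = ca.with_samples(ca.samples + ca_noise, label="ca")
    lfp_trace = Trace(samples=lfp, sampling_rate=rate, channel_role="LFP",
                      units="mV", label="lfp")

    half_win = 2.0 * max(cfg.em_half_width, cfg.field_half_width)
    windows = np.column_stack([ev_times_arr - half_win, ev_times_arr + half_win])
    ground_truth = {
        "event_times_s": ev_times_arr,
        "event_windows_s": windows,
        "event_field_amplitudes": ev_amp_field,
        "event_em_deflections_mv": ev_amp_em,
        "ap_times_s": ap_times_arr,
        "mua_times_s": np.sort(np.array(mua_times)),
    }
    return SessionBundle(
        traces={"lfp": lfp_trace, "ca": ca, "wc_clean": wc},
        protocols=[],
        ground_truth=ground_truth,
        provenance={"generator": "simulate_network_session", "seed": seed,
                    "kind": cfg.kind, "rate_hz": rate},
    )


def simulate_gaba_experiment(
    neuron: NeuronConfig,
    Em_levels: Sequence[float],
    n_stim: int,
    circuit: PatchCircuitParams,
    noise: NoiseConfig,
    seed: int,
    rate: float = 5000.0,
    sweep_duration: float = 1.0,
    stim_time: float = 0.4,
    amp_noise_sd: float = 0.5,
) -> SessionBundle:
    """Evoked GABA-PSP sweeps at imposed membrane potentials.

    At each WC holding level ``Em`` the evoked response amplitude is
    ``gaba_g_scale * (E_GABA - Em)`` plus per-stimulus Gaussian noise
    (``amp_noise_sd`` mV); ``n_stim`` sweeps are averaged per level.  The CA
    sweep is the WC sweep through the circuit filter, with averaged excess
    noise, so the CA baseline sits at ``dc_transfer * Em`` (the seal-induced
    depolarizing offset) and the CA amplitude is attenuated by the transfer
    at the PSP's dominant frequency.

    Traces are named ``wc_level_<i>`` / ``ca_level_<i>``.
    """
    if len(Em_levels) == 0:
        raise ValueError("Em_levels must not be empty")
    rng = np.random.default_rng(seed)
    n = int(round(sweep_duration * rate))
    psp_w, _ = psp_waveform(rate, neuron.psp_rise, neuron.psp_decay)
    stim_idx = int(round(stim_time * rate))

    traces: dict[str, Trace] = {}
    em_wc = np.asarray(Em_levels, dtype=float)
    em_ca = np.empty_like(em_wc)
    mean_amps = np.empty_like(em_wc)
    for i, em_level in enumerate(em_wc):
        amps = neuron.gaba_g_scale * (neuron.E_GABA - em_level) + amp_noise_sd * rng.standard_normal(n_stim)
        mean_amp = float(np.mean(amps))
        mean_amps[i] = mean_amp
        wc_sweep = np.full(n, em_level)
        _add_at(wc_sweep, stim_idx, mean_amp * psp_w)
        # averaged residual noise scales as 1/sqrt(n_stim)
        wc_sweep = wc_sweep + noise.wc_sd_at(rate) / np.sqrt(n_stim) * rng.standard_normal(n)
        wc_tr = Trace(samples=wc_sweep, sampling_rate=rate, channel_role="WC",
                      label=f"wc_level_{i}")
        ca_tr = filter_trace(circuit, wc_tr.with_samples(np.full(n, em_level) + mean_amp * _pad(psp_w, n, stim_idx)))
        ca_sweep = ca_tr.samples + (noise.ca_sd_at(rate) /
                                    np.sqrt(n_stim)) * rng.standard_normal(n)
        traces[f"wc_level_{i}"] = wc_tr
        traces[f"ca_level_{i}"] = Trace(samples=ca_sweep, sampling_rate=rate,
                                        channel_role="CA", label=f"ca_level_{i}")
        em_ca[i] = dc_transfer(circuit) * em_level

    ground_truth = {
        "em_wc_levels_mv": em_wc,
        "em_ca_levels_mv": em_ca,
        "mean_amplitudes_mv": mean_amps,
        "e_gaba_mv": float(neuron.E_GABA),
        "stim_time_s": float(stim_time),
    }
    return SessionBundle(
        traces=traces,
        protocols=[StimulusProtocol(kind="extracellular_pulse", pulse_times=(stim_time,))],
        ground_truth=ground_truth,
        provenance={"generator": "simulate_gaba_experiment", "seed": seed, "rate_hz": rate},
    )


def _pad(w: np.ndarray, n: int, start: int) -> np.ndarray:
    out = np.zeros(n)
    end = min(start + w.size, n)
    out[start:end] = w[: end - start]
    return out
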