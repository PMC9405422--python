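"""Trace-level corrections and primitive measurements.

Liquid-junction correction, Nernst equilibrium potentials, offline bridge
compensation, zero-phase band-pass and median low-pass filtering, the
"quietest interval" noise estimate, and steady-state voltage shifts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .traces import Trace

R_GAS = 8.31446261815324  # J / (mol K)
FARADAY = 96485.33212     # C / mol


@dataclass(frozen=True)
class IntervalStat:
    """Summary of one time window of a trace (start/duration s, sd/mean mV)."""

    start: float
    duration: float
    sd: float
    mean: float

    def __post_init__(self) -> None:
        if not (self.duration > 0):
            raise ValueError("duration must be > 0")


# ---------------------------------------------------------------------------
# corrections


def correct_ljp(trace: Trace, ljp: float) -> Trace:
    """Apply a liquid-junction-potential correction of ``ljp`` mV.

    Convention: corrected = recorded - ljp, i.e. a positive LJP makes the
    membrane potential more negative (a -65 mV recording with a 16 mV LJP
    becomes -81 mV).  Refuses traces already corrected.
    """
    if trace.ljp_applied != 0:
        raise ValueError("trace already LJP-corrected; refusing double application")
    return trace.with_samples(trace.samples - ljp, ljp_applied=ljp)


def nernst_potential(z: int, conc_in: float, conc_out: float, temperature: float = 30.0) -> float:
    """Nernst equilibrium potential in mV.

    E = (R T / z F) ln(conc_out / conc_in), with T in degrees Celsius
    converted to Kelvin.  The default bath temperature is 30 C.
    """
    if conc_in <= 0 or conc_out <= 0:
        raise ValueError("concentrations must be > 0")
    if z == 0:
        raise ValueError("valence must be nonzero")
    t_kelvin = temperature + 273.15
    return 1e3 * (R_GAS * t_kelvin / (z * FARADAY)) * np.log(conc_out / conc_in)


# ---------------------------------------------------------------------------
# bridge compensation


def bridge_compensate(
    trace: Trace,
    derivative_threshold_frac: float = 0.30,
    edge_window: float = 0.2e-3,
):
    """Offline bridge compensation of a step-evoked episode.

    The voltage drop across the electrode resistance appears as a rectangle
    riding on the membrane response.  Boundaries are found where |dV/dt|
    exceeds ``derivative_threshold_frac`` x (peak |dV/dt| of the ON phase);
    the rectangle amplitude is the instantaneous jump at the ON boundary,
    estimated as the difference of ``edge_window``-long means immediately
    inside and outside the boundary (the membrane charges with a much longer
    time constant, so its contribution over 0.2 ms is negligible).

    Returns ``(corrected_trace, info)`` where ``info`` has keys ``applied``,
    ``on``, ``off`` (s) and ``amplitude`` (mV).  A trace without a detectable
    step is returned unchanged with ``applied=False``.
    """
    v = trace.samples
    dv = np.gradient(v) * trace.sampling_rate  # mV/s
    global_peak = float(np.max(np.abs(dv)))
    if global_peak == 0.0:
        return trace, {"applied": False, "on": None, "off": None, "amplitude": 0.0}
    # ON phase = first large-derivative excursion (step onset); the threshold
    # is 30% of the derivative peak within that phase
    coarse = np.abs(dv) > derivative_threshold_frac * global_peak
    i_first = int(np.argmax(coarse))
    stop = i_first
    while stop < dv.size and coarse[stop]:
        stop += 1
    i_on = i_first + int(np.argmax(np.abs(dv[i_first:stop])))
    on_sign = np.sign(dv[i_on])
    thr = derivative_threshold_frac * abs(dv[i_on])
    # ON boundary: start of the contiguous supra-threshold region at the peak
    i0 = i_on
    while i0 > 0 and abs(dv[i0 - 1]) > thr:
        i0 -= 1
    # OFF boundary: first later supra-threshold excursion of opposite sign
    after = np.where((np.abs(dv) > thr) & (np.sign(dv) == -on_sign))[0]
    after = after[after > stop]
    if after.size == 0:
        return trace, {"applied": False, "on": None, "off": None, "amplitude": 0.0}
    i1 = int(after[0])
    while i1 > 0 and abs(dv[i1 - 1]) > thr and np.sign(dv[i1 - 1]) == -on_sign:
        i1 -= 1

    w = max(1, int(round(edge_window * trace.sampling_rate)))
    pre = v[max(0, i0 - w):i0]
    post = v[i0 + 1:i0 + 1 + w]
    if pre.size == 0 or post.size == 0:
        return trace, {"applied": False, "on": None, "off": None, "amplitude": 0.0}
    amplitude = float(np.mean(post) - np.mean(pre))
    corrected = v.copy()
    corrected[i0:i1] -= amplitude
    info = {
        "applied": True,
        "on": trace.t0 + i0 / trace.sampling_rate,
        "off": trace.t0 + i1 / trace.sampling_rate,
        "amplitude": amplitude,
    }
    return trace.with_samples(corrected), info


# ---------------------------------------------------------------------------
# noise / filtering


def quietest_interval(trace: Trace, duration: float, stride: float | None = None) -> IntervalStat:
    """Window of given duration (s) minimising sample SD.

    Searched on a sliding grid with stride ``duration / 10`` by default,
    which bounds runtime while closely approximating the global minimum.
    """
    n_win = int(round(duration * trace.sampling_rate))
    if n_win < 2 or n_win > trace.n_samples:
        raise ValueError("duration must fit within the trace (and contain >= 2 samples)")
    if n_win == trace.n_samples:
        starts = np.array([0])
    else:
        n_stride = max(1, int(round((stride if stride is not None else duration / 10.0)
                                    * trace.sampling_rate)))
        starts = np.arange(0, trace.n_samples - n_win + 1, n_stride)
    # O(1) window variance via cumulative sums
    c1 = np.concatenate(([0.0], np.cumsum(trace.samples)))
    c2 = np.concatenate(([0.0], np.cumsum(trace.samples**2)))
    s1 = c1[starts + n_win] - c1[starts]
    s2 = c2[starts + n_win] - c2[starts]
    mean = s1 / n_win
    var = np.maximum(s2 / n_win - mean**2, 0.0)
    best = int(np.argmin(var))
    return IntervalStat(
        start=trace.t0 + starts[best] / trace.sampling_rate,
        duration=n_win / trace.sampling_rate,
        sd=float(np.sqrt(var[best])),
        mean=float(mean[best]),
    )


def bandpass(trace: Trace, lo: float, hi: float, order: int = 4) -> Trace:
    """Zero-phase (forward-backward) Butterworth band-pass between lo and hi Hz."""
    nyq = trace.sampling_rate / 2.0
    if not (0 < lo < hi < nyq):
        raise ValueError("need 0 < lo < hi < sampling_rate/2")
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=trace.sampling_rate, output="sos")
    return trace.with_samples(signal.sosfiltfilt(sos, trace.samples))


def lowpass(trace: Trace, cutoff: float, order: int = 4) -> Trace:
    """Zero-phase Butterworth low-pass (smoothing used before differentiation)."""
    if not (0 < cutoff < trace.sampling_rate / 2.0):
        raise ValueError("cutoff must be in (0, rate/2)")
    sos = signal.butter(order, cutoff, btype="lowpass", fs=trace.sampling_rate, output="sos")
    return trace.with_samples(signal.sosfiltfilt(sos, trace.samples))


def median_lowpass(trace: Trace, cutoff: float) -> Trace:
    """Running-median low-pass with window 1/cutoff seconds.

    Suppresses brief events (action potentials) while following slow baseline
    shifts; used to isolate slow depolarisations.
    """
    if not (0 < cutoff < trace.sampling_rate / 2.0):
        raise ValueError("cutoff must be in (0, rate/2)")
    w = max(1, int(round(trace.sampling_rate / cutoff)))
    med = (
        pd.Series(trace.samples)
        .rolling(window=w, center=True, min_periods=1)
        .median()
        .to_numpy()
    )
    return trace.with_samples(med)


def steady_state_shift(
    trace: Trace,
    baseline_window: tuple[float, float],
    response_window: tuple[float, float],
) -> float:
    """Mean of the response window minus mean of the baseline window (mV).

    Windows are (start, end) in seconds, must lie within the trace and not
    overlap.
    """
    for name, (a, b) in (("baseline", baseline_window), ("response", response_window)):
        if not (a < b):
            raise ValueError(f"{name} window must have start < end")
        if a < trace.t0 - 1e-12 or b > trace.t0 + trace.duration + 1e-12:
            raise ValueError(f"{name} window outside trace")
    b0, b1 = baseline_window
    r0, r1 = response_window
    if max(b0, r0) < min(b1, r1):
        raise ValueError("baseline and response windows overlap")

    def _mean(a, b):
        i0, i1 = trace.index_at(a), trace.index_at(b)
        return float(np.mean(trace.samples[i0:i1 + 1]))

    return _mean(r0, r1) - _mean(b0, b1)
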