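"""Network-event analysis: field GDP/SWR detection, multi-unit activity,
peri-event averages and spike histograms.

Field events are detected from the 1-100 Hz band-passed LFP at 3 standard
deviations of the quietest 100 s episode (quietest half for shorter traces,
flagged), with declared polarity (GDPs are negative deflections in the CA3
pyramidal layer, SWRs positive in CA1).  Multi-unit spikes come from the
300-2,500 Hz band at the same 3-SD rule, as negative-going crossings with a
1 ms dead time.  Because thresholds are SD-relative, detection is invariant
to the (declared, never assumed) LFP units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .processing import bandpass, lowpass, quietest_interval
from .traces import Trace


@dataclass(frozen=True)
class NetworkEvent:
    """One detected field event (times s, field amplitude in trace units)."""

    ref_time: float              # field extremum
    window: tuple[float, float]  # (start, end), s
    field_amplitude: float
    kind: str                    # "GDP" | "SWR"
    em_change: float = float("nan")  # mV, filled in by event_em_change
    ap_times: tuple = ()
    flagged: bool = False

    def __post_init__(self) -> None:
        if not (self.window[0] <= self.ref_time <= self.window[1]):
            raise ValueError("ref_time must lie within the event window")


@dataclass(frozen=True)
class PeriEventResult:
    """Event-aligned average: time axis symmetric about the reference."""

    time: np.ndarray      # s, relative to ref
    mean: np.ndarray      # mV (baseline-subtracted)
    se: np.ndarray        # mV
    ap_hist: np.ndarray   # counts per bin
    ap_bins: np.ndarray   # bin edges, s
    n_events: int

    def __post_init__(self) -> None:
        if self.n_events < 1:
            raise ValueError("need at least one event")


def _noise_sd(trace: Trace, episode: float, stride: float) -> tuple[float, bool]:
    """SD of the quietest episode; falls back to the quietest half (flagged)."""
    if trace.duration >= episode:
        return quietest_interval(trace, episode, stride=stride).sd, False
    return quietest_interval(trace, trace.duration / 2.0).sd, True


def detect_field_events(
    lfp: Trace,
    polarity: str,
    kind: str | None = None,
    band: tuple[float, float] = (1.0, 100.0),
    n_sd: float = 3.0,
    quiet_episode: float = 100.0,
    quiet_stride: float = 10.0,
    merge_gap: float = 0.2,
) -> list[NetworkEvent]:
    """Detect GDP/SWR-like deflections in an LFP trace.

    ``polarity`` is "negative" or "positive"; events are contiguous
    excursions of the signed band-passed signal beyond n_sd x (quietest-
    episode SD), merged when closer than ``merge_gap`` seconds.  The
    reference time is the extremum of each excursion.
    """
    if polarity not in ("negative", "positive"):
        raise ValueError("polarity must be 'negative' or 'positive'")
    kind = kind or ("GDP" if polarity == "negative" else "SWR")
    filt = bandpass(lfp, *band)
    sd, flagged = _noise_sd(filt, quiet_episode, quiet_stride)
    sig = -filt.samples if polarity == "negative" else filt.samples
    thr = n_sd * sd
    above = sig >= thr
    if not above.any():
        return []
    edges = np.diff(above.astype(np.int8))
    starts = (np.flatnonzero(edges == 1) + 1).tolist()
    ends = (np.flatnonzero(edges == -1) + 1).tolist()
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(above.size)
    # merge excursions separated by less than merge_gap
    gap = int(round(merge_gap * lfp.sampling_rate))
    merged = [[starts[0], ends[0]]]
    for s, e in zip(starts[1:], ends[1:]):
        if s - merged[-1][1] < gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    events = []
    for s, e in merged:
        i_peak = s + int(np.argmax(sig[s:e]))
        amp = filt.samples[i_peak]
        events.append(NetworkEvent(
            ref_time=lfp.t0 + i_peak / lfp.sampling_rate,
            window=(lfp.t0 + s / lfp.sampling_rate, lfp.t0 + e / lfp.sampling_rate),
            field_amplitude=float(amp),
            kind=kind,
            flagged=flagged,
        ))
    return events


def detect_mua(
    lfp: Trace,
    band: tuple[float, float] = (300.0, 2500.0),
    n_sd: float = 3.0,
    quiet_episode: float = 100.0,
    quiet_stride: float = 10.0,
    dead_time: float = 1e-3,
) -> np.ndarray:
    """Multi-unit spike times from the 300-2,500 Hz band.

    Negative-going crossings of -n_sd x (quietest-episode SD) with a 1 ms
    dead time.  Requires a sampling rate of at least 10 kHz for the 2,500 Hz
    corner.
    """
    if lfp.sampling_rate < 10_000:
        raise ValueError("detect_mua requires a sampling rate >= 10 kHz")
    filt = bandpass(lfp, *band)
    sd, _ = _noise_sd(filt, quiet_episode, quiet_stride)
    below = filt.samples <= -n_sd * sd
    crossings = np.flatnonzero(~below[:-1] & below[1:]) + 1
    dead = max(1, int(round(dead_time * lfp.sampling_rate)))
    times = []
    last = -dead
    for idx in crossings:
        if idx - last >= dead:
            times.append(lfp.t0 + idx / lfp.sampling_rate)
            last = idx
    return np.asarray(times)


def peri_event(
    ca: Trace,
    events: list[NetworkEvent] | np.ndarray,
    window: float = 0.5,
    bin_width: float = 10e-3,
    ap_times: np.ndarray | None = None,
) -> PeriEventResult:
    """Event-aligned mean +/- SE of the CA voltage and AP histogram.

    For each event the CA segment in [ref - window, ref + window] is taken,
    its baseline (median of the first half of the pre-window) subtracted,
    and segments averaged.  Events whose window leaves the trace are dropped
    (an error if none survive).  The AP histogram counts spikes per
    ``bin_width`` bin relative to the references.
    """
    refs = np.asarray([e.ref_time if isinstance(e, NetworkEvent) else float(e)
                       for e in events], dtype=float)
    if refs.size == 0:
        raise ValueError("need at least one event")
    rate = ca.sampling_rate
    n_half = int(round(window * rate))
    segs = []
    kept_refs = []
    for ref in refs:
        i_ref = int(round((ref - ca.t0) * rate))
        i0, i1 = i_ref - n_half, i_ref + n_half + 1
        if i0 < 0 or i1 > ca.n_samples:
            continue
        seg = ca.samples[i0:i1].astype(float)
        seg = seg - np.median(seg[: n_half // 2])
        segs.append(seg)
        kept_refs.append(ref)
    if not segs:
        raise ValueError("all events fall at trace edges")
    arr = np.vstack(segs)
    mean = arr.mean(axis=0)
    se = arr.std(axis=0, ddof=1) / np.sqrt(arr.shape[0]) if arr.shape[0] > 1 else np.zeros(mean.size)
    t_axis = (np.arange(-n_half, n_half + 1)) / rate

    n_bins = max(1, int(round(2 * window / bin_width)))
    bins = np.linspace(-window, window, n_bins + 1)
    if ap_times is not None and len(ap_times):
        rel = np.concatenate([np.asarray(ap_times) - r for r in kept_refs])
        hist, _ = np.histogram(rel, bins=bins)
    else:
        hist = np.zeros(n_bins, dtype=int)
    return PeriEventResult(time=t_axis, mean=mean, se=se, ap_hist=hist,
                           ap_bins=bins, n_events=len(segs))


def event_em_change(
    ca: Trace,
    event: NetworkEvent,
    baseline_duration: float = 1.0,
    smooth_cutoff: float = 50.0,
) -> float:
    """Signed membrane-potential change of one network event (mV).

    Extremum of the (low-passed) CA voltage within the event window minus
    the median of the ``baseline_duration`` seconds preceding the window
    (truncated at the trace start if needed).  Smoothing keeps the extremum
    from riding on wide-band noise; 50 Hz comfortably passes GDP/SWR-band
    deflections.
    """
    sm = lowpass(ca, smooth_cutoff) if smooth_cutoff < ca.sampling_rate / 2 else ca
    i0 = ca.index_at(event.window[0])
    i1 = ca.index_at(event.window[1])
    if i1 <= i0:
        raise ValueError("empty event window")
    b0 = max(0, i0 - int(round(baseline_duration * ca.sampling_rate)))
    if b0 == i0:
        raise ValueError("no baseline available before the event window")
    baseline = float(np.median(sm.samples[b0:i0]))
    seg = sm.samples[i0:i1 + 1] - baseline
    return float(seg[np.argmax(np.abs(seg))])
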