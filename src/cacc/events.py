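"""Detection and measurement of action potentials and synaptic potentials.

Detection rules (thresholds are the analysis defaults, all configurable):

* WC action potentials: excursions exceeding 40 mV above the resting
  potential; one event per contiguous supra-threshold excursion.
* CA action potentials and WC spontaneous PSPs: upward crossings of
  1 mV/ms on the first derivative of the (smoothed) voltage.
* Event onset: latest upward crossing before the peak of 10 mV/ms (APs) or
  0.1 mV/ms (PSPs), scanned backwards from the peak.
* Amplitude: extremum value minus the mean voltage in the interval 1-5 ms
  before onset; half-duration measured at half amplitude with interpolated
  crossings.
* Evoked responses: largest deflection within 200 ms after the stimulus in
  the averaged trace, minus the median baseline of the 200 ms before it.
* Dominant frequency of an event: 1 / (3 x half-width), i.e. the half-width
  is taken as a third of the period of the matched oscillation.

Derivatives are taken on a low-pass-smoothed copy (default 1 kHz cutoff; the
CA spike detector uses 300 Hz because of the larger CA excess noise) so the
mV/ms thresholds remain meaningful in the presence of wide-band noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .processing import lowpass
from .traces import Trace

DEFAULT_SMOOTH_CUTOFF = 1000.0  # Hz, derivative pre-smoothing for detection
CA_AP_SMOOTH_CUTOFF = 300.0     # Hz, CA spike detection (larger excess noise)
PSP_MEASURE_CUTOFF = 100.0      # Hz, onset/measurement smoothing for slow PSPs


@dataclass(frozen=True)
class EventRecord:
    """One detected and measured event (times s, amplitude mV, widths ms)."""

    onset: float
    peak_time: float
    amplitude: float
    half_duration: float
    onset_to_peak: float
    kind: str                 # "AP" | "PSP"
    channel_role: str
    baseline: float = 0.0     # mV, pre-onset reference used for the amplitude
    flagged: bool = False

    def __post_init__(self) -> None:
        if self.peak_time < self.onset:
            raise ValueError("peak_time must be >= onset")


@dataclass(frozen=True)
class PairedEvents:
    """A WC event and its measurement on the simultaneous CA trace."""

    wc_event: EventRecord
    ca_measurement: EventRecord
    lag: float  # ms, CA peak minus WC peak

    def __post_init__(self) -> None:
        if not np.isfinite(self.lag):
            raise ValueError("lag must be finite")

    @property
    def amplitude_ratio(self) -> float:
        return self.ca_measurement.amplitude / self.wc_event.amplitude


# ---------------------------------------------------------------------------
# helpers


def _smoothed(trace: Trace, cutoff: float | None) -> np.ndarray:
    if cutoff is None or cutoff >= trace.sampling_rate / 2.0:
        return trace.samples
    return lowpass(trace, cutoff).samples


def _derivative_mv_per_ms(samples: np.ndarray, rate: float) -> np.ndarray:
    return np.gradient(samples) * rate * 1e-3


def event_onset(
    trace: Trace,
    peak_time: float,
    derivative_threshold: float,
    max_lookback: float = 0.1,
    smooth_cutoff: float | None = DEFAULT_SMOOTH_CUTOFF,
) -> tuple[float, bool]:
    """Onset time: latest upward crossing of the derivative threshold
    (mV/ms) before the peak, scanning backwards.

    Returns ``(onset_s, flagged)``; if no crossing occurs within
    ``max_lookback`` seconds before the peak, the onset falls back to
    ``peak - max_lookback`` and is flagged.
    """
    i_peak = trace.index_at(peak_time)
    i_lo = max(0, i_peak - int(round(max_lookback * trace.sampling_rate)))
    v = _smoothed(trace, smooth_cutoff)
    dv = _derivative_mv_per_ms(v[i_lo:i_peak + 1], trace.sampling_rate)
    above = dv >= derivative_threshold
    # latest upward crossing: last index where above goes False -> True
    if not above.any():
        return trace.t0 + i_lo / trace.sampling_rate, True
    rising = np.flatnonzero(~above[:-1] & above[1:])
    if rising.size:
        i_on = i_lo + int(rising[-1]) + 1
    else:  # above from the very start of the window
        i_on = i_lo + int(np.flatnonzero(above)[0])
    return trace.t0 + i_on / trace.sampling_rate, False


def measure_event(
    trace: Trace,
    onset: float,
    peak_time: float,
    kind: str = "PSP",
    smooth_cutoff: float | None = DEFAULT_SMOOTH_CUTOFF,
    peak_refine: float = 2e-3,
) -> EventRecord:
    """Measure amplitude, half-duration and onset-to-peak of one event.

    Amplitude is the value at the extremum minus the mean voltage in the
    interval 1-5 ms before onset (signed; negative for hyperpolarizing
    events).  The peak index is refined to the local extremum of the
    measurement-bandwidth signal within ``peak_refine`` seconds of the
    supplied peak, so measurements are consistent whichever bandwidth
    located the peak.  Half-duration is the width at half amplitude around
    the peak, with sub-sample linear interpolation of the crossings.  A
    baseline window truncated by the trace start flags the record.
    """
    if peak_time < onset:
        raise ValueError("peak_time must be >= onset")
    rate = trace.sampling_rate
    v = _smoothed(trace, smooth_cutoff)
    i_on = trace.index_at(onset)
    i_peak = trace.index_at(peak_time)
    b0 = i_on - int(round(5e-3 * rate))
    b1 = i_on - int(round(1e-3 * rate))
    flagged = False
    if b0 < 0:
        b0, flagged = 0, True
    if b1 <= b0:
        b1 = b0 + 1
    baseline = float(np.mean(v[b0:b1]))
    if peak_refine > 0:
        r = max(1, int(round(peak_refine * rate)))
        w0, w1 = max(i_on, i_peak - r), min(v.size, i_peak + r + 1)
        i_peak = w0 + int(np.argmax(np.abs(v[w0:w1] - baseline)))
    amplitude = float(v[i_peak] - baseline)
    half = baseline + amplitude / 2.0
    n_hold = max(1, int(round(5e-3 * rate)))  # noise dips must persist 5 ms

    def _crossing(idx_from: int, step: int) -> float:
        """Sub-sample time at which v crosses `half` moving from the peak.

        A crossing only counts if the signal stays beyond it for the hold
        window, so brief noise dips during slow decays are skipped.
        """
        i = idx_from
        sign = np.sign(amplitude) if amplitude != 0 else 1.0
        while 0 < i < v.size - 1:
            j = i + step
            if j < 0 or j >= v.size:
                break
            if sign * (v[j] - half) <= 0:
                if step > 0:
                    run = v[j:min(j + n_hold, v.size)]
                else:
                    run = v[max(j - n_hold + 1, 0):j + 1]
                if np.all(sign * (run - half) <= 0) or run.size < n_hold:
                    frac = (v[i] - half) / (v[i] - v[j]) if v[i] != v[j] else 0.0
                    return (i + step * frac) / rate
                i = j + step * run.size  # skip past the brief dip
                continue
            i = j
        return min(max(i, 0), v.size - 1) / rate

    t_left = _crossing(i_peak, -1)
    t_right = _crossing(i_peak, +1)
    half_duration_ms = max(t_right - t_left, 1.0 / rate) * 1e3
    return EventRecord(
        onset=trace.t0 + i_on / rate,
        peak_time=trace.t0 + i_peak / rate,
        amplitude=amplitude,
        half_duration=half_duration_ms,
        onset_to_peak=(i_peak - i_on) / rate * 1e3,
        kind=kind,
        channel_role=trace.channel_role,
        baseline=baseline,
        flagged=flagged,
    )


# ---------------------------------------------------------------------------
# detectors


def detect_aps_wc(
    trace: Trace,
    resting: float | None = None,
    threshold_above_rest: float = 40.0,
    onset_threshold: float = 10.0,
    smooth_cutoff: float | None = DEFAULT_SMOOTH_CUTOFF,
) -> list[EventRecord]:
    """Detect action potentials in a WC trace.

    Events are contiguous excursions above resting + 40 mV (resting defaults
    to the trace median); the peak is the maximum of each excursion and the
    onset comes from the 10 mV/ms backward-scan rule.
    """
    if trace.channel_role != "WC":
        raise ValueError("detect_aps_wc expects a WC trace")
    if resting is None:
        resting = float(np.median(trace.samples))
    thr = resting + threshold_above_rest
    above = trace.samples >= thr
    if not above.any():
        return []
    edges = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.concatenate(([0], starts))
    if above[-1]:
        ends = np.concatenate((ends, [above.size]))
    events = []
    for s, e in zip(starts, ends):
        i_peak = s + int(np.argmax(trace.samples[s:e]))
        t_peak = trace.t0 + i_peak / trace.sampling_rate
        onset, flag = event_onset(trace, t_peak, onset_threshold, smooth_cutoff=smooth_cutoff)
        # APs are fast relative to the smoothing cutoff: measure on raw samples
        rec = measure_event(trace, onset, t_peak, kind="AP", smooth_cutoff=None)
        if flag:
            rec = EventRecord(**{**rec.__dict__, "flagged": True})
        events.append(rec)
    return events


def _derivative_events(
    trace: Trace,
    derivative_threshold: float,
    refractory: float,
    peak_window: float,
    smooth_cutoff: float | None,
) -> list[tuple[int, int]]:
    """(crossing_index, peak_index) pairs from an upward derivative threshold."""
    v = _smoothed(trace, smooth_cutoff)
    dv = _derivative_mv_per_ms(v, trace.sampling_rate)
    above = dv >= derivative_threshold
    rising = np.flatnonzero(~above[:-1] & above[1:]) + 1
    n_refrac = max(1, int(round(refractory * trace.sampling_rate)))
    n_peak = max(1, int(round(peak_window * trace.sampling_rate)))
    out = []
    last = -n_refrac
    for idx in rising:
        if idx - last < n_refrac:
            continue
        last = idx
        stop = min(idx + n_peak, v.size)
        i_peak = idx + int(np.argmax(v[idx:stop]))
        out.append((int(idx), int(i_peak)))
    return out


def detect_aps_ca(
    trace: Trace,
    derivative_threshold: float = 1.0,
    refractory: float = 2e-3,
    peak_window: float = 10e-3,
    smooth_cutoff: float | None = CA_AP_SMOOTH_CUTOFF,
) -> list[EventRecord]:
    """Detect (attenuated, slowed) action potentials in a CA trace from the
    first derivative at 1 mV/ms, grouping crossings within a 2 ms refractory
    window.  The default smoothing is heavier than for WC detection because
    CA excess noise would otherwise dominate the derivative.

    Onsets are taken at the detection crossing itself: the WC 10 mV/ms onset
    rule cannot fire on CA spikes whose peak slope is only a few mV/ms.
    """
    if trace.channel_role != "CA":
        raise ValueError("detect_aps_ca expects a CA trace")
    pairs = _derivative_events(trace, derivative_threshold, refractory, peak_window, smooth_cutoff)
    events = []
    for i_on, i_peak in pairs:
        rec = measure_event(
            trace,
            trace.t0 + i_on / trace.sampling_rate,
            trace.t0 + i_peak / trace.sampling_rate,
            kind="AP",
            smooth_cutoff=None,  # raw samples: CA spikes are still fast events
        )
        events.append(rec)
    return events


def detect_spsps(
    trace: Trace,
    derivative_threshold: float = 1.0,
    onset_threshold: float = 0.1,
    refractory: float = 50e-3,
    peak_window: float = 50e-3,
    ap_blank: float = 10e-3,
    smooth_cutoff: float | None = DEFAULT_SMOOTH_CUTOFF,
    measure_cutoff: float | None = PSP_MEASURE_CUTOFF,
    resting: float | None = None,
) -> list[EventRecord]:
    """Detect spontaneous PSPs in a WC trace.

    Action-potential episodes are excluded first (blanking +/- 10 ms around
    detected APs); remaining upward 1 mV/ms derivative crossings start PSP
    candidates, the peak is the local maximum within 50 ms, and the onset
    comes from the 0.1 mV/ms backward-scan rule.  Onset and amplitude are
    read from a more heavily smoothed copy (``measure_cutoff``): the
    0.1 mV/ms onset threshold sits at the derivative noise floor of the
    detection-bandwidth signal, while PSPs are slow enough that 100 Hz
    passes them essentially undistorted.
    """
    if trace.channel_role != "WC":
        raise ValueError("detect_spsps expects a WC trace")
    aps = detect_aps_wc(trace, resting=resting, smooth_cutoff=smooth_cutoff)
    ap_times = np.array([a.peak_time for a in aps])
    pairs = _derivative_events(trace, derivative_threshold, refractory, peak_window, smooth_cutoff)
    events = []
    for i_on, i_peak in pairs:
        t_peak = trace.t0 + i_peak / trace.sampling_rate
        if ap_times.size and np.min(np.abs(ap_times - t_peak)) <= ap_blank:
            continue
        onset, flag = event_onset(trace, t_peak, onset_threshold, smooth_cutoff=measure_cutoff)
        rec = measure_event(trace, onset, t_peak, kind="PSP", smooth_cutoff=measure_cutoff)
        if flag:
            rec = EventRecord(**{**rec.__dict__, "flagged": True})
        events.append(rec)
    return events


# ---------------------------------------------------------------------------
# derived measures


def evoked_amplitude(
    avg_trace: Trace,
    stim_time: float,
    response_window: float = 0.2,
    baseline_window: float = 0.2,
) -> float:
    """Signed evoked-response amplitude from an averaged trace.

    The largest |deflection| within 200 ms after the stimulus minus the
    median voltage over the 200 ms before it.
    """
    rate = avg_trace.sampling_rate
    i_stim = avg_trace.index_at(stim_time)
    i0 = i_stim - int(round(baseline_window * rate))
    i1 = i_stim + int(round(response_window * rate))
    if i0 < 0 or i1 > avg_trace.n_samples:
        raise ValueError("stimulus windows fall outside the trace")
    baseline = float(np.median(avg_trace.samples[i0:i_stim]))
    seg = avg_trace.samples[i_stim + 1:i1 + 1] - baseline
    if seg.size == 0:
        raise ValueError("empty response window")
    return float(seg[np.argmax(np.abs(seg))])


def dominant_frequency(half_width_ms: float) -> float:
    """Dominant frequency (Hz) of an event whose half-width (ms) is one third
    of the matched oscillation period: f = 1 / (3 x half_width)."""
    if half_width_ms <= 0:
        raise ValueError("half-width must be > 0")
    return 1.0 / (3.0 * half_width_ms * 1e-3)


def amplitude_noise_ratio(events: list[EventRecord], noise_sd: float) -> float:
    """Mean |event amplitude| divided by the baseline noise SD."""
    if not events:
        raise ValueError("no events to summarise")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be > 0")
    return float(np.mean([abs(e.amplitude) for e in events]) / noise_sd)


def pair_and_transfer(
    wc_events: list[EventRecord],
    ca_trace: Trace,
    max_lag: float = 5e-3,
    smooth_cutoff: float | None = PSP_MEASURE_CUTOFF,
) -> tuple[list[PairedEvents], dict]:
    """Measure CA transfer for WC-detected events.

    Each WC event keeps its own onset; the CA peak is searched between that
    onset and the WC peak time + ``max_lag`` (CA peaks lag the WC ones), and
    the CA event is measured with the WC-derived onset.  The summary reports
    the per-event amplitude-ratio median and IQR, a through-origin regression
    slope, and the Pearson correlation of the paired amplitudes.
    """
    pairs: list[PairedEvents] = []
    v_slow = _smoothed(ca_trace, smooth_cutoff)
    rate = ca_trace.sampling_rate
    for ev in wc_events:
        v = ca_trace.samples if ev.kind == "AP" else v_slow
        i_lo = ca_trace.index_at(ev.peak_time - 1e-3)
        i_hi = ca_trace.index_at(ev.peak_time + max_lag)
        if i_hi <= i_lo:
            continue
        sign = 1.0 if ev.amplitude >= 0 else -1.0
        seg = sign * v[i_lo:i_hi + 1]
        i_peak = i_lo + int(np.argmax(seg))
        ca_rec = measure_event(
            ca_trace, ev.onset, ca_trace.t0 + i_peak / rate,
            kind=ev.kind,
            smooth_cutoff=None if ev.kind == "AP" else smooth_cutoff,
        )
        lag_ms = (ca_rec.peak_time - ev.peak_time) * 1e3
        pairs.append(PairedEvents(wc_event=ev, ca_measurement=ca_rec, lag=lag_ms))
    summary: dict = {"n": len(pairs)}
    if pairs:
        wc_amp = np.array([p.wc_event.amplitude for p in pairs])
        ca_amp = np.array([p.ca_measurement.amplitude for p in pairs])
        ratios = ca_amp / wc_amp
        q25, q50, q75 = np.percentile(ratios, [25, 50, 75])
        if len(pairs) > 1 and np.ptp(wc_amp) > 0 and np.ptp(ca_amp) > 0:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", stats.NearConstantInputWarning)
                r = float(stats.pearsonr(wc_amp, ca_amp)[0])
        else:
            r = float("nan")
        summary.update({
            "ratio_median": float(q50),
            "ratio_iqr": (float(q25), float(q75)),
            "slope_through_origin": float(np.sum(wc_amp * ca_amp) / np.sum(wc_amp**2)),
            "pearson_r": r,
        })
    return pairs, summary
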