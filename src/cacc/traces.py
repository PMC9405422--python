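"""Core data model for voltage recordings.

Internal unit convention (fixed across the package): voltages in mV, time in
seconds, frequencies in Hz, currents in pA, resistances in GOhm, capacitances
in pF.  Note GOhm x pF gives milliseconds; every derived time constant is
converted to seconds explicitly at the point of computation.

Time is stored as ``sampling_rate`` + ``t0``; acquisition is uniform, so no
per-sample timestamps are kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

ChannelRole = Literal["WC", "CA", "LFP"]

_VALID_ROLES = ("WC", "CA", "LFP")


@dataclass(frozen=True)
class Trace:
    """A uniformly sampled voltage series.

    Parameters
    ----------
    samples : array of float
        Voltage samples.  mV for intracellular channels; LFP traces declare
        their own units via ``units`` (never assumed).
    sampling_rate : float
        Samples per second (Hz), > 0.
    channel_role : {"WC", "CA", "LFP"}
        Recording configuration the trace came from.  Fixed after creation
        (the dataclass is frozen).
    t0 : float
        Time of the first sample, seconds.
    ljp_applied : float
        Liquid-junction-potential correction already applied, mV (0 if none).
    units : str
        Unit label of ``samples`` ("mV" default; LFP may be "uV").
    label : str
        Free-text description.
    """

    samples: np.ndarray
    sampling_rate: float
    channel_role: ChannelRole
    t0: float = 0.0
    ljp_applied: float = 0.0
    units: str = "mV"
    label: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples must be finite")
        if not (self.sampling_rate > 0):
            raise ValueError("sampling_rate must be > 0")
        if self.channel_role not in _VALID_ROLES:
            raise ValueError(f"channel_role must be one of {_VALID_ROLES}")

    # -- convenience ------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def dt(self) -> float:
        """Sample interval in seconds."""
        return 1.0 / self.sampling_rate

    @property
    def duration(self) -> float:
        """Trace duration in seconds (n / rate)."""
        return self.n_samples / self.sampling_rate

    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t0 + np.arange(self.n_samples) / self.sampling_rate

    def index_at(self, t: float) -> int:
        """Nearest sample index for time ``t`` (seconds), clipped to bounds."""
        i = int(round((t - self.t0) * self.sampling_rate))
        return min(max(i, 0), self.n_samples - 1)

    def with_samples(self, samples: np.ndarray, **changes) -> "Trace":
        """Copy of this trace with new samples (and optional field changes)."""
        return replace(self, samples=np.asarray(samples, dtype=np.float64), **changes)


@dataclass(frozen=True)
class StimulusProtocol:
    """Timing/shape of an applied stimulus.

    ``amplitude`` is pA for injected current (step/sinusoid); for
    ``high_K`` it is the target drive shift in mV; for extracellular pulses
    it is a dimensionless marker.
    """

    kind: Literal["none", "step", "sinusoid", "extracellular_pulse", "high_K"]
    onset: float = 0.0
    offset: float = 0.0
    amplitude: float = 0.0
    frequency: float | None = None
    pulse_times: tuple = ()

    def __post_init__(self) -> None:
        if self.kind not in ("none", "step", "sinusoid", "extracellular_pulse", "high_K"):
            raise ValueError(f"unknown stimulus kind {self.kind!r}")
        if self.kind != "none" and not self.kind == "extracellular_pulse":
            if not (self.offset > self.onset):
                raise ValueError("offset must be > onset")
        if self.kind == "sinusoid":
            if self.frequency is None or not (self.frequency > 0):
                raise ValueError("sinusoid requires frequency > 0")
        object.__setattr__(self, "pulse_times", tuple(float(t) for t in self.pulse_times))


@dataclass(frozen=True)
class SolutionComposition:
    """Ionic composition of a solution, concentrations in mM, temperature in C."""

    concentrations: dict = field(default_factory=dict)
    temperature: float = 30.0

    def __post_init__(self) -> None:
        for ion, conc in self.concentrations.items():
            if conc < 0:
                raise ValueError(f"negative concentration for {ion}")
        if not (0.0 <= self.temperature <= 40.0):
            raise ValueError("temperature outside 0-40 C")

    def __getitem__(self, ion: str) -> float:
        return self.concentrations[ion]


@dataclass
class SessionBundle:
    """A named collection of simultaneously recorded traces.

    ``ground_truth`` is present iff the bundle is synthetic: a dict of 1-D
    float arrays (event times, amplitudes, window edges) plus optional scalar
    entries.  All traces share the same ``t0`` reference.
    """

    traces: dict
    protocols: list = field(default_factory=list)
    ground_truth: dict | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t0s = {tr.t0 for tr in self.traces.values()}
        if len(t0s) > 1:
            raise ValueError("all traces in a bundle must share t0")

    def trace_by_role(self, role: ChannelRole) -> Trace:
        """First trace with the given channel role; KeyError if absent."""
        for tr in self.traces.values():
            if tr.channel_role == role:
                return tr
        raise KeyError(f"bundle has no {role} trace")

    @property
    def is_synthetic(self) -> bool:
        return self.ground_truth is not None
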