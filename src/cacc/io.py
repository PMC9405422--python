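"""Readers and writers: two-column CSV traces and HDF5 session bundles.

CSV layout: header ``time_s,voltage_mV``, decimal point, comma separator
(or a single voltage column with the sampling rate declared by the caller).

HDF5 layout::

    /traces/<name>      1-D float64 dataset
        attrs: sampling_rate_hz, channel_role, units, ljp_applied_mv, t0_s, label
    /protocols          JSON-serialised attribute on the root group
    /ground_truth/<name>  1-D/2-D float datasets; scalar entries become attrs
"""

from __future__ import annotations

import dataclasses
import json

import h5py
import numpy as np
import pandas as pd

from .traces import SessionBundle, StimulusProtocol, Trace


class TraceFormatError(ValueError):
    """Raised for malformed trace/bundle files."""


# ---------------------------------------------------------------------------
# CSV


def read_trace_csv(
    path,
    channel_role: str = "WC",
    sampling_rate: float | None = None,
    units: str = "mV",
    label: str = "",
    rel_tol: float = 1e-6,
) -> Trace:
    """Read a trace from CSV.

    Two numeric columns are interpreted as (time s, voltage mV); the sampling
    rate is inferred from the time column, which must be uniform to within
    ``rel_tol`` relative tolerance.  A single column requires a declared
    ``sampling_rate``.
    """
    try:
        df = pd.read_csv(path)
        values = df.to_numpy(dtype=float)
    except (ValueError, TypeError) as exc:
        raise TraceFormatError(f"non-numeric data in {path}: {exc}") from exc
    if values.ndim != 2 or values.shape[1] not in (1, 2):
        raise TraceFormatError("expected one or two columns")
    if values.shape[1] == 1:
        if sampling_rate is None:
            raise TraceFormatError("single-column file requires a declared sampling_rate")
        return Trace(values[:, 0], sampling_rate, channel_role, units=units, label=label)
    t, v = values[:, 0], values[:, 1]
    if t.size < 2:
        raise TraceFormatError("need at least 2 samples to infer the sampling rate")
    steps = np.diff(t)
    dt = np.median(steps)
    if dt <= 0 or np.any(np.abs(steps - dt) > rel_tol * dt):
        raise TraceFormatError("non-uniform time steps")
    return Trace(v, 1.0 / dt, channel_role, t0=float(t[0]), units=units, label=label)


def write_trace_csv(trace: Trace, path) -> None:
    """Write a trace as ``time_s,voltage_mV`` CSV."""
    df = pd.DataFrame({"time_s": trace.times(), "voltage_mV": trace.samples})
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# HDF5 bundles


def write_bundle_hdf5(bundle: SessionBundle, path) -> None:
    """Write a session bundle to HDF5 (lossless for samples and metadata)."""
    with h5py.File(path, "w") as f:
        grp = f.create_group("traces")
        for name, tr in bundle.traces.items():
            ds = grp.create_dataset(name, data=tr.samples, dtype="float64")
            ds.attrs["sampling_rate_hz"] = tr.sampling_rate
            ds.attrs["channel_role"] = tr.channel_role
            ds.attrs["units"] = tr.units
            ds.attrs["ljp_applied_mv"] = tr.ljp_applied
            ds.attrs["t0_s"] = tr.t0
            ds.attrs["label"] = tr.label
        f.attrs["protocols"] = json.dumps(
            [dataclasses.asdict(p) for p in bundle.protocols]
        )
        f.attrs["provenance"] = json.dumps(bundle.provenance, default=str)
        if bundle.ground_truth is not None:
            gt = f.create_group("ground_truth")
            for key, val in bundle.ground_truth.items():
                arr = np.asarray(val)
                if arr.ndim == 0:
                    gt.attrs[key] = float(arr)
                else:
                    gt.create_dataset(key, data=arr.astype(np.float64))


def read_bundle_hdf5(path) -> SessionBundle:
    """Read a session bundle written by :func:`write_bundle_hdf5`."""
    with h5py.File(path, "r") as f:
        if "traces" not in f:
            raise TraceFormatError("bundle lacks a /traces group")
        traces = {}
        for name, ds in f["traces"].items():
            attrs = ds.attrs
            if "sampling_rate_hz" not in attrs:
                raise TraceFormatError(f"trace {name!r} lacks sampling_rate_hz")
            traces[name] = Trace(
                samples=ds[...],
                sampling_rate=float(attrs["sampling_rate_hz"]),
                channel_role=str(attrs.get("channel_role", "WC")),
                t0=float(attrs.get("t0_s", 0.0)),
                ljp_applied=float(attrs.get("ljp_applied_mv", 0.0)),
                units=str(attrs.get("units", "mV")),
                label=str(attrs.get("label", "")),
            )
        protocols = [
            StimulusProtocol(**p) for p in json.loads(f.attrs.get("protocols", "[]"))
        ]
        provenance = json.loads(f.attrs.get("provenance", "{}"))
        ground_truth = None
        if "ground_truth" in f:
            ground_truth = {k: v[...] for k, v in f["ground_truth"].items()}
            ground_truth.update({k: float(v) for k, v in f["ground_truth"].attrs.items()})
    return SessionBundle(
        traces=traces, protocols=protocols,
        ground_truth=ground_truth, provenance=provenance,
    )
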