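"""Plain-text trace and table I/O.

Traces are written as tab-delimited text: one time column followed by one
column per sweep, with a header row carrying the step voltages (vclamp) or
a label (current clamp), plus a JSON sidecar (`<file>.meta.json`) holding
the structured metadata needed to regenerate the file.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .vclamp import CurrentTraceSet

__all__ = ["write_traces", "read_traces", "write_voltage_trace", "sidecar_path"]


def sidecar_path(path) -> Path:
    return Path(str(path) + ".meta.json")


def write_traces(traces: CurrentTraceSet, path) -> Path:
    """Write a voltage-clamp trace set; returns the data-file path."""
    path = Path(path)
    cols = {"time_ms": traces.time_ms}
    for i, v in enumerate(traces.step_levels_mV):
        cols[f"{v:g}mV"] = traces.currents_uA[i]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format="%.9g")
    meta = dict(
        traces.meta,
        step_levels_mV=list(map(float, traces.step_levels_mV)),
        step_onset_ms=traces.step_onset_ms,
        step_offset_ms=traces.step_offset_ms,
        units={"time": "ms", "current": "uA"},
    )
    sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_traces(path) -> CurrentTraceSet:
    """Round-trip reader for :func:`write_traces`."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    meta = json.loads(sidecar_path(path).read_text())
    levels = np.array(meta["step_levels_mV"], dtype=float)
    currents = df.iloc[:, 1:].to_numpy().T
    return CurrentTraceSet(
        time_ms=df["time_ms"].to_numpy(),
        step_levels_mV=levels,
        currents_uA=currents,
        step_onset_ms=meta["step_onset_ms"],
        step_offset_ms=meta["step_offset_ms"],
        meta={k: v for k, v in meta.items()
              if k not in ("step_levels_mV", "step_onset_ms", "step_offset_ms", "units")},
    )


def write_voltage_trace(trace, path, meta_extra: dict | None = None) -> Path:
    """Write a current-clamp VoltageTrace (time, Vm, stimulus current)."""
    path = Path(path)
    pd.DataFrame(
        {"time_ms": trace.time_ms, "v_mV": trace.v_mV, "i_stim_pA": trace.i_stim_pA}
    ).to_csv(path, sep="\t", index=False, float_format="%.9g")
    meta = {
        "dt_ms": trace.dt_ms,
        "rest_mV": trace.rest_mV,
        "settle_ms": trace.settle_ms,
        "stimulus": repr(trace.stimulus),
        "units": {"time": "ms", "voltage": "mV", "current": "pA"},
    }
    if meta_extra:
        meta.update(meta_extra)
    sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path
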