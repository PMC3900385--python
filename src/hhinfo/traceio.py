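"""HDF5 persistence for stimuli and simulation results, CSV export for
small fixtures."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np

from .simulate import SimulationResult, VoltageTrace
from .stimulus import CurrentTrace, StimulusConfig


def save_stimuli(path, traces: Sequence[CurrentTrace]) -> None:
    with h5py.File(path, "w") as f:
        grp = f.create_group("stimulus")
        for k, tr in enumerate(traces):
            d = grp.create_dataset(f"trial_{k}", data=tr.values)
            d.attrs["dt"] = tr.dt
            d.attrs["units"] = "uA/cm^2"
            if tr.metadata is not None:
                d.attrs["config"] = json.dumps(asdict(tr.metadata))


def load_stimuli(path) -> list[CurrentTrace]:
    out = []
    with h5py.File(path, "r") as f:
        grp = f["stimulus"]
        for k in range(len(grp)):
            d = grp[f"trial_{k}"]
            meta = None
            if "config" in d.attrs:
                meta = StimulusConfig(**json.loads(d.attrs["config"]))
            out.append(CurrentTrace(d[...], float(d.attrs["dt"]), meta))
    return out


def save_result(path, result: SimulationResult) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("voltage", data=result.voltage.values)
        f.create_dataset("open_fractions/Na", data=result.open_fraction_na)
        f.create_dataset("open_fractions/K", data=result.open_fraction_k)
        f.create_dataset("currents/K_total", data=result.current_k())
        f.create_dataset("currents/Na", data=result.current_na())
        f.attrs["dt"] = result.dt
        f.attrs["seed"] = result.seed
        f.attrs["na_mode"] = result.config.na_mode
        f.attrs["k_mode"] = result.config.k_mode
        f.attrs["params"] = json.dumps(asdict(result.config.params))


def load_voltage(path) -> VoltageTrace:
    with h5py.File(path, "r") as f:
        return VoltageTrace(f["voltage"][...], float(f.attrs["dt"]))


def export_csv(path, trace) -> None:
    values = trace.values if hasattr(trace, "values") else np.asarray(trace)
    np.savetxt(path, np.column_stack([np.arange(values.size) * trace.dt, values]),
               delimiter=",", header="time_s,value", comments="")
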