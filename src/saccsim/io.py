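"""Writers and readers for simulation outputs.

Plain-text formats throughout: spike tables and response traces as TSV,
sweep results as tidy TSV (parameter, replicate, value), matrices as
TSV with the grids in the header row/column, run summaries as JSON.
An optional HDF5 container for full traces is available when h5py is
installed.
"""

from __future__ import annotations

import hashlib
import json
import pathlib

import numpy as np
import pandas as pd

from .analysis import ResponseTrace, SweepResult
from .simulator import SimulationResult, SpikeTable

__all__ = [
    "write_spikes",
    "read_spikes",
    "write_trace",
    "read_trace",
    "write_sweep",
    "read_sweep",
    "write_matrix",
    "read_matrix",
    "write_summary",
    "write_result_h5",
    "config_hash",
]


def write_spikes(spikes: SpikeTable, path) -> None:
    spikes.to_frame().to_csv(path, sep="\t", index=False)


def read_spikes(path) -> SpikeTable:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    lgn = df[df.layer == "lgn"]
    v1 = df[df.layer == "v1"]
    return SpikeTable(
        lgn.neuron_index.to_numpy(dtype=np.int64),
        lgn.time_ms.to_numpy(dtype=float),
        v1.neuron_index.to_numpy(dtype=np.int64),
        v1.time_ms.to_numpy(dtype=float),
    )


def write_trace(trace: ResponseTrace, path) -> None:
    df = pd.DataFrame({"time_ms": trace.times, "n_sp": trace.counts})
    with open(path, "w") as fh:
        fh.write(f"# t_bin={trace.t_bin} step={trace.step}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_trace(path) -> ResponseTrace:
    with open(path) as fh:
        header = fh.readline().strip().lstrip("# ")
        meta = dict(kv.split("=") for kv in header.split())
        df = pd.read_csv(fh, sep="\t", float_precision="round_trip")
    return ResponseTrace(
        df.time_ms.to_numpy(dtype=float),
        df.n_sp.to_numpy(),
        float(meta["t_bin"]),
        float(meta["step"]),
    )


def write_sweep(sweep: SweepResult, path) -> None:
    rows = []
    for name, mat in sweep.samples.items():
        for a, v in enumerate(sweep.values):
            for b in range(mat.shape[1]):
                rows.append((sweep.parameter, v, name, b, mat[a, b]))
    pd.DataFrame(
        rows, columns=["parameter", "value", "measure", "replicate", "sample"]
    ).to_csv(path, sep="\t", index=False)


def read_sweep(path) -> SweepResult:
    df = pd.read_csv(path, sep="\t")
    parameter = df.parameter.iloc[0]
    values = np.sort(df.value.unique())
    samples = {}
    for name, grp in df.groupby("measure"):
        piv = grp.pivot_table(index="value", columns="replicate", values="sample")
        samples[name] = piv.loc[values].to_numpy()
    return SweepResult(parameter, values, samples)


def write_matrix(matrix: np.ndarray, row_grid, col_grid, path) -> None:
    df = pd.DataFrame(matrix, index=np.asarray(row_grid), columns=np.asarray(col_grid))
    df.to_csv(path, sep="\t")


def read_matrix(path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(), df.index.to_numpy(dtype=float), df.columns.to_numpy(dtype=float)


def config_hash(params_dict: dict) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(params_dict, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_summary(result: SimulationResult, path) -> None:
    summary = {
        "seed": result.seed,
        "params_hash": config_hash(result.params.to_dict()),
        "params": result.params.to_dict(),
        "protocol": result.protocol.to_dict(),
        "n_lgn_spikes": result.spikes.count("lgn"),
        "n_v1_spikes": result.spikes.count("v1"),
    }
    pathlib.Path(path).write_text(json.dumps(summary, indent=1))


def write_result_h5(result: SimulationResult, path) -> None:
    """Full-trace container; requires the optional h5py dependency."""
    import h5py

    with h5py.File(path, "w") as fh:
        fh.attrs["seed"] = result.seed
        fh.attrs["params"] = result.params.to_json()
        g = fh.create_group("spikes")
        g.create_dataset("lgn_neurons", data=result.spikes.lgn_neurons)
        g.create_dataset("lgn_times", data=result.spikes.lgn_times)
        g.create_dataset("v1_neurons", data=result.spikes.v1_neurons)
        g.create_dataset("v1_times", data=result.spikes.v1_times)
        if result.synapse_trace is not None:
            fh.create_dataset("synapse_times", data=result.synapse_sample_times)
            fh.create_dataset("synapse_trace", data=result.synapse_trace)
        if result.membrane_trace is not None:
            fh.create_dataset("membrane_times", data=result.membrane_sample_times)
            fh.create_dataset("membrane_trace", data=result.membrane_trace)
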