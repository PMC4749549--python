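"""File formats: event tables and registration tables as CSV, traces and
footprints as HDF5 groups, ground truth as a JSON sidecar."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .synthetic import (EVENT_COLUMNS, FootprintRecord, FootprintSet, TraceSet)

REGISTRATION_COLUMNS = ["master_id", "env", "day", "local_id", "score",
                        "method", "true_cell_id"]


def write_events(events: pd.DataFrame, path) -> None:
    events[EVENT_COLUMNS].to_csv(path, index=False)


def read_events(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"event table missing columns: {missing}")
    return df


def write_registration(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_registration(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in REGISTRATION_COLUMNS[:6] if c not in df.columns]
    if missing:
        raise ValueError(f"registration table missing columns: {missing}")
    return df


def write_traces(traces: TraceSet, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["frame_rate"] = traces.frame_rate
        f.attrs["trial_frames"] = traces.trial_frames
        f.attrs["n_trials"] = traces.n_trials
        for (env, day), arr in traces.traces.items():
            f.create_dataset(f"/traces/{env}/{day}", data=arr,
                             compression="gzip")


def read_traces(path) -> TraceSet:
    traces = {}
    with h5py.File(path, "r") as f:
        fr = float(f.attrs["frame_rate"])
        tf = int(f.attrs["trial_frames"])
        nt = int(f.attrs["n_trials"])
        for env in f["/traces"]:
            for day in f[f"/traces/{env}"]:
                traces[(env, int(day))] = f[f"/traces/{env}/{day}"][...]
    return TraceSet(traces, fr, tf, nt)


def write_footprints(fps: FootprintSet, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["um_per_px"] = fps.um_per_px
        f.attrs["fov_px"] = fps.fov_px
        f.create_dataset("/true_centroids_um", data=fps.true_centroids_um)
        for (env, day), recs in fps.sessions.items():
            g = f.create_group(f"/footprints/{env}/{day}")
            for i, rec in enumerate(recs):
                d = g.create_dataset(str(i), data=rec.patch, compression="gzip")
                d.attrs["cell_id"] = rec.cell_id
                d.attrs["offset"] = rec.offset
                d.attrs["centroid_um"] = rec.centroid_um


def read_footprints(path) -> FootprintSet:
    sessions = {}
    with h5py.File(path, "r") as f:
        upp = float(f.attrs["um_per_px"])
        fov = int(f.attrs["fov_px"])
        true_c = f["/true_centroids_um"][...]
        for env in f["/footprints"]:
            for day in f[f"/footprints/{env}"]:
                g = f[f"/footprints/{env}/{day}"]
                recs = []
                for k in sorted(g, key=int):
                    d = g[k]
                    recs.append(FootprintRecord(
                        int(d.attrs["cell_id"]), d[...],
                        tuple(int(v) for v in d.attrs["offset"]),
                        np.asarray(d.attrs["centroid_um"])))
                sessions[(env, int(day))] = recs
    return FootprintSet(sessions, upp, fov, true_c)


def write_ground_truth(gt: dict, path) -> None:
    Path(path).write_text(json.dumps(gt, indent=1))


def read_ground_truth(path) -> dict:
    return json.loads(Path(path).read_text())
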