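"""Plain-text file formats for spike data and derived series.

Spike tables are two-column tab-delimited files (``neuron_id\\tspike_time_s``,
times printed with 6 decimals, so round-trips are lossless at 1 us) with a
JSON sidecar holding the recording metadata.  Rate matrices round-trip to a
gzipped TSV (first column ``time_s``, one column per neuron) plus a JSON
sidecar; embeddings serialise to a directory of TSVs with a JSON manifest.
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .embed import Embedding
from .errors import ValidationError
from .spikes import RateMatrix, SpikeData


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_spike_table(spikes: SpikeData, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("neuron_id\tspike_time_s\n")
        for nid, train in zip(spikes.neuron_ids, spikes.spikes):
            for t in train:
                fh.write(f"{nid}\t{t:.6f}\n")
    meta = {
        "duration_s": spikes.duration,
        "stim_on_s": spikes.stim_on,
        "stim_off_s": spikes.stim_off,
        "n_neurons": spikes.n_neurons,
        "neuron_ids": list(spikes.neuron_ids),
    }
    if spikes.coords is not None:
        meta["coords"] = np.asarray(spikes.coords).tolist()
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_spike_table(path: str | Path) -> SpikeData:
    """Read a spike table and its JSON sidecar, validating as we go.

    Unsorted or negative times, or times beyond the recorded duration, raise
    a :class:`ValidationError` naming the offending line numbers.  Neurons
    present in the metadata but absent from the table are retained as silent.
    """
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    duration = float(meta["duration_s"])
    ids = list(meta.get("neuron_ids") or [])
    trains: dict[str, list[float]] = {nid: [] for nid in ids}
    bad_lines: list[int] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("neuron_id"):
            raise ValidationError(f"{path}: missing header line")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            nid, t_str = line.rstrip("\n").split("\t")
            t = float(t_str)
            if t < 0 or t > duration:
                bad_lines.append(lineno)
                continue
            trains.setdefault(nid, []).append(t)
    if bad_lines:
        raise ValidationError(f"{path}: spike times outside [0, {duration}] on lines {bad_lines[:20]}")
    if not ids:
        ids = sorted(trains)
    arrays = []
    for nid in ids:
        arr = np.asarray(trains.get(nid, []), dtype=float)
        if np.any(np.diff(arr) < 0):
            raise ValidationError(f"{path}: spike times of neuron {nid} are not sorted")
        arrays.append(arr)
    coords = meta.get("coords")
    return SpikeData(
        spikes=arrays,
        duration=duration,
        stim_on=float(meta["stim_on_s"]),
        stim_off=float(meta["stim_off_s"]),
        neuron_ids=ids,
        coords=None if coords is None else np.asarray(coords, dtype=float),
    )


def write_rate_matrix(rates: RateMatrix, path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame(rates.F, columns=rates.neuron_ids)
    df.insert(0, "time_s", rates.t)
    with gzip.open(path, "wt") as fh:
        df.to_csv(fh, sep="\t", index=False, float_format="%.8g")
    meta = {
        "sigma": rates.sigma,
        "dt": rates.dt,
        "window_range": list(rates.window_range),
        "stim_on": rates.stim_on,
        "stim_off": rates.stim_off,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_rate_matrix(path: str | Path) -> RateMatrix:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    with gzip.open(path, "rt") as fh:
        df = pd.read_csv(fh, sep="\t")
    t = df["time_s"].to_numpy()
    F = df.drop(columns="time_s").to_numpy()
    return RateMatrix(
        t=t, F=F, sigma=float(meta["sigma"]), dt=float(meta["dt"]),
        window_range=tuple(meta["window_range"]),
        neuron_ids=[c for c in df.columns if c != "time_s"],
        stim_on=meta.get("stim_on"), stim_off=meta.get("stim_off"),
    )


def write_embedding(embedding: Embedding, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    np.savetxt(out / "axes.tsv", embedding.axes, delimiter="\t")
    np.savetxt(out / "eigenvalues.tsv", embedding.eigvals, delimiter="\t")
    traj = np.column_stack([embedding.t, embedding.P])
    np.savetxt(out / "trajectory.tsv", traj, delimiter="\t",
               header="time_s\t" + "\t".join(f"p{i + 1}" for i in range(embedding.d)),
               comments="")
    manifest = {
        "d": embedding.d,
        "var_explained": embedding.var_explained.tolist(),
        "mean": embedding.mean.tolist(),
        "fit_range": list(embedding.fit_range),
        "neuron_ids": embedding.neuron_ids,
        "source": embedding.source,
        "dt": embedding.dt,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))


def read_embedding(out_dir: str | Path) -> Embedding:
    out = Path(out_dir)
    manifest = json.loads((out / "manifest.json").read_text())
    axes = np.loadtxt(out / "axes.tsv", delimiter="\t", ndmin=2)
    eigvals = np.loadtxt(out / "eigenvalues.tsv", delimiter="\t", ndmin=1)
    traj = np.loadtxt(out / "trajectory.tsv", delimiter="\t", skiprows=1, ndmin=2)
    return Embedding(
        axes=axes, eigvals=eigvals,
        var_explained=np.asarray(manifest["var_explained"]),
        d=int(manifest["d"]), P=traj[:, 1:], t=traj[:, 0],
        mean=np.asarray(manifest["mean"]),
        fit_range=tuple(manifest["fit_range"]),
        neuron_ids=list(manifest["neuron_ids"]),
        source=manifest.get("source", ""), dt=float(manifest.get("dt", 0.01)),
    )
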