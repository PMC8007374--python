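"""Plain-text I/O: the TSV epoch layout, matrices, networks, configs.

Epoch layout (one file per subject/session): tab-separated with columns
``trial`` (1-based), ``sample_index`` (0-based within the trial), then one
column per channel label, values in microvolts.  A ``# sampling_rate=`` and
``# epoch_start=`` comment header carries the metadata needed to rebuild an
:class:`EpochSet`.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .containers import BinaryNetwork, CoherenceMatrix, DifferentialNetwork, EpochSet

PathLike = Union[str, Path]


def write_epochs_tsv(epochs: EpochSet, path: PathLike) -> None:
    path = Path(path)
    n_ch, n_samp, n_tr = epochs.data.shape
    trial = np.repeat(np.arange(1, n_tr + 1), n_samp)
    sample = np.tile(np.arange(n_samp), n_tr)
    cols = {"trial": trial, "sample_index": sample}
    flat = epochs.data.transpose(2, 1, 0).reshape(n_tr * n_samp, n_ch)
    for i, label in enumerate(epochs.channel_labels):
        cols[label] = flat[:, i]
    with open(path, "w") as fh:
        fh.write(f"# sampling_rate={epochs.sampling_rate}\n")
        fh.write(f"# epoch_start={epochs.epoch_window[0]}\n")
        pd.DataFrame(cols).to_csv(fh, sep="\t", index=False, float_format="%.6f")


def read_epochs_tsv(path: PathLike) -> EpochSet:
    path = Path(path)
    meta = {}
    with open(path) as fh:
        while True:
            pos = fh.tell()
            line = fh.readline()
            if not line.startswith("#"):
                fh.seek(pos)
                break
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = float(val)
        df = pd.read_csv(fh, sep="\t")
    if "sampling_rate" not in meta:
        raise ValueError(f"{path}: missing '# sampling_rate=' header")
    fs = meta["sampling_rate"]
    start = meta.get("epoch_start", 0.0)
    labels = [c for c in df.columns if c not in ("trial", "sample_index")]
    trials = sorted(df["trial"].unique())
    n_samp = int(df["sample_index"].max()) + 1
    data = np.empty((len(labels), n_samp, len(trials)))
    for k, tr in enumerate(trials):
        block = df[df["trial"] == tr].sort_values("sample_index")
        if len(block) != n_samp:
            raise ValueError(f"{path}: trial {tr} has {len(block)} samples, "
                             f"expected {n_samp}")
        data[:, :, k] = block[labels].to_numpy().T
    return EpochSet(
        data=data, channel_labels=labels, sampling_rate=fs,
        epoch_window=(start, start + n_samp / fs),
    )


def epoch_filename(subject: int, session: int) -> str:
    return f"epochs_sub{subject:02d}_ses{session}.tsv"


def write_matrix_tsv(matrix: CoherenceMatrix, path: PathLike) -> None:
    df = pd.DataFrame(matrix.values, index=list(matrix.node_labels),
                      columns=list(matrix.node_labels))
    df.to_csv(path, sep="\t", float_format="%.6f")


def read_matrix_tsv(path: PathLike, band) -> CoherenceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CoherenceMatrix(
        values=df.to_numpy(float), band=band, node_labels=list(df.columns),
        n_trials_used=0, welch_params=(float("nan"), float("nan"), "unknown"),
    )


def network_to_graphml(net, path: PathLike) -> None:
    """Export a BinaryNetwork or DifferentialNetwork as GraphML."""
    adj = net.adjacency if hasattr(net, "adjacency") else net.significant
    g = nx.from_numpy_array(np.asarray(adj))
    nx.relabel_nodes(g, dict(enumerate(net.node_labels)), copy=False)
    nx.write_graphml(g, path)


def write_edge_list(net, path: PathLike) -> None:
    adj = np.asarray(net.adjacency if hasattr(net, "adjacency") else net.significant)
    labels = list(net.node_labels)
    iu = np.triu_indices(len(labels), k=1)
    rows = [
        {"node_a": labels[i], "node_b": labels[j]}
        for i, j in zip(*iu) if adj[i, j]
    ]
    pd.DataFrame(rows, columns=["node_a", "node_b"]).to_csv(
        path, sep="\t", index=False
    )


def write_behavior_tsv(trials: pd.DataFrame, path: PathLike) -> None:
    trials.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_behavior_tsv(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def load_config(path: PathLike) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def dump_json(obj, path: PathLike) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")
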