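"""Plain-text file formats: Matrix Market adjacency, CSV type labels,
GDF-like spike trains and YAML config echoes.

A network is stored as ``PREFIX.mtx`` (sparse coordinate, real, general;
0-based node ids are converted to the format's 1-based convention by
scipy) plus ``PREFIX.types.csv`` with columns ``node_id,type``.  Spikes are
two-column whitespace text ``time_ms neuron_id``, time-sorted, with ``#``
header comment lines.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

from .networks import NeuronTypes, WeightedNetwork
from .simulate import SpikeTrainSet


def save_network(net: WeightedNetwork, prefix: str) -> None:
    scipy.io.mmwrite(prefix + ".mtx", sp.coo_matrix(net.g))
    pd.DataFrame({"node_id": np.arange(net.n),
                  "type": net.types.labels}).to_csv(prefix + ".types.csv",
                                                    index=False)


def load_network(prefix: str, g_e: float | None = None,
                 g_i: float | None = None) -> WeightedNetwork:
    """Load a network written by :func:`save_network`.

    The type weights are inferred from the stored entries unless given
    explicitly (needed only if a population makes no connection at all).
    """
    g = np.asarray(scipy.io.mmread(prefix + ".mtx").todense(), dtype=float)
    df = pd.read_csv(prefix + ".types.csv")
    types = NeuronTypes(df.sort_values("node_id")["type"].to_numpy())
    w_e = g[:, types.labels == "E"]
    w_i = g[:, types.labels == "I"]
    if g_e is None:
        nz = w_e[w_e != 0]
        g_e = float(nz[0]) if nz.size else 1.0
    if g_i is None:
        nz = w_i[w_i != 0]
        g_i = float(nz[0]) if nz.size else -1.0
    return WeightedNetwork(g, types, g_e, g_i)


def save_spikes(spikes: SpikeTrainSet, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("# time_ms neuron_id\n")
        fh.write(f"# n_neurons {spikes.n} duration_ms {spikes.duration!r} "
                 f"rectified_fraction {spikes.rectified_fraction!r}\n")
        for t, i in zip(spikes.times, spikes.ids):
            fh.write(f"{t:.6f} {i}\n")


def load_spikes(path: str) -> SpikeTrainSet:
    n = duration = rect = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") and "n_neurons" in line:
                parts = line.split()
                n = int(parts[parts.index("n_neurons") + 1])
                duration = float(parts[parts.index("duration_ms") + 1])
                rect = float(parts[parts.index("rectified_fraction") + 1])
            if not line.startswith("#"):
                break
    data = np.loadtxt(path, comments="#", ndmin=2)
    times = data[:, 0] if data.size else np.empty(0)
    ids = data[:, 1].astype(np.int64) if data.size else np.empty(0, dtype=np.int64)
    if n is None:
        n = int(ids.max()) + 1 if ids.size else 0
    if duration is None:
        duration = float(times.max()) if times.size else 0.0
    return SpikeTrainSet(times=times, ids=ids, n=n, duration=duration,
                         rectified_fraction=rect or 0.0)


def write_config(path: str, config: dict) -> None:
    """Echo a fully resolved run configuration next to its results."""
    os.makedirs(os.path.dirname(path) or ".", exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def read_config(path: str) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
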