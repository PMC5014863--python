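"""Array-container snapshots of networks (NumPy ``.npz``).

Connection and bookkeeping matrices are stored as sparse (row, col,
value) triplets, population states as dense vectors.  Intended for
checkpointing runs; small-scale matrices can also be exported densely as
CSV for inspection.
"""

from __future__ import annotations

import numpy as np

from .networks import Network

__all__ = ["save_snapshot", "load_snapshot_arrays", "export_matrix_csv"]


def save_snapshot(net: Network, path) -> None:
    """Write all matrices and dynamic states of ``net`` to an ``.npz`` file."""
    payload: dict[str, np.ndarray] = {}
    for name, pop in net.populations.items():
        for kind, state in (("exc", pop.exc), ("inh", pop.inh)):
            payload[f"pop/{name}/{kind}/v"] = state.v
            payload[f"pop/{name}/{kind}/g_e"] = state.g_e
            payload[f"pop/{name}/{kind}/g_i"] = state.g_i
    for c in net.connections:
        rows, cols, vals = c.cm.to_triplets()
        payload[f"conn/{c.name}/rows"] = rows
        payload[f"conn/{c.name}/cols"] = cols
        payload[f"conn/{c.name}/weights"] = vals
        payload[f"conn/{c.name}/shape"] = np.array(c.cm.w.shape)
        if c.bk is not None:
            payload[f"conn/{c.name}/bk"] = c.bk.b[rows, cols]
            payload[f"conn/{c.name}/c_float"] = c.bk.c_float
        if c.trace is not None:
            payload[f"conn/{c.name}/trace_r"] = c.trace.r
            payload[f"conn/{c.name}/trace_o"] = c.trace.o
    np.savez_compressed(path, **payload)


def load_snapshot_arrays(path) -> dict[str, np.ndarray]:
    """Load a snapshot back as a flat {key: array} dict."""
    with np.load(path) as data:
        return {k: data[k] for k in data.files}


def export_matrix_csv(cm, path) -> None:
    """Dense CSV export of a connection matrix (small scales only)."""
    np.savetxt(path, cm.w, delimiter=",")
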