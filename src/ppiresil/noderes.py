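"""Node Resilience (NR): per-protein contribution to network stability.

NR of a node is the integrated resilience of the network that remains after
deleting the node and all its interactions.  The residual (N-1)-node graph
is treated as its own reference network: its entropy normalizer is its own
node count, so every NR lives on the same [0, 1] scale as R itself.  A
residual graph may be disconnected at failure fraction 0 — that is precisely
the mechanism by which removing an inter-module bridge depresses NR, since
its entropy curve then starts above zero and the integral grows.

Low NR marks the nodes whose loss most fragments the network; the lowest
decile forms the Key Component Nodes (KCNs).
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, replace

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .entropy import _as_arrays, _simulate_curve_arrays
from .exceptions import DisconnectedGraphError, ParameterError

__all__ = [
    "NodeResilienceTable",
    "node_resilience_all",
    "detect_outliers",
    "key_component_nodes",
]


@dataclass
class NodeResilienceTable:
    """Per-node NR values with ranks and (after detection) outlier flags.

    ``frame`` has one row per node with columns ``node``, ``nr``, ``rank``
    and ``outlier``; rank 1 is the lowest NR (most critical node).  Ties in
    NR are broken by node identifier so the ranking is deterministic.
    """

    frame: pd.DataFrame
    network: str
    step: float
    reps: int
    seed: int
    baseline_r: float
    outlier_percent: float | None = None
    outlier_level: float | None = None
    outlier_method: str | None = None

    @property
    def n(self) -> int:
        return len(self.frame)

    def nr_of(self, node) -> float:
        row = self.frame.loc[self.frame["node"] == node, "nr"]
        if row.empty:
            raise KeyError(node)
        return float(row.iloc[0])

    def to_tsv(self, path: str | os.PathLike) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    def to_dict(self) -> dict:
        return {
            "network": self.network,
            "step": self.step,
            "reps": self.reps,
            "seed": self.seed,
            "baseline_R": self.baseline_r,
            "outlier_percent": self.outlier_percent,
            "outlier_level": self.outlier_level,
            "outlier_method": self.outlier_method,
        }


def _ranked_frame(nodes: list, nr: np.ndarray) -> pd.DataFrame:
    order = np.lexsort(([str(x) for x in nodes], nr))
    rank = np.empty(len(nodes), dtype=int)
    rank[order] = np.arange(1, len(nodes) + 1)
    return pd.DataFrame(
        {"node": [str(x) for x in nodes], "nr": nr, "rank": rank, "outlier": False}
    )


def node_resilience_all(
    g: nx.Graph, step: float = 0.01, reps: int = 100, seed: int = 0
) -> NodeResilienceTable:
    """NR of every node of a connected network.

    For each node (in canonical order) the node is deleted, and the
    resilience of the residual graph is simulated with its own random
    stream, derived deterministically from ``(seed, node rank)``.  Results
    are therefore bit-reproducible and independent of evaluation order, so
    the sweep could be parallelized without changing a single value.
    """
    n = g.number_of_nodes()
    if n < 3:
        raise ParameterError("node resilience needs N >= 3")
    if not nx.is_connected(g):
        raise DisconnectedGraphError("node resilience is defined on a connected network")
    nodes, u, v = _as_arrays(g)
    nr = np.empty(n, dtype=float)
    for rank, _node in enumerate(nodes):
        keep = (u != rank) & (v != rank)
        # reindex the residual graph to 0..n-2
        ru = np.where(u[keep] > rank, u[keep] - 1, u[keep])
        rv = np.where(v[keep] > rank, v[keep] - 1, v[keep])
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), rank]))
        grid, H = _simulate_curve_arrays(
            np.ascontiguousarray(ru), np.ascontiguousarray(rv), n - 1, step, reps, rng
        )
        nr[rank] = 1.0 - float(np.trapezoid(H.mean(axis=1), grid))
    baseline_rng = np.random.default_rng(np.random.SeedSequence([int(seed), n]))
    grid, H = _simulate_curve_arrays(u, v, n, step, reps, baseline_rng)
    baseline_r = 1.0 - float(np.trapezoid(H.mean(axis=1), grid))
    return NodeResilienceTable(
        frame=_ranked_frame(nodes, nr),
        network=g.graph.get("name", ""),
        step=step,
        reps=reps,
        seed=seed,
        baseline_r=baseline_r,
    )


def detect_outliers(
    t: NodeResilienceTable, level: float = 0.95, method: str = "normal"
) -> NodeResilienceTable:
    """Flag nodes whose NR falls outside the central ``level`` band.

    ``method="normal"`` uses the normal-approximation interval
    mean ± z(level)·sd (z(0.95) = 1.959964); ``method="percentile"`` uses
    the empirical (1-level)/2 and 1-(1-level)/2 quantiles.  Zero NR variance
    flags nothing.  Returns a new table with flags and the outlier
    percentage; the input is untouched.
    """
    if t.n == 0:
        raise ParameterError("empty table")
    if not 0.0 < level < 1.0:
        raise ParameterError("level must lie in (0, 1)")
    nr = t.frame["nr"].to_numpy()
    if method == "normal":
        sd = nr.std(ddof=1) if t.n > 1 else 0.0
        if sd == 0.0:
            flags = np.zeros(t.n, dtype=bool)
        else:
            z = stats.norm.ppf(0.5 + level / 2.0)
            mu = nr.mean()
            flags = (nr < mu - z * sd) | (nr > mu + z * sd)
    elif method == "percentile":
        lo, hi = np.quantile(nr, [(1 - level) / 2.0, 1 - (1 - level) / 2.0])
        flags = (nr < lo) | (nr > hi)
    else:
        raise ParameterError(f"unknown outlier method {method!r}")
    frame = t.frame.copy()
    frame["outlier"] = flags
    return replace(
        t,
        frame=frame,
        outlier_percent=100.0 * flags.mean(),
        outlier_level=level,
        outlier_method=method,
    )


def key_component_nodes(t: NodeResilienceTable, fraction: float = 0.10) -> list:
    """The ceil(fraction·N) lowest-NR nodes, most critical first.

    Ties in NR are broken by node identifier.
    """
    if not 0.0 < fraction <= 1.0:
        raise ParameterError("fraction must lie in (0, 1]")
    k = math.ceil(fraction * t.n)
    ordered = t.frame.sort_values(["nr", "node"], kind="mergesort")
    return ordered["node"].head(k).tolist()
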