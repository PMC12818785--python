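"""Fragmentation entropy and the integrated network-resilience score.

The failure model isolates nodes: a failed protein keeps its place in the
network but loses every interaction, so it persists as a size-1 component.
After isolating a fraction ``f`` of the ``N`` nodes the network splits into
``k`` components with sizes ``|c_i|`` and proportions ``p_i = |c_i|/N``, and
its fragmentation is scored by the modified Shannon diversity

    H_msh(G_f) = -(1/ln N) * sum_i p_i ln p_i,

which is 0 for an intact connected network and 1 when every node is
isolated.  Network resilience integrates this entropy over the whole
failure range,

    R(G) = 1 - integral_0^1 H_msh(G_f) df,

so networks that keep a giant component under heavy random failure score
close to 1.  The integral is evaluated by the trapezoid rule on a discrete
failure grid, with the entropy at each grid point averaged over independent
Monte-Carlo draws of the failed node set.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass
from typing import Iterable

import networkx as nx
import numpy as np

from ._kernels import entropy_isolated_batch
from .exceptions import DisconnectedGraphError, MembershipError, ParameterError
from .graphio import canonical_nodes

__all__ = [
    "ComponentPartition",
    "EntropyCurve",
    "ResilienceValue",
    "isolate_nodes",
    "component_partition",
    "msh_entropy",
    "entropy_curve",
    "resilience",
]


# ---------------------------------------------------------------------------
# component partitions


@dataclass(frozen=True)
class ComponentPartition:
    """Multiset of connected-component sizes of a fragmented network.

    ``total`` is the node count of the reference network; sizes must sum to
    it, so the proportions ``p_i = size_i / total`` sum to one.
    """

    sizes: tuple
    total: int

    def __post_init__(self):
        sizes = tuple(sorted((int(s) for s in self.sizes), reverse=True))
        object.__setattr__(self, "sizes", sizes)
        if len(sizes) == 0:
            raise ParameterError("a partition needs at least one component")
        if any(s < 1 for s in sizes):
            raise ParameterError("component sizes must be >= 1")
        if sum(sizes) != self.total:
            raise ParameterError(
                f"component sizes sum to {sum(sizes)}, expected total {self.total}"
            )

    @property
    def k(self) -> int:
        """Number of components."""
        return len(self.sizes)

    @property
    def proportions(self) -> np.ndarray:
        return np.asarray(self.sizes, dtype=float) / self.total


def isolate_nodes(g: nx.Graph, targets: Iterable) -> nx.Graph:
    """Isolate ``targets``: drop all their incident edges, keep the nodes.

    Returns a new graph on the same node set; the input is untouched.
    """
    targets = set(targets)
    unknown = targets - set(g.nodes())
    if unknown:
        raise MembershipError(f"targets not in graph: {sorted(map(str, unknown))}")
    out = g.copy()
    out.remove_edges_from([(u, v) for u, v in g.edges(targets)])
    return out


def component_partition(g: nx.Graph) -> ComponentPartition:
    """Connected-component sizes of ``g`` (isolated nodes count as size 1)."""
    if g.number_of_nodes() == 0:
        raise ParameterError("partition of an empty graph is undefined")
    sizes = tuple(len(c) for c in nx.connected_components(g))
    return ComponentPartition(sizes=sizes, total=g.number_of_nodes())


def msh_entropy(partition: ComponentPartition) -> float:
    """Modified Shannon diversity of a component partition, in [0, 1].

    Evaluated as ``1 - (sum s ln s)/(N ln N)``, which equals
    ``-(1/ln N) sum p ln p`` exactly (the convention 0*ln 0 = 0 is automatic
    because singletons contribute ``1*ln 1 = 0``).  The logarithm base
    cancels in the ratio, so any base gives the same value.
    """
    n = partition.total
    if n < 2:
        raise ParameterError(
            "entropy normalizer log(N) vanishes for N=1; single-node networks are out of scope"
        )
    acc = sum(s * math.log(s) for s in partition.sizes if s > 1)
    return 1.0 - acc / (n * math.log(n))


# ---------------------------------------------------------------------------
# failure grids


def _make_grid(step: float) -> np.ndarray:
    """Failure-fraction grid {0, step, 2 step, ..., 1}."""
    if not 0.0 < step <= 1.0:
        raise ParameterError(f"step must lie in (0, 1], got {step}")
    k = int(math.floor(1.0 / step + 1e-9))
    grid = np.arange(k + 1, dtype=float) * step
    if grid[-1] < 1.0 - 1e-9:
        grid = np.append(grid, 1.0)
    grid[-1] = 1.0
    return grid


def _m_of_f(f: float, n: int) -> int:
    """Failed-node count at fraction ``f``: floor(f*N + 0.5), round half up."""
    return int(math.floor(f * n + 0.5 + 1e-12))


def _as_arrays(g: nx.Graph) -> tuple[list, np.ndarray, np.ndarray]:
    """Canonical node list plus edge-index arrays for the kernels."""
    nodes = canonical_nodes(g)
    index = {node: i for i, node in enumerate(nodes)}
    if g.number_of_edges():
        uv = np.array([[index[a], index[b]] for a, b in g.edges()], dtype=np.int64)
        u, v = np.ascontiguousarray(uv[:, 0]), np.ascontiguousarray(uv[:, 1])
    else:
        u = np.empty(0, dtype=np.int64)
        v = np.empty(0, dtype=np.int64)
    return nodes, u, v


# ---------------------------------------------------------------------------
# entropy curves and resilience


@dataclass
class EntropyCurve:
    """Mean fragmentation entropy as a function of the failure fraction."""

    grid: np.ndarray
    mean_H: np.ndarray
    sd_H: np.ndarray
    reps: int
    seed: int
    per_rep_H: np.ndarray | None = None
    name: str = ""

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"f": self.grid, "mean_H": self.mean_H, "sd_H": self.sd_H, "reps": self.reps}
        )

    def to_tsv(self, path: str | os.PathLike) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "seed": int(self.seed),
            "reps": int(self.reps),
            "f": [float(x) for x in self.grid],
            "mean_H": [float(x) for x in self.mean_H],
            "sd_H": [float(x) for x in self.sd_H],
        }

    def to_json(self, path: str | os.PathLike) -> None:
        with open(path, "wt", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1)


@dataclass
class ResilienceValue:
    """Integrated resilience R(G) = 1 - trapezoid(mean_H over f)."""

    value: float
    curve: EntropyCurve
    method: str = "trapezoid"

    def to_dict(self) -> dict:
        return {
            "R": float(self.value),
            "method": self.method,
            "seed": int(self.curve.seed),
            "reps": int(self.curve.reps),
            "grid_points": int(self.curve.grid.size),
            "name": self.curve.name,
        }

    def to_json(self, path: str | os.PathLike) -> None:
        with open(path, "wt", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def _simulate_curve_arrays(
    u: np.ndarray,
    v: np.ndarray,
    n: int,
    step: float,
    reps: int,
    rng: np.random.Generator,
    keep_replicates: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Replicate entropy matrix (grid x reps) for an indexed edge array.

    At every grid point each replicate isolates an independent uniformly
    random subset of ``m(f)`` nodes.  Works on disconnected inputs too (the
    per-node resilience sweep needs that); the curve then starts above 0.
    """
    grid = _make_grid(step)
    H = np.empty((grid.size, reps), dtype=float)
    for i, f in enumerate(grid):
        m = _m_of_f(float(f), n)
        if m == 0:
            h0 = entropy_isolated_batch(u, v, n, np.empty((1, 0), dtype=np.int64))[0]
            H[i, :] = h0
        elif m >= n:
            H[i, :] = 1.0
        else:
            removed = np.argsort(rng.random((reps, n)), axis=1)[:, :m]
            H[i, :] = entropy_isolated_batch(u, v, n, np.ascontiguousarray(removed))
    return grid, H


def _curve_from_H(grid, H, reps, seed, keep_replicates, name) -> EntropyCurve:
    mean_H = H.mean(axis=1)
    sd_H = H.std(axis=1, ddof=1) if reps > 1 else np.zeros(grid.size)
    return EntropyCurve(
        grid=grid,
        mean_H=mean_H,
        sd_H=sd_H,
        reps=reps,
        seed=seed,
        per_rep_H=H if keep_replicates else None,
        name=name,
    )


def entropy_curve(
    g: nx.Graph,
    step: float = 0.01,
    reps: int = 100,
    seed: int = 0,
    keep_replicates: bool = False,
) -> EntropyCurve:
    """Monte-Carlo fragmentation-entropy curve of a connected network.

    Parameters
    ----------
    g
        Connected graph with at least 2 nodes (resilience is defined on the
        largest connected component; extract it first if needed).
    step
        Failure-fraction increment of the grid (default 1%).
    reps
        Independent random failure sets per grid point (default 100).
    seed
        Seed of the random stream; identical inputs give a bit-identical
        curve.
    """
    if reps < 1:
        raise ParameterError("reps must be >= 1")
    if g.number_of_nodes() < 2:
        raise ParameterError("entropy curve needs N >= 2")
    if not nx.is_connected(g):
        raise DisconnectedGraphError(
            "input graph is disconnected; resilience is defined on the LCC"
        )
    nodes, u, v = _as_arrays(g)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed)]))
    grid, H = _simulate_curve_arrays(u, v, len(nodes), step, reps, rng)
    return _curve_from_H(grid, H, reps, seed, keep_replicates, g.graph.get("name", ""))


def integrate_curve(curve: EntropyCurve) -> float:
    """Trapezoid integral of the mean entropy over the failure grid."""
    return float(np.trapezoid(curve.mean_H, curve.grid))


def resilience(
    g: nx.Graph, step: float = 0.01, reps: int = 100, seed: int = 0
) -> ResilienceValue:
    """Integrated resilience R(G) of a connected network, in [0, 1].

    High values mean fragmentation is delayed: the network keeps a giant
    component deep into the random-failure process.
    """
    curve = entropy_curve(g, step=step, reps=reps, seed=seed)
    return ResilienceValue(value=1.0 - integrate_curve(curve), curve=curve)
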