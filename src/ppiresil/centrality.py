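"""Classical centralities, NR-centrality correlation, and key-node overlap.

Degree (DC), betweenness (BC), closeness (CC) and eigenvector (EC)
centralities are the standard static importance measures for PPI networks.
Comparing them with Node Resilience separates two notions of criticality:
BC captures inter-module brokerage (shortest-path bridging), which is
exactly what NR penalizes when lost — hence the characteristically strong
negative NR-BC correlation — while DC, CC and EC reflect local or
spectral prominence and correlate only weakly with NR.

The top decile by BC forms the Key Bridge Nodes (KBNs); their overlap with
the Key Component Nodes (lowest decile by NR) quantifies how far the two
ranking philosophies agree on the network's keystones.
"""

from __future__ import annotations

import json
import math
import os
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import AlignmentError, ConvergenceError, DisconnectedGraphError, ParameterError
from .graphio import canonical_nodes
from .noderes import NodeResilienceTable

__all__ = [
    "CentralityTable",
    "CorrelationReport",
    "OverlapReport",
    "centralities",
    "correlate",
    "key_bridge_nodes",
    "overlap_report",
    "multi_network_summary",
]

MEASURES = ("dc", "bc", "cc", "ec")

_NORMALIZATION = {
    "dc": "degree / (N-1)",
    "bc": "pair-normalized: 2 / ((N-1)(N-2)) for undirected graphs",
    "cc": "(N-1) / sum of shortest-path distances",
    "ec": "principal adjacency eigenvector, unit Euclidean norm",
}


@dataclass
class CentralityTable:
    """Per-node DC/BC/CC/EC values with their normalization conventions."""

    frame: pd.DataFrame
    normalization: Mapping[str, str]
    network: str = ""

    @property
    def n(self) -> int:
        return len(self.frame)

    def to_tsv(self, path: str | os.PathLike) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


@dataclass
class CorrelationReport:
    """Correlation of NR against each centrality measure on one network."""

    coefficients: Mapping[str, float]  # keys dc, bc, cc, ec; NaN if undefined
    method: str
    n: int
    network: str = ""

    def to_dict(self) -> dict:
        return {
            "network": self.network,
            "method": self.method,
            "n": self.n,
            "coefficients": {k: float(v) for k, v in self.coefficients.items()},
        }

    def to_json(self, path: str | os.PathLike) -> None:
        with open(path, "wt", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1)


@dataclass
class OverlapReport:
    """Set algebra between Key Component Nodes and Key Bridge Nodes.

    ``fraction`` is |KCN ∩ KBN| / |KCN|; the Jaccard index divides by the
    union instead and is never larger.
    """

    kcn: tuple
    kbn: tuple
    intersection: tuple
    union: tuple
    count: int
    fraction: float
    jaccard: float

    def to_dict(self) -> dict:
        return {
            "kcn": list(self.kcn),
            "kbn": list(self.kbn),
            "intersection": list(self.intersection),
            "union": list(self.union),
            "overlap_count": self.count,
            "overlap_fraction": self.fraction,
            "jaccard": self.jaccard,
        }

    def to_json(self, path: str | os.PathLike) -> None:
        with open(path, "wt", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def eigenvector_centrality(
    g: nx.Graph, tol: float = 1e-8, max_iter: int = 1000
) -> dict:
    """Principal eigenvector of the adjacency structure by power iteration.

    Iterates ``x <- (A + I) x`` (the identity shift leaves eigenvectors
    unchanged but makes the iteration aperiodic, so it converges on
    bipartite graphs such as stars) from a uniform start vector, normalizing
    to unit Euclidean norm each step, until the max-norm change drops below
    ``tol``.  Deterministic: no randomness involved.
    """
    nodes = canonical_nodes(g)
    a = nx.to_scipy_sparse_array(g, nodelist=nodes, dtype=float, format="csr")
    n = len(nodes)
    x = np.full(n, 1.0 / math.sqrt(n))
    for _ in range(max_iter):
        y = a @ x + x
        norm = np.linalg.norm(y)
        if norm == 0.0:
            raise ConvergenceError("zero vector encountered in power iteration")
        y /= norm
        if float(np.max(np.abs(y - x))) < tol:
            return dict(zip(nodes, y))
        x = y
    residual = float(np.max(np.abs(a @ x - (x @ (a @ x)) * x)))
    raise ConvergenceError(
        f"eigenvector centrality did not converge in {max_iter} iterations "
        f"(eigen-equation residual {residual:.3e})"
    )


def centralities(g: nx.Graph) -> CentralityTable:
    """DC, BC, CC and EC for every node of a connected network (N >= 3)."""
    if g.number_of_nodes() < 3:
        raise ParameterError("centralities need N >= 3")
    if not nx.is_connected(g):
        raise DisconnectedGraphError("closeness centrality is undefined on disconnected graphs")
    nodes = canonical_nodes(g)
    dc = nx.degree_centrality(g)
    bc = nx.betweenness_centrality(g, normalized=True)
    cc = nx.closeness_centrality(g)
    ec = eigenvector_centrality(g)
    frame = pd.DataFrame(
        {
            "node": [str(x) for x in nodes],
            "dc": [dc[x] for x in nodes],
            "bc": [bc[x] for x in nodes],
            "cc": [cc[x] for x in nodes],
            "ec": [ec[x] for x in nodes],
        }
    )
    return CentralityTable(
        frame=frame, normalization=dict(_NORMALIZATION), network=g.graph.get("name", "")
    )


def correlate(
    nr: NodeResilienceTable, c: CentralityTable, method: str = "spearman"
) -> CorrelationReport:
    """Correlate NR with each centrality measure, nodes matched by id.

    Spearman rank correlation is the default (robust to the heavy-tailed NR
    and BC distributions and invariant to monotone transforms); Pearson is
    available via ``method="pearson"``.  A zero-variance column yields NaN.
    """
    if method not in ("spearman", "pearson"):
        raise ParameterError(f"unknown correlation method {method!r}")
    left = set(nr.frame["node"])
    right = set(c.frame["node"])
    if left != right:
        diff = sorted(left.symmetric_difference(right))
        raise AlignmentError(f"node sets differ; symmetric difference: {diff}")
    merged = nr.frame[["node", "nr"]].merge(c.frame, on="node")
    corr = stats.spearmanr if method == "spearman" else stats.pearsonr
    coeffs = {}
    for measure in MEASURES:
        x = merged["nr"].to_numpy()
        y = merged[measure].to_numpy()
        if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
            coeffs[measure] = float("nan")
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            coeffs[measure] = float(corr(x, y).statistic)
    return CorrelationReport(
        coefficients=coeffs, method=method, n=len(merged), network=nr.network
    )


def key_bridge_nodes(c: CentralityTable, fraction: float = 0.10) -> list:
    """The ceil(fraction·N) highest-BC nodes, descending BC, ties by id."""
    if not 0.0 < fraction <= 1.0:
        raise ParameterError("fraction must lie in (0, 1]")
    k = math.ceil(fraction * c.n)
    ordered = c.frame.sort_values(["bc", "node"], ascending=[False, True], kind="mergesort")
    return ordered["node"].head(k).tolist()


def overlap_report(kcn: Iterable, kbn: Iterable) -> OverlapReport:
    """Exact set overlap between KCNs and KBNs."""
    kcn = [str(x) for x in kcn]
    kbn = [str(x) for x in kbn]
    if not kcn or not kbn:
        raise ParameterError("both key-node sets must be nonempty")
    a, b = set(kcn), set(kbn)
    inter = a & b
    union = a | b
    return OverlapReport(
        kcn=tuple(kcn),
        kbn=tuple(kbn),
        intersection=tuple(sorted(inter)),
        union=tuple(sorted(union)),
        count=len(inter),
        fraction=len(inter) / len(a),
        jaccard=len(inter) / len(union),
    )


def multi_network_summary(reports: Sequence[CorrelationReport]) -> pd.DataFrame:
    """Distribution of NR-centrality coefficients across many networks.

    Returns one row per measure with the mean and the quantiles needed for
    a violin-style summary (min, 2.5%, 25%, median, 75%, 97.5%, max).
    """
    if len(reports) < 2:
        raise ParameterError("summary needs at least 2 correlation reports")
    rows = []
    for measure in MEASURES:
        vals = np.array([r.coefficients[measure] for r in reports], dtype=float)
        q = np.nanquantile(vals, [0.0, 0.025, 0.25, 0.5, 0.75, 0.975, 1.0])
        rows.append(
            {
                "measure": measure,
                "mean": float(np.nanmean(vals)),
                "min": q[0],
                "q2.5": q[1],
                "q25": q[2],
                "median": q[3],
                "q75": q[4],
                "q97.5": q[5],
                "max": q[6],
                "n_networks": len(reports),
            }
        )
    return pd.DataFrame(rows)
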