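"""Plain-text edge-list input/output and largest-connected-component extraction.

Protein-protein interaction networks are exchanged as whitespace-separated
edge lists (one interacting pair per line, ``#`` comments), the dialect used
by the SNAP tree-of-life interactome dumps.  Node identifiers are opaque
strings (locus tags such as ``lmo1570``); nothing here assumes integer ids.

Graphs are held as :class:`networkx.Graph` objects: undirected, simple
(self-loops dropped, parallel edges collapsed), with an optional free-text
label under ``g.graph["name"]``.
"""

from __future__ import annotations

import os
from typing import Iterable

import networkx as nx

from .exceptions import EmptyInputError

__all__ = ["read_edge_list", "write_edge_list", "extract_lcc", "canonical_nodes"]


def read_edge_list(path: str | os.PathLike, delimiter: str | None = None) -> nx.Graph:
    """Read an undirected simple graph from a plain-text edge list.

    Parameters
    ----------
    path
        File with one edge per line: two (or more; extras are ignored)
        delimiter-separated node identifiers.  Lines starting with ``#`` and
        blank lines are skipped.  A line with a single token declares an
        isolated node, so that graphs written by :func:`write_edge_list`
        round-trip exactly.
    delimiter
        Token separator; ``None`` splits on any run of whitespace.

    Returns
    -------
    networkx.Graph
        Self-loops dropped, duplicate edges collapsed, ``name`` set to the
        file's base name.

    Raises
    ------
    EmptyInputError
        If the file contains no nodes at all.
    OSError
        If the file cannot be read.
    """
    g = nx.Graph()
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split(delimiter)
            if len(tokens) == 1:
                g.add_node(tokens[0])
                continue
            u, v = tokens[0], tokens[1]
            if u == v:
                g.add_node(u)  # self-loop: keep the node, drop the edge
                continue
            g.add_edge(u, v)
    if g.number_of_nodes() == 0:
        raise EmptyInputError(f"no nodes or edges parsed from {os.fspath(path)!r}")
    g.graph["name"] = os.path.basename(os.fspath(path))
    return g


def write_edge_list(g: nx.Graph, path: str | os.PathLike, delimiter: str = " ") -> None:
    """Write ``g`` in the same dialect :func:`read_edge_list` reads.

    Edge endpoints are sorted within each line and lines are sorted, so the
    output is a canonical form: two equal graphs always serialize to
    identical bytes.  Isolated nodes are emitted as single-token lines after
    the edges.
    """
    lines = sorted(delimiter.join(sorted((str(u), str(v)))) for u, v in g.edges())
    isolated = sorted(str(n) for n in g.nodes() if g.degree(n) == 0)
    with open(path, "wt", encoding="utf-8") as fh:
        for line in lines:
            fh.write(line + "\n")
        for node in isolated:
            fh.write(node + "\n")


def canonical_nodes(g: nx.Graph) -> list:
    """Nodes of ``g`` in canonical (lexicographic) order.

    All seeded per-node randomness in the package is keyed by a node's rank
    in this order, so results never depend on graph insertion order.
    """
    return sorted(g.nodes(), key=str)


def extract_lcc(g: nx.Graph) -> nx.Graph:
    """Induced subgraph on the largest connected component of ``g``.

    Ties between equal-size components are broken by the lexicographically
    smallest member identifier, making the result order-independent.  The
    returned graph is a copy; the input is untouched.
    """
    if g.number_of_nodes() == 0:
        raise EmptyInputError("cannot extract the LCC of an empty graph")
    components: Iterable[set] = nx.connected_components(g)
    best = min(components, key=lambda c: (-len(c), min(str(n) for n in c)))
    out = g.subgraph(best).copy()
    out.graph.update(g.graph)
    return out
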