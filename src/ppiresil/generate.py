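"""Synthetic network generation: analytic fixtures and modular PPI surrogates.

Two kinds of graphs are produced.  Exact families (star, path, cycle,
complete) serve as closed-form oracles: their symmetry makes entropy curves
and centralities computable by hand.  Random families (Erdős–Rényi,
preferential attachment, planted modular) emulate statistical features of
real interactomes; ``planted_modular`` in particular builds the structure
the resilience analysis is designed to probe — dense functional modules
whose only inter-module routes run through a few designated bridge nodes,
so the bridges carry essentially all cross-module shortest paths.

All node identifiers are zero-padded strings, and every family is
bit-reproducible from its seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .exceptions import ParameterError

__all__ = ["SyntheticSpec", "generate_synthetic", "planted_modular_graph"]

_FAMILIES = (
    "erdos_renyi",
    "preferential_attachment",
    "planted_modular",
    "star",
    "path",
    "cycle",
    "complete",
)


@dataclass(frozen=True)
class SyntheticSpec:
    """Declarative description of a synthetic network.

    Parameters
    ----------
    family
        One of ``erdos_renyi``, ``preferential_attachment``,
        ``planted_modular``, ``star``, ``path``, ``cycle``, ``complete``.
    n
        Node count (exact families, ER, preferential attachment).
    p
        Edge probability (ER) or intra-module edge probability
        (planted modular; default 0.15, which gives modules the ~5 mean
        degree typical of bacterial interactomes).
    attach
        Edges per new node (preferential attachment).
    modules, module_size, bridges
        Planted-modular shape: number of dense modules, nodes per module,
        and number of bridge nodes joining them.
    attachments
        How many members of each module every bridge links to (default 2).
    seed
        Reproducibility seed; identical spec + seed gives an identical graph.
    """

    family: str
    n: int | None = None
    p: float | None = None
    attach: int | None = None
    modules: int | None = None
    module_size: int | None = None
    bridges: int | None = None
    attachments: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise ParameterError(f"unknown family {self.family!r}; choose from {_FAMILIES}")
        for name in ("n", "attach", "modules", "module_size", "bridges", "attachments"):
            val = getattr(self, name)
            if val is not None and val <= 0:
                raise ParameterError(f"{name} must be strictly positive, got {val}")
        if self.p is not None and not 0.0 <= self.p <= 1.0:
            raise ParameterError(f"p must lie in [0, 1], got {self.p}")


def _label(i: int, width: int, prefix: str = "v") -> str:
    return f"{prefix}{i:0{width}d}"


def _relabel(g: nx.Graph, prefix: str = "v") -> nx.Graph:
    width = max(2, len(str(max(g.number_of_nodes() - 1, 1))))
    return nx.relabel_nodes(g, {i: _label(i, width, prefix) for i in g.nodes()})


def planted_modular_graph(
    modules: int,
    module_size: int,
    bridges: int,
    intra_p: float = 0.15,
    attachments: int = 2,
    seed: int = 0,
) -> nx.Graph:
    """Modular graph whose modules communicate only through bridge nodes.

    Each module is an internally connected random graph: a random recursive
    spanning tree guarantees connectivity, and every remaining intra-module
    pair is added independently with probability ``intra_p``.  Each bridge
    node is then joined to ``attachments`` randomly chosen members of every
    module (bridges are mutually non-adjacent).  The result is connected by
    construction, and the bridges are the sole inter-module cut set: they
    carry every cross-module shortest path, which is what gives them extreme
    betweenness and — because their loss decouples modules — depressed node
    resilience.

    Two attachments per module (rather than one) split each module's
    cross-traffic between two gateway members, so no single gateway can
    out-rank the bridge itself on betweenness and the bridge remains the
    unambiguous keystone.
    """
    if attachments > module_size:
        raise ParameterError("attachments cannot exceed module_size")
    if not 0.0 <= intra_p <= 1.0:
        raise ParameterError(f"intra_p must lie in [0, 1], got {intra_p}")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x9E37]))
    g = nx.Graph()
    width = max(2, len(str(module_size - 1)))
    module_members: list[list[str]] = []
    for m in range(modules):
        members = [f"m{m}_{i:0{width}d}" for i in range(module_size)]
        module_members.append(members)
        g.add_nodes_from(members)
        # random recursive tree keeps the module connected
        for i in range(1, module_size):
            j = int(rng.integers(0, i))
            g.add_edge(members[i], members[j])
        for i in range(module_size):
            for j in range(i + 1, module_size):
                if not g.has_edge(members[i], members[j]) and rng.random() < intra_p:
                    g.add_edge(members[i], members[j])
    for b in range(bridges):
        bridge = f"b{b:02d}"
        g.add_node(bridge)
        for members in module_members:
            picks = rng.choice(module_size, size=attachments, replace=False)
            for k in picks:
                g.add_edge(bridge, members[int(k)])
    g.graph["name"] = f"planted_modular_{modules}x{module_size}_b{bridges}_s{seed}"
    return g


def generate_synthetic(spec: SyntheticSpec) -> nx.Graph:
    """Build the graph a :class:`SyntheticSpec` describes."""
    fam = spec.family
    if fam in ("star", "path", "cycle", "complete"):
        if spec.n is None:
            raise ParameterError(f"{fam} requires n")
        builder = {
            "star": lambda n: nx.star_graph(n - 1),
            "path": nx.path_graph,
            "cycle": nx.cycle_graph,
            "complete": nx.complete_graph,
        }[fam]
        if fam in ("cycle",) and spec.n < 3:
            raise ParameterError("a cycle needs at least 3 nodes")
        g = _relabel(builder(spec.n))
    elif fam == "erdos_renyi":
        if spec.n is None or spec.p is None:
            raise ParameterError("erdos_renyi requires n and p")
        g = _relabel(nx.gnp_random_graph(spec.n, spec.p, seed=int(spec.seed)))
    elif fam == "preferential_attachment":
        if spec.n is None or spec.attach is None:
            raise ParameterError("preferential_attachment requires n and attach")
        if spec.attach >= spec.n:
            raise ParameterError("attach must be smaller than n")
        g = _relabel(nx.barabasi_albert_graph(spec.n, spec.attach, seed=int(spec.seed)))
    else:  # planted_modular
        if None in (spec.modules, spec.module_size, spec.bridges):
            raise ParameterError("planted_modular requires modules, module_size and bridges")
        g = planted_modular_graph(
            spec.modules,
            spec.module_size,
            spec.bridges,
            intra_p=0.15 if spec.p is None else spec.p,
            attachments=spec.attachments,
            seed=spec.seed,
        )
    g.graph.setdefault("name", f"{fam}_s{spec.seed}")
    return g
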