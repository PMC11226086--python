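"""Default-mode-network specification: nodes, typed directed edges, subsets.

The network is a fully connected four-node graph (no self-edges) over the
medial prefrontal cortex (mPFC), precuneus / posterior cingulate (Prec) and
the two lateral parietal cortices (lLP, rLP).  Edges are typed forward,
backward or lateral according to the cortical hierarchy
mPFC > Prec > {lLP, rLP}: connections ascending the hierarchy are forward
(driving, targeting the granular layer), descending ones backward
(modulatory, targeting supra/infragranular layers), and connections between
the two lateral parietal nodes lateral.
"""

from __future__ import annotations

from dataclasses import dataclass, field


EdgeType = str  # "forward" | "backward" | "lateral"

_EDGE_TYPES = ("forward", "backward", "lateral")


@dataclass(frozen=True)
class Edge:
    source: str
    target: str
    type: EdgeType

    @property
    def name(self) -> str:
        return f"{self.source}->{self.target}"


@dataclass
class NetworkSpec:
    """Named nodes with MNI coordinates plus typed directed edges.

    ``subsets`` maps a label to a list of edge indices into ``edges``;
    the ``"full"`` subset always contains every edge.
    """

    nodes: list[tuple[str, tuple[float, float, float]]]
    edges: list[Edge]
    subsets: dict[str, list[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- helpers -----------------------------------------------------------

    @property
    def node_names(self) -> list[str]:
        return [name for name, _ in self.nodes]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def node_index(self, name: str) -> int:
        return self.node_names.index(name)

    def edge_index(self, source: str, target: str) -> int:
        for k, e in enumerate(self.edges):
            if e.source == source and e.target == target:
                return k
        raise KeyError(f"no edge {source}->{target}")

    def edge_names(self) -> list[str]:
        return [e.name for e in self.edges]

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        names = self.node_names
        if len(self.nodes) != 4:
            raise ValueError(f"expected 4 nodes, got {len(self.nodes)}")
        if len(set(names)) != len(names):
            raise ValueError("duplicate node names")
        if len(self.edges) != 12:
            raise ValueError(f"expected 12 edges, got {len(self.edges)}")
        pairs = set()
        for e in self.edges:
            if e.source == e.target:
                raise ValueError(f"self-edge {e.source}->{e.target}")
            if e.source not in names or e.target not in names:
                raise ValueError(f"edge references unknown node: {e}")
            if e.type not in _EDGE_TYPES:
                raise ValueError(f"bad edge type {e.type!r}")
            pairs.add((e.source, e.target))
        if len(pairs) != 12:
            raise ValueError("edge list must contain each ordered pair once")
        for label, idx in self.subsets.items():
            if any(i < 0 or i >= len(self.edges) for i in idx):
                raise ValueError(f"subset {label!r} has out-of-range indices")


# MNI coordinates (mm) of the four DMN sources.
DMN_COORDINATES: dict[str, tuple[float, float, float]] = {
    "lLP": (-46.0, -66.0, 30.0),
    "rLP": (49.0, -63.0, 33.0),
    "Prec": (0.0, -52.0, 7.0),
    "mPFC": (-1.0, 54.0, 27.0),
}

# Hierarchy-derived edge typing (ascending = forward, descending = backward,
# lLP<->rLP lateral).
_EDGES: list[tuple[str, str, EdgeType]] = [
    ("lLP", "mPFC", "forward"),
    ("rLP", "mPFC", "forward"),
    ("Prec", "mPFC", "forward"),
    ("lLP", "Prec", "forward"),
    ("rLP", "Prec", "forward"),
    ("mPFC", "lLP", "backward"),
    ("mPFC", "rLP", "backward"),
    ("mPFC", "Prec", "backward"),
    ("Prec", "lLP", "backward"),
    ("Prec", "rLP", "backward"),
    ("lLP", "rLP", "lateral"),
    ("rLP", "lLP", "lateral"),
]


def default_dmn() -> NetworkSpec:
    """The four-node default mode network used throughout the package.

    Returns the standard node set (lLP, rLP, Prec, mPFC) with their MNI
    coordinates, the 12 typed directed edges, and the named connection
    subsets ``full`` (all 12), ``frontoparietal`` (the six edges incident to
    mPFC) and ``parietal`` (the six edges among lLP, rLP and Prec).
    """
    nodes = [(n, DMN_COORDINATES[n]) for n in ("lLP", "rLP", "Prec", "mPFC")]
    edges = [Edge(s, t, ty) for s, t, ty in _EDGES]
    fronto = [k for k, e in enumerate(edges) if "mPFC" in (e.source, e.target)]
    parietal = [k for k, e in enumerate(edges) if "mPFC" not in (e.source, e.target)]
    subsets = {
        "full": list(range(len(edges))),
        "frontoparietal": fronto,
        "parietal": parietal,
    }
    return NetworkSpec(nodes=nodes, edges=edges, subsets=subsets)
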