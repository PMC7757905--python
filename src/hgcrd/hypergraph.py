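"""Hypergraph and graph containers plus text-format readers and writers.

A hypergraph here is a multiset of hyperedges (node sets of size >= 2) over an
integer node set; in the motif setting every hyperedge is one instance of a
small pattern (e.g. one triangle, or the three participants of one metabolic
reaction).  Incidence lists are kept in edge order because the diffusion
breaks ties by the position of a hyperedge in this list.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import ParseError

__all__ = [
    "Hypergraph",
    "Graph",
    "load_hypergraph",
    "write_hypergraph",
    "load_edgelist",
    "load_communities",
    "write_communities",
    "motif_degree",
    "motif_volume",
]

_COMMENT_PREFIXES = ("#", "%")


@dataclass
class Hypergraph:
    """A multi-hypergraph with integer node ids.

    Parameters
    ----------
    edges
        Hyperedges in a fixed order; each is stored as a sorted tuple of
        distinct node ids.  Duplicate hyperedges are kept as separate entries.
    nodes
        Optional extra nodes; the node set always includes every edge member,
        and isolated nodes are permitted.
    labels
        Optional mapping from internal id to an external label, retained by
        readers that densify labelled input.
    """

    edges: list[tuple[int, ...]] = field(default_factory=list)
    nodes: set[int] = field(default_factory=set)
    labels: dict[int, str] | None = None

    def __post_init__(self) -> None:
        clean: list[tuple[int, ...]] = []
        for e in self.edges:
            t = tuple(sorted(e))
            if len(t) < 2 or len(set(t)) != len(t):
                raise ValueError(f"invalid hyperedge {e!r}: need >=2 distinct nodes")
            clean.append(t)
        self.edges = clean
        self.nodes = set(self.nodes)
        for e in self.edges:
            self.nodes.update(e)
        self._incidence: dict[int, list[int]] = {v: [] for v in self.nodes}
        for i, e in enumerate(self.edges):
            for v in e:
                self._incidence[v].append(i)

    # -- basic queries -----------------------------------------------------

    @property
    def incidence(self) -> Mapping[int, list[int]]:
        return self._incidence

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def k_uniform(self) -> int | None:
        """Common hyperedge size k, or None for a non-uniform hypergraph."""
        sizes = {len(e) for e in self.edges}
        return sizes.pop() if len(sizes) == 1 else None

    def eta(self, v: int) -> int:
        """Number of hyperedges containing v (written eta(v))."""
        return len(self._incidence[v])

    def neighbors(self, v: int) -> set[int]:
        """Nodes co-occurring with v in at least one hyperedge."""
        out: set[int] = set()
        for i in self._incidence[v]:
            out.update(self.edges[i])
        out.discard(v)
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Hypergraph):
            return NotImplemented
        return self.nodes == other.nodes and self.edges == other.edges

    def __repr__(self) -> str:
        k = self.k_uniform
        ktag = f", k_uniform={k}" if k is not None else ""
        return f"Hypergraph(n_nodes={self.n_nodes}, n_edges={self.n_edges}{ktag})"


@dataclass
class Graph:
    """A simple graph with optional direction and non-negative edge weights."""

    edges: list[tuple[int, int]] = field(default_factory=list)
    nodes: set[int] = field(default_factory=set)
    directed: bool = False
    weights: list[float] | None = None

    def __post_init__(self) -> None:
        seen: set[tuple[int, int]] = set()
        clean: list[tuple[int, int]] = []
        w = list(self.weights) if self.weights is not None else None
        for idx, (u, v) in enumerate(self.edges):
            if u == v:
                raise ValueError(f"self-loop ({u},{v}) not allowed")
            key = (u, v) if self.directed else (min(u, v), max(u, v))
            if key in seen:
                raise ValueError(f"duplicate edge {key}")
            seen.add(key)
            clean.append((u, v) if self.directed else key)
            if w is not None and w[idx] < 0:
                raise ValueError("edge weights must be non-negative")
        self.edges = clean
        self.weights = w
        self.nodes = set(self.nodes)
        for u, v in self.edges:
            self.nodes.add(u)
            self.nodes.add(v)

    def weight(self, i: int) -> float:
        return 1.0 if self.weights is None else self.weights[i]

    def adjacency(self) -> dict[int, set[int]]:
        """Undirected adjacency sets (direction ignored)."""
        adj: dict[int, set[int]] = {v: set() for v in self.nodes}
        for u, v in self.edges:
            adj[u].add(v)
            adj[v].add(u)
        return adj

    def out_adjacency(self) -> dict[int, set[int]]:
        adj: dict[int, set[int]] = {v: set() for v in self.nodes}
        for u, v in self.edges:
            adj[u].add(v)
            if not self.directed:
                adj[v].add(u)
        return adj

    def degree(self, v: int) -> float:
        """Weighted degree (direction ignored)."""
        d = 0.0
        for i, (a, b) in enumerate(self.edges):
            if v in (a, b):
                d += self.weight(i)
        return d

    def __repr__(self) -> str:
        kind = "directed" if self.directed else "undirected"
        return f"Graph({kind}, n_nodes={len(self.nodes)}, n_edges={len(self.edges)})"


# -- motif-based degrees and volumes --------------------------------------


def motif_degree(H: Hypergraph, v: int) -> int:
    """Motif-based degree d_M(v) = sum over hyperedges e containing v of (|e|-1).

    For a k-uniform hypergraph this is (k-1) * eta(v).  The per-edge-additive
    form is the natural extension to variable hyperedge sizes: each incident
    hyperedge contributes one unit per co-member.
    """
    if v not in H.nodes:
        raise KeyError(f"node {v} not in hypergraph")
    return sum(len(H.edges[i]) - 1 for i in H.incidence[v])


def motif_volume(H: Hypergraph, S: Iterable[int], scaled: bool = False) -> int:
    """Motif volume of S: the number of hyperedge end points falling in S.

    vol_M(S) = sum over v in S of eta(v).  With ``scaled=True`` returns the
    degree-weighted volume sum d_M(v), which equals (k-1) * vol_M(S) on a
    k-uniform hypergraph.
    """
    S = set(S)
    extra = S - H.nodes
    if extra:
        raise KeyError(f"nodes {sorted(extra)} not in hypergraph")
    if scaled:
        return sum(motif_degree(H, v) for v in S)
    return sum(H.eta(v) for v in S)


# -- text formats ----------------------------------------------------------


def _data_lines(path: str) -> Iterable[tuple[int, str]]:
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(_COMMENT_PREFIXES):
                continue
            yield lineno, line


def load_hypergraph(path: str, dialect: str = "index-lists") -> Hypergraph:
    """Read a hypergraph from a one-hyperedge-per-line text file.

    Each non-comment line holds the whitespace-separated node tokens of one
    hyperedge (an hMETIS-like dialect).  Lines starting with '#' or '%' are
    ignored.  A leading header line with exactly two integers matching the
    final node and edge counts is tolerated and dropped.

    With ``dialect="index-lists"`` tokens must be integers and are used as
    node ids directly; with ``dialect="labeled"`` tokens are arbitrary labels
    mapped to dense 0-based ids (first-appearance order), with the mapping
    kept on the returned object.
    """
    if dialect not in ("index-lists", "labeled"):
        raise ValueError(f"unknown dialect {dialect!r}")
    rows: list[tuple[int, list[str]]] = []
    for lineno, line in _data_lines(path):
        rows.append((lineno, line.split()))

    # optional "n m" header
    if rows and len(rows[0][1]) == 2:
        try:
            n_hdr, m_hdr = int(rows[0][1][0]), int(rows[0][1][1])
        except ValueError:
            n_hdr = m_hdr = -1
        if n_hdr >= 0:
            body = rows[1:]
            nodes_body: set[str] = set()
            for _, toks in body:
                nodes_body.update(toks)
            if m_hdr == len(body) and n_hdr == len(nodes_body):
                rows = body

    label_map: dict[str, int] = {}
    labels: dict[int, str] = {}

    def to_id(tok: str, lineno: int) -> int:
        if dialect == "index-lists":
            try:
                return int(tok)
            except ValueError:
                raise ParseError(f"non-integer node token {tok!r}", lineno) from None
        if tok not in label_map:
            label_map[tok] = len(label_map)
            labels[label_map[tok]] = tok
        return label_map[tok]

    edges: list[tuple[int, ...]] = []
    for lineno, toks in rows:
        ids = [to_id(t, lineno) for t in toks]
        if len(set(ids)) != len(ids):
            raise ParseError("repeated node in hyperedge", lineno)
        if len(ids) < 2:
            raise ParseError("hyperedge needs at least 2 distinct nodes", lineno)
        edges.append(tuple(sorted(ids)))
    return Hypergraph(edges=edges, labels=labels or None)


def write_hypergraph(H: Hypergraph, path: str) -> None:
    """Write one hyperedge per line; external labels are used when present."""
    with open(path, "w", encoding="utf-8") as fh:
        for e in H.edges:
            if H.labels:
                fh.write(" ".join(H.labels.get(v, str(v)) for v in e) + "\n")
            else:
                fh.write(" ".join(str(v) for v in e) + "\n")


def load_edgelist(path: str, directed: bool = False) -> Graph:
    """Read a "u v" or "u v w" whitespace-separated edge list.

    The directed flag is supplied by the caller; the file does not carry it.
    """
    edges: list[tuple[int, int]] = []
    weights: list[float] = []
    any_weight = False
    for lineno, line in _data_lines(path):
        toks = line.split()
        if len(toks) not in (2, 3):
            raise ParseError(f"expected 'u v' or 'u v w', got {line!r}", lineno)
        try:
            u, v = int(toks[0]), int(toks[1])
            w = float(toks[2]) if len(toks) == 3 else 1.0
        except ValueError:
            raise ParseError(f"non-numeric token in {line!r}", lineno) from None
        if len(toks) == 3:
            any_weight = True
        edges.append((u, v))
        weights.append(w)
    return Graph(edges=edges, directed=directed, weights=weights if any_weight else None)


def load_communities(path: str) -> list[set[int]]:
    """Read one community per line of whitespace-separated node ids."""
    out: list[set[int]] = []
    for lineno, line in _data_lines(path):
        try:
            out.append({int(t) for t in line.split()})
        except ValueError:
            raise ParseError(f"non-integer node id in {line!r}", lineno) from None
    return out


def write_communities(communities: Sequence[Iterable[int]], path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for com in communities:
            fh.write(" ".join(str(v) for v in sorted(com)) + "\n")
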