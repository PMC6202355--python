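"""Read, validate and curate undirected networks.

All downstream scoring consumes the :class:`UndirectedNetwork` container,
a thin deterministic wrapper over :class:`networkx.Graph`: node identifiers
are opaque strings, orderings are lexicographic, self-loops and duplicate
edges are rejected at construction, so every ranking built on top of it is
bit-reproducible.
"""

from __future__ import annotations

import io
import logging
import os
from pathlib import Path
from typing import Iterable, Sequence, TextIO

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "UndirectedNetwork",
    "EdgeListParseError",
    "read_edge_list",
    "read_adjacency",
    "write_edge_list",
    "curate",
]


class EdgeListParseError(ValueError):
    """Raised when an edge-list or adjacency source cannot be parsed."""


def _canonical(u: str, v: str) -> tuple[str, str]:
    return (u, v) if u <= v else (v, u)


class UndirectedNetwork:
    """Simple undirected graph with stable, lexicographically ordered nodes.

    Parameters
    ----------
    edges
        Iterable of node-identifier pairs. Duplicates (in either
        orientation) collapse to a single edge; self-loops raise.
    nodes
        Optional extra node identifiers (for isolated nodes).
    """

    def __init__(
        self,
        edges: Iterable[tuple[str, str]] = (),
        nodes: Iterable[str] = (),
    ) -> None:
        g = nx.Graph()
        g.add_nodes_from(str(n) for n in nodes)
        for u, v in edges:
            u, v = str(u), str(v)
            if u == v:
                raise ValueError(f"self-loop not allowed: {u!r}")
            g.add_edge(u, v)
        self._g = g
        self._nodes: tuple[str, ...] = tuple(sorted(g.nodes))
        self._edges: tuple[tuple[str, str], ...] = tuple(
            sorted(_canonical(u, v) for u, v in g.edges)
        )

    # -- queries -----------------------------------------------------------

    @property
    def nodes(self) -> tuple[str, ...]:
        """Nodes in lexicographic order."""
        return self._nodes

    @property
    def edges(self) -> tuple[tuple[str, str], ...]:
        """Edges as (min, max) pairs, lexicographically sorted."""
        return self._edges

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def __contains__(self, node: str) -> bool:
        return node in self._g

    def has_edge(self, u: str, v: str) -> bool:
        return self._g.has_edge(u, v)

    def neighbours(self, v: str) -> frozenset[str]:
        """First-node-neighbour set N(v)."""
        self._require(v)
        return frozenset(self._g[v])

    def degree(self, v: str) -> int:
        self._require(v)
        return self._g.degree[v]

    @property
    def mean_degree(self) -> float:
        """Average node degree 2|E| / |V|."""
        if self.n_nodes == 0:
            return 0.0
        return 2.0 * self.n_edges / self.n_nodes

    def _require(self, v: str) -> None:
        if v not in self._g:
            raise KeyError(f"unknown node: {v!r}")

    # -- derived graphs ----------------------------------------------------

    def subgraph(self, nodes: Iterable[str]) -> "UndirectedNetwork":
        keep = set(nodes)
        sub = self._g.subgraph(keep)
        return UndirectedNetwork(sub.edges, nodes=sub.nodes)

    def connected_components(self) -> list[frozenset[str]]:
        """Components sorted by decreasing size, ties by smallest member."""
        comps = [frozenset(c) for c in nx.connected_components(self._g)]
        return sorted(comps, key=lambda c: (-len(c), min(c)))

    def to_networkx(self) -> nx.Graph:
        return self._g.copy()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, UndirectedNetwork):
            return NotImplemented
        return self._nodes == other._nodes and self._edges == other._edges

    def __hash__(self) -> int:
        return hash((self._nodes, self._edges))

    def __repr__(self) -> str:
        return f"UndirectedNetwork(n_nodes={self.n_nodes}, n_edges={self.n_edges})"


# ---------------------------------------------------------------------------
# I/O


def _open_text(source) -> TextIO:
    if isinstance(source, (str, os.PathLike)):
        return open(source, "r", encoding="utf-8")
    return source


def read_edge_list(source, delimiter: str | None = "\t") -> UndirectedNetwork:
    """Parse a two-column edge-list text stream into an UndirectedNetwork.

    Lines starting with ``#`` are comments. Duplicate lines and reversed
    duplicates collapse to a single edge. Self-loops are dropped with a
    logged warning; a third column (e.g. a weight) is ignored with a
    warning because every index here is a binary-topology function.

    Parameters
    ----------
    source
        Path or text stream.
    delimiter
        Field separator; ``None`` splits on any whitespace.

    Raises
    ------
    EdgeListParseError
        On a line with fewer than two fields (the message names the line
        number) or on empty input.
    """
    stream = _open_text(source)
    close = stream is not source
    edges: list[tuple[str, str]] = []
    nodes: set[str] = set()
    extra_cols_warned = False
    try:
        for lineno, raw in enumerate(stream, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split(delimiter) if delimiter else line.split()
            fields = [f for f in fields if f != ""]
            if len(fields) < 2:
                raise EdgeListParseError(
                    f"line {lineno}: expected at least 2 fields, got {len(fields)}"
                )
            if len(fields) > 2 and not extra_cols_warned:
                logger.warning(
                    "line %d: extra columns ignored (networks are unweighted)",
                    lineno,
                )
                extra_cols_warned = True
            u, v = fields[0], fields[1]
            if u == v:
                logger.warning("line %d: self-loop %r dropped", lineno, u)
                nodes.add(u)
                continue
            edges.append((u, v))
            nodes.update((u, v))
    finally:
        if close:
            stream.close()
    if not nodes:
        raise EdgeListParseError("empty input: no edges or nodes found")
    return UndirectedNetwork(edges, nodes=nodes)


def write_edge_list(net: UndirectedNetwork, dest, delimiter: str = "\t") -> None:
    """Write the network as a two-column edge list (lexicographic order)."""
    if isinstance(dest, (str, os.PathLike)):
        with open(dest, "w", encoding="utf-8") as fh:
            write_edge_list(net, fh, delimiter)
        return
    for u, v in net.edges:
        dest.write(f"{u}{delimiter}{v}\n")


def _load_matrix(source) -> np.ndarray:
    """Load a dense CSV or MatrixMarket adjacency matrix."""
    path = Path(source) if isinstance(source, (str, os.PathLike)) else None
    if path is not None and path.suffix.lower() in {".mtx", ".mm"}:
        from scipy.io import mmread

        m = mmread(path)
        return np.asarray(m.todense()) if hasattr(m, "todense") else np.asarray(m)
    if path is not None:
        return np.loadtxt(path, delimiter=",", ndmin=2)
    text = source.read()
    return np.loadtxt(io.StringIO(text), delimiter=",", ndmin=2)


def read_adjacency(
    source,
    labels: Sequence[str] | str | os.PathLike | None = None,
) -> UndirectedNetwork:
    """Build a network from a square binary adjacency matrix.

    Accepts dense CSV or MatrixMarket (``.mtx``). An asymmetric matrix is
    symmetrized by logical OR with a logged warning; the diagonal is
    ignored.

    Parameters
    ----------
    labels
        Node names: a sequence, or a path to a sidecar file with one label
        per line. Defaults to ``v0, v1, ...``.

    Raises
    ------
    EdgeListParseError
        If the matrix is not square or has entries outside {0, 1}.
    """
    mat = _load_matrix(source)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise EdgeListParseError(f"adjacency matrix must be square, got shape {mat.shape}")
    if not np.isin(mat, (0, 1)).all():
        bad = mat[~np.isin(mat, (0, 1))][0]
        raise EdgeListParseError(f"adjacency entries must be 0 or 1, found {bad}")
    n = mat.shape[0]
    if labels is None:
        names = [f"v{i}" for i in range(n)]
    elif isinstance(labels, (str, os.PathLike)):
        names = Path(labels).read_text(encoding="utf-8").split()
    else:
        names = [str(x) for x in labels]
    if len(names) != n:
        raise EdgeListParseError(f"{len(names)} labels for a {n}x{n} matrix")
    if not np.array_equal(mat, mat.T):
        logger.warning("asymmetric adjacency matrix: symmetrizing by logical OR")
        mat = np.logical_or(mat, mat.T).astype(int)
    iu, ju = np.nonzero(np.triu(mat, k=1))
    edges = [(names[i], names[j]) for i, j in zip(iu, ju)]
    return UndirectedNetwork(edges, nodes=names)


# ---------------------------------------------------------------------------
# Curation


def curate(
    net: UndirectedNetwork,
    min_component_size: int | None = None,
) -> UndirectedNetwork:
    """Remove small isolated components.

    Interactome datasets typically carry a large connected core plus a dust
    of tiny disconnected fragments on which neighbourhood indices are
    uninformative; curation keeps only components of at least
    ``min_component_size`` nodes.

    Parameters
    ----------
    min_component_size
        Minimum component size to keep. The default ``None`` keeps only the
        largest connected component. ``1`` is the identity.

    Raises
    ------
    ValueError
        If no component survives the threshold, or the threshold is < 1.
    """
    comps = net.connected_components()
    if min_component_size is None:
        if not comps:
            raise ValueError("cannot curate an empty network")
        keep = comps[0]
    else:
        if min_component_size < 1:
            raise ValueError("min_component_size must be >= 1")
        if min_component_size == 1:
            return net
        kept = [c for c in comps if len(c) >= min_component_size]
        if not kept:
            raise ValueError(
                f"no connected component has >= {min_component_size} nodes"
            )
        keep = frozenset().union(*kept)
    return net.subgraph(keep)
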