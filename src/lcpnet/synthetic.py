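"""Synthetic inputs: worked graph, random graphs, planted-complex benchmarks.

Real interactomes pair a network whose true interactions concentrate inside
protein complexes (dense, topologically isolated subgraphs) with GO
annotations that agree with those complexes. The planted benchmark
emulates exactly that premise: dense planted cliques ("complexes") plus a
few genuine inter-complex contacts, contaminated with random false-positive
edges, and BP/CC similarity channels drawn above 0.5 for genuine edges and
below 0.5 for contaminants, optionally with a fraction of annotation noise.
Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np

from .evaluation import SimilarityChannel
from .graph_core import UndirectedNetwork

__all__ = ["worked_graph", "erdos_renyi", "planted_benchmark", "PlantedBenchmark"]


def worked_graph() -> UndirectedNetwork:
    """The 6-node, 8-edge hand-checkable fixture G0.

    Nodes {x, y, a, b, c, d}; edges x-y, x-a, x-b, x-d, y-a, y-b, a-b,
    a-c. Relative to the edge (x, y) the local community is {a, b} and
    every link class is represented: one internal link (a-b), one external
    link (a-c), one non-local-community link (x-d).
    """
    return UndirectedNetwork(
        [
            ("x", "y"),
            ("x", "a"),
            ("x", "b"),
            ("x", "d"),
            ("y", "a"),
            ("y", "b"),
            ("a", "b"),
            ("a", "c"),
        ]
    )


def erdos_renyi(n: int, p: float, seed: int) -> UndirectedNetwork:
    """G(n, p) random graph with zero-padded string node names."""
    g = nx.gnp_random_graph(n, p, seed=seed)
    width = len(str(n - 1))
    name = {i: f"n{i:0{width}d}" for i in g.nodes}
    return UndirectedNetwork(
        ((name[u], name[v]) for u, v in g.edges), nodes=name.values()
    )


def _canonical(u: str, v: str) -> tuple[str, str]:
    return (u, v) if u <= v else (v, u)


@dataclass(frozen=True)
class PlantedBenchmark:
    """A planted-complex network with ground truth and similarity channels.

    ``true_edges`` are the intra-complex edges, ``bridge_edges`` the
    genuine inter-complex contacts, ``noise_edges`` the injected false
    positives; the three sets are disjoint and cover all edges. Genuine
    edges (intra + bridge) carry BP/CC similarities above 0.5, noise edges
    below, before annotation noise flips a fraction of edges across the
    0.5 boundary in both channels.
    """

    network: UndirectedNetwork
    true_edges: frozenset[tuple[str, str]]
    bridge_edges: frozenset[tuple[str, str]]
    noise_edges: frozenset[tuple[str, str]]
    bp: SimilarityChannel
    cc: SimilarityChannel
    params: dict

    @property
    def genuine_edges(self) -> frozenset[tuple[str, str]]:
        """Edges whose similarity is drawn above the 0.5 boundary."""
        return self.true_edges | self.bridge_edges

    def truth_labels(self) -> np.ndarray:
        """Generator ground truth aligned with ``network.edges``."""
        genuine = self.genuine_edges
        return np.array([e in genuine for e in self.network.edges], dtype=bool)


def planted_benchmark(
    n_complexes: int = 10,
    complex_size: int = 8,
    intra_density: float = 0.9,
    n_bridges: int = 5,
    n_noise_edges: int = 30,
    similarity_noise: float = 0.1,
    seed: int = 0,
) -> PlantedBenchmark:
    """Generate a planted-complex benchmark network with similarity channels.

    Parameters
    ----------
    n_complexes, complex_size
        Number and size of the planted complexes.
    intra_density
        Probability in (0, 1] of each intra-complex edge.
    n_bridges
        Genuine inter-complex edges (labelled true).
    n_noise_edges
        False-positive inter-complex edges (labelled false).
    similarity_noise
        Fraction in [0, 1) of edges whose BP and CC similarities are both
        flipped across the 0.5 boundary (s -> 1 - s), emulating wrong or
        missing annotations. At 0, thresholding the combined channel at
        0.5 recovers the generator's truth exactly.
    seed
        Single integer driving all randomness.

    Raises
    ------
    ValueError
        If the requested bridge/noise edges exceed the available
        inter-complex non-edges, or a parameter is out of range.

    Notes
    -----
    Genuine similarities are drawn uniform(0.55, 1) and noise similarities
    uniform(0, 0.45), leaving a margin around the strict 0.5 threshold.
    """
    if not 0 < intra_density <= 1:
        raise ValueError("intra_density must be in (0, 1]")
    if not 0 <= similarity_noise < 1:
        raise ValueError("similarity_noise must be in [0, 1)")
    rng = np.random.default_rng(seed)
    cwidth = len(str(max(n_complexes - 1, 1)))
    nwidth = len(str(max(complex_size - 1, 1)))
    groups = [
        [f"c{ci:0{cwidth}d}n{j:0{nwidth}d}" for j in range(complex_size)]
        for ci in range(n_complexes)
    ]
    nodes = [n for grp in groups for n in grp]

    true_edges: set[tuple[str, str]] = set()
    for grp in groups:
        for u, v in combinations(grp, 2):
            if rng.random() < intra_density:
                true_edges.add(_canonical(u, v))

    inter_pairs = sorted(
        _canonical(u, v)
        for gi, gj in combinations(range(n_complexes), 2)
        for u in groups[gi]
        for v in groups[gj]
    )
    n_wanted = n_bridges + n_noise_edges
    if n_wanted > len(inter_pairs):
        raise ValueError(
            f"requested {n_wanted} inter-complex edges but only "
            f"{len(inter_pairs)} pairs exist"
        )
    chosen = rng.choice(len(inter_pairs), size=n_wanted, replace=False)
    bridge_edges = frozenset(inter_pairs[i] for i in chosen[:n_bridges])
    noise_edges = frozenset(inter_pairs[i] for i in chosen[n_bridges:])

    network = UndirectedNetwork(
        sorted(true_edges | bridge_edges | noise_edges), nodes=nodes
    )

    genuine = true_edges | bridge_edges
    edges = network.edges
    bp_vals: dict[tuple[str, str], float] = {}
    cc_vals: dict[tuple[str, str], float] = {}
    for e in edges:
        if e in genuine:
            bp_vals[e] = rng.uniform(0.55, 1.0)
            cc_vals[e] = rng.uniform(0.55, 1.0)
        else:
            bp_vals[e] = rng.uniform(0.0, 0.45)
            cc_vals[e] = rng.uniform(0.0, 0.45)
    n_flip = round(similarity_noise * len(edges))
    if n_flip:
        flip_idx = rng.choice(len(edges), size=n_flip, replace=False)
        for i in flip_idx:
            e = edges[i]
            bp_vals[e] = 1.0 - bp_vals[e]
            cc_vals[e] = 1.0 - cc_vals[e]

    bp = SimilarityChannel.from_edge_values(nodes, bp_vals, "BP")
    cc = SimilarityChannel.from_edge_values(nodes, cc_vals, "CC")
    return PlantedBenchmark(
        network=network,
        true_edges=frozenset(true_edges),
        bridge_edges=bridge_edges,
        noise_edges=noise_edges,
        bp=bp,
        cc=cc,
        params={
            "n_complexes": n_complexes,
            "complex_size": complex_size,
            "intra_density": intra_density,
            "n_bridges": n_bridges,
            "n_noise_edges": n_noise_edges,
            "similarity_noise": similarity_noise,
            "seed": seed,
        },
    )
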