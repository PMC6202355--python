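"""The 20 link-reliability indices and deterministic edge ranking.

Three families:

* classical node-neighbourhood indices CN, AA, RA, PA, JC, SCD, LHN plus
  the network-biology baselines FSW, ACD, IG1;
* local-community-paradigm (LCP) corrections LCL, CAR, CAA, CRA, CPA, CJC,
  which complement common-neighbour counts with the links *between* the
  common neighbours;
* the local-ring network automata C1, C1*, C2, C2* built on the full
  iLCL / eLCL / nLCL decomposition: C1 rewards common neighbours with few
  links leaving the community, C2 rewards many links inside it, and the
  starred variants divide by (nLCL(x) + nLCL(y))**exponent to penalise
  seed pairs whose neighbourhoods mostly point away from the community.

Every index is a pure function of binary topology; higher score means a
more reliable link, except IG1 (an interaction-generality count) which is
ranked ascending.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .graph_core import UndirectedNetwork
from .local_community import NeighbourhoodDecomposition, decompose

logger = logging.getLogger(__name__)

__all__ = [
    "ALL_METHODS",
    "CLASSICAL_METHODS",
    "BIO_BASELINE_METHODS",
    "LCP_METHODS",
    "C_FAMILY_METHODS",
    "EdgeScoreTable",
    "score_classical",
    "score_bio_baseline",
    "score_lcp",
    "score_c_family",
    "score_pair",
    "rank_edges",
]

CLASSICAL_METHODS = ("CN", "AA", "RA", "PA", "JC", "SCD", "LHN")
BIO_BASELINE_METHODS = ("FSW", "ACD", "IG1")
LCP_METHODS = ("LCL", "CAR", "CAA", "CRA", "CPA", "CJC")
C_FAMILY_METHODS = ("C1", "C1star", "C2", "C2star")
ALL_METHODS = CLASSICAL_METHODS + BIO_BASELINE_METHODS + LCP_METHODS + C_FAMILY_METHODS

#: Methods whose raw value ranks ascending (lower = more reliable).
ASCENDING_METHODS = frozenset({"IG1"})


def _union_size(dec: NeighbourhoodDecomposition, deg_x: int, deg_y: int) -> int:
    # |N(x) ∪ N(y)| = |N(x)| + |N(y)| - |N(x) ∩ N(y)|; the intersection is
    # exactly cn because a node is never its own neighbour.
    return deg_x + deg_y - len(dec.cn)


def score_classical(
    dec: NeighbourhoodDecomposition,
    deg_x: int,
    deg_y: int,
    method: str,
    aa_log_base: float | None = None,
) -> float:
    """Classical node-neighbourhood index for one pair.

    ``aa_log_base`` sets the logarithm base of AA (default: natural log).
    Degrees of common neighbours are recovered from the decomposition, so
    the scorer needs no further graph access.
    """
    cn = len(dec.cn)
    if method == "CN":
        return float(cn)
    if method == "PA":
        return float(deg_x * deg_y)
    if method == "AA":
        log = math.log if aa_log_base is None else (lambda t: math.log(t, aa_log_base))
        return sum(1.0 / log(dec.degree_of(i)) for i in dec.cn)
    if method == "RA":
        return sum(1.0 / dec.degree_of(i) for i in dec.cn)
    if method == "JC":
        return cn / _union_size(dec, deg_x, deg_y) if cn else 0.0
    if method == "SCD":
        return 2.0 * cn / (deg_x + deg_y) if cn else 0.0
    if method == "LHN":
        return cn / (deg_x * deg_y) if cn else 0.0
    raise ValueError(f"unknown classical method: {method!r}")


def score_bio_baseline(net: UndirectedNetwork, x: str, y: str, method: str) -> float:
    """Network-biology baseline index (FSW, ACD or IG1) for one pair.

    FSW and ACD adjust their normalisation when a seed has fewer
    interactions than the network's average node degree, compensating for
    under-sampled proteins. FSW uses neighbour sets that include the node
    itself; it is the product of two directed ratios and lies in [0, 1].
    IG1 is 1 plus the number of neighbourhood nodes whose only interaction
    is with one of the seeds; a *low* value indicates a reliable link.
    """
    if x == y:
        raise ValueError(f"self-pair rejected: ({x!r}, {y!r})")
    nx_, ny_ = net.neighbours(x), net.neighbours(y)
    if method == "IG1":
        halo = (nx_ | ny_) - {x, y}
        return float(1 + sum(1 for v in halo if net.degree(v) == 1))
    n_bar = net.mean_degree
    if method == "ACD":
        cn = len((nx_ & ny_) - {x, y})
        if cn == 0:
            return 0.0
        lam_x = max(0.0, n_bar - len(nx_))
        lam_y = max(0.0, n_bar - len(ny_))
        return 2.0 * cn / (len(nx_) + lam_x + len(ny_) + lam_y)
    if method == "FSW":
        sx = nx_ | {x}
        sy = ny_ | {y}
        inter = len(sx & sy)
        only_x = len(sx - sy)
        only_y = len(sy - sx)
        lam_x = max(0.0, n_bar - (only_x + 2 * inter))
        lam_y = max(0.0, n_bar - (only_y + 2 * inter))
        if inter == 0:
            return 0.0
        left = 2.0 * inter / (only_x + 2 * inter + lam_x)
        right = 2.0 * inter / (only_y + 2 * inter + lam_y)
        return left * right
    raise ValueError(f"unknown bio-baseline method: {method!r}")


def score_lcp(
    dec: NeighbourhoodDecomposition,
    deg_x: int,
    deg_y: int,
    method: str,
) -> float:
    """LCP-corrected index (LCL, CAR, CAA, CRA, CPA or CJC) for one pair.

    These replace the "how many common neighbours" question with "how
    interlinked are they": each formula weighs common neighbours by their
    internal local-community links. CAA divides by log2|N(i)| exactly as
    the index is defined (distinct from AA's natural log).
    """
    if method == "LCL":
        return float(dec.lcl)
    car = float(len(dec.cn) * dec.lcl)
    if method == "CAR":
        return car
    if method == "CAA":
        return sum(dec.ilcl[i] / math.log2(dec.degree_of(i)) for i in dec.cn)
    if method == "CRA":
        return sum(dec.ilcl[i] / dec.degree_of(i) for i in dec.cn)
    if method == "CPA":
        nx_, ny_ = dec.nlcl_x, dec.nlcl_y
        return nx_ * ny_ + nx_ * car + ny_ * car + car * car
    if method == "CJC":
        return car / _union_size(dec, deg_x, deg_y) if car else 0.0
    raise ValueError(f"unknown LCP method: {method!r}")


def score_c_family(
    dec: NeighbourhoodDecomposition,
    method: str,
    exponent: int = 2,
) -> float:
    """Local-ring network-automaton score (C1, C1*, C2 or C2*) for one pair.

    C1 = Σ_i 1/(1 + eLCL(i)) rewards externally isolated communities;
    C2 = Σ_i [1 - 1/(1 + iLCL(i))] rewards internally dense ones. The
    starred variants divide by (nLCL(x) + nLCL(y))**exponent; with zero
    non-local-community links (maximal isolation, the most favourable
    case) the denominator is taken as 1 since the formula's penalty term
    vanishes.

    Parameters
    ----------
    exponent
        Denominator exponent of the starred variants, default 2 (the
        square introduces a cross-term 2·nLCL(x)·nLCL(y) penalising pairs
        where *both* seeds are rich in outward links).
    """
    if exponent < 1:
        raise ValueError(f"exponent must be >= 1, got {exponent}")
    if not dec.cn:
        return 0.0
    if method in ("C1", "C1star"):
        raw = sum(1.0 / (1 + dec.elcl[i]) for i in dec.cn)
    elif method in ("C2", "C2star"):
        raw = sum(1.0 - 1.0 / (1 + dec.ilcl[i]) for i in dec.cn)
    else:
        raise ValueError(f"unknown C-family method: {method!r}")
    if method in ("C1", "C2"):
        return raw
    denom_base = dec.nlcl_x + dec.nlcl_y
    if denom_base == 0:
        logger.debug(
            "pair (%s, %s): zero nLCL denominator, using 1", dec.seed_x, dec.seed_y
        )
        return raw
    return raw / denom_base**exponent


def score_pair(
    net: UndirectedNetwork,
    x: str,
    y: str,
    method: str,
    exponent: int = 2,
    aa_log_base: float | None = None,
    dec: NeighbourhoodDecomposition | None = None,
) -> float:
    """Score a single node pair with any of the 20 methods.

    The pair may be an existing edge (reliability) or absent (prediction).
    A precomputed decomposition can be passed to amortise repeated calls.
    """
    if method in BIO_BASELINE_METHODS:
        return score_bio_baseline(net, x, y, method)
    if dec is None:
        dec = decompose(net, x, y)
    if method in CLASSICAL_METHODS:
        return score_classical(dec, net.degree(x), net.degree(y), method, aa_log_base)
    if method in LCP_METHODS:
        return score_lcp(dec, net.degree(x), net.degree(y), method)
    if method in C_FAMILY_METHODS:
        return score_c_family(dec, method, exponent)
    raise ValueError(
        f"unknown method: {method!r}; valid methods are {', '.join(ALL_METHODS)}"
    )


@dataclass(frozen=True)
class EdgeScoreTable:
    """Per-edge scores and deterministic reliability rankings.

    ``table`` has one row per edge (columns ``node_u``, ``node_v``, one
    score column per method and one ``<method>_rank`` column, rank 1 =
    most reliable). Ties break by lexicographic (min-node, max-node) edge
    identifier so rankings are bit-reproducible. IG1 ranks by increasing
    raw value; every other method by decreasing score.
    """

    table: pd.DataFrame
    methods: tuple[str, ...]

    @property
    def edges(self) -> list[tuple[str, str]]:
        return list(zip(self.table["node_u"], self.table["node_v"]))

    def scores(self, method: str) -> pd.Series:
        return self.table[method]

    def ranking(self, method: str) -> list[tuple[str, str]]:
        """Edges in decreasing order of reliability under ``method``."""
        order = self.table[f"{method}_rank"].sort_values().index
        sub = self.table.loc[order]
        return list(zip(sub["node_u"], sub["node_v"]))

    def to_tsv(self, dest) -> None:
        self.table.to_csv(dest, sep="\t", index=False)


def rank_edges(
    net: UndirectedNetwork,
    methods: Sequence[str] | str = "all",
    exponent: int = 2,
    aa_log_base: float | None = None,
) -> EdgeScoreTable:
    """Score every existing edge of ``net`` with each requested method.

    Parameters
    ----------
    methods
        Method names, or ``"all"`` for all 20.

    Raises
    ------
    ValueError
        On an unknown method name or a network with zero edges.
    """
    if isinstance(methods, str):
        methods = ALL_METHODS if methods == "all" else (methods,)
    methods = tuple(methods)
    if not methods:
        raise ValueError("methods list must be non-empty")
    unknown = [m for m in methods if m not in ALL_METHODS]
    if unknown:
        raise ValueError(
            f"unknown methods: {unknown}; valid methods are {', '.join(ALL_METHODS)}"
        )
    if net.n_edges == 0:
        raise ValueError("network has no edges to rank")

    rows: dict[str, list] = {"node_u": [], "node_v": []}
    for m in methods:
        rows[m] = []
    for u, v in net.edges:
        dec = decompose(net, u, v)
        rows["node_u"].append(u)
        rows["node_v"].append(v)
        for m in methods:
            rows[m].append(score_pair(net, u, v, m, exponent, aa_log_base, dec=dec))
    table = pd.DataFrame(rows)
    for m in methods:
        ascending = m in ASCENDING_METHODS
        order = sorted(
            table.index,
            key=lambda idx: (
                table.at[idx, m] if ascending else -table.at[idx, m],
                table.at[idx, "node_u"],
                table.at[idx, "node_v"],
            ),
        )
        ranks = pd.Series(0, index=table.index, dtype=int)
        ranks.loc[order] = range(1, len(order) + 1)
        table[f"{m}_rank"] = ranks
    return EdgeScoreTable(table=table, methods=methods)
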