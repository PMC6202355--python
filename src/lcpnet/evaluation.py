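"""Conservative GO-similarity-based evaluation of reliability rankings.

Ground truth comes from precomputed GO semantic-similarity matrices (e.g.
Wang similarity, values in [0, 1]), one per GO category. The conservative
combined label takes, for each interaction, the *minimum* of its biological
process (BP) and cellular component (CC) similarities and calls the
interaction true only when that minimum is strictly above 0.5 -- i.e. the
two proteins must share both process and compartment. Molecular function
is deliberately excluded from the combined label: two proteins with the
same molecular function (two kinases, say) need not interact.

A ranking is then summarised by three scalars:

* **AUP** -- mean of the precision curve sampled every ``step`` ranks;
* **sAUR** -- twice the area under the recall curve over the first P ranks
  (P = number of positives, x-axis normalised by P, trapezoids from the
  origin); a perfect ranking gives exactly sAUR = 1;
* **AUPR** -- area under the precision-recall curve, computed as average
  precision over the positive ranks.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .graph_core import UndirectedNetwork
from .indices import rank_edges

logger = logging.getLogger(__name__)

__all__ = [
    "SimilarityChannel",
    "EvaluationCurves",
    "combine_channels",
    "label_edges",
    "precision_curve",
    "recall_curve",
    "aupr",
    "evaluate_ranking",
    "benchmark",
]

CHANNEL_TAGS = ("BP", "CC", "MF", "combined")


class SimilarityChannel:
    """Symmetric per-node-pair similarity matrix in [0, 1] for one GO category.

    Parameters
    ----------
    nodes
        Node identifiers; stored sorted.
    matrix
        Square matrix aligned with the sorted node order. Must be
        symmetric with values in [0, 1]; the diagonal is ignored.
    tag
        One of ``BP``, ``CC``, ``MF`` or ``combined``.
    """

    def __init__(self, nodes: Iterable[str], matrix: np.ndarray, tag: str) -> None:
        if tag not in CHANNEL_TAGS:
            raise ValueError(f"tag must be one of {CHANNEL_TAGS}, got {tag!r}")
        order = sorted(str(n) for n in nodes)
        mat = np.asarray(matrix, dtype=float)
        if mat.shape != (len(order), len(order)):
            raise ValueError(
                f"matrix shape {mat.shape} does not match {len(order)} nodes"
            )
        if not np.allclose(mat, mat.T):
            raise ValueError("similarity matrix must be symmetric")
        off_diag = mat[~np.eye(len(order), dtype=bool)]
        if off_diag.size and (off_diag.min() < 0 or off_diag.max() > 1):
            raise ValueError("similarity values must lie in [0, 1]")
        self.nodes: tuple[str, ...] = tuple(order)
        self._index = {n: i for i, n in enumerate(order)}
        self.matrix = mat
        self.tag = tag

    def value(self, u: str, v: str) -> float:
        try:
            return float(self.matrix[self._index[u], self._index[v]])
        except KeyError as exc:
            raise KeyError(f"pair ({u!r}, {v!r}) not covered by channel: {exc}") from exc

    @classmethod
    def from_edge_values(
        cls,
        nodes: Iterable[str],
        edge_values: dict[tuple[str, str], float],
        tag: str,
    ) -> "SimilarityChannel":
        """Build a channel from sparse per-edge values (missing pairs = 0)."""
        order = sorted(str(n) for n in nodes)
        idx = {n: i for i, n in enumerate(order)}
        mat = np.zeros((len(order), len(order)))
        for (u, v), s in edge_values.items():
            mat[idx[u], idx[v]] = s
            mat[idx[v], idx[u]] = s
        return cls(order, mat, tag)

    # -- I/O: dense CSV keyed by labels, or TSV triples --------------------

    def write_csv(self, dest) -> None:
        pd.DataFrame(self.matrix, index=self.nodes, columns=self.nodes).to_csv(dest)

    @classmethod
    def read_csv(cls, source, tag: str) -> "SimilarityChannel":
        df = pd.read_csv(source, index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        if list(df.index) != list(df.columns):
            raise ValueError("channel CSV must have identical row and column labels")
        return cls(df.index, df.loc[sorted(df.index), sorted(df.index)].to_numpy(), tag)

    @classmethod
    def read_triples(cls, source, tag: str) -> "SimilarityChannel":
        df = pd.read_csv(source, sep="\t", header=None, names=["u", "v", "value"])
        values = {
            (str(r.u), str(r.v)): float(r.value) for r in df.itertuples(index=False)
        }
        nodes = {n for pair in values for n in pair}
        return cls.from_edge_values(nodes, values, tag)


def combine_channels(bp: SimilarityChannel, cc: SimilarityChannel) -> SimilarityChannel:
    """Element-wise minimum of the BP and CC channels (tag ``combined``).

    An interaction is only as well supported as its weaker channel: the
    minimum requires shared biological process *and* cellular component.

    Raises
    ------
    ValueError
        If the two channels cover different node sets.
    """
    if bp.nodes != cc.nodes:
        raise ValueError("channels cover different node sets")
    return SimilarityChannel(bp.nodes, np.minimum(bp.matrix, cc.matrix), "combined")


def label_edges(
    channel: SimilarityChannel,
    edges: Sequence[tuple[str, str]],
    threshold: float = 0.5,
) -> np.ndarray:
    """Boolean reliability labels: similarity strictly above ``threshold``.

    The inequality is strict: a similarity of exactly 0.5 is *not*
    reliable under the default threshold.

    Raises
    ------
    KeyError
        Naming the first edge whose endpoints the channel does not cover.
    """
    labels = np.empty(len(edges), dtype=bool)
    for k, (u, v) in enumerate(edges):
        labels[k] = channel.value(u, v) > threshold
    return labels


@dataclass(frozen=True)
class EvaluationCurves:
    """Precision and recall curves for one ranking, plus scalar summaries."""

    precision_ranks: np.ndarray
    precision: np.ndarray
    recall_x: np.ndarray
    recall: np.ndarray
    aup: float
    aur: float
    saur: float
    aupr: float
    step: int


def precision_curve(
    ranked_labels: Sequence[bool] | np.ndarray,
    step: int = 10,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Precision sampled every ``step`` ranks, and its mean (AUP).

    Precision of the first ``step`` ranked interactions makes the first
    point, of the first ``2·step`` the second, and so on to the end of the
    list (a final partial window is included). AUP is the arithmetic mean
    of the points.

    Returns
    -------
    ranks, precision, aup
    """
    labels = np.asarray(ranked_labels, dtype=bool)
    if labels.size == 0:
        raise ValueError("ranked label sequence is empty")
    if step < 1:
        raise ValueError("step must be >= 1")
    if step > labels.size:
        logger.warning(
            "step %d exceeds list length %d: single precision point", step, labels.size
        )
    ranks = np.arange(step, labels.size + 1, step)
    if ranks.size == 0 or ranks[-1] != labels.size:
        ranks = np.append(ranks, labels.size)
    cum_tp = np.cumsum(labels)
    precision = cum_tp[ranks - 1] / ranks
    return ranks, precision, float(precision.mean())


def recall_curve(
    ranked_labels: Sequence[bool] | np.ndarray,
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Recall over the first P ranks (P = total positives), AUR and sAUR.

    Recall at rank k is TP(k)/P, evaluated for k = 1..P with the x-axis
    normalised to k/P; the area (AUR) is trapezoidal from the origin
    (0, 0). A ranking that places all P positives first traces recall(k) =
    k/P and yields AUR = 0.5 exactly, the best attainable, so sAUR = 2·AUR
    rescales to [0, 1].

    Returns
    -------
    x, recall, aur, saur

    Raises
    ------
    ValueError
        If no label is positive (recall undefined).
    """
    labels = np.asarray(ranked_labels, dtype=bool)
    p = int(labels.sum())
    if p == 0:
        raise ValueError("recall curve undefined: no positive labels")
    cum_tp = np.cumsum(labels[:p])
    recall = cum_tp / p
    x = np.arange(1, p + 1) / p
    aur = float(np.trapezoid(np.concatenate(([0.0], recall)), np.concatenate(([0.0], x))))
    return x, recall, aur, 2.0 * aur


def aupr(ranked_labels: Sequence[bool] | np.ndarray) -> float:
    """Area under the precision-recall curve via average precision.

    Mean of precision@k over the ranks k holding a positive label -- the
    standard non-interpolated estimator, monotone under ranking
    improvements.

    Raises
    ------
    ValueError
        If no label is positive.
    """
    labels = np.asarray(ranked_labels, dtype=bool)
    if not labels.any():
        raise ValueError("AUPR undefined: no positive labels")
    ranks = np.arange(1, labels.size + 1)
    precision_at_k = np.cumsum(labels) / ranks
    return float(precision_at_k[labels].mean())


def evaluate_ranking(
    ranked_labels: Sequence[bool] | np.ndarray,
    step: int = 10,
) -> EvaluationCurves:
    """All curves and summaries (AUP, AUR, sAUR, AUPR) for one ranking."""
    p_ranks, prec, aup = precision_curve(ranked_labels, step)
    r_x, rec, aur, saur = recall_curve(ranked_labels)
    return EvaluationCurves(
        precision_ranks=p_ranks,
        precision=prec,
        recall_x=r_x,
        recall=rec,
        aup=aup,
        aur=aur,
        saur=saur,
        aupr=aupr(ranked_labels),
        step=step,
    )


def benchmark(
    net: UndirectedNetwork,
    methods: Sequence[str] | str,
    truth: Sequence[bool] | np.ndarray,
    step: int = 10,
    exponent: int = 2,
) -> pd.DataFrame:
    """Rank the network's edges with each method and evaluate against truth.

    Parameters
    ----------
    truth
        Boolean labels aligned with ``net.edges`` (lexicographic edge
        order).

    Returns
    -------
    DataFrame indexed by method with columns AUP, sAUR, AUPR and per-metric
    rank columns (1 = best). Deterministic given inputs.
    """
    truth = np.asarray(truth, dtype=bool)
    if truth.size != net.n_edges:
        raise ValueError(
            f"{truth.size} labels for {net.n_edges} edges: truth must align with net.edges"
        )
    label_of = dict(zip(net.edges, truth))
    table = rank_edges(net, methods, exponent=exponent)
    rows = {}
    for m in table.methods:
        ranked = [label_of[e] for e in table.ranking(m)]
        curves = evaluate_ranking(ranked, step)
        rows[m] = {"AUP": curves.aup, "sAUR": curves.saur, "AUPR": curves.aupr}
    df = pd.DataFrame.from_dict(rows, orient="index")
    for col in ("AUP", "sAUR", "AUPR"):
        df[f"{col}_rank"] = df[col].rank(ascending=False, method="min").astype(int)
    return df
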