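"""Phase III: condition-specific correlation-weighted PPI networks.

The PPI scaffold is restricted to the genes kept by the information-gain
filter; genes left without any edge are removed (their count is logged).
For each of the two conditions, every retained edge is weighted by the
Pearson correlation (c.c.) of its endpoint genes across that condition's
samples.  Each edge carries:

    cc        Pearson correlation in [-1, 1]
    affinity  |cc|  (connection strength; used for eigenvector centrality)
    distance  1 - |cc|  (dissimilarity; used for shortest paths)

The two condition networks share exactly the same nodes and edges and
differ only in these weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .errors import DiceInputError, EmptyResultError
from .io import EdgeList, ExpressionMatrix

logger = logging.getLogger("dice")

__all__ = ["ConditionNetwork", "condition_correlations", "build_weighted_networks"]


@dataclass
class ConditionNetwork:
    """One condition's weighted PPI network.

    ``graph`` is an undirected :class:`networkx.Graph` whose edges carry
    ``cc``, ``affinity`` and ``distance`` attributes.
    """

    condition: str
    graph: nx.Graph

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def condition_correlations(
    matrix: ExpressionMatrix,
    genes: set[str],
    edges: EdgeList,
    condition: str,
) -> dict[tuple[str, str], float]:
    """Pearson correlation per retained edge, within one condition's samples.

    Edges are retained when both endpoints are in ``genes``.  A correlation
    that is undefined because one endpoint has zero variance within the
    condition is set to 0 (distance 1); the number of such edges is logged.
    """
    samples = matrix.samples_of(condition)
    if len(samples) < 3:
        raise DiceInputError(
            f"condition {condition!r} has {len(samples)} samples; >= 3 required "
            "for correlation estimation"
        )
    pairs = [
        (a, b) for a, b in edges.pairs()
        if a in genes and b in genes and a in matrix.values.index and b in matrix.values.index
    ]
    used_genes = sorted({g for p in pairs for g in p})
    x = matrix.values.loc[used_genes, samples].to_numpy(dtype=float)
    x = x - x.mean(axis=1, keepdims=True)
    norms = np.sqrt((x ** 2).sum(axis=1))
    row = {g: i for i, g in enumerate(used_genes)}
    cc: dict[tuple[str, str], float] = {}
    n_degenerate = 0
    for a, b in pairs:
        i, j = row[a], row[b]
        denom = norms[i] * norms[j]
        if denom == 0:
            cc[(a, b)] = 0.0
            n_degenerate += 1
        else:
            r = float(np.dot(x[i], x[j]) / denom)
            cc[(a, b)] = float(np.clip(r, -1.0, 1.0))
    if n_degenerate:
        logger.warning(
            "condition %r: %d edge(s) with a zero-variance endpoint; cc set to 0",
            condition, n_degenerate,
        )
    return cc


def build_weighted_networks(
    edges: EdgeList,
    kept_genes: set[str],
    matrix: ExpressionMatrix,
) -> tuple[ConditionNetwork, ConditionNetwork]:
    """Build the two condition-specific weighted networks.

    The edge set is the PPI edges with both endpoints among ``kept_genes``;
    genes with no retained edge are dropped (count logged).  The returned
    networks have identical topology and per-condition ``cc`` /
    ``affinity`` / ``distance`` edge weights.
    """
    c1, c2 = matrix.conditions  # type: ignore[misc]
    present = kept_genes & set(matrix.values.index)
    retained = [(a, b) for a, b in edges.pairs() if a in present and b in present]
    if not retained:
        raise EmptyResultError(
            "no PPI edges connect the information-gain-retained genes"
        )
    connected = {g for p in retained for g in p}
    n_dropped = len(present) - len(connected)
    if n_dropped:
        logger.info(
            "phase3: excluding %d gene(s) that lack connections; %d genes, %d edges remain",
            n_dropped, len(connected), len(retained),
        )
    cc1 = condition_correlations(matrix, connected, edges, c1)
    cc2 = condition_correlations(matrix, connected, edges, c2)

    nets = []
    for cond, cc in ((c1, cc1), (c2, cc2)):
        g = nx.Graph()
        g.add_nodes_from(sorted(connected))
        for (a, b) in retained:
            r = cc[(a, b)]
            g.add_edge(a, b, cc=r, affinity=abs(r), distance=1.0 - abs(r))
        nets.append(ConditionNetwork(condition=cond, graph=g))
    return nets[0], nets[1]
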