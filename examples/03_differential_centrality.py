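"""Differential centrality on a small two-condition network.

Builds the same 6-gene interaction graph under two conditions, weakens one
hub's correlations in the second condition (network rewiring), and shows
how its weighted betweenness and eigenvector centrality shift while every
other gene barely moves.
"""

import networkx as nx

from dice.centrality import centrality_table
from dice.network import ConditionNetwork


def build(condition, hub_cc):
    """Star around HUB plus a peripheral triangle; hub_cc sets the
    correlation of the hub's edges in this condition."""
    g = nx.Graph()
    edges = [
        ("HUB", "A", hub_cc), ("HUB", "B", hub_cc), ("HUB", "C", hub_cc),
        ("A", "B", 0.5), ("C", "D", 0.6), ("D", "E", 0.6), ("C", "E", 0.6),
    ]
    for u, v, cc in edges:
        g.add_edge(u, v, cc=cc, affinity=abs(cc), distance=1 - abs(cc))
    return ConditionNetwork(condition=condition, graph=g)


net_control = build("control", hub_cc=0.8)   # hub tightly co-expressed
net_case = build("case", hub_cc=0.1)         # hub's correlations collapse

table = centrality_table(net_control, net_case)
print(table.round(4))

print(
    "\nHUB's eigenvector centrality collapses in the case network and its "
    "betweenness drops too (see the delta columns); the triangle genes "
    "keep their roles. Differential centrality flags exactly this kind of "
    "gene."
)
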