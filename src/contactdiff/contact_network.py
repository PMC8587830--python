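"""The alpha-carbon contact graph and betweenness centrality.

Residues become nodes (placed at their CA atoms) and contacts become
undirected, unweighted edges.  The betweenness centrality of a node x
is the sum, over unordered node pairs {u, v} with u != x != v, of the
fraction of shortest u-v paths that pass through x; disconnected pairs
contribute 0 and values are left unnormalised.  Residues with high
betweenness mediate many shortest communication paths through the
structure and are prioritised when selecting mutation sites.

Betweenness is computed with Brandes' dependency-accumulation
algorithm (O(VE) for unweighted graphs).
"""

from __future__ import annotations

import dataclasses
import math
from collections import deque
from typing import Iterable

import networkx as nx
import pandas as pd

from .contact_map import ContactMap, MissingAtomError
from .structure_io import StructureModel

__all__ = [
    "BetweennessResult",
    "build_graph",
    "betweenness",
    "brandes_betweenness",
    "top_percentile",
]


def build_graph(cm: ContactMap, s: StructureModel) -> nx.Graph:
    """One node per polymer residue (CA position attached), one edge per contact."""
    missing = [
        f"{r.name3} {r.author_number}"
        for r in s.polymer
        if r.get_atom("CA") is None
    ]
    if missing:
        raise MissingAtomError(f"{s.id}: residues without CA atom: {', '.join(missing)}")
    g = nx.Graph()
    for idx, r in enumerate(s.polymer, start=1):
        g.add_node(idx, ca=tuple(r.get_atom("CA").coord), aa=r.aa1)
    for i, j in cm.contacts:
        if i != j:
            g.add_edge(i, j)
    return g


def brandes_betweenness(nodes: Iterable, adjacency: dict) -> dict:
    """Unnormalised betweenness over unordered pairs, endpoints excluded.

    ``adjacency`` maps node -> iterable of neighbours.  Standard Brandes
    accumulation; the ordered-pair total is halved for an undirected
    graph.
    """
    nodes = list(nodes)
    bc = {v: 0.0 for v in nodes}
    for source in nodes:
        stack: list = []
        preds: dict = {v: [] for v in nodes}
        sigma = {v: 0.0 for v in nodes}
        dist = {v: -1 for v in nodes}
        sigma[source] = 1.0
        dist[source] = 0
        queue = deque([source])
        while queue:
            v = queue.popleft()
            stack.append(v)
            for w in adjacency.get(v, ()):
                if dist[w] < 0:
                    dist[w] = dist[v] + 1
                    queue.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    preds[w].append(v)
        delta = {v: 0.0 for v in nodes}
        while stack:
            w = stack.pop()
            for v in preds[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != source:
                bc[w] += delta[w]
    return {v: b / 2.0 for v, b in bc.items()}


@dataclasses.dataclass
class BetweennessResult:
    bc: dict  # node -> unnormalised betweenness
    percentile: dict  # node -> percentile rank in [0, 100]

    def frame(self, graph: nx.Graph | None = None) -> pd.DataFrame:
        rows = []
        for node in sorted(self.bc):
            row = {"node": node, "bc": self.bc[node], "percentile": self.percentile[node]}
            if graph is not None:
                row["degree"] = graph.degree[node]
            rows.append(row)
        return pd.DataFrame(rows)


def betweenness(g: nx.Graph) -> BetweennessResult:
    """Betweenness of every node plus its percentile rank.

    Percentile rank of x = 100 * (#nodes with BC <= BC(x)) / #nodes, so
    the highest-BC nodes rank at 100.
    """
    adjacency = {v: list(g.neighbors(v)) for v in g.nodes}
    bc = brandes_betweenness(g.nodes, adjacency)
    n = len(bc)
    values = sorted(bc.values())
    import bisect

    percentile = {
        v: 100.0 * bisect.bisect_right(values, bc[v]) / n for v in bc
    }
    return BetweennessResult(bc=bc, percentile=percentile)


def top_percentile(result: BetweennessResult, fraction: float = 0.10) -> set:
    """The ceil(fraction * n) highest-BC nodes; boundary ties all included."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    n = len(result.bc)
    if n == 0:
        return set()
    k = math.ceil(fraction * n)
    ranked = sorted(result.bc.items(), key=lambda kv: -kv[1])
    threshold = ranked[k - 1][1]
    return {v for v, b in result.bc.items() if b >= threshold}
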