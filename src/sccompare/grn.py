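"""Signed regulatory subnetworks, degree hubs and perturbagen scoring.

A subnetwork is induced on a DEG category's genes plus every prior regulator
with at least one target in the category.  Two rankings are produced:

* **hubs** — total (in+out) degree, the simple topological centrality;
* **perturbagens** — for a candidate node, the predicted influence sign on
  each DEG-carrying node is the product of edge signs along shortest directed
  paths (nodes whose equal-length shortest paths disagree in sign are excluded
  as ambiguous).  Modulating the candidate in direction ``d`` (+1 activation,
  -1 inhibition) is predicted to *reverse* a target whose observed sign equals
  ``-d * influence``; the perturbagen score is the larger reversal count over
  the two modulation directions (ties resolved to inhibition, the
  pharmacologically common mode).
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd


@dataclass
class SignedGRN:
    """Directed signed graph plus observed DEG signs on (some) nodes."""

    graph: nx.DiGraph
    deg_signs: dict[str, int] = field(default_factory=dict)

    @property
    def is_empty(self) -> bool:
        return self.graph.number_of_nodes() == 0

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"regulator": u, "target": v, "sign": d["sign"]}
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["regulator", "target", "sign"])


def build_subnetwork(
    genes_in_category: set[str] | list[str],
    prior_edges: pd.DataFrame,
    deg_signs: dict[str, int] | None = None,
) -> SignedGRN:
    """Induce the signed subnetwork on category genes plus their regulators.

    Self-loops are dropped; parallel edges collapse to their common sign, or
    are dropped entirely (with a warning) when duplicated with conflicting
    signs.
    """
    if prior_edges is None or len(prior_edges) == 0:
        raise ValueError("prior edge list is empty")
    category = set(genes_in_category)
    regulators = set(
        prior_edges.loc[prior_edges["target"].isin(category), "regulator"]
    )
    nodes = category | regulators

    edge_signs: dict[tuple[str, str], int] = {}
    conflicted: set[tuple[str, str]] = set()
    for row in prior_edges.itertuples(index=False):
        u, v, s = row.regulator, row.target, int(row.sign)
        if u == v or u not in nodes or v not in nodes:
            continue
        key = (u, v)
        if key in edge_signs and edge_signs[key] != s:
            conflicted.add(key)
        edge_signs.setdefault(key, s)
    if conflicted:
        warnings.warn(f"dropped {len(conflicted)} sign-conflicting edges")
        for key in conflicted:
            edge_signs.pop(key, None)

    g = nx.DiGraph()
    for (u, v), s in edge_signs.items():
        g.add_edge(u, v, sign=s)
    g.remove_nodes_from([n for n in list(g.nodes) if g.degree(n) == 0])
    signs = {
        n: int(s) for n, s in (deg_signs or {}).items() if n in g and s != 0
    }
    return SignedGRN(graph=g, deg_signs=signs)


def degree_rank(grn: SignedGRN) -> list[tuple[str, int]]:
    """Nodes by total connection count, descending; ties alphabetical."""
    if grn.is_empty:
        raise ValueError("network is empty")
    return sorted(grn.graph.degree(), key=lambda kv: (-kv[1], kv[0]))


def _shortest_path_signs(
    graph: nx.DiGraph, source: str, max_depth: int
) -> dict[str, set[int]]:
    """BFS sign products along shortest directed paths from ``source``.

    Returns, for each node within ``max_depth``, the set of sign products
    realized by its shortest paths ({+1}, {-1}, or {+1,-1} when ambiguous).
    """
    dist = {source: 0}
    signs: dict[str, set[int]] = {source: {1}}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        if dist[u] >= max_depth:
            continue
        for v in graph.successors(u):
            s_uv = graph[u][v]["sign"]
            new = {s * s_uv for s in signs[u]}
            if v not in dist:
                dist[v] = dist[u] + 1
                signs[v] = set(new)
                queue.append(v)
            elif dist[v] == dist[u] + 1:
                signs[v] |= new
    signs.pop(source, None)
    return signs


def perturbagen_score(
    grn: SignedGRN, candidate: str, max_depth: int = 5
) -> tuple[int, int]:
    """Count of downstream DEGs whose observed change the candidate can
    reverse; returns ``(score, modulation_direction)``."""
    if candidate not in grn.graph:
        raise ValueError(f"candidate {candidate!r} not in network")
    reach = _shortest_path_signs(grn.graph, candidate, max_depth)
    n_rev_inhibit = 0  # d = -1 reverses targets with influence == observed
    n_rev_activate = 0  # d = +1 reverses targets with influence == -observed
    for node, sign_set in reach.items():
        obs = grn.deg_signs.get(node)
        if obs is None or len(sign_set) != 1:
            continue
        (infl,) = sign_set
        if infl == obs:
            n_rev_inhibit += 1
        else:
            n_rev_activate += 1
    if n_rev_activate > n_rev_inhibit:
        return n_rev_activate, 1
    return n_rev_inhibit, -1


def rank_perturbagens(grn: SignedGRN, max_depth: int = 5) -> pd.DataFrame:
    """All nodes with positive perturbagen score, ranked descending (ties by
    degree, then name); columns ``node, score, direction, degree``."""
    if grn.is_empty:
        raise ValueError("network is empty")
    degree = dict(grn.graph.degree())
    rows = []
    for node in grn.graph.nodes:
        score, direction = perturbagen_score(grn, node, max_depth=max_depth)
        if score > 0:
            rows.append(
                {"node": node, "score": score, "direction": direction,
                 "degree": degree[node]}
            )
    out = pd.DataFrame(rows, columns=["node", "score", "direction", "degree"])
    if len(out):
        out = out.sort_values(
            ["score", "degree", "node"], ascending=[False, False, True],
            kind="mergesort",
        ).reset_index(drop=True)
    return out
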