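"""Contact-correlation network and betweenness-centrality ranking.

Residues become nodes; an edge joins residues whose representative mDCC is at
least ``mdcc_threshold`` (default 0.5) *and* whose maximizing mode pair has
center distance below ``distance_threshold`` (default 5 A) — a highly
positive correlation through an actual atomic contact.  An edge is flagged
*transient* when the companion conventional DCC falls below the threshold
while the mDCC passes it: an interaction formed only during part of the
trajectory, invisible to the conventional analysis.

Node importance is measured by betweenness centrality

    g(i) = sum over unordered pairs {s, t} (s, t != i) of sigma_st(i) / sigma_st,

where sigma_st counts shortest paths between s and t and sigma_st(i) those
passing through i.  Paths are unweighted (edges are thresholded, not
weighted); pairs in different components contribute nothing.  The
computation is Brandes' linear-time dependency accumulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ParameterError
from .mdcc import ModePairCorrelation, ResidueCorrelationMatrix

__all__ = [
    "CorrelationNetwork",
    "build_network",
    "betweenness",
    "top_betweenness",
    "export_edges_tsv",
    "export_graphml",
]


@dataclass
class CorrelationNetwork:
    """Residue nodes, thresholded contact-correlation edges, betweenness.

    ``graph`` is an undirected networkx graph whose nodes are residue labels
    (``chain:resseq:resname``) carrying ``molecule`` and ``order`` attributes;
    edges carry ``mdcc``, ``distance``, ``transient`` and provenance ids.
    """

    graph: nx.Graph
    mdcc_threshold: float
    distance_threshold: float
    node_order: list[str]
    betweenness_values: dict[str, float] | None = None

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges(self) -> list[tuple[str, str, dict]]:
        return [(a, b, dict(d)) for a, b, d in self.graph.edges(data=True)]


def build_network(
    matrix: ResidueCorrelationMatrix,
    mdcc_threshold: float = 0.5,
    distance_threshold: float = 5.0,
    edge_rule: str = "provenance",
) -> CorrelationNetwork:
    """Build the contact-correlation network from a residue matrix.

    ``edge_rule='provenance'`` (default) applies both thresholds to the
    maximizing (provenance) mode pair of each cell.  ``edge_rule='any'``
    accepts a pair if *any* rare-pair-filtered mode pair jointly passes both
    thresholds; this needs a matrix built with ``store_candidates=True``.
    Self-pairs are never edges.  An empty edge set is valid.
    """
    if edge_rule not in ("provenance", "any"):
        raise ParameterError(f"unknown edge rule {edge_rule!r}")
    if edge_rule == "any" and matrix.candidates is None:
        raise ParameterError(
            "edge_rule='any' requires a matrix built with store_candidates=True"
        )

    g = nx.Graph()
    for order, (label, mol) in enumerate(zip(matrix.labels, matrix.molecules)):
        g.add_node(label, molecule=mol, order=order)

    R = matrix.n_residues
    for a in range(R):
        for b in range(a + 1, R):
            if edge_rule == "provenance":
                prov = matrix.provenance.get((a, b))
                if prov is None:
                    continue
                ok = (
                    prov.mdcc_value >= mdcc_threshold
                    and prov.center_distance < distance_threshold
                )
                chosen = prov
            else:
                passing = [
                    c
                    for c in matrix.candidates.get((a, b), [])
                    if c.mdcc_value >= mdcc_threshold
                    and c.center_distance < distance_threshold
                ]
                ok = bool(passing)
                chosen = (
                    max(passing, key=lambda c: c.mdcc_value) if passing else None
                )
            if not ok:
                continue
            companion_dcc = matrix.dcc[a, b]
            transient = bool(
                (np.isnan(companion_dcc) or companion_dcc < mdcc_threshold)
                and chosen.mdcc_value >= mdcc_threshold
            )
            g.add_edge(
                matrix.labels[a],
                matrix.labels[b],
                mdcc=float(chosen.mdcc_value),
                dcc=float(companion_dcc) if np.isfinite(companion_dcc) else float("nan"),
                distance=float(chosen.center_distance),
                transient=transient,
                atom_i=int(chosen.atom_i),
                atom_j=int(chosen.atom_j),
                mode_k=int(chosen.mode_k),
                mode_l=int(chosen.mode_l),
            )
    return CorrelationNetwork(
        graph=g,
        mdcc_threshold=mdcc_threshold,
        distance_threshold=distance_threshold,
        node_order=list(matrix.labels),
    )


def _brandes_betweenness(g: nx.Graph) -> dict:
    """Unweighted betweenness over unordered pairs (Brandes accumulation)."""
    bet = {v: 0.0 for v in g.nodes}
    for s in g.nodes:
        stack: list = []
        pred: dict = {v: [] for v in g.nodes}
        sigma = {v: 0.0 for v in g.nodes}
        dist = {v: -1 for v in g.nodes}
        sigma[s] = 1.0
        dist[s] = 0
        queue = [s]
        head = 0
        while head < len(queue):
            v = queue[head]
            head += 1
            stack.append(v)
            for w in g.neighbors(v):
                if dist[w] < 0:
                    dist[w] = dist[v] + 1
                    queue.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    pred[w].append(v)
        delta = {v: 0.0 for v in g.nodes}
        while stack:
            w = stack.pop()
            for v in pred[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                bet[w] += delta[w]
    # each unordered pair {s, t} was accumulated from both endpoints
    return {v: b / 2.0 for v, b in bet.items()}


def betweenness(network: CorrelationNetwork) -> dict[str, float]:
    """Betweenness g(i) per node; results are cached on the network."""
    values = _brandes_betweenness(network.graph)
    network.betweenness_values = values
    return values


def top_betweenness(network: CorrelationNetwork, per_molecule: int = 15) -> pd.DataFrame:
    """Top-ranked residues by betweenness within each molecule.

    Returns a DataFrame with columns molecule, rank, residue, betweenness;
    ties are broken by node order, molecules with fewer residues give
    shorter lists.
    """
    values = network.betweenness_values or betweenness(network)
    order = {label: i for i, label in enumerate(network.node_order)}
    rows = []
    molecules = sorted({d["molecule"] for _, d in network.graph.nodes(data=True)})
    for mol in molecules:
        members = [
            n for n, d in network.graph.nodes(data=True) if d["molecule"] == mol
        ]
        members.sort(key=lambda n: (-values[n], order[n]))
        for rank, node in enumerate(members[:per_molecule], start=1):
            rows.append(
                {
                    "molecule": mol,
                    "rank": rank,
                    "residue": node,
                    "betweenness": values[node],
                }
            )
    return pd.DataFrame(rows, columns=["molecule", "rank", "residue", "betweenness"])


def export_edges_tsv(network: CorrelationNetwork, path) -> None:
    rows = [
        {
            "a": a,
            "b": b,
            "mdcc": d["mdcc"],
            "dcc": d["dcc"],
            "distance": d["distance"],
            "transient": d["transient"],
        }
        for a, b, d in network.graph.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["a", "b", "mdcc", "dcc", "distance", "transient"]).to_csv(
        path, sep="\t", index=False
    )


def export_graphml(network: CorrelationNetwork, path) -> None:
    nx.write_graphml(network.graph, path)
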