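"""Protein-protein interaction degree analysis and hub selection.

The pipeline consumes a STRING-style confidence-scored undirected edge list,
restricts it to the subnetwork induced by a gene set (e.g. one lamina's
uDEGs) at a confidence cutoff (default 0.4, the usual STRING medium-
confidence threshold), counts distinct interaction partners per gene, and
ranks hubs.  Graphs are simple and undirected throughout; degrees count
distinct partners, never multi-edges.
"""

from __future__ import annotations

import networkx as nx
import pandas as pd

from .errors import ParameterError


def induced_subnetwork(
    graph: nx.Graph, nodes: set[str], min_confidence: float = 0.4
) -> nx.Graph:
    """Subnetwork induced by ``nodes``, keeping edges at or above the cutoff.

    Both endpoints must lie in ``nodes`` and the edge confidence must be
    >= ``min_confidence``; edges without a recorded confidence are kept at
    any cutoff.  Nodes of the input graph that fall in ``nodes`` are
    retained even if isolated, so zero-degree genes stay visible.
    """
    if not 0 <= min_confidence <= 1:
        raise ParameterError(f"min_confidence must be in [0, 1], got {min_confidence}")
    sub = nx.Graph()
    sub.add_nodes_from(n for n in graph.nodes if n in nodes)
    for a, b, attrs in graph.edges(data=True):
        if a in nodes and b in nodes:
            conf = attrs.get("confidence")
            if conf is None or conf >= min_confidence:
                sub.add_edge(a, b, **attrs)
    return sub


def node_degrees(subnet: nx.Graph) -> pd.DataFrame:
    """Distinct-partner degree per node, sorted by descending degree then id.

    Satisfies the handshake identity: degrees sum to twice the edge count.
    """
    rows = [{"gene_id": n, "degree": d} for n, d in subnet.degree()]
    return pd.DataFrame(rows, columns=["gene_id", "degree"]).sort_values(
        ["degree", "gene_id"], ascending=[False, True], ignore_index=True
    )


def select_hubs(
    degrees: pd.DataFrame,
    top_k: int | None = None,
    min_degree: int | None = None,
) -> list[str]:
    """Ordered hub list by descending degree, gene id breaking ties.

    Exactly one of ``top_k`` / ``min_degree`` may be given, or both, in
    which case nodes meeting ``min_degree`` are returned capped at
    ``top_k``.
    """
    if top_k is None and min_degree is None:
        raise ParameterError("give top_k and/or min_degree")
    if top_k is not None and top_k <= 0:
        raise ParameterError(f"top_k must be positive, got {top_k}")
    ranked = degrees.sort_values(["degree", "gene_id"], ascending=[False, True])
    if min_degree is not None:
        ranked = ranked[ranked["degree"] >= min_degree]
    if top_k is not None:
        ranked = ranked.head(top_k)
    return list(ranked["gene_id"])
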