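"""Per-node topology metrics and hub identification.

Metrics are computed on the undirected simple graph underlying a protein
network: degree, betweenness (unnormalized shortest-path counting, equal
split across equal-length paths), local clustering coefficient (nodes of
degree < 2 score 0), and eigenvector centrality.  Eigenvector centrality
is computed separately on each connected component and scaled so the
largest value within a component is 1; isolated nodes get 0.  Disconnected
networks are therefore handled without special-casing by the caller.
"""

from __future__ import annotations

from typing import Union

import networkx as nx
import numpy as np
import pandas as pd

from .errors import NetworkError
from .network_builder import ProteinNetwork

__all__ = ["compute_topology", "find_hubs"]

HUB_RULES = ("degree_top_k", "degree_quantile")


def _as_graph(network: Union[ProteinNetwork, nx.Graph]) -> nx.Graph:
    return network.graph if isinstance(network, ProteinNetwork) else network


def _eigenvector_by_component(g: nx.Graph) -> dict[str, float]:
    values: dict[str, float] = {}
    for component in nx.connected_components(g):
        if len(component) == 1:
            values[next(iter(component))] = 0.0
            continue
        nodes = sorted(component)
        a = nx.to_numpy_array(g, nodelist=nodes)
        # leading eigenvector of the symmetric adjacency matrix; by
        # Perron-Frobenius it has one sign on a connected component
        w, v = np.linalg.eigh(a)
        vec = np.abs(v[:, int(np.argmax(w))])
        top = vec.max()
        for node, val in zip(nodes, vec):
            values[node] = float(val / top) if top > 0 else 0.0
    return values


def compute_topology(
    network: Union[ProteinNetwork, nx.Graph], normalized_betweenness: bool = False
) -> pd.DataFrame:
    """Per-node metric table, sorted by accession.

    Columns: ``degree``, ``betweenness``, ``clustering_coefficient``,
    ``eigenvector_centrality``.  Betweenness is unnormalized by default
    (raw shortest-path counts; each unordered pair counted once).
    """
    g = _as_graph(network)
    if g.number_of_nodes() == 0:
        raise NetworkError("cannot compute topology of an empty network")
    betweenness = nx.betweenness_centrality(g, normalized=normalized_betweenness)
    clustering = nx.clustering(g)
    eigen = _eigenvector_by_component(g)
    report = pd.DataFrame(
        {
            "degree": pd.Series(dict(g.degree), dtype=int),
            "betweenness": pd.Series(betweenness, dtype=float),
            "clustering_coefficient": pd.Series(clustering, dtype=float),
            "eigenvector_centrality": pd.Series(eigen, dtype=float),
        }
    ).sort_index()
    report.index.name = "accession"
    return report


def find_hubs(report: pd.DataFrame, rule: str, param: float) -> list[str]:
    """Select hub nodes from a topology report.

    ``degree_top_k`` takes the k highest-degree nodes (k clamped to the
    node count); ``degree_quantile`` takes every node whose degree is at or
    above the given quantile (in [0, 1]) of the degree distribution.
    Ordering is deterministic: degree descending, accession ascending on
    ties.
    """
    ordered = report.sort_values(
        by="degree", ascending=False, kind="mergesort"
    )
    # stable sort on descending degree; break ties on the index explicitly
    ordered = ordered.loc[
        sorted(ordered.index, key=lambda a: (-ordered.loc[a, "degree"], a))
    ]
    if rule == "degree_top_k":
        k = int(param)
        if k < 0:
            raise NetworkError(f"k must be non-negative, got {k}")
        return list(ordered.index[: min(k, len(ordered))])
    if rule == "degree_quantile":
        q = float(param)
        if not 0.0 <= q <= 1.0:
            raise NetworkError(f"quantile must be in [0, 1], got {q}")
        cut = float(np.quantile(report["degree"].to_numpy(dtype=float), q))
        return [a for a in ordered.index if report.loc[a, "degree"] >= cut]
    raise NetworkError(f"unknown hub rule {rule!r}; expected one of {HUB_RULES}")
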