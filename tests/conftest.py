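"""Shared fixtures: seeded synthetic corpora and independent oracles."""

from __future__ import annotations

import itertools
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from pathexnet.fixtures import FixtureSpec, generate_corpus, notch_like_fixture
from pathexnet.network_builder import ProteinNetwork


@pytest.fixture(scope="session")
def corpus(tmp_path_factory) -> tuple[Path, object]:
    """A default three-pathway seeded corpus (dir, ground truth)."""
    out = tmp_path_factory.mktemp("corpus")
    truth = generate_corpus(FixtureSpec(seed=7), out)
    return out, truth


@pytest.fixture(scope="session")
def notch_corpus(tmp_path_factory) -> tuple[Path, object]:
    """The deterministic 48-protein case-study corpus (dir, ground truth)."""
    out = tmp_path_factory.mktemp("notch")
    truth = notch_like_fixture(out)
    return out, truth


def random_protein_network(rng: np.random.Generator, n_max: int = 20) -> ProteinNetwork:
    """An in-memory random undirected protein network with full attributes."""
    n = int(rng.integers(3, n_max + 1))
    p = float(rng.uniform(0.1, 0.5))
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
    g = nx.relabel_nodes(g, {i: f"P{10000 + i}" for i in g.nodes})
    for node in g.nodes:
        g.nodes[node].update(
            gene_symbol=node, origin="local", state=None, score=None
        )
    for a, b in g.edges:
        g.edges[a, b].update(
            categories={"other"},
            pathway_ids={"hsa90001"},
            ppi_supported=False,
            display_category="other",
        )
    return ProteinNetwork(g, "local", "hsa90001")


def random_scores(
    rng: np.random.Generator, network: ProteinNetwork, na_fraction: float = 0.15
) -> pd.DataFrame:
    """Random [0, 1] scores for a network's nodes, some left unmeasured."""
    rows = {}
    for node in sorted(network.graph.nodes):
        if rng.uniform() < na_fraction:
            continue
        rows[node] = float(rng.uniform())
    return pd.DataFrame({"ctx": pd.Series(rows, dtype=float)})


# ------------------------------------------------------- topology oracles


def brute_force_betweenness(g: nx.Graph) -> dict:
    """Unnormalized betweenness by explicit enumeration of all shortest
    paths between every unordered node pair (even split across ties)."""
    bc = {v: 0.0 for v in g.nodes}
    nodes = list(g.nodes)
    for i, s in enumerate(nodes):
        for t in nodes[i + 1 :]:
            paths = _all_simple_paths(g, s, t)
            if not paths:
                continue
            shortest = min(len(p) for p in paths)
            sp = [p for p in paths if len(p) == shortest]
            for path in sp:
                for v in path[1:-1]:
                    bc[v] += 1.0 / len(sp)
    return bc


def _all_simple_paths(g: nx.Graph, s, t) -> list[list]:
    out: list[list] = []

    def walk(node, path):
        if node == t:
            out.append(path)
            return
        for nb in g.neighbors(node):
            if nb not in path:
                walk(nb, path + [nb])

    walk(s, [s])
    return out


def brute_force_clustering(g: nx.Graph) -> dict:
    """Local clustering by direct triangle counting; degree < 2 scores 0."""
    out = {}
    for v in g.nodes:
        nbrs = list(g.neighbors(v))
        k = len(nbrs)
        if k < 2:
            out[v] = 0.0
            continue
        links = sum(
            1 for a, b in itertools.combinations(nbrs, 2) if g.has_edge(a, b)
        )
        out[v] = 2.0 * links / (k * (k - 1))
    return out
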