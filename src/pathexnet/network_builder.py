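"""Construct local and global undirected protein networks from the store.

Two network scopes mirror the two views of a pathway corpus:

* the **local** network contains exactly the proteins and links of one
  canonical pathway;
* the **global** network adds, by one-hop expansion, every relation in the
  whole store that touches a local protein, together with the "external"
  partner proteins those relations introduce.  External nodes' own further
  neighbours are *not* pulled in — a transitive closure would rebuild the
  entire corpus interactome.

Edges are undirected and simple: parallel relations between the same pair
(e.g. an activation and an expression link) merge into one edge carrying a
category set, and a single ``display_category`` is chosen by the fixed
precedence activation > inhibition > expression > other (the order the
four classes are conventionally drawn in).

Physical-interaction evidence decorates edges (``ppi_supported``) rather
than adding edges, unless union mode is requested explicitly.

Networks export to GraphML (with full node/edge attributes, round-trip
safe), SIF, and sorted TSV node/edge tables — all loadable by Cytoscape.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Union

import networkx as nx

from .errors import NetworkError
from .pathway_store import CATEGORIES, Store, canonical_pair

__all__ = [
    "ProteinNetwork",
    "build_local",
    "build_global",
    "merge_ppi",
    "load_ppi_pairs",
    "export_network",
    "read_graphml",
    "display_category",
]

log = logging.getLogger(__name__)

EXPORT_FORMATS = ("graphml", "sif", "tsv")

_SET_SEP = ";"


def display_category(categories: Iterable[str]) -> str:
    """Pick the single category shown for a multi-category edge."""
    cats = set(categories)
    for cat in CATEGORIES:
        if cat in cats:
            return cat
    raise NetworkError(f"no known category among {sorted(cats)!r}")


@dataclass
class ProteinNetwork:
    """An undirected protein network over UniProt-accession nodes.

    Node attributes: ``gene_symbol`` (display only), ``origin``
    (``local``/``external``), ``state`` (``ON``/``OFF``/``NA`` or ``None``
    before an overlay), ``score`` (float or ``None``).
    Edge attributes: ``categories`` (non-empty set), ``pathway_ids`` (set),
    ``ppi_supported`` (bool), ``display_category``.
    """

    graph: nx.Graph
    scope: str  # "local" | "global"
    seed_pathway: str

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def edges(self) -> set[tuple[str, str]]:
        return {canonical_pair(a, b) for a, b in self.graph.edges}

    def copy(self) -> "ProteinNetwork":
        g = self.graph.copy()
        for _, _, data in g.edges(data=True):
            data["categories"] = set(data["categories"])
            data["pathway_ids"] = set(data["pathway_ids"])
        return ProteinNetwork(g, self.scope, self.seed_pathway)

    def equal(self, other: "ProteinNetwork") -> bool:
        """Structural + attribute equality (used by round-trip tests)."""
        if (self.scope, self.seed_pathway) != (other.scope, other.seed_pathway):
            return False
        if self.nodes() != other.nodes() or self.edges() != other.edges():
            return False
        for n in self.graph.nodes:
            if _norm_node(self.graph.nodes[n]) != _norm_node(other.graph.nodes[n]):
                return False
        for a, b in self.graph.edges:
            if _norm_edge(self.graph.edges[a, b]) != _norm_edge(other.graph.edges[a, b]):
                return False
        return True


def _norm_node(data: dict) -> tuple:
    return (
        data.get("gene_symbol", ""),
        data.get("origin", "local"),
        data.get("state"),
        data.get("score"),
    )


def _norm_edge(data: dict) -> tuple:
    return (
        frozenset(data["categories"]),
        frozenset(data["pathway_ids"]),
        bool(data.get("ppi_supported", False)),
        data["display_category"],
    )


def _add_node(g: nx.Graph, accession: str, symbol: str, origin: str) -> None:
    if accession in g:
        return
    g.add_node(
        accession, gene_symbol=symbol, origin=origin, state=None, score=None
    )


def _add_relation_edge(g: nx.Graph, row) -> None:
    a, b = row.protein_a, row.protein_b
    if g.has_edge(a, b):
        data = g.edges[a, b]
        data["categories"].add(row.category)
        data["pathway_ids"].update(row.pathway_ids)
    else:
        g.add_edge(
            a,
            b,
            categories={row.category},
            pathway_ids=set(row.pathway_ids),
            ppi_supported=False,
        )
    g.edges[a, b]["display_category"] = display_category(
        g.edges[a, b]["categories"]
    )


def _require_pathway(store: Store, pathway_id: str) -> None:
    known = store.pathway_ids()
    if pathway_id not in known:
        raise NetworkError(
            f"pathway {pathway_id!r} not in store; known pathways: "
            + ", ".join(sorted(known))
        )


def build_local(store: Store, pathway_id: str) -> ProteinNetwork:
    """The network of exactly one canonical pathway: its proteins as nodes
    (isolated proteins included) and its relations as merged edges."""
    _require_pathway(store, pathway_id)
    proteins, relations = store.query_pathway(pathway_id)
    g = nx.Graph()
    for prow in proteins:
        _add_node(g, prow.uniprot_accession, prow.gene_symbol, "local")
    for rrow in relations:
        _add_relation_edge(g, rrow)
    return ProteinNetwork(g, "local", pathway_id)


def build_global(store: Store, pathway_id: str) -> ProteinNetwork:
    """The local network plus every store relation incident to a local
    protein, with the external partner proteins flagged
    ``origin="external"`` (one-hop expansion)."""
    net = build_local(store, pathway_id)
    g = net.graph
    local_nodes = set(g.nodes)
    for row in sorted(store.relations.values(), key=lambda r: r.key):
        if row.protein_a in local_nodes or row.protein_b in local_nodes:
            for acc in (row.protein_a, row.protein_b):
                if acc not in g:
                    prow = store.proteins.get(acc)
                    symbol = prow.gene_symbol if prow else ""
                    _add_node(g, acc, symbol, "external")
            _add_relation_edge(g, row)
    return ProteinNetwork(g, "global", pathway_id)


def load_ppi_pairs(path: Union[str, Path]) -> list[tuple[str, str]]:
    """Read a two-column TSV of physical-interaction accession pairs.

    A header row is tolerated (detected on line 1 by non-accession-looking
    tokens is *not* attempted — instead any line equal to common header
    names is skipped); malformed rows raise with the line number.
    """
    pairs: list[tuple[str, str]] = []
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 2:
                raise NetworkError(
                    f"{path.name}:{lineno}: expected 2 tab-separated columns, "
                    f"got {len(cols)}"
                )
            a, b = cols[0].strip(), cols[1].strip()
            if lineno == 1 and {a.lower(), b.lower()} & {
                "protein_a",
                "proteina",
                "interactor_a",
                "uniprot_a",
            }:
                continue
            pairs.append((a, b))
    return pairs


def merge_ppi(
    network: ProteinNetwork,
    ppi_pairs: Iterable[tuple[str, str]],
    add_edges: bool = False,
) -> tuple[ProteinNetwork, int]:
    """Overlay physical-interaction evidence on a network.

    Every network edge whose unordered pair appears in ``ppi_pairs`` gets
    ``ppi_supported=True``; the number of matched edges is returned.  By
    default PPI pairs absent from the network are ignored; with
    ``add_edges=True`` pairs whose *both* endpoints are network nodes are
    added as new ``other``-category edges with empty pathway provenance.
    """
    net = network.copy()
    g = net.graph
    pair_set = {canonical_pair(a, b) for a, b in ppi_pairs}
    matched = 0
    for a, b in g.edges:
        if canonical_pair(a, b) in pair_set:
            g.edges[a, b]["ppi_supported"] = True
            matched += 1
    if add_edges:
        for a, b in sorted(pair_set):
            if a in g and b in g and not g.has_edge(a, b) and a != b:
                g.add_edge(
                    a,
                    b,
                    categories={"other"},
                    pathway_ids=set(),
                    ppi_supported=True,
                    display_category="other",
                )
    return net, matched


# ------------------------------------------------------------------ export


def export_network(
    network: ProteinNetwork, path: Union[str, Path], fmt: str
) -> list[Path]:
    """Write a network to ``graphml``, ``sif`` or ``tsv``.

    Returns the list of files written (TSV produces a node table and an
    edge table side by side).
    """
    path = Path(path)
    if fmt == "graphml":
        _write_graphml(network, path)
        return [path]
    if fmt == "sif":
        _write_sif(network, path)
        return [path]
    if fmt == "tsv":
        nodes_path = path.with_suffix(".nodes.tsv")
        edges_path = path.with_suffix(".edges.tsv")
        _write_tsv(network, nodes_path, edges_path)
        return [nodes_path, edges_path]
    raise NetworkError(
        f"unknown export format {fmt!r}; expected one of {EXPORT_FORMATS}"
    )


def _write_graphml(network: ProteinNetwork, path: Path) -> None:
    g = nx.Graph()
    g.graph["scope"] = network.scope
    g.graph["seed_pathway"] = network.seed_pathway
    for n, data in network.graph.nodes(data=True):
        g.add_node(
            n,
            gene_symbol=data.get("gene_symbol", ""),
            origin=data.get("origin", "local"),
            state=data.get("state") or "",
            score=-1.0 if data.get("score") is None else float(data["score"]),
        )
    for a, b, data in network.graph.edges(data=True):
        g.add_edge(
            a,
            b,
            categories=_SET_SEP.join(sorted(data["categories"])),
            pathway_ids=_SET_SEP.join(sorted(data["pathway_ids"])),
            ppi_supported=bool(data.get("ppi_supported", False)),
            display_category=data["display_category"],
        )
    nx.write_graphml(g, path)


def read_graphml(path: Union[str, Path]) -> ProteinNetwork:
    """Load a network previously written by :func:`export_network` with
    ``fmt="graphml"`` (lossless round-trip of all attributes)."""
    raw = nx.read_graphml(str(path))
    g = nx.Graph()
    for n, data in raw.nodes(data=True):
        score = data.get("score", -1.0)
        g.add_node(
            n,
            gene_symbol=data.get("gene_symbol", ""),
            origin=data.get("origin", "local"),
            state=data.get("state") or None,
            score=None if score is None or float(score) < 0 else float(score),
        )
    for a, b, data in raw.edges(data=True):
        cats = set(filter(None, data.get("categories", "").split(_SET_SEP)))
        pids = set(filter(None, data.get("pathway_ids", "").split(_SET_SEP)))
        g.add_edge(
            a,
            b,
            categories=cats or {"other"},
            pathway_ids=pids,
            ppi_supported=bool(data.get("ppi_supported", False)),
            display_category=data.get("display_category")
            or display_category(cats or {"other"}),
        )
    return ProteinNetwork(
        g,
        raw.graph.get("scope", "local"),
        raw.graph.get("seed_pathway", ""),
    )


def _write_sif(network: ProteinNetwork, path: Path) -> None:
    lines = []
    isolated = []
    for a, b in sorted(network.edges()):
        lines.append(
            f"{a}\t{network.graph.edges[a, b]['display_category']}\t{b}"
        )
    for n in sorted(network.graph.nodes):
        if network.graph.degree(n) == 0:
            isolated.append(n)
    path.write_text("\n".join(lines + isolated) + "\n", encoding="utf-8")


def _write_tsv(network: ProteinNetwork, nodes_path: Path, edges_path: Path) -> None:
    with open(nodes_path, "w", encoding="utf-8") as fh:
        fh.write("accession\tgene_symbol\torigin\tstate\tscore\n")
        for n in sorted(network.graph.nodes):
            data = network.graph.nodes[n]
            score = data.get("score")
            fh.write(
                "\t".join(
                    [
                        n,
                        data.get("gene_symbol", ""),
                        data.get("origin", "local"),
                        data.get("state") or "",
                        "" if score is None else f"{score:.6g}",
                    ]
                )
                + "\n"
            )
    with open(edges_path, "w", encoding="utf-8") as fh:
        fh.write(
            "protein_a\tprotein_b\tdisplay_category\tcategories\t"
            "ppi_supported\tpathway_ids\n"
        )
        for a, b in sorted(network.edges()):
            data = network.graph.edges[a, b]
            fh.write(
                "\t".join(
                    [
                        a,
                        b,
                        data["display_category"],
                        _SET_SEP.join(sorted(data["categories"])),
                        str(bool(data.get("ppi_supported", False))),
                        _SET_SEP.join(sorted(data["pathway_ids"])),
                    ]
                )
                + "\n"
            )
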