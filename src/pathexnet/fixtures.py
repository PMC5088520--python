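"""Synthetic KGML corpora with known ground truth.

Every other module of the package is exercised offline against corpora
produced here: a set of valid KGML pathway documents, a KEGG-to-UniProt
mapping table, an expression score table over several contexts, a
physical-interaction pair list, and a machine-readable ground-truth
manifest recording exactly what the generator planted — entry and relation
counts per pathway, the unique protein pairs and relation rows the store
must contain, the ON/OFF/NA state of every protein in every context, and
the node/edge counts of every filtered local network.

All randomness flows from a single integer seed through one generator
instance; the same seed produces a byte-identical corpus.  Scores are
drawn away from the 0.4 state threshold by default so that calls are
unambiguous; a boundary flag plants exact-threshold values to exercise the
strict-inequality rule.

The :func:`notch_like_fixture` corpus mirrors the shape of a well-known
case study — a 48-protein signalling pathway overlaid with one B-cell-like
and two T-cell-like contexts, two platform-absent (NA) genes, a block of
ligand-like genes silent in every lymphocyte context, and one
strongly-differential gene scoring 1.00 / 0.41 / 0.17 across the three
contexts — without claiming any real pathway's content.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .errors import FixtureError
from .kgml_io import Entry, Pathway, Relation, serialize_kgml
from .pathway_store import canonical_pair, collapse_subtypes

__all__ = [
    "FixtureSpec",
    "GroundTruth",
    "generate_corpus",
    "notch_like_fixture",
    "load_manifest",
]

DEFAULT_SUBTYPE_DISTRIBUTION = {
    "activation": 0.30,
    "inhibition": 0.20,
    "expression": 0.15,
    "phosphorylation": 0.10,
    "binding/association": 0.10,
    "indirect effect": 0.05,
    "": 0.10,  # KGML permits relations without any subtype element
}

STATE_THRESHOLD = 0.4  # the generator plants states relative to this


@dataclass
class FixtureSpec:
    """Parameters of a synthetic corpus.

    ``expression_spec`` maps each context name to the fraction of scored
    proteins that are ON and the fraction of all proteins left off the
    expression platform (NA).  ``shared_protein_fraction`` controls
    cross-pathway protein reuse, which is what makes global networks
    larger than local ones.
    """

    n_pathways: int = 3
    genes_per_pathway: tuple[int, int] = (8, 14)
    multi_gene_entry_prob: float = 0.25
    group_entry_prob: float = 0.15
    relation_density: float = 0.25
    subtype_distribution: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SUBTYPE_DISTRIBUTION)
    )
    shared_protein_fraction: float = 0.25
    expression_spec: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "ctx_A": {"fraction_on": 0.7, "na_fraction": 0.1},
            "ctx_B": {"fraction_on": 0.4, "na_fraction": 0.1},
        }
    )
    boundary_scores: bool = False
    seed: int = 0

    def validate(self) -> None:
        probs = [
            self.multi_gene_entry_prob,
            self.group_entry_prob,
            self.relation_density,
            self.shared_protein_fraction,
        ]
        for ctx, cfg in self.expression_spec.items():
            probs += [cfg["fraction_on"], cfg["na_fraction"]]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise FixtureError("all probabilities must lie in [0, 1]")
        total = sum(self.subtype_distribution.values())
        if not np.isclose(total, 1.0):
            raise FixtureError(
                f"subtype distribution sums to {total}, expected 1"
            )
        if self.n_pathways < 1:
            raise FixtureError("need at least one pathway")
        lo, hi = self.genes_per_pathway
        if lo < 2 or hi < lo:
            raise FixtureError("genes_per_pathway must be (lo>=2, hi>=lo)")


@dataclass
class GroundTruth:
    """What the generator planted, in the shapes downstream modules report."""

    pathways: dict[str, dict]  # pid -> n_entries, n_relations, n_proteins, n_local_edges
    store: dict  # n_protein_rows, n_relation_rows
    states: dict[str, dict[str, str]]  # context -> accession -> state
    scores: dict[str, dict[str, float]]  # context -> accession -> score
    filtered: dict[str, dict[str, dict]]  # pid -> context -> counts
    ppi: dict  # n_pairs, n_matched_local per pathway

    def to_json(self) -> str:
        payload = {
            "pathways": self.pathways,
            "store": self.store,
            "states": self.states,
            "scores": self.scores,
            "filtered": self.filtered,
            "ppi": self.ppi,
        }
        return json.dumps(payload, indent=1, sort_keys=True)


def load_manifest(path: Union[str, Path]) -> GroundTruth:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    return GroundTruth(
        pathways=payload["pathways"],
        store=payload["store"],
        states=payload["states"],
        scores=payload["scores"],
        filtered=payload["filtered"],
        ppi=payload["ppi"],
    )


# --------------------------------------------------------------- internals


class _Universe:
    """Allocates protein identities (accession / KEGG gene id / symbol)."""

    def __init__(self, accession_base: int = 10001, kegg_base: int = 1001):
        self.accession_base = accession_base
        self.kegg_base = kegg_base
        self.accessions: list[str] = []

    def new_protein(self) -> str:
        i = len(self.accessions)
        acc = f"P{self.accession_base + i:05d}"
        self.accessions.append(acc)
        return acc

    def kegg_id(self, acc: str) -> str:
        i = self.accessions.index(acc)
        return f"hsa:{self.kegg_base + i}"

    def symbol(self, acc: str) -> str:
        i = self.accessions.index(acc)
        return f"SYG{i + 1:03d}"


def _draw_subtype(rng: np.random.Generator, dist: dict[str, float]) -> str:
    names = sorted(dist)
    probs = np.array([dist[n] for n in names], dtype=float)
    probs = probs / probs.sum()
    return names[int(rng.choice(len(names), p=probs))]


def _draw_scores(
    rng: np.random.Generator, state: str, boundary: bool
) -> Optional[float]:
    """A score consistent with the planted state (never exactly at the
    threshold unless boundary injection asks for it)."""
    if state == "NA":
        return None
    if state == "ON":
        return float(np.round(rng.uniform(0.45, 1.0), 6))
    if boundary and rng.uniform() < 0.15:
        return STATE_THRESHOLD  # exactly at threshold: must come out OFF
    return float(np.round(rng.uniform(0.0, 0.35), 6))


def _write_corpus_files(
    out_dir: Path,
    pathways: list[Pathway],
    universe: _Universe,
    used_accessions: list[str],
    states: dict[str, dict[str, str]],
    scores: dict[str, dict[str, float]],
    ppi_pairs: list[tuple[str, str]],
    truth: GroundTruth,
) -> None:
    out_dir = Path(out_dir)
    kgml_dir = out_dir / "kgml"
    kgml_dir.mkdir(parents=True, exist_ok=True)
    for pw in pathways:
        (kgml_dir / f"{pw.pathway_id}.xml").write_bytes(serialize_kgml(pw))

    with open(out_dir / "mapping.tsv", "w", encoding="utf-8") as fh:
        for acc in used_accessions:
            fh.write(f"{universe.kegg_id(acc)}\t{acc}\n")

    with open(out_dir / "symbols.tsv", "w", encoding="utf-8") as fh:
        for acc in used_accessions:
            fh.write(f"{acc}\t{universe.symbol(acc)}\n")

    contexts = sorted(states)
    with open(out_dir / "expression.tsv", "w", encoding="utf-8") as fh:
        fh.write("accession\t" + "\t".join(contexts) + "\n")
        for acc in used_accessions:
            row = []
            measurable = any(states[c].get(acc) != "NA" for c in contexts)
            if not measurable:
                continue  # NA proteins are simply absent from the platform
            for c in contexts:
                row.append(f"{scores[c][acc]:.6f}")
            fh.write(acc + "\t" + "\t".join(row) + "\n")

    with open(out_dir / "ppi.tsv", "w", encoding="utf-8") as fh:
        for a, b in ppi_pairs:
            fh.write(f"{a}\t{b}\n")

    (out_dir / "ground_truth.json").write_text(
        truth.to_json() + "\n", encoding="utf-8"
    )


def _filtered_counts(
    proteins: set[str],
    pairs: set[tuple[str, str]],
    ctx_states: dict[str, str],
) -> dict:
    on = {a for a in proteins if ctx_states[a] == "ON"}
    na = {a for a in proteins if ctx_states[a] == "NA"}
    kept_nodes = on | na
    kept_edges = {p for p in pairs if p[0] in kept_nodes and p[1] in kept_nodes}
    return {
        "n_nodes": len(kept_nodes),
        "n_edges": len(kept_edges),
        "n_on": len(on),
        "n_na": len(na),
        "n_off_removed": len(proteins) - len(kept_nodes),
        "n_edges_removed": len(pairs) - len(kept_edges),
    }


def generate_corpus(spec: FixtureSpec, out_dir: Union[str, Path]) -> GroundTruth:
    """Generate a corpus under ``out_dir`` and return its ground truth.

    Layout: ``kgml/*.xml``, ``mapping.tsv``, ``symbols.tsv``,
    ``expression.tsv`` (accession × context), ``ppi.tsv``, and
    ``ground_truth.json``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    universe = _Universe()
    pool: list[str] = []  # proteins already used, for cross-pathway sharing

    pathways: list[Pathway] = []
    pathway_proteins: dict[str, set[str]] = {}
    pathway_pairs: dict[str, set[tuple[str, str]]] = {}
    store_rows: dict[tuple[str, str, str], set[str]] = {}
    truth_pathways: dict[str, dict] = {}

    for p_index in range(spec.n_pathways):
        pid = f"hsa{90001 + p_index}"
        lo, hi = spec.genes_per_pathway
        n_genes = int(rng.integers(lo, hi + 1))

        genes: list[str] = []
        for _ in range(n_genes):
            candidates = [a for a in pool if a not in genes]
            if candidates and rng.uniform() < spec.shared_protein_fraction:
                genes.append(candidates[int(rng.integers(len(candidates)))])
            else:
                genes.append(universe.new_protein())
        for acc in genes:
            if acc not in pool:
                pool.append(acc)

        # Partition genes into entries; some entries are multi-protein boxes.
        entries: list[Entry] = []
        entry_genes: dict[str, list[str]] = {}
        next_id = 1
        i = 0
        while i < len(genes):
            take = 1
            if rng.uniform() < spec.multi_gene_entry_prob and i + 1 < len(genes):
                take = int(rng.integers(2, 4))
            box = genes[i : i + take]
            eid = str(next_id)
            next_id += 1
            entries.append(
                Entry(
                    entry_id=eid,
                    entry_type="gene",
                    kegg_names=tuple(universe.kegg_id(a) for a in box),
                )
            )
            entry_genes[eid] = box
            i += take

        gene_entry_ids = [e.entry_id for e in entries]

        # Optional group entries bundling two gene entries.
        group_members: dict[str, list[str]] = {}
        if len(gene_entry_ids) >= 2 and rng.uniform() < spec.group_entry_prob:
            a, b = rng.choice(len(gene_entry_ids), size=2, replace=False)
            gid = str(next_id)
            next_id += 1
            members = [gene_entry_ids[int(a)], gene_entry_ids[int(b)]]
            entries.append(
                Entry(entry_id=gid, entry_type="group", component_ids=tuple(members))
            )
            group_members[gid] = members

        # Non-protein entries for parser coverage (never reach the store).
        compound_id = map_id = None
        if rng.uniform() < 0.4:
            compound_id = str(next_id)
            next_id += 1
            entries.append(
                Entry(compound_id, "compound", kegg_names=("cpd:C00076",))
            )
        if rng.uniform() < 0.4:
            map_id = str(next_id)
            next_id += 1
            entries.append(Entry(map_id, "map", kegg_names=(f"path:hsa{90101 + p_index}",)))

        def genes_of(eid: str) -> list[str]:
            if eid in group_members:
                out: list[str] = []
                for m in group_members[eid]:
                    out.extend(entry_genes[m])
                return out
            return entry_genes[eid]

        relation_endpoints = gene_entry_ids + list(group_members)
        relations: list[Relation] = []
        pairs_here: set[tuple[str, str]] = set()
        for ia in range(len(relation_endpoints)):
            for ib in range(ia + 1, len(relation_endpoints)):
                if rng.uniform() >= spec.relation_density:
                    continue
                subtype = _draw_subtype(rng, spec.subtype_distribution)
                rtype = "GErel" if subtype == "expression" else "PPrel"
                e1, e2 = relation_endpoints[ia], relation_endpoints[ib]
                subtypes = (subtype,) if subtype else ()
                relations.append(Relation(e1, e2, rtype, subtypes))
                category = collapse_subtypes(subtypes)
                for ga in genes_of(e1):
                    for gb in genes_of(e2):
                        if ga == gb:
                            continue
                        pair = canonical_pair(ga, gb)
                        store_rows.setdefault((*pair, category), set()).add(pid)
                        pairs_here.add(pair)
        if compound_id is not None and gene_entry_ids:
            src = gene_entry_ids[int(rng.integers(len(gene_entry_ids)))]
            relations.append(Relation(src, compound_id, "PCrel", ("compound",)))
        if map_id is not None and gene_entry_ids:
            src = gene_entry_ids[int(rng.integers(len(gene_entry_ids)))]
            relations.append(Relation(src, map_id, "maplink", ()))

        pathways.append(
            Pathway(
                pathway_id=pid,
                organism="hsa",
                title=f"synthetic pathway {p_index + 1}",
                entries=entries,
                relations=relations,
            )
        )
        pathway_proteins[pid] = set(genes)
        pathway_pairs[pid] = pairs_here
        truth_pathways[pid] = {
            "n_entries": len(entries),
            "n_relations": len(relations),
            "n_proteins": len(set(genes)),
            "n_local_edges": len(pairs_here),
        }

    used_accessions = sorted(
        set().union(*pathway_proteins.values()) if pathway_proteins else set()
    )

    # Expression states per context (NA is a platform property: a protein is
    # NA in every context or none, matching how an absent probe behaves).
    states: dict[str, dict[str, str]] = {}
    scores: dict[str, dict[str, float]] = {}
    contexts = sorted(spec.expression_spec)
    na_fraction = max(
        spec.expression_spec[c]["na_fraction"] for c in contexts
    ) if contexts else 0.0
    na_set = {
        acc for acc in used_accessions if rng.uniform() < na_fraction
    }
    for ctx in contexts:
        cfg = spec.expression_spec[ctx]
        ctx_states: dict[str, str] = {}
        ctx_scores: dict[str, float] = {}
        for acc in used_accessions:
            if acc in na_set:
                ctx_states[acc] = "NA"
                continue
            state = "ON" if rng.uniform() < cfg["fraction_on"] else "OFF"
            score = _draw_scores(rng, state, spec.boundary_scores)
            # planting a boundary score (exactly at threshold) keeps OFF
            ctx_states[acc] = "ON" if score > STATE_THRESHOLD else "OFF"
            ctx_scores[acc] = score
        states[ctx] = ctx_states
        scores[ctx] = ctx_scores

    filtered = {
        pid: {
            ctx: _filtered_counts(pathway_proteins[pid], pathway_pairs[pid], states[ctx])
            for ctx in contexts
        }
        for pid in pathway_proteins
    }

    # PPI list: roughly half the corpus pairs, plus decoys outside it.
    all_pairs = sorted({(a, b) for (a, b, _c) in store_rows})
    n_take = len(all_pairs) // 2
    take_idx = sorted(
        rng.choice(len(all_pairs), size=n_take, replace=False).tolist()
    ) if all_pairs else []
    ppi_pairs = [all_pairs[i] for i in take_idx]
    ppi_set = set(ppi_pairs)
    decoys = [("P99991", "P99992"), ("P99993", "P99994")]
    ppi_out = ppi_pairs + decoys
    n_matched_local = {
        pid: len(pathway_pairs[pid] & ppi_set) for pid in pathway_pairs
    }

    truth = GroundTruth(
        pathways=truth_pathways,
        store={
            "n_protein_rows": len(used_accessions),
            "n_relation_rows": len(store_rows),
            "n_unique_pairs": len(all_pairs),
        },
        states=states,
        scores=scores,
        filtered=filtered,
        ppi={"n_pairs": len(ppi_out), "n_matched_local": n_matched_local},
    )

    _write_corpus_files(
        Path(out_dir),
        pathways,
        universe,
        used_accessions,
        states,
        scores,
        ppi_out,
        truth,
    )
    return truth


# ----------------------------------------------------------- case study


NOTCH_LIKE_N_PROTEINS = 48
NOTCH_LIKE_CONTEXTS = ("B_CD19", "T_CD4", "T_CD8")
_B_ON = 32  # proteins 1..32 ON in the B-like context
_CD4_ON = 24  # 1..24 ON in the first T-like context (subset of B)
_CD8_ON = 22  # 1..22 ON in the second T-like context (subset of CD4)
_N_NA = 2  # proteins 47, 48 absent from the platform in every context
_LIGAND_LIKE = range(33, 38)  # 5 ligand-like proteins OFF everywhere
_DIFFERENTIAL = 23  # scores 1.00 / 0.41 / 0.17 across the three contexts


def notch_like_fixture(out_dir: Union[str, Path], seed: int = 20161025) -> GroundTruth:
    """A deterministic 48-protein signalling-pathway corpus with three
    lymphocyte-like contexts.

    Planted structure: 32 proteins ON in the B-like context, with the two
    T-like ON sets nested inside it (24 and 22 proteins); 2 NA proteins in
    every context; a block of ligand-like proteins OFF in all contexts;
    and one strongly differential protein scoring 1.00 (B-like), 0.41
    (first T-like, just above threshold) and 0.17 (second T-like).  The
    nesting guarantees the filtered B-like network strictly contains each
    filtered T-like network in both nodes and edges.
    """
    rng = np.random.default_rng(seed)
    universe = _Universe(accession_base=60001, kegg_base=60001)
    accs = [universe.new_protein() for _ in range(NOTCH_LIKE_N_PROTEINS)]
    pid = "hsa04330"

    # 48 single-protein entries; a ring scaffold plus seeded chords.
    entries = [
        Entry(str(i + 1), "gene", kegg_names=(universe.kegg_id(accs[i]),))
        for i in range(NOTCH_LIKE_N_PROTEINS)
    ]
    edge_ids: set[tuple[int, int]] = set()
    for i in range(NOTCH_LIKE_N_PROTEINS):
        j = (i + 1) % NOTCH_LIKE_N_PROTEINS
        edge_ids.add((min(i, j), max(i, j)))
    while len(edge_ids) < 90:  # chords bring the edge count near the ring*2
        i, j = rng.choice(NOTCH_LIKE_N_PROTEINS, size=2, replace=False)
        i, j = int(min(i, j)), int(max(i, j))
        edge_ids.add((i, j))

    subtype_cycle = (
        "activation",
        "inhibition",
        "expression",
        "binding/association",
        "",
    )
    relations = []
    pairs: set[tuple[str, str]] = set()
    store_rows: dict[tuple[str, str, str], set[str]] = {}
    for k, (i, j) in enumerate(sorted(edge_ids)):
        subtype = subtype_cycle[k % len(subtype_cycle)]
        rtype = "GErel" if subtype == "expression" else "PPrel"
        subtypes = (subtype,) if subtype else ()
        relations.append(Relation(str(i + 1), str(j + 1), rtype, subtypes))
        pair = canonical_pair(accs[i], accs[j])
        pairs.add(pair)
        store_rows.setdefault((*pair, collapse_subtypes(subtypes)), set()).add(pid)

    pathway = Pathway(
        pathway_id=pid,
        organism="hsa",
        title="synthetic notch-like signalling pathway",
        entries=entries,
        relations=relations,
    )

    on_counts = dict(zip(NOTCH_LIKE_CONTEXTS, (_B_ON, _CD4_ON, _CD8_ON)))
    na_idx = set(range(NOTCH_LIKE_N_PROTEINS - _N_NA, NOTCH_LIKE_N_PROTEINS))
    states: dict[str, dict[str, str]] = {}
    scores: dict[str, dict[str, float]] = {}
    for ctx in NOTCH_LIKE_CONTEXTS:
        n_on = on_counts[ctx]
        ctx_states: dict[str, str] = {}
        ctx_scores: dict[str, float] = {}
        for i, acc in enumerate(accs):
            if i in na_idx:
                ctx_states[acc] = "NA"
                continue
            if i == _DIFFERENTIAL - 1:
                score = {"B_CD19": 1.00, "T_CD4": 0.41, "T_CD8": 0.17}[ctx]
            elif i < n_on:
                score = float(np.round(0.5 + 0.5 * (i + 1) / 50, 6))
            else:
                score = float(np.round(0.02 + 0.3 * (i + 1) / 50, 6))
            ctx_states[acc] = "ON" if score > STATE_THRESHOLD else "OFF"
            ctx_scores[acc] = score
        states[ctx] = ctx_states
        scores[ctx] = ctx_scores

    # construction-time checks of the planted shape
    assert all(states[c][accs[i]] == "OFF" for c in NOTCH_LIKE_CONTEXTS
               for i in _LIGAND_LIKE)
    assert sum(s == "ON" for s in states["B_CD19"].values()) == _B_ON
    assert sum(s == "ON" for s in states["T_CD4"].values()) == _CD4_ON
    assert sum(s == "ON" for s in states["T_CD8"].values()) == _CD8_ON

    pathway_proteins = {pid: set(accs)}
    filtered = {
        pid: {
            ctx: _filtered_counts(set(accs), pairs, states[ctx])
            for ctx in NOTCH_LIKE_CONTEXTS
        }
    }
    b, t4, t8 = (filtered[pid][c] for c in NOTCH_LIKE_CONTEXTS)
    assert b["n_on"] > t4["n_on"] and b["n_on"] > t8["n_on"]
    assert b["n_edges"] > t4["n_edges"] and b["n_edges"] > t8["n_edges"]

    all_pairs = sorted(pairs)
    take_idx = sorted(
        rng.choice(len(all_pairs), size=len(all_pairs) // 2, replace=False).tolist()
    )
    ppi_pairs = [all_pairs[i] for i in take_idx]

    truth = GroundTruth(
        pathways={
            pid: {
                "n_entries": len(entries),
                "n_relations": len(relations),
                "n_proteins": NOTCH_LIKE_N_PROTEINS,
                "n_local_edges": len(pairs),
            }
        },
        store={
            "n_protein_rows": NOTCH_LIKE_N_PROTEINS,
            "n_relation_rows": len(store_rows),
            "n_unique_pairs": len(all_pairs),
        },
        states=states,
        scores=scores,
        filtered=filtered,
        ppi={
            "n_pairs": len(ppi_pairs),
            "n_matched_local": {pid: len(set(ppi_pairs) & pairs)},
        },
    )
    _write_corpus_files(
        Path(out_dir),
        [pathway],
        universe,
        accs,
        states,
        scores,
        ppi_pairs,
        truth,
    )
    return truth
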