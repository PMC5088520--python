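"""Relational store of pathway-derived protein relations.

A corpus of KGML files is distilled into two indexed tables keyed on
UniProt accessions:

* **relations** — one row per unique pair-wise link between two proteins.
  A "unique interaction" is the unordered accession pair plus its collapsed
  category; the same link found in several pathways is one row whose
  ``pathway_ids`` records every pathway of origin.
* **proteins** — one row per singular protein, with its KEGG gene ids,
  an optional gene symbol, and the pathways it occurs in.

A KGML relation between an entry with m mapped accessions and an entry
with n mapped accessions expands to m*n candidate pairs (every distinct
protein of a multi-protein box participates); self-pairs are dropped and
pairs are stored in canonical lexicographic order, so the store describes
an undirected relation set.

Relation subtypes collapse onto four categories — ``activation``,
``inhibition`` (including ``repression``), ``expression``, and ``other``
for any remaining or missing subtype.  Relations through compounds
(``PCrel``) and map links contribute no protein-pair rows.

The store lives in memory, persists to a single-file SQLite database, and
exports a portable SQL dump (plain ``CREATE TABLE`` + ``INSERT``
statements) whose reload reproduces the store exactly.
"""

from __future__ import annotations

import logging
import sqlite3
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

from .errors import StoreError
from .id_mapping import MappingTable, map_ids
from .kgml_io import Pathway, expand_groups, parse_kgml

__all__ = [
    "RelationRow",
    "ProteinRow",
    "Store",
    "CATEGORIES",
    "collapse_subtypes",
    "canonical_pair",
    "build_store",
    "build_store_from_pathways",
]

log = logging.getLogger(__name__)

#: Collapsed relation categories, in display-precedence order.
CATEGORIES = ("activation", "inhibition", "expression", "other")

#: Relation types that connect two protein-coding entries directly.
_PROTEIN_RELATION_TYPES = {"PPrel", "GErel", "ECrel"}

_SUBTYPE_TO_CATEGORY = {
    "activation": "activation",
    "inhibition": "inhibition",
    "repression": "inhibition",
    "expression": "expression",
}


def collapse_subtypes(subtypes: Iterable[str]) -> str:
    """Collapse a KGML subtype list onto one category.

    When several recognized subtypes co-occur the highest-precedence one
    wins (activation > inhibition > expression); anything else, including
    an empty subtype list, is ``other``.
    """
    cats = {_SUBTYPE_TO_CATEGORY.get(s) for s in subtypes}
    for cat in ("activation", "inhibition", "expression"):
        if cat in cats:
            return cat
    return "other"


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Order an unordered accession pair lexicographically."""
    return (a, b) if a <= b else (b, a)


@dataclass
class RelationRow:
    protein_a: str
    protein_b: str
    category: str
    raw_subtypes: set[str] = field(default_factory=set)
    pathway_ids: set[str] = field(default_factory=set)

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.protein_a, self.protein_b, self.category)


@dataclass
class ProteinRow:
    uniprot_accession: str
    kegg_gene_ids: set[str] = field(default_factory=set)
    gene_symbol: str = ""
    pathway_ids: set[str] = field(default_factory=set)


class Store:
    """In-memory two-table store with SQLite persistence."""

    def __init__(self) -> None:
        self.relations: dict[tuple[str, str, str], RelationRow] = {}
        self.proteins: dict[str, ProteinRow] = {}

    # ---------------------------------------------------------------- build

    def add_protein(
        self,
        accession: str,
        kegg_gene_ids: Iterable[str] = (),
        gene_symbol: str = "",
        pathway_id: Optional[str] = None,
    ) -> ProteinRow:
        row = self.proteins.setdefault(accession, ProteinRow(accession))
        row.kegg_gene_ids.update(kegg_gene_ids)
        if gene_symbol and not row.gene_symbol:
            row.gene_symbol = gene_symbol
        if pathway_id:
            row.pathway_ids.add(pathway_id)
        return row

    def add_relation(
        self,
        a: str,
        b: str,
        category: str,
        raw_subtypes: Iterable[str] = (),
        pathway_id: Optional[str] = None,
    ) -> Optional[RelationRow]:
        """Add a pair, deduplicating on (canonical pair, category).

        Self-loops are rejected (returns ``None``); repeated pairs union
        their subtype and pathway provenance.
        """
        if a == b:
            return None
        if category not in CATEGORIES:
            raise StoreError(f"unknown category {category!r}")
        pa, pb = canonical_pair(a, b)
        key = (pa, pb, category)
        row = self.relations.setdefault(key, RelationRow(pa, pb, category))
        row.raw_subtypes.update(raw_subtypes)
        if pathway_id:
            row.pathway_ids.add(pathway_id)
        return row

    # ---------------------------------------------------------------- query

    def pathway_ids(self) -> set[str]:
        out: set[str] = set()
        for row in self.proteins.values():
            out |= row.pathway_ids
        for row in self.relations.values():
            out |= row.pathway_ids
        return out

    def query_pathway(
        self, pathway_id: str
    ) -> tuple[list[ProteinRow], list[RelationRow]]:
        """Rows whose ``pathway_ids`` contain ``pathway_id``.

        An unknown id yields an empty result with a warning, not an error.
        """
        proteins = sorted(
            (r for r in self.proteins.values() if pathway_id in r.pathway_ids),
            key=lambda r: r.uniprot_accession,
        )
        relations = sorted(
            (r for r in self.relations.values() if pathway_id in r.pathway_ids),
            key=lambda r: r.key,
        )
        if not proteins and not relations:
            log.warning("pathway %s not present in store", pathway_id)
        return proteins, relations

    # --------------------------------------------------------- persistence

    _SCHEMA = (
        "CREATE TABLE proteins (\n"
        "  uniprot_accession TEXT PRIMARY KEY,\n"
        "  kegg_gene_ids TEXT NOT NULL,\n"
        "  gene_symbol TEXT NOT NULL,\n"
        "  pathway_ids TEXT NOT NULL\n"
        ");",
        "CREATE TABLE relations (\n"
        "  protein_a TEXT NOT NULL,\n"
        "  protein_b TEXT NOT NULL,\n"
        "  category TEXT NOT NULL,\n"
        "  raw_subtypes TEXT NOT NULL,\n"
        "  pathway_ids TEXT NOT NULL,\n"
        "  PRIMARY KEY (protein_a, protein_b, category)\n"
        ");",
        "CREATE INDEX idx_relations_a ON relations (protein_a);",
        "CREATE INDEX idx_relations_b ON relations (protein_b);",
    )

    @staticmethod
    def _join(values: Iterable[str]) -> str:
        return ";".join(sorted(values))

    @staticmethod
    def _split(text: str) -> set[str]:
        return set(text.split(";")) if text else set()

    def _protein_tuples(self):
        for acc in sorted(self.proteins):
            row = self.proteins[acc]
            yield (
                acc,
                self._join(row.kegg_gene_ids),
                row.gene_symbol,
                self._join(row.pathway_ids),
            )

    def _relation_tuples(self):
        for key in sorted(self.relations):
            row = self.relations[key]
            yield (
                row.protein_a,
                row.protein_b,
                row.category,
                self._join(row.raw_subtypes),
                self._join(row.pathway_ids),
            )

    def save(self, path: Union[str, Path]) -> None:
        """Persist to a single-file SQLite database (overwrites)."""
        path = Path(path)
        if path.exists():
            path.unlink()
        con = sqlite3.connect(path)
        try:
            with con:
                for stmt in self._SCHEMA:
                    con.execute(stmt)
                con.executemany(
                    "INSERT INTO proteins VALUES (?,?,?,?)", self._protein_tuples()
                )
                con.executemany(
                    "INSERT INTO relations VALUES (?,?,?,?,?)",
                    self._relation_tuples(),
                )
        finally:
            con.close()

    @classmethod
    def load(cls, path: Union[str, Path]) -> "Store":
        path = Path(path)
        if not path.exists():
            raise StoreError(f"store file {path} does not exist")
        con = sqlite3.connect(path)
        try:
            return cls._from_connection(con)
        finally:
            con.close()

    @classmethod
    def _from_connection(cls, con: sqlite3.Connection) -> "Store":
        store = cls()
        for acc, kegg, symbol, pids in con.execute(
            "SELECT * FROM proteins ORDER BY uniprot_accession"
        ):
            store.proteins[acc] = ProteinRow(
                acc, cls._split(kegg), symbol, cls._split(pids)
            )
        for a, b, cat, subs, pids in con.execute(
            "SELECT * FROM relations ORDER BY protein_a, protein_b, category"
        ):
            store.relations[(a, b, cat)] = RelationRow(
                a, b, cat, cls._split(subs), cls._split(pids)
            )
        return store

    # ----------------------------------------------------------- SQL dump

    @staticmethod
    def _sql_quote(value: str) -> str:
        return "'" + value.replace("'", "''") + "'"

    def dump_sql(self, path: Union[str, Path]) -> None:
        """Write a portable SQL dump (schema + one INSERT per row, in
        canonical sorted order) whose reload reproduces the store exactly."""
        lines: list[str] = ["BEGIN TRANSACTION;"]
        lines.extend(self._SCHEMA)
        for tup in self._protein_tuples():
            lines.append(
                "INSERT INTO proteins VALUES ("
                + ",".join(self._sql_quote(v) for v in tup)
                + ");"
            )
        for tup in self._relation_tuples():
            lines.append(
                "INSERT INTO relations VALUES ("
                + ",".join(self._sql_quote(v) for v in tup)
                + ");"
            )
        lines.append("COMMIT;")
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")

    @classmethod
    def load_sql(cls, path: Union[str, Path]) -> "Store":
        """Rebuild a store by executing a SQL dump into an in-memory
        database."""
        script = Path(path).read_text(encoding="utf-8")
        con = sqlite3.connect(":memory:")
        try:
            con.executescript(script)
            return cls._from_connection(con)
        finally:
            con.close()

    # ------------------------------------------------------------- export

    def to_tsv(self, proteins_path: Union[str, Path], relations_path: Union[str, Path]) -> None:
        """Canonical sorted TSV exports of both tables (diff-friendly)."""
        with open(proteins_path, "w", encoding="utf-8") as fh:
            fh.write("uniprot_accession\tkegg_gene_ids\tgene_symbol\tpathway_ids\n")
            for tup in self._protein_tuples():
                fh.write("\t".join(tup) + "\n")
        with open(relations_path, "w", encoding="utf-8") as fh:
            fh.write("protein_a\tprotein_b\tcategory\traw_subtypes\tpathway_ids\n")
            for tup in self._relation_tuples():
                fh.write("\t".join(tup) + "\n")

    # ----------------------------------------------------------- equality

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Store):
            return NotImplemented
        return list(self._protein_tuples()) == list(other._protein_tuples()) and list(
            self._relation_tuples()
        ) == list(other._relation_tuples())

    def __repr__(self) -> str:
        return (
            f"Store({len(self.proteins)} proteins, "
            f"{len(self.relations)} relations, "
            f"{len(self.pathway_ids())} pathways)"
        )


def _ingest_pathway(
    store: Store,
    pathway: Pathway,
    mapping: MappingTable,
    gene_symbols: Optional[dict[str, str]] = None,
) -> None:
    pathway = expand_groups(pathway)
    by_id = pathway.entry_by_id()

    # Resolve each gene entry to its set of accessions (multi-gene boxes
    # expand to every distinct protein; many-to-many mappings fan out).
    entry_accessions: dict[str, set[str]] = {}
    unmapped_entries: list[str] = []
    for entry in pathway.gene_entries():
        result = map_ids(entry.kegg_names, mapping)
        accs = set().union(*result.mapping.values()) if result.mapping else set()
        entry_accessions[entry.entry_id] = accs
        if not accs:
            unmapped_entries.append(entry.entry_id)
        for acc in accs:
            mapped_ids = {
                gid for gid, hits in result.mapping.items() if acc in hits
            }
            symbol = (gene_symbols or {}).get(acc, "")
            store.add_protein(acc, mapped_ids, symbol, pathway.pathway_id)
    if unmapped_entries:
        log.info(
            "pathway %s: %d gene entries with no mapped accession: %s",
            pathway.pathway_id,
            len(unmapped_entries),
            ", ".join(unmapped_entries),
        )

    for rel in pathway.relations:
        if rel.relation_type not in _PROTEIN_RELATION_TYPES:
            continue
        left = entry_accessions.get(rel.entry1, set())
        right = entry_accessions.get(rel.entry2, set())
        category = collapse_subtypes(rel.subtypes)
        for a in left:
            for b in right:
                store.add_relation(
                    a, b, category, rel.subtypes, pathway.pathway_id
                )


def build_store_from_pathways(
    pathways: Iterable[Pathway],
    mapping: MappingTable,
    gene_symbols: Optional[dict[str, str]] = None,
) -> Store:
    """Build a store from already-parsed pathway models."""
    store = Store()
    for pathway in pathways:
        _ingest_pathway(store, pathway, mapping, gene_symbols)
    return store


def build_store(
    kgml_dir: Union[str, Path],
    mapping: MappingTable,
    gene_symbols: Optional[dict[str, str]] = None,
) -> Store:
    """Build the two-table store from a directory of KGML files.

    Files are processed in sorted name order so the build is deterministic.
    A file that fails to parse is logged and skipped; an empty directory is
    an error.
    """
    kgml_dir = Path(kgml_dir)
    files = sorted(kgml_dir.glob("*.xml"))
    if not files:
        raise StoreError(f"no KGML (*.xml) files found in {kgml_dir}")
    store = Store()
    for path in files:
        try:
            pathway = parse_kgml(path)
        except Exception as exc:  # parse or validation failure: skip file
            log.warning("skipping %s: %s", path.name, exc)
            continue
        _ingest_pathway(store, pathway, mapping, gene_symbols)
    return store
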