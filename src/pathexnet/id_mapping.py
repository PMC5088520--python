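"""Unify gene identifiers to UniProt accessions.

The package keys every protein on its UniProtKB accession; KEGG gene ids
(``hsa:4851``) and Ensembl gene ids (``ENSG00000148400``) are translated
through two-column mapping tables of the kind UniProt distributes.  The
mapping is a multimap and may be many-to-many in both directions: a KEGG
gene mapping to k accessions yields k protein nodes downstream, and no
filtering by review status is applied — the table as provided is
authoritative.

Isoform accessions (dash-suffixed, e.g. ``P46531-2``) are collapsed to
their canonical stem: the networks built here are protein-level, not
isoform-level.
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Union

from .errors import MappingError

__all__ = ["MappingTable", "MapResult", "load_mapping", "map_ids"]

log = logging.getLogger(__name__)

# 6- or 10-character UniProt accession (canonical, after isoform collapse).
UNIPROT_RE = re.compile(r"^[A-Z][A-Z0-9]{5}(?:[A-Z0-9]{4})?$")

_NAMESPACE_PATTERNS = {
    "kegg_gene": re.compile(r"^[a-z]{2,4}:\w+$"),
    "ensembl_gene": re.compile(r"^ENS[A-Z]{0,4}G\d{6,13}(?:\.\d+)?$"),
}


@dataclass
class MappingTable:
    """Multimap from source gene identifiers to sets of UniProt accessions."""

    source_namespace: str
    pairs: dict[str, set[str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.pairs)

    def accessions(self) -> set[str]:
        return set().union(*self.pairs.values()) if self.pairs else set()

    def get(self, source_id: str) -> set[str]:
        return set(self.pairs.get(source_id, set()))


@dataclass
class MapResult:
    """Outcome of mapping a batch of ids: the full mapping (every input id
    is a key; unmapped ids map to the empty set) plus the unmapped list."""

    mapping: dict[str, set[str]]
    unmapped: list[str]


def _canonical_accession(acc: str) -> str:
    """Collapse an isoform accession (``P46531-2``) to its canonical stem."""
    return acc.split("-", 1)[0].strip()


def load_mapping(
    path: Union[str, Path], namespace: str = "kegg_gene"
) -> MappingTable:
    """Load a two-column TSV (``source_id <TAB> uniprot_accession``).

    A header row is auto-detected: if column 1 of the first row does not
    match the namespace's identifier pattern, the row is treated as a
    header.  Gzip-compressed files (``.gz``) are accepted.  Duplicate rows
    collapse; a row with the wrong column count raises :class:`MappingError`
    naming the line.
    """
    if namespace not in _NAMESPACE_PATTERNS:
        raise MappingError(
            f"unknown namespace {namespace!r}; expected one of "
            + ", ".join(_NAMESPACE_PATTERNS)
        )
    id_pattern = _NAMESPACE_PATTERNS[namespace]
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    table = MappingTable(source_namespace=namespace)
    with opener(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            cols = line.split("\t")
            if len(cols) != 2:
                raise MappingError(
                    f"{path.name}:{lineno}: expected 2 tab-separated columns, "
                    f"got {len(cols)}"
                )
            source_id, acc = cols[0].strip(), cols[1].strip()
            if lineno == 1 and not id_pattern.match(source_id):
                continue  # header row
            acc = _canonical_accession(acc)
            if not UNIPROT_RE.match(acc):
                raise MappingError(
                    f"{path.name}:{lineno}: {acc!r} is not a UniProt accession"
                )
            table.pairs.setdefault(source_id, set()).add(acc)
    if not table.pairs:
        log.warning("mapping table %s is empty", path)
    return table


def map_ids(ids: Iterable[str], table: MappingTable) -> MapResult:
    """Map source ids through the table.

    Every distinct input id appears as a key of the result; ids absent from
    the table map to the empty set and are listed (in input order) in
    ``unmapped``.  An unmapped id is a reported outcome, never an error.
    """
    mapping: dict[str, set[str]] = {}
    unmapped: list[str] = []
    for source_id in ids:
        if source_id in mapping:
            continue
        hits = table.get(source_id)
        mapping[source_id] = hits
        if not hits:
            unmapped.append(source_id)
    return MapResult(mapping=mapping, unmapped=unmapped)
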