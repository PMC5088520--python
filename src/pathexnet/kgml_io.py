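"""Read and write KGML (KEGG Markup Language) pathway documents.

A KGML file describes one pathway as a set of *entries* (the boxes of the
pathway chart: genes, orthologs, compounds, linked maps, and groups of
entries) and *relations* (typed links between two entries, optionally
annotated with subtypes such as ``activation`` or ``phosphorylation``).
A single gene entry may carry several KEGG gene identifiers — a
multi-protein box — which is why the ``name`` attribute is space-split
into a list.

This module parses such documents into a small validated object model
(:class:`Pathway`, :class:`Entry`, :class:`Relation`), serializes the
model back to KGML, and resolves group entries into their member entries
so that downstream network construction only ever sees concrete entries.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Union

from lxml import etree

from .errors import KGMLParseError, KGMLValidationError

__all__ = [
    "Entry",
    "Relation",
    "Pathway",
    "parse_kgml",
    "serialize_kgml",
    "expand_groups",
    "ENTRY_TYPES",
    "RELATION_TYPES",
]

PATHWAY_ID_RE = re.compile(r"^[a-z]{2,4}\d{5}$")

#: Entry types carried by the model.  Anything else found in a document is
#: preserved verbatim (KGML has historically added types), but only these
#: participate in validation rules.
ENTRY_TYPES = ("gene", "ortholog", "compound", "map", "group")

RELATION_TYPES = ("PPrel", "GErel", "ECrel", "PCrel", "maplink")


@dataclass(frozen=True)
class Entry:
    """One KGML entry element.

    ``kegg_names`` is the space-split ``name`` attribute; the KGML
    placeholder string ``"undefined"`` (used for group entries) yields an
    empty list.  ``component_ids`` is non-empty only for ``group`` entries.
    """

    entry_id: str
    entry_type: str
    kegg_names: tuple[str, ...] = ()
    component_ids: tuple[str, ...] = ()

    @property
    def is_gene(self) -> bool:
        return self.entry_type == "gene"


@dataclass(frozen=True)
class Relation:
    """One KGML relation element: an (entry1, entry2) link with a relation
    type and zero or more subtype names.  KGML permits relations without
    any subtype element, so ``subtypes`` may be empty."""

    entry1: str
    entry2: str
    relation_type: str
    subtypes: tuple[str, ...] = ()


@dataclass
class Pathway:
    """A parsed KGML pathway document."""

    pathway_id: str
    organism: str
    title: str = ""
    entries: list[Entry] = field(default_factory=list)
    relations: list[Relation] = field(default_factory=list)

    def entry_by_id(self) -> dict[str, Entry]:
        return {e.entry_id: e for e in self.entries}

    def gene_entries(self) -> list[Entry]:
        return [e for e in self.entries if e.is_gene]


def _strip_namespace(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _parse_name_attr(name: str) -> tuple[str, ...]:
    name = (name or "").strip()
    if not name or name == "undefined":
        return ()
    return tuple(name.split())


def parse_kgml(source: Union[str, Path, bytes]) -> Pathway:
    """Parse a KGML document into a :class:`Pathway`.

    Parameters
    ----------
    source:
        A file path, or the XML document itself as ``bytes`` / a string
        starting with ``<``.

    Raises
    ------
    KGMLParseError
        If the XML is not well-formed (the message names the line).
    KGMLValidationError
        If a relation references an entry id that is not defined, or the
        root element is not ``pathway``.
    """
    try:
        if isinstance(source, bytes):
            root = etree.fromstring(source)
        elif isinstance(source, str) and source.lstrip().startswith("<"):
            root = etree.fromstring(source.encode("utf-8"))
        else:
            # lxml resolves external DTDs by default only when asked; KGML
            # files declare a DTD at genome.jp which must never be fetched.
            parser = etree.XMLParser(no_network=True, load_dtd=False)
            root = etree.parse(str(source), parser).getroot()
    except etree.XMLSyntaxError as exc:
        raise KGMLParseError(f"malformed XML: {exc}") from exc

    if _strip_namespace(root.tag) != "pathway":
        raise KGMLValidationError(
            f"root element is <{_strip_namespace(root.tag)}>, expected <pathway>"
        )

    raw_name = root.get("name", "")
    pathway_id = raw_name.split(":", 1)[-1] if raw_name else ""
    organism = root.get("org", "")
    if not organism and PATHWAY_ID_RE.match(pathway_id):
        organism = re.match(r"^[a-z]{2,4}", pathway_id).group(0)
    title = root.get("title", "")

    entries: list[Entry] = []
    relations: list[Relation] = []
    n_relation_elements = 0
    for child in root:
        tag = _strip_namespace(child.tag) if isinstance(child.tag, str) else None
        if tag == "entry":
            components = tuple(
                sub.get("id")
                for sub in child
                if isinstance(sub.tag, str) and _strip_namespace(sub.tag) == "component"
            )
            entries.append(
                Entry(
                    entry_id=child.get("id", ""),
                    entry_type=child.get("type", ""),
                    kegg_names=_parse_name_attr(child.get("name", "")),
                    component_ids=components,
                )
            )
        elif tag == "relation":
            n_relation_elements += 1
            subtypes = tuple(
                sub.get("name", "")
                for sub in child
                if isinstance(sub.tag, str) and _strip_namespace(sub.tag) == "subtype"
            )
            relations.append(
                Relation(
                    entry1=child.get("entry1", ""),
                    entry2=child.get("entry2", ""),
                    relation_type=child.get("type", ""),
                    subtypes=subtypes,
                )
            )
        # 'reaction' and graphics elements are deliberately ignored: the
        # relational model downstream is built from relation links only.

    pathway = Pathway(
        pathway_id=pathway_id,
        organism=organism,
        title=title,
        entries=entries,
        relations=relations,
    )
    assert len(pathway.relations) == n_relation_elements
    _validate(pathway)
    return pathway


def _validate(pathway: Pathway) -> None:
    ids = {e.entry_id for e in pathway.entries}
    dangling = [
        (r.entry1, r.entry2)
        for r in pathway.relations
        if r.entry1 not in ids or r.entry2 not in ids
    ]
    if dangling:
        missing = sorted(
            {eid for pair in dangling for eid in pair if eid not in ids}
        )
        raise KGMLValidationError(
            f"{len(dangling)} relation(s) reference undefined entry ids: "
            + ", ".join(missing)
        )
    for entry in pathway.entries:
        if entry.entry_type == "group":
            if not entry.component_ids:
                raise KGMLValidationError(
                    f"group entry {entry.entry_id} has no components"
                )
            unresolved = [c for c in entry.component_ids if c not in ids]
            if unresolved:
                raise KGMLValidationError(
                    f"group entry {entry.entry_id} has unresolvable components: "
                    + ", ".join(unresolved)
                )


def serialize_kgml(pathway: Pathway) -> bytes:
    """Serialize a :class:`Pathway` back to a KGML document (UTF-8 bytes).

    Only the model's information content is written (ids, types, names,
    components, relations and subtypes); graphics elements are not
    reconstructed.  ``parse_kgml(serialize_kgml(p))`` returns a model equal
    to ``p``.
    """
    root = etree.Element(
        "pathway",
        name=f"path:{pathway.pathway_id}",
        org=pathway.organism,
        title=pathway.title,
    )
    for entry in pathway.entries:
        el = etree.SubElement(
            root,
            "entry",
            id=entry.entry_id,
            name=" ".join(entry.kegg_names) if entry.kegg_names else "undefined",
            type=entry.entry_type,
        )
        for cid in entry.component_ids:
            etree.SubElement(el, "component", id=cid)
    for rel in pathway.relations:
        el = etree.SubElement(
            root,
            "relation",
            entry1=rel.entry1,
            entry2=rel.entry2,
            type=rel.relation_type,
        )
        for st in rel.subtypes:
            etree.SubElement(el, "subtype", name=st)
    return etree.tostring(
        root, xml_declaration=True, encoding="UTF-8", pretty_print=True
    )


def _resolve_group(
    entry_id: str, by_id: dict[str, Entry], _seen: frozenset = frozenset()
) -> list[str]:
    """Resolve an entry id to the concrete (non-group) entry ids behind it."""
    entry = by_id.get(entry_id)
    if entry is None:
        raise KGMLValidationError(f"unresolvable entry id {entry_id!r}")
    if entry.entry_type != "group":
        return [entry_id]
    if entry_id in _seen:
        raise KGMLValidationError(f"cyclic group definition at entry {entry_id!r}")
    out: list[str] = []
    for cid in entry.component_ids:
        out.extend(_resolve_group(cid, by_id, _seen | {entry_id}))
    return out


def expand_groups(pathway: Pathway) -> Pathway:
    """Fan group-entry relation endpoints out to their member entries.

    Every relation endpoint that is a group is replaced by one relation per
    component (a relation between two groups of sizes m and n becomes m*n
    relations); group entries are then removed.  Idempotent; a pathway
    without groups is returned structurally unchanged.
    """
    by_id = pathway.entry_by_id()
    for entry in pathway.entries:
        if entry.entry_type == "group":
            _resolve_group(entry.entry_id, by_id)  # raises if unresolvable
    if not any(e.entry_type == "group" for e in pathway.entries):
        return replace(
            pathway,
            entries=list(pathway.entries),
            relations=list(pathway.relations),
        )

    new_relations: list[Relation] = []
    for rel in pathway.relations:
        left = _resolve_group(rel.entry1, by_id)
        right = _resolve_group(rel.entry2, by_id)
        for a in left:
            for b in right:
                new_relations.append(replace(rel, entry1=a, entry2=b))
    new_entries = [e for e in pathway.entries if e.entry_type != "group"]
    return replace(pathway, entries=new_entries, relations=new_relations)


def pathways_equal(a: Pathway, b: Pathway) -> bool:
    """Model equality on identity fields and entry/relation multisets."""
    from collections import Counter

    return (
        (a.pathway_id, a.organism, a.title) == (b.pathway_id, b.organism, b.title)
        and Counter(a.entries) == Counter(b.entries)
        and Counter(a.relations) == Counter(b.relations)
    )


def count_relation_elements(source: Union[str, Path, bytes]) -> int:
    """Count ``relation`` elements in a KGML document without building the
    model — used to assert that parsing never drops a relation."""
    if isinstance(source, bytes):
        root = etree.fromstring(source)
    elif isinstance(source, str) and source.lstrip().startswith("<"):
        root = etree.fromstring(source.encode("utf-8"))
    else:
        root = etree.parse(str(source)).getroot()
    return sum(
        1
        for child in root
        if isinstance(child.tag, str) and _strip_namespace(child.tag) == "relation"
    )
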