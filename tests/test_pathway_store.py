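"""Relational store: entry expansion, deduplication, SQL round-trips."""

import shutil

import pytest

from pathexnet.errors import StoreError
from pathexnet.id_mapping import MappingTable, load_mapping
from pathexnet.kgml_io import Entry, Pathway, Relation
from pathexnet.pathway_store import (
    Store,
    build_store,
    build_store_from_pathways,
    canonical_pair,
    collapse_subtypes,
)


def make_mapping(n: int = 10) -> MappingTable:
    return MappingTable(
        "kegg_gene", {f"hsa:{i}": {f"P{10000 + i:05d}"} for i in range(1, n + 1)}
    )


def one_relation_pathway(left: list[int], right: list[int], subtype="activation",
                         pid="hsa90001") -> Pathway:
    return Pathway(
        pid,
        "hsa",
        entries=[
            Entry("1", "gene", kegg_names=tuple(f"hsa:{i}" for i in left)),
            Entry("2", "gene", kegg_names=tuple(f"hsa:{i}" for i in right)),
        ],
        relations=[Relation("1", "2", "PPrel", (subtype,))],
    )


class TestCategoryCollapse:
    @pytest.mark.parametrize(
        "subtypes,expected",
        [
            (("activation",), "activation"),
            (("inhibition",), "inhibition"),
            (("repression",), "inhibition"),
            (("expression",), "expression"),
            (("phosphorylation",), "other"),
            (("binding/association",), "other"),
            ((), "other"),
            (("phosphorylation", "activation"), "activation"),
            (("inhibition", "expression"), "inhibition"),
        ],
    )
    def test_collapse(self, subtypes, expected):
        assert collapse_subtypes(subtypes) == expected


class TestBuildStore:
    def test_m_by_n_entry_expansion(self):
        pw = one_relation_pathway([1, 2], [3, 4, 5])
        store = build_store_from_pathways([pw], make_mapping())
        assert len(store.relations) == 6
        assert len(store.proteins) == 5

    def test_same_relation_in_two_pathways_dedups_with_provenance(self):
        pw1 = one_relation_pathway([1], [2], pid="hsa90001")
        pw2 = one_relation_pathway([1], [2], pid="hsa90002")
        store = build_store_from_pathways([pw1, pw2], make_mapping())
        assert len(store.relations) == 1
        (row,) = store.relations.values()
        assert row.pathway_ids == {"hsa90001", "hsa90002"}

    def test_self_loop_excluded(self):
        # two entries that map to the same single accession
        mapping = MappingTable("kegg_gene", {"hsa:1": {"P10001"}, "hsa:2": {"P10001"}})
        pw = one_relation_pathway([1], [2])
        store = build_store_from_pathways([pw], mapping)
        assert len(store.relations) == 0
        assert "P10001" in store.proteins

    def test_pairs_are_canonical_and_unordered(self):
        pw = Pathway(
            "hsa90001",
            "hsa",
            entries=[
                Entry("1", "gene", kegg_names=("hsa:2",)),
                Entry("2", "gene", kegg_names=("hsa:1",)),
            ],
            relations=[Relation("1", "2", "PPrel", ("activation",))],
        )
        store = build_store_from_pathways([pw], make_mapping())
        (row,) = store.relations.values()
        assert (row.protein_a, row.protein_b) == canonical_pair(
            row.protein_b, row.protein_a
        )
        assert row.protein_a < row.protein_b

    def test_unmapped_entry_contributes_no_relations(self):
        mapping = MappingTable("kegg_gene", {"hsa:1": {"P10001"}})
        pw = one_relation_pathway([1], [9])  # hsa:9 unmapped
        store = build_store_from_pathways([pw], mapping)
        assert len(store.relations) == 0
        assert set(store.proteins) == {"P10001"}

    def test_pcrel_and_maplink_contribute_no_rows(self):
        pw = Pathway(
            "hsa90001",
            "hsa",
            entries=[
                Entry("1", "gene", kegg_names=("hsa:1",)),
                Entry("2", "gene", kegg_names=("hsa:2",)),
                Entry("3", "compound", kegg_names=("cpd:C00076",)),
            ],
            relations=[
                Relation("1", "3", "PCrel", ("compound",)),
                Relation("1", "2", "maplink", ()),
            ],
        )
        store = build_store_from_pathways([pw], make_mapping())
        assert len(store.relations) == 0

    def test_empty_directory_is_an_error(self, tmp_path):
        with pytest.raises(StoreError, match="no KGML"):
            build_store(tmp_path, make_mapping())

    def test_unparseable_file_is_skipped_not_fatal(self, corpus, tmp_path):
        corpus_dir, truth = corpus
        work = tmp_path / "kgml"
        shutil.copytree(corpus_dir / "kgml", work)
        (work / "broken.xml").write_text("<pathway")
        mapping = load_mapping(corpus_dir / "mapping.tsv")
        store = build_store(work, mapping)
        assert len(store.relations) == truth.store["n_relation_rows"]

    def test_corpus_ground_truth_counts(self, corpus):
        corpus_dir, truth = corpus
        mapping = load_mapping(corpus_dir / "mapping.tsv")
        store = build_store(corpus_dir / "kgml", mapping)
        assert len(store.proteins) == truth.store["n_protein_rows"]
        assert len(store.relations) == truth.store["n_relation_rows"]

    def test_build_is_invariant_under_corpus_duplication(self, corpus, tmp_path):
        corpus_dir, _ = corpus
        work = tmp_path / "kgml"
        shutil.copytree(corpus_dir / "kgml", work)
        for f in list(work.glob("*.xml")):
            shutil.copy(f, work / f"copy_{f.name}")
        mapping = load_mapping(corpus_dir / "mapping.tsv")
        assert build_store(work, mapping) == build_store(corpus_dir / "kgml", mapping)

    def test_referential_integrity(self, corpus):
        corpus_dir, _ = corpus
        mapping = load_mapping(corpus_dir / "mapping.tsv")
        store = build_store(corpus_dir / "kgml", mapping)
        in_relations = {
            acc for row in store.relations.values()
            for acc in (row.protein_a, row.protein_b)
        }
        assert in_relations <= set(store.proteins)


class TestQuery:
    @pytest.fixture()
    def store(self, corpus):
        corpus_dir, _ = corpus
        mapping = load_mapping(corpus_dir / "mapping.tsv")
        return build_store(corpus_dir / "kgml", mapping)

    def test_query_returns_only_tagged_rows(self, store):
        pid = sorted(store.pathway_ids())[0]
        proteins, relations = store.query_pathway(pid)
        assert all(pid in r.pathway_ids for r in proteins)
        assert all(pid in r.pathway_ids for r in relations)

    def test_query_union_over_all_pathways_covers_store(self, store):
        seen_rel, seen_prot = set(), set()
        for pid in store.pathway_ids():
            proteins, relations = store.query_pathway(pid)
            seen_prot |= {p.uniprot_accession for p in proteins}
            seen_rel |= {r.key for r in relations}
        assert seen_prot == set(store.proteins)
        assert seen_rel == set(store.relations)

    def test_absent_pathway_gives_empty_result_with_warning(self, store, caplog):
        with caplog.at_level("WARNING"):
            proteins, relations = store.query_pathway("hsa99999")
        assert proteins == [] and relations == []
        assert any("hsa99999" in rec.message for rec in caplog.records)


class TestPersistence:
    @pytest.fixture()
    def store(self, corpus):
        corpus_dir, _ = corpus
        mapping = load_mapping(corpus_dir / "mapping.tsv")
        return build_store(corpus_dir / "kgml", mapping)

    def test_sql_dump_round_trip(self, store, tmp_path):
        dump = tmp_path / "store.sql"
        store.dump_sql(dump)
        assert Store.load_sql(dump) == store

    def test_sqlite_save_load_round_trip(self, store, tmp_path):
        db = tmp_path / "store.db"
        store.save(db)
        assert Store.load(db) == store

    def test_empty_store_dump_is_schema_only(self, tmp_path):
        dump = tmp_path / "empty.sql"
        Store().dump_sql(dump)
        text = dump.read_text()
        assert "CREATE TABLE" in text and "INSERT" not in text

    def test_dump_has_one_insert_per_relation_row(self, store, tmp_path):
        dump = tmp_path / "store.sql"
        store.dump_sql(dump)
        n_inserts = sum(
            1
            for line in dump.read_text().splitlines()
            if line.startswith("INSERT INTO relations")
        )
        assert n_inserts == len(store.relations)

    def test_dump_is_deterministic(self, store, tmp_path):
        a, b = tmp_path / "a.sql", tmp_path / "b.sql"
        store.dump_sql(a)
        store.dump_sql(b)
        assert a.read_bytes() == b.read_bytes()

    def test_tsv_export_is_sorted_and_complete(self, store, tmp_path):
        store.to_tsv(tmp_path / "p.tsv", tmp_path / "r.tsv")
        plines = (tmp_path / "p.tsv").read_text().splitlines()[1:]
        rlines = (tmp_path / "r.tsv").read_text().splitlines()[1:]
        assert len(plines) == len(store.proteins)
        assert len(rlines) == len(store.relations)
        assert plines == sorted(plines)
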