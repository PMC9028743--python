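"""Readers/writers: round-trips, invariant enforcement, diagnostics."""

import numpy as np
import pytest

from cochleapharm.data import (
    AgeGroup,
    CountMatrix,
    CuratedGeneLists,
    DrugCatalog,
    DrugRecord,
    DrugTarget,
    FormatError,
    GeneSet,
    GeneSetCollection,
    OntologyDag,
    SampleAnnotation,
    Substructure,
    read_count_table,
    read_drug_catalog,
    read_gene_list,
    read_gmt,
    read_sample_sheet,
    read_slim_dag,
    read_target_knowledge,
    validate_annotations,
    write_count_table,
    write_drug_catalog,
    write_gene_list,
    write_gmt,
    write_sample_sheet,
    write_slim_dag,
    write_target_knowledge,
    TargetKnowledge,
)


class TestCountTable:
    def test_round_trip_identity(self, tmp_path, random_counts):
        path = tmp_path / "counts.tsv"
        write_count_table(random_counts, path)
        back = read_count_table(path)
        assert back.gene_ids == random_counts.gene_ids
        assert back.sample_ids == random_counts.sample_ids
        np.testing.assert_array_equal(back.counts, random_counts.counts)

    def test_small_table_dims(self, tmp_path):
        path = tmp_path / "c.tsv"
        path.write_text("gene_id\tA\tB\ng1\t1\t2\ng2\t3\t4\n")
        cm = read_count_table(path)
        assert cm.n_genes == 2 and cm.n_samples == 2
        assert cm.counts[1, 1] == 4

    def test_negative_cell_rejected(self, tmp_path):
        path = tmp_path / "c.tsv"
        path.write_text("gene_id\tA\tB\ng1\t1\t-3\n")
        with pytest.raises(FormatError, match="g1"):
            read_count_table(path)

    def test_non_integer_cell_rejected(self, tmp_path):
        path = tmp_path / "c.tsv"
        path.write_text("gene_id\tA\ng1\t1.5\n")
        with pytest.raises(FormatError):
            read_count_table(path)

    def test_duplicate_gene_rejected(self, tmp_path):
        path = tmp_path / "c.tsv"
        path.write_text("gene_id\tA\ng1\t1\ng1\t2\n")
        with pytest.raises(FormatError, match="g1"):
            read_count_table(path)

    def test_htseq_special_rows_dropped(self, tmp_path):
        path = tmp_path / "c.tsv"
        path.write_text("gene_id\tA\ng1\t5\n__no_feature\t99\n__ambiguous\t3\n")
        cm = read_count_table(path)
        assert cm.gene_ids == ["g1"]


class TestSampleSheet:
    def test_enum_parsing_case_insensitive(self, tmp_path):
        path = tmp_path / "s.tsv"
        path.write_text(
            "sample_id\tsubstructure\tage_group\treplicate\nS1\toc_sgn\tYOUNG\t1\n"
        )
        (a,) = read_sample_sheet(path)
        assert a.substructure is Substructure.OC_SGN
        assert a.age_group is AgeGroup.young
        assert a.replicate == 1

    def test_unknown_substructure_rejected(self, tmp_path):
        path = tmp_path / "s.tsv"
        path.write_text("sample_id\tsubstructure\tage_group\treplicate\nS1\tcortex\tyoung\t1\n")
        with pytest.raises(FormatError, match="cortex"):
            read_sample_sheet(path)

    def test_full_design_grid_round_trips(self, tmp_path):
        annotations = [
            SampleAnnotation(f"{sub.value}_{age.value}_{rep}", sub, age, rep)
            for sub in Substructure
            for age in AgeGroup
            for rep in (1, 2, 3)
        ]
        path = tmp_path / "s.tsv"
        write_sample_sheet(annotations, path)
        back = read_sample_sheet(path)
        assert back == annotations
        assert len({(a.substructure, a.age_group, a.replicate) for a in back}) == 12

    def test_duplicate_design_cell_rejected(self):
        dup = [
            SampleAnnotation("A", Substructure.OC_SGN, AgeGroup.young, 1),
            SampleAnnotation("B", Substructure.OC_SGN, AgeGroup.young, 1),
        ]
        with pytest.raises(FormatError, match="share design cell"):
            validate_annotations(dup)

    def test_count_table_join_consistency(self):
        counts = CountMatrix(["g1"], ["A", "B"], np.array([[1, 2]]))
        anns = [SampleAnnotation("A", Substructure.OC_SGN, AgeGroup.young, 1)]
        with pytest.raises(FormatError, match="B"):
            validate_annotations(anns, counts)


class TestGmt:
    def test_basic_parse_and_dedup(self, tmp_path):
        path = tmp_path / "x.gmt"
        path.write_text("T1\tGO-BP\tA\tB\nT2\tGO-MF\tA\tA\tC\n")
        coll = read_gmt(path)
        assert len(coll["T1"].members) == 2
        assert len(coll["T2"].members) == 2  # duplicate member collapsed

    def test_short_line_rejected(self, tmp_path):
        path = tmp_path / "x.gmt"
        path.write_text("T1\tdesc-only\n")
        with pytest.raises(FormatError, match="fewer than 3"):
            read_gmt(path)

    def test_random_collection_round_trips(self, tmp_path, rng):
        genes = [f"G{i}" for i in range(200)]
        sets = [
            GeneSet(
                f"T{t}",
                f"T{t}",
                "GO-BP" if t % 2 else "GO-MF",
                frozenset(rng.choice(genes, rng.integers(3, 30), replace=False)),
            )
            for t in range(100)
        ]
        coll = GeneSetCollection(sets)
        path = tmp_path / "r.gmt"
        write_gmt(coll, path)
        back = read_gmt(path)
        assert {s.term_id: s.members for s in back} == {s.term_id: s.members for s in coll}
        assert {s.term_id: s.namespace for s in back} == {
            s.term_id: s.namespace for s in coll
        }


class TestSlimDag:
    def test_ancestors_transitive(self, tmp_path):
        path = tmp_path / "d.tsv"
        path.write_text("#slim\tt3\nt1\tt2\nt2\tt3\n")
        dag = read_slim_dag(path)
        assert {"t2", "t3"} <= dag.ancestors("t1")
        assert dag.slim_ancestors("t1") == {"t3"}

    def test_cycle_rejected(self, tmp_path):
        path = tmp_path / "d.tsv"
        path.write_text("t1\tt2\nt2\tt1\n")
        with pytest.raises(FormatError, match="cycle"):
            read_slim_dag(path)

    def test_random_dag_ancestors_match_closure_oracle(self, rng):
        # random DAG on a topological order; brute-force reachability oracle
        n = 50
        nodes = [f"n{i}" for i in range(n)]
        edges = [
            (nodes[i], nodes[j])
            for i in range(n)
            for j in range(i + 1, n)
            if rng.random() < 0.08
        ]
        reach = {v: set() for v in nodes}
        for _ in range(n):  # Floyd-Warshall-style fixpoint
            for c, p in edges:
                before = len(reach[c])
                reach[c] |= {p} | reach[p]
                _ = before
        dag = OntologyDag(nodes, edges, slim_terms=[nodes[-1]])
        for v in nodes:
            assert dag.ancestors(v) == reach[v]

    def test_round_trip(self, tmp_path):
        dag = OntologyDag(["a", "b", "c", "iso"], [("a", "b"), ("b", "c")], ["c"])
        path = tmp_path / "d.tsv"
        write_slim_dag(dag, path)
        back = read_slim_dag(path)
        assert back.nodes == dag.nodes
        assert back.edges == dag.edges
        assert back.slim_terms == dag.slim_terms


class TestDrugCatalog:
    def _digoxin(self):
        return DrugRecord(
            "digoxin",
            "digoxin",
            frozenset({"approved"}),
            False,
            (DrugTarget("ATP1A1", "human", frozenset({"inhibitor"})),),
        )

    def test_single_record_catalog(self, tmp_path):
        catalog = DrugCatalog([self._digoxin()])
        path = tmp_path / "c.json"
        write_drug_catalog(catalog, path)
        back = read_drug_catalog(path)
        assert len(back) == 1
        drug = back["digoxin"]
        assert not drug.ototoxic
        assert drug.targets[0].gene_symbol == "ATP1A1"
        assert drug.targets[0].actions == frozenset({"inhibitor"})

    def test_two_targets_load_unfiltered(self):
        rec = DrugRecord(
            "d2",
            "d2",
            frozenset({"approved"}),
            False,
            (
                DrugTarget("A", "human", frozenset({"inhibitor"})),
                DrugTarget("B", "human", frozenset({"agonist"})),
            ),
        )
        assert len(DrugCatalog([rec])["d2"].targets) == 2

    def test_action_outside_vocabulary_rejected(self):
        with pytest.raises(FormatError, match="vocabulary"):
            DrugTarget("A", "human", frozenset({"frobnicator"}))

    def test_degradation_alias_normalized(self, tmp_path):
        path = tmp_path / "c.json"
        path.write_text(
            '{"drugs": [{"drug_id": "d", "name": "d", "approval_groups": ["approved"],'
            ' "ototoxic": false, "targets": [{"gene_symbol": "A", "organism": "human",'
            ' "actions": ["degradation"]}]}]}'
        )
        assert read_drug_catalog(path)["d"].targets[0].actions == frozenset({"degrader"})

    def test_missing_ototoxic_flag_rejected(self, tmp_path):
        path = tmp_path / "c.json"
        path.write_text(
            '{"drugs": [{"drug_id": "d", "name": "d", "approval_groups": [], "targets": []}]}'
        )
        with pytest.raises(FormatError, match="ototoxic"):
            read_drug_catalog(path)

    def test_random_catalog_round_trips(self, tmp_path, rng):
        actions = sorted({"inhibitor", "agonist", "binder", "antibody", "activator"})
        drugs = [
            DrugRecord(
                f"d{i}",
                f"drug {i}",
                frozenset(rng.choice(["approved", "investigational", "withdrawn"],
                                     rng.integers(1, 3), replace=False)),
                bool(rng.random() < 0.2),
                tuple(
                    DrugTarget(
                        f"G{rng.integers(100)}",
                        "human",
                        frozenset(rng.choice(actions, rng.integers(1, 3), replace=False)),
                    )
                    for _ in range(rng.integers(1, 4))
                ),
            )
            for i in range(30)
        ]
        catalog = DrugCatalog(drugs)
        path = tmp_path / "c.json"
        write_drug_catalog(catalog, path)
        back = read_drug_catalog(path)
        assert len(back) == 30
        for d in catalog:
            b = back[d.drug_id]
            assert b.approval_groups == d.approval_groups
            assert b.ototoxic == d.ototoxic
            assert {(t.gene_symbol, t.actions) for t in b.targets} == {
                (t.gene_symbol, t.actions) for t in d.targets
            }


class TestListsAndKnowledge:
    def test_gene_list_round_trip(self, tmp_path):
        path = tmp_path / "l.txt"
        write_gene_list({"Atp1a1", "GABRA1"}, path)
        assert read_gene_list(path) == {"Atp1a1", "GABRA1"}

    def test_curated_lists_case_normalized(self):
        lists = CuratedGeneLists(frozenset({"Atp1a1"}), frozenset({"trp53"}), frozenset({"CDH23"}))
        assert lists.ageing == {"ATP1A1"}
        assert lists.senescence == {"TRP53"}

    def test_knowledge_round_trip(self, tmp_path):
        kn = {
            "A": TargetKnowledge("A", True, False, True, False),
            "B": TargetKnowledge("B", False, False, False, False),
        }
        path = tmp_path / "k.tsv"
        write_target_knowledge(kn, path)
        assert read_target_knowledge(path) == kn
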