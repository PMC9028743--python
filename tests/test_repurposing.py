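"""Candidate-drug selection, TDL classification and the GO-slim network."""

from itertools import product

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from cochleapharm.data import (
    DrugCatalog,
    DrugRecord,
    DrugTarget,
    GeneSet,
    GeneSetCollection,
    OntologyDag,
    TargetKnowledge,
)
from cochleapharm.repurposing import (
    RepurposingCandidate,
    assign_tdl,
    candidates_to_frame,
    goslim_network,
    map_symbols,
    select_candidates,
    tdl_distribution,
)
from cochleapharm.simulate import arhl_fixture


def _deg(genes_up=(), genes_down=(), sub="OC_SGN"):
    genes = list(genes_up) + list(genes_down)
    return {
        sub: pd.DataFrame(
            {
                "log2fc": [1.0] * len(genes_up) + [-1.0] * len(genes_down),
                "fdr": [0.01] * len(genes),
                "direction": ["up"] * len(genes_up) + ["down"] * len(genes_down),
            },
            index=pd.Index(genes, name="gene"),
        )
    }


def _drug(drug_id, target, actions, approved=True, ototoxic=False, extra_targets=()):
    groups = frozenset({"approved"} if approved else {"investigational"})
    targets = (DrugTarget(target, "human", frozenset(actions)),) + tuple(
        DrugTarget(t, "human", frozenset({"inhibitor"})) for t in extra_targets
    )
    return DrugRecord(drug_id, drug_id, groups, ototoxic, targets)


class TestMapSymbols:
    def test_default_uppercases(self):
        assert map_symbols(["Atp1a1"]) == {"Atp1a1": "ATP1A1"}

    def test_explicit_table_matches_default(self):
        assert map_symbols(["Atp1a1"], {"Atp1a1": "ATP1A1"}) == {"Atp1a1": "ATP1A1"}

    def test_one_to_many_rejected(self):
        with pytest.raises(ValueError, match="ambiguous"):
            map_symbols(["Atp1a1"], {"Atp1a1": ["ATP1A1", "ATP1A2"]})

    def test_many_to_one_rejected(self):
        with pytest.raises(ValueError):
            map_symbols(["a", "b"], {"a": "X", "b": "X"})


class TestSelectCandidates:
    def test_inhibitor_of_upregulated_target_selected(self):
        deg = _deg(genes_up=["Atp1a1"])
        catalog = DrugCatalog([_drug("digoxin", "ATP1A1", {"inhibitor"})])
        cands, audit = select_candidates(deg, catalog)
        assert len(cands) == 1
        c = cands[0]
        assert (c.substructure, c.de_direction, c.action) == ("OC_SGN", "up", "inhibitor")
        assert audit["passed"].all()

    def test_agonist_of_downregulated_target_selected(self):
        deg = _deg(genes_down=["Pth1r"], sub="SV_SL")
        catalog = DrugCatalog([_drug("abaloparatide", "PTH1R", {"agonist"})])
        cands, _ = select_candidates(deg, catalog)
        assert [(c.substructure, c.de_direction) for c in cands] == [("SV_SL", "down")]

    @pytest.mark.parametrize(
        "drug,expected_filter",
        [
            (_drug("d", "ATP1A1", {"agonist"}), "action_concordant"),
            (_drug("d", "ATP1A1", {"inhibitor"}, extra_targets=["XYZ"]), "single_target"),
            (_drug("d", "ATP1A1", {"inhibitor"}, ototoxic=True), "non_ototoxic"),
            (_drug("d", "ATP1A1", {"inhibitor"}, approved=False), "approved"),
            (_drug("d", "NOTDE1", {"inhibitor"}), "deg_target"),
        ],
    )
    def test_each_decoy_class_rejected_at_its_filter(self, drug, expected_filter):
        deg = _deg(genes_up=["Atp1a1"])
        cands, audit = select_candidates(deg, DrugCatalog([drug]))
        assert cands == []
        failed = audit[~audit["passed"]]
        assert not failed.empty
        # the filter chain runs in order per (drug, target) pair; the pair
        # carrying the DEG target is the one attributed to the decoy's flaw
        deg_pair = failed[failed["target_gene"] == drug.targets[0].gene_symbol]
        assert (deg_pair["failed_filter"] == expected_filter).all()

    def test_multiple_actions_pass_with_one_concordant(self):
        deg = _deg(genes_up=["Il4r"], sub="SV_SL")
        catalog = DrugCatalog([_drug("dupilumab", "IL4R", {"antibody", "agonist"})])
        cands, _ = select_candidates(deg, catalog)
        assert len(cands) == 1 and cands[0].action == "antibody"

    def test_exclusive_flag_and_strict_mode(self):
        deg = {
            "OC_SGN": _deg(genes_up=["Shared1"])["OC_SGN"],
            "SV_SL": _deg(genes_up=["Shared1", "Only2"], sub="SV_SL")["SV_SL"],
        }
        catalog = DrugCatalog(
            [_drug("d1", "SHARED1", {"inhibitor"}), _drug("d2", "ONLY2", {"inhibitor"})]
        )
        cands, _ = select_candidates(deg, catalog)
        by_drug = {c.drug_id: c for c in cands}
        assert not by_drug["d1"].exclusive and by_drug["d2"].exclusive
        assert sum(c.drug_id == "d1" for c in cands) == 2  # one per substructure
        strict, _ = select_candidates(deg, catalog, require_exclusive=True)
        assert {c.drug_id for c in strict} == {"d2"}

    def test_candidates_satisfy_all_filters_by_audit(self):
        deg_tables, catalog, _ = arhl_fixture()
        cands, audit = select_candidates(deg_tables, catalog)
        emitted = {(c.drug_id, c.target_gene) for c in cands}
        passed = {
            (r.drug_id, r.target_gene) for r in audit.itertuples() if r.passed
        }
        assert emitted == passed

    def test_idempotent_on_selected_drugs(self):
        deg_tables, catalog, _ = arhl_fixture()
        cands, _ = select_candidates(deg_tables, catalog)
        selected_ids = {c.drug_id for c in cands}
        sub_catalog = DrugCatalog([d for d in catalog if d.drug_id in selected_ids])
        again, _ = select_candidates(deg_tables, sub_catalog)
        assert {(c.drug_id, c.target_gene, c.substructure) for c in again} == {
            (c.drug_id, c.target_gene, c.substructure) for c in cands
        }


class TestTdl:
    def test_all_sixteen_flag_combinations(self):
        # precedence: approved drug > active ligand > (GO | phenotype) > dark
        for drug, ligand, go, pheno in product([False, True], repeat=4):
            kn = {"G": TargetKnowledge("G", drug, ligand, go, pheno)}
            level = assign_tdl(kn, ["G"])["G"]
            if drug:
                assert level == "Tclin"
            elif ligand:
                assert level == "Tchem"
            elif go or pheno:
                assert level == "Tbio"
            else:
                assert level == "Tdark"

    def test_missing_record_is_dark(self):
        assert assign_tdl({}, ["UNKNOWN"])["UNKNOWN"] == "Tdark"

    def test_distribution_partitions_and_sums(self):
        kn = {
            "A": TargetKnowledge("A", True, False, False, False),
            "B": TargetKnowledge("B", False, True, False, False),
            "C": TargetKnowledge("C", False, False, True, False),
            "D": TargetKnowledge("D", False, False, False, False),
        }
        dist = tdl_distribution({"OC_SGN": ["A", "B", "C", "D"]}, kn)
        assert dist["n"].sum() == 4
        assert dist["pct"].sum() == pytest.approx(100.0)
        assert (dist["pct"] == 25.0).all()

    def test_planted_proportions_recovered(self, rng):
        genes = [f"G{i}" for i in range(40)]
        levels = ["Tclin"] * 4 + ["Tchem"] * 8 + ["Tbio"] * 20 + ["Tdark"] * 8
        kn = {
            g: TargetKnowledge(
                g,
                lv == "Tclin",
                lv == "Tchem",
                lv == "Tbio",
                False,
            )
            for g, lv in zip(genes, levels)
        }
        dist = tdl_distribution({"SV_SL": genes}, kn).set_index("level")
        assert dist.loc["Tclin", "n"] == 4
        assert dist.loc["Tchem", "pct"] == pytest.approx(20.0)
        assert dist.loc["Tbio", "pct"] == pytest.approx(50.0)


class TestGoslimNetwork:
    def _candidate(self, gene, lfc=1.0):
        return RepurposingCandidate("d", "d", gene, gene, "OC_SGN", "up", "inhibitor",
                                    lfc, True)

    def test_true_path_edge_to_slim_ancestor(self):
        sets = GeneSetCollection([GeneSet("t1", "t1", "GO-BP", frozenset({"GENE"}))])
        dag = OntologyDag(["t1", "s1"], [("t1", "s1")], ["s1"])
        g = goslim_network([self._candidate("GENE", 2.5)], sets, dag)
        assert g.has_edge("GENE", "s1")
        assert g.nodes["GENE"]["log2fc"] == 2.5

    def test_unconnected_gene_omitted(self):
        sets = GeneSetCollection([GeneSet("t1", "t1", "GO-BP", frozenset({"GENE"}))])
        dag = OntologyDag(["t1", "s_elsewhere"], [], ["s_elsewhere"])
        g = goslim_network([self._candidate("GENE")], sets, dag)
        assert "GENE" not in g

    def test_namespace_filter_splits_aspects(self):
        sets = GeneSetCollection(
            [
                GeneSet("bp1", "bp1", "GO-BP", frozenset({"GENE"})),
                GeneSet("mf1", "mf1", "GO-MF", frozenset({"GENE"})),
            ]
        )
        dag = OntologyDag(["bp1", "mf1", "sb", "sm"], [("bp1", "sb"), ("mf1", "sm")],
                          ["sb", "sm"])
        g_bp = goslim_network([self._candidate("GENE")], sets, dag, namespace="GO-BP")
        assert set(g_bp.nodes) == {"GENE", "sb"}

    def test_edges_match_transitive_closure_oracle(self, rng):
        # random layered DAG; the network must contain edge (gene, slim) iff
        # some annotation term reaches that slim by child->parent paths
        n = 50
        nodes = [f"n{i}" for i in range(n)]
        edges = [
            (nodes[i], nodes[j])
            for i in range(n)
            for j in range(i + 1, n)
            if rng.random() < 0.06
        ]
        slim = set(rng.choice(nodes, 10, replace=False))
        dag = OntologyDag(nodes, edges, slim)
        reach = {v: {v} for v in nodes}
        for _ in range(n):
            for c, p in edges:
                reach[c] |= reach[p]
        genes = [f"GENE{i}" for i in range(8)]
        annot = []
        for gi, gene in enumerate(genes):
            terms = rng.choice(nodes, 3, replace=False)
            for t in terms:
                annot.append((gene, t))
        sets = GeneSetCollection(
            [
                GeneSet(t, t, "GO-BP", frozenset({g for g, tt in annot if tt == t}))
                for t in {t for _, t in annot}
            ]
        )
        cands = [self._candidate(g) for g in genes]
        graph = goslim_network(cands, sets, dag)
        expected_edges = set()
        for gene, term in annot:
            for s in reach[term] & slim:
                expected_edges.add((gene, s))
        got = {(u, v) if u.startswith("GENE") else (v, u) for u, v in graph.edges}
        assert got == expected_edges

    def test_graphml_round_trip(self, tmp_path):
        sets = GeneSetCollection([GeneSet("t1", "t1", "GO-BP", frozenset({"GENE"}))])
        dag = OntologyDag(["t1", "s1"], [("t1", "s1")], ["s1"])
        g = goslim_network([self._candidate("GENE", -1.5)], sets, dag)
        path = tmp_path / "net.graphml"
        nx.write_graphml(g, path)
        back = nx.read_graphml(path)
        assert back.nodes["GENE"]["log2fc"] == -1.5
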