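"""Direction-concordant drug repurposing from differential-expression tables.

The core selection procedure: map differentially expressed genes to drug
targets, then keep drugs that are (1) targeting a significant DEG,
(2) approved, (3) specific (a single protein target), (4) safe (no known
ototoxicity), and (5) mechanism-concordant — antagonist-class actions
(antagonist / inhibitor / binder / antibody / degrader) for upregulated
targets, agonist-class actions (agonist / partial agonist / activator) for
downregulated targets.  Every considered (drug, target) pair leaves an
audit trail naming the first filter it failed.

Also here: Pharos-style target-development-level (TDL) classification of
the DEG druggability landscape, and the GO-slim bipartite network of
candidate targets under the true-path rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

from .data import (
    AGONIST_CLASS,
    ANTAGONIST_CLASS,
    DrugCatalog,
    GeneSetCollection,
    OntologyDag,
    TargetKnowledge,
)

__all__ = [
    "RepurposingCandidate",
    "TDL_LEVELS",
    "FILTER_NAMES",
    "map_symbols",
    "select_candidates",
    "assign_tdl",
    "tdl_distribution",
    "goslim_network",
]

FILTER_NAMES = (
    "deg_target",
    "approved",
    "single_target",
    "non_ototoxic",
    "action_concordant",
)

TDL_LEVELS = ("Tclin", "Tchem", "Tbio", "Tdark")


@dataclass(frozen=True)
class RepurposingCandidate:
    """One admissible (drug, target, substructure) repurposing call."""

    drug_id: str
    drug_name: str
    target_gene: str  # human-style symbol
    source_gene: str  # identifier as in the DEG table
    substructure: str
    de_direction: str  # "up" | "down"
    action: str  # the concordant action that admitted the pair
    log2fc: float
    exclusive: bool  # target DE in exactly one substructure


def map_symbols(
    genes: Sequence[str], mapping_table: Mapping[str, str] | None = None
) -> dict[str, str]:
    """Map gene identifiers to human-style symbols.

    With an explicit table the mapping must be one-to-one on the given
    genes (a gene mapping to several symbols, or two genes mapping to the
    same symbol, is an error listing the offenders); without one, symbols
    are upper-cased (the usual mouse->human convention for symbol-level
    matching).
    """
    if mapping_table is not None:
        multi = {
            g: mapping_table[g]
            for g in genes
            if isinstance(mapping_table.get(g), (list, tuple, set, frozenset))
            and len(mapping_table[g]) != 1
        }
        if multi:
            raise ValueError(f"ambiguous symbol mapping (one-to-many): {multi}")
        mapping_table = {
            g: (next(iter(v)) if isinstance(v, (list, tuple, set, frozenset)) else v)
            for g, v in mapping_table.items()
        }
        values = [mapping_table[g] for g in genes if g in mapping_table]
        seen: dict[str, str] = {}
        ambiguous = []
        for g in genes:
            if g not in mapping_table:
                continue
            v = mapping_table[g]
            if v in seen and seen[v] != g:
                ambiguous.append((seen[v], g, v))
            seen[v] = g
        if ambiguous:
            raise ValueError(f"ambiguous symbol mapping (many-to-one): {ambiguous}")
        if len(set(values)) != len(values):
            raise ValueError("mapping table is not one-to-one on the given genes")
        return {g: mapping_table.get(g, str(g).upper()) for g in genes}
    return {g: str(g).upper() for g in genes}


def _direction_by_symbol(
    deg_tables: Mapping[str, pd.DataFrame], mapping_table: Mapping[str, str] | None
) -> dict[str, dict[str, tuple[str, str, float]]]:
    """symbol -> {substructure: (direction, source_gene, log2fc)} for significant DEGs."""
    out: dict[str, dict[str, tuple[str, str, float]]] = {}
    for sub, table in deg_tables.items():
        sig = table[table["direction"].isin(["up", "down"])]
        symbols = map_symbols(list(sig.index), mapping_table)
        for gene, row in sig.iterrows():
            sym = symbols[gene]
            out.setdefault(sym, {})[sub] = (row["direction"], gene, float(row["log2fc"]))
    return out


def select_candidates(
    deg_tables: Mapping[str, pd.DataFrame],
    catalog: DrugCatalog,
    mapping_table: Mapping[str, str] | None = None,
    require_exclusive: bool = False,
    protein_organisms: frozenset[str] | None = None,
) -> tuple[list[RepurposingCandidate], pd.DataFrame]:
    """Apply the approved / specific / safe / concordant filter chain.

    ``deg_tables`` maps substructure name -> classified DE table (index =
    gene, columns include log2fc and direction).  For each (drug, target)
    pair the five filters run in order and evaluation stops at the first
    failure, so every rejection is attributed to exactly one filter.  A drug
    with several recorded actions passes concordance if at least one action
    matches the target's direction.  One candidate is emitted per
    (drug, target, substructure); the ``exclusive`` flag marks targets DE in
    exactly one substructure, and ``require_exclusive`` turns that flag into
    a hard filter.

    Returns the candidate list and the audit table with one row per
    (drug, target) pair considered.
    """
    directions = _direction_by_symbol(deg_tables, mapping_table)
    candidates: list[RepurposingCandidate] = []
    audit_rows = []
    filter_chain = FILTER_NAMES + (("exclusive",) if require_exclusive else ())
    for drug in catalog:
        protein_targets = [
            t
            for t in drug.targets
            if protein_organisms is None or t.organism in protein_organisms
        ]
        for target in drug.targets:
            record = {
                "drug_id": drug.drug_id,
                "drug_name": drug.name,
                "target_gene": target.gene_symbol,
            }
            hits = directions.get(target.gene_symbol, {})
            outcome = None

            def fails(name: str) -> bool:
                if name == "deg_target":
                    return not hits
                if name == "approved":
                    return "approved" not in drug.approval_groups
                if name == "single_target":
                    return len(protein_targets) != 1
                if name == "non_ototoxic":
                    return drug.ototoxic
                if name == "action_concordant":
                    return not any(
                        _concordant_actions(target.actions, d) for d, _, _ in hits.values()
                    )
                if name == "exclusive":
                    return len(hits) != 1
                raise AssertionError(name)

            for name in filter_chain:
                if fails(name):
                    outcome = name
                    break
            record["passed"] = outcome is None
            record["failed_filter"] = outcome or ""
            audit_rows.append(record)
            if outcome is not None:
                continue
            for sub, (direction, source_gene, log2fc) in sorted(hits.items()):
                concordant = _concordant_actions(target.actions, direction)
                if not concordant:
                    continue
                candidates.append(
                    RepurposingCandidate(
                        drug_id=drug.drug_id,
                        drug_name=drug.name,
                        target_gene=target.gene_symbol,
                        source_gene=source_gene,
                        substructure=sub,
                        de_direction=direction,
                        action=sorted(concordant)[0],
                        log2fc=log2fc,
                        exclusive=len(hits) == 1,
                    )
                )
    audit = pd.DataFrame(
        audit_rows, columns=["drug_id", "drug_name", "target_gene", "passed", "failed_filter"]
    )
    return candidates, audit


def _concordant_actions(actions: frozenset[str], direction: str) -> set[str]:
    if direction == "up":
        return set(actions) & ANTAGONIST_CLASS
    if direction == "down":
        return set(actions) & AGONIST_CLASS
    return set()


def candidates_to_frame(candidates: Sequence[RepurposingCandidate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "drug_id": c.drug_id,
                "drug_name": c.drug_name,
                "target_gene": c.target_gene,
                "source_gene": c.source_gene,
                "substructure": c.substructure,
                "de_direction": c.de_direction,
                "action": c.action,
                "log2fc": c.log2fc,
                "exclusive": c.exclusive,
            }
            for c in candidates
        ],
        columns=[
            "drug_id",
            "drug_name",
            "target_gene",
            "source_gene",
            "substructure",
            "de_direction",
            "action",
            "log2fc",
            "exclusive",
        ],
    )


def assign_tdl(knowledge: Mapping[str, TargetKnowledge], genes: Sequence[str]) -> dict[str, str]:
    """Pharos-style target development levels with strict precedence.

    Tclin: linked to an approved drug.  Tchem: established chemistry (an
    active ligand) but no approved drug.  Tbio: GO annotation or a disease
    phenotype but neither of the above.  Tdark: none of the criteria.  A
    gene without a knowledge record gets all-false flags, hence Tdark.
    """
    out = {}
    for gene in genes:
        k = knowledge.get(gene)
        if k is None:
            out[gene] = "Tdark"
        elif k.has_approved_drug:
            out[gene] = "Tclin"
        elif k.has_active_ligand:
            out[gene] = "Tchem"
        elif k.has_go_annotation or k.has_disease_phenotype:
            out[gene] = "Tbio"
        else:
            out[gene] = "Tdark"
    return out


def tdl_distribution(
    deg_genes: Mapping[str, Sequence[str]],
    knowledge: Mapping[str, TargetKnowledge],
) -> pd.DataFrame:
    """Counts and percentages of TDL levels among DEGs, per substructure."""
    rows = []
    for sub, genes in deg_genes.items():
        genes = list(dict.fromkeys(genes))
        levels = assign_tdl(knowledge, genes)
        total = len(genes)
        for level in TDL_LEVELS:
            n = sum(1 for g in genes if levels[g] == level)
            rows.append(
                {
                    "substructure": sub,
                    "level": level,
                    "n": n,
                    "pct": 100.0 * n / total if total else 0.0,
                }
            )
    return pd.DataFrame(rows, columns=["substructure", "level", "n", "pct"])


def goslim_network(
    candidates: Sequence[RepurposingCandidate],
    annotations: GeneSetCollection,
    dag: OntologyDag,
    namespace: str | None = None,
) -> nx.Graph:
    """Bipartite gene <-> GO-slim term network of candidate drug targets.

    Each target gene's annotation terms are propagated to every slim
    ancestor under the true-path rule; an edge connects the gene to each
    slim term so reached.  Gene nodes carry the log2 fold change and
    substructure; genes with no slim-reachable annotation are omitted.
    Restrict to one namespace (e.g. "GO-BP") to mirror per-aspect views.
    """
    sets = annotations if namespace is None else annotations.filter_namespace(namespace)
    graph = nx.Graph()
    for cand in candidates:
        slims: set[str] = set()
        for term in sets.terms_for_gene(cand.target_gene):
            slims |= dag.slim_ancestors(term.term_id)
        if not slims:
            continue
        graph.add_node(
            cand.target_gene,
            bipartite="gene",
            log2fc=float(cand.log2fc),
            substructure=cand.substructure,
            de_direction=cand.de_direction,
        )
        for slim in slims:
            graph.add_node(slim, bipartite="term")
            graph.add_edge(cand.target_gene, slim)
    return graph
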