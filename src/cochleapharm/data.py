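"""Domain types and file I/O for the cochlear drug-repurposing pipeline.

Validated containers for every external format the pipeline touches:
HTSeq-style count tables, sample sheets, GMT gene-set collections,
slim-ontology DAGs, drug-catalog snapshots, curated gene lists and
target-knowledge tables.  Readers reject inputs that violate the type
invariants with a diagnostic naming the offending record; read/write pairs
round-trip.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Substructure",
    "AgeGroup",
    "CountMatrix",
    "SampleAnnotation",
    "GeneSet",
    "GeneSetCollection",
    "OntologyDag",
    "DrugTarget",
    "DrugRecord",
    "DrugCatalog",
    "TargetKnowledge",
    "CuratedGeneLists",
    "FormatError",
    "ACTION_VOCABULARY",
    "read_count_table",
    "write_count_table",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_gmt",
    "write_gmt",
    "read_drug_catalog",
    "write_drug_catalog",
    "read_slim_dag",
    "write_slim_dag",
    "read_gene_list",
    "write_gene_list",
    "read_target_knowledge",
    "write_target_knowledge",
]


class FormatError(ValueError):
    """An input file violates the format contract or a type invariant."""


class Substructure(str, Enum):
    """Micro-dissected cochlear substructure.

    OC_SGN: organ of Corti plus spiral ganglion neurons (sensorineural).
    SV_SL: stria vascularis plus spiral ligament (endocochlear-potential
    generating).
    """

    OC_SGN = "OC_SGN"
    SV_SL = "SV_SL"


class AgeGroup(str, Enum):
    young = "young"
    old = "old"


#: Controlled vocabulary of drug mechanism-of-action terms.  The antagonist
#: class (antagonist, inhibitor, binder, antibody, degrader) is matched to
#: upregulated targets; the agonist class (agonist, partial agonist,
#: activator) to downregulated targets.
ACTION_VOCABULARY = frozenset(
    {
        "agonist",
        "partial agonist",
        "activator",
        "antagonist",
        "inhibitor",
        "binder",
        "antibody",
        "degrader",
    }
)

#: Antagonist-class actions: concordant with upregulated targets.
ANTAGONIST_CLASS = frozenset({"antagonist", "inhibitor", "binder", "antibody", "degrader"})
#: Agonist-class actions: concordant with downregulated targets.
AGONIST_CLASS = frozenset({"agonist", "partial agonist", "activator"})

# aliases normalised on load ("degradation" appears in free-text sources)
_ACTION_ALIASES = {"degradation": "degrader"}


@dataclass
class CountMatrix:
    """Gene x sample matrix of non-negative integer read counts."""

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray  # shape (n_genes, n_samples), integer dtype

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dup = _first_duplicate(self.gene_ids)
            raise FormatError(f"duplicate gene id: {dup!r}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dup = _first_duplicate(self.sample_ids)
            raise FormatError(f"duplicate sample id: {dup!r}")
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise FormatError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                bad = np.argwhere(np.mod(self.counts, 1) != 0)[0]
                raise FormatError(
                    f"non-integer count for gene {self.gene_ids[bad[0]]!r}, "
                    f"sample {self.sample_ids[bad[1]]!r}"
                )
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            bad = np.argwhere(self.counts < 0)[0]
            raise FormatError(
                f"negative count for gene {self.gene_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return CountMatrix(list(self.gene_ids), list(sample_ids), self.counts[:, idx])

    def subset_genes(self, gene_ids: Sequence[str]) -> "CountMatrix":
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        idx = [pos[g] for g in gene_ids]
        return CountMatrix(list(gene_ids), list(self.sample_ids), self.counts[idx, :])


@dataclass(frozen=True)
class SampleAnnotation:
    """Design labels for one RNA-seq sample: substructure, age, replicate."""

    sample_id: str
    substructure: Substructure
    age_group: AgeGroup
    replicate: int

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise FormatError(f"sample {self.sample_id!r}: replicate must be >= 1")


def validate_annotations(
    annotations: Sequence[SampleAnnotation], counts: CountMatrix | None = None
) -> None:
    """Check design-cell uniqueness and, if given, the join with a count matrix."""
    seen: dict[tuple, str] = {}
    ids = set()
    for a in annotations:
        if a.sample_id in ids:
            raise FormatError(f"duplicate sample id in sample sheet: {a.sample_id!r}")
        ids.add(a.sample_id)
        cell = (a.substructure, a.age_group, a.replicate)
        if cell in seen:
            raise FormatError(
                f"samples {seen[cell]!r} and {a.sample_id!r} share design cell "
                f"({a.substructure.value}, {a.age_group.value}, rep {a.replicate})"
            )
        seen[cell] = a.sample_id
    if counts is not None:
        missing = [s for s in counts.sample_ids if s not in ids]
        if missing:
            raise FormatError(f"count-table samples without annotation: {missing}")


@dataclass(frozen=True)
class GeneSet:
    term_id: str
    term_name: str
    namespace: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise FormatError(f"term {self.term_id!r} has no members")


@dataclass
class GeneSetCollection:
    """Collection of named gene sets (GO terms, pathways)."""

    sets: list[GeneSet]

    def __post_init__(self) -> None:
        ids = [s.term_id for s in self.sets]
        if len(set(ids)) != len(ids):
            raise FormatError(f"duplicate term id: {_first_duplicate(ids)!r}")
        self._by_id = {s.term_id: s for s in self.sets}

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, term_id: str) -> GeneSet:
        return self._by_id[term_id]

    def __contains__(self, term_id: str) -> bool:
        return term_id in self._by_id

    def terms_for_gene(self, gene: str) -> list[GeneSet]:
        return [s for s in self.sets if gene in s.members]

    def filter_namespace(self, namespace: str) -> "GeneSetCollection":
        return GeneSetCollection([s for s in self.sets if s.namespace == namespace])


class OntologyDag:
    """Acyclic child->parent term graph with a designated slim subset.

    Ancestor queries implement the true-path rule used for GO-slim
    annotation: a gene annotated to a term is annotated to every ancestor.
    """

    def __init__(
        self,
        nodes: Iterable[str],
        edges: Iterable[tuple[str, str]],
        slim_terms: Iterable[str],
    ) -> None:
        import networkx as nx

        self.graph = nx.DiGraph()
        self.graph.add_nodes_from(nodes)
        self.graph.add_edges_from(edges)  # child -> parent
        if not nx.is_directed_acyclic_graph(self.graph):
            cycle = nx.find_cycle(self.graph)
            raise FormatError(f"ontology contains a cycle through {cycle[0][0]!r}")
        self.slim_terms = frozenset(slim_terms)
        unknown = self.slim_terms - set(self.graph.nodes)
        if unknown:
            raise FormatError(f"slim terms not in DAG: {sorted(unknown)}")

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return set(self.graph.edges)

    def ancestors(self, term: str) -> set[str]:
        """All terms reachable by child->parent edges (excludes *term*)."""
        import networkx as nx

        if term not in self.graph:
            return set()
        return nx.descendants(self.graph, term)

    def slim_ancestors(self, term: str) -> set[str]:
        """Slim terms implied by *term* under the true-path rule (self included)."""
        if term not in self.graph:
            return set()
        return (self.ancestors(term) | {term}) & self.slim_terms


@dataclass(frozen=True)
class DrugTarget:
    gene_symbol: str
    organism: str
    actions: frozenset[str]

    def __post_init__(self) -> None:
        bad = set(self.actions) - ACTION_VOCABULARY
        if bad:
            raise FormatError(
                f"target {self.gene_symbol!r}: actions {sorted(bad)} outside "
                f"the controlled vocabulary"
            )


@dataclass(frozen=True)
class DrugRecord:
    drug_id: str
    name: str
    approval_groups: frozenset[str]
    ototoxic: bool
    targets: tuple[DrugTarget, ...]


@dataclass
class DrugCatalog:
    """DrugBank-like snapshot: approval status, ototoxicity flag, protein targets."""

    drugs: list[DrugRecord]
    action_vocabulary: frozenset[str] = field(default_factory=lambda: ACTION_VOCABULARY)

    def __post_init__(self) -> None:
        ids = [d.drug_id for d in self.drugs]
        if len(set(ids)) != len(ids):
            raise FormatError(f"duplicate drug id: {_first_duplicate(ids)!r}")
        self._by_id = {d.drug_id: d for d in self.drugs}

    def __len__(self) -> int:
        return len(self.drugs)

    def __iter__(self):
        return iter(self.drugs)

    def __getitem__(self, drug_id: str) -> DrugRecord:
        return self._by_id[drug_id]


@dataclass(frozen=True)
class TargetKnowledge:
    """Pharos-like evidence flags per gene symbol, for TDL classification."""

    gene_symbol: str
    has_approved_drug: bool
    has_active_ligand: bool
    has_go_annotation: bool
    has_disease_phenotype: bool


@dataclass
class CuratedGeneLists:
    """Curated ageing / senescence / deafness gene symbol sets."""

    ageing: frozenset[str]
    senescence: frozenset[str]
    deafness: frozenset[str]

    def __post_init__(self) -> None:
        for name in ("ageing", "senescence", "deafness"):
            symbols = getattr(self, name)
            if any(not s for s in symbols):
                raise FormatError(f"curated list {name!r} contains an empty symbol")
            setattr(self, name, frozenset(s.upper() for s in symbols))

    def as_dict(self) -> dict[str, frozenset[str]]:
        return {"ageing": self.ageing, "senescence": self.senescence, "deafness": self.deafness}


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _first_duplicate(items: Sequence) -> object:
    seen = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return None


def read_count_table(path: str | Path) -> CountMatrix:
    """Read an HTSeq-style TSV count table (genes x samples).

    First column holds gene identifiers, the header row sample identifiers.
    HTSeq special counter rows (gene id starting with ``__``, e.g.
    ``__no_feature``) are dropped with a logged count; they tally reads, not
    genes.
    """
    df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype={0: str})
    special = df.index.astype(str).str.startswith("__")
    if special.any():
        logger.info("dropped %d HTSeq special counter rows from %s", int(special.sum()), path)
        df = df.loc[~special]
    gene_ids = [str(g) for g in df.index]
    sample_ids = [str(s) for s in df.columns]
    try:
        values = df.to_numpy()
        return CountMatrix(gene_ids, sample_ids, values)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_count_table(counts: CountMatrix, path: str | Path) -> None:
    counts.to_frame().to_csv(path, sep="\t", index_label="gene_id")


def read_sample_sheet(path: str | Path) -> list[SampleAnnotation]:
    """Read a sample sheet TSV with columns sample_id, substructure, age_group, replicate."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "substructure", "age_group", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing sample-sheet columns {sorted(missing)}")
    annotations = []
    for _, row in df.iterrows():
        sub_token = row["substructure"].strip()
        age_token = row["age_group"].strip()
        try:
            sub = Substructure(sub_token.upper().replace("/", "_"))
        except ValueError:
            raise FormatError(
                f"{path}: sample {row['sample_id']!r}: unknown substructure {sub_token!r}"
            ) from None
        try:
            age = AgeGroup(age_token.lower())
        except ValueError:
            raise FormatError(
                f"{path}: sample {row['sample_id']!r}: unknown age group {age_token!r}"
            ) from None
        try:
            rep = int(row["replicate"])
        except ValueError:
            raise FormatError(
                f"{path}: sample {row['sample_id']!r}: replicate {row['replicate']!r} "
                "is not an integer"
            ) from None
        annotations.append(SampleAnnotation(str(row["sample_id"]), sub, age, rep))
    validate_annotations(annotations)
    return annotations


def write_sample_sheet(annotations: Sequence[SampleAnnotation], path: str | Path) -> None:
    pd.DataFrame(
        {
            "sample_id": [a.sample_id for a in annotations],
            "substructure": [a.substructure.value for a in annotations],
            "age_group": [a.age_group.value for a in annotations],
            "replicate": [a.replicate for a in annotations],
        }
    ).to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: term, description, then tab-separated member symbols.

    The description field carries the namespace (e.g. GO-BP); duplicate
    members on a line are collapsed.
    """
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            term_id, desc = fields[0], fields[1]
            members = frozenset(m for m in fields[2:] if m)
            namespace = desc if desc else "unspecified"
            sets.append(GeneSet(term_id, term_id, namespace, members))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in collection:
            fh.write("\t".join([s.term_id, s.namespace, *sorted(s.members)]) + "\n")


def _parse_actions(raw: Iterable[str]) -> frozenset[str]:
    return frozenset(_ACTION_ALIASES.get(a.strip().lower(), a.strip().lower()) for a in raw)


def read_drug_catalog(path: str | Path) -> DrugCatalog:
    """Read a drug catalog from JSON (canonical, nested targets) or TSV.

    JSON schema: ``{"action_vocabulary": [...], "drugs": [{drug_id, name,
    approval_groups, ototoxic, targets: [{gene_symbol, organism, actions}]}]}``.
    The TSV form holds one row per (drug, target) pair.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            payload = json.load(fh)
        records = payload["drugs"] if isinstance(payload, dict) else payload
        drugs = []
        for rec in records:
            if "ototoxic" not in rec:
                raise FormatError(f"{path}: drug {rec.get('drug_id')!r} missing ototoxic flag")
            targets = tuple(
                DrugTarget(
                    gene_symbol=t["gene_symbol"],
                    organism=t.get("organism", "human"),
                    actions=_parse_actions(t.get("actions", [])),
                )
                for t in rec.get("targets", [])
            )
            drugs.append(
                DrugRecord(
                    drug_id=rec["drug_id"],
                    name=rec.get("name", rec["drug_id"]),
                    approval_groups=frozenset(rec.get("approval_groups", [])),
                    ototoxic=bool(rec["ototoxic"]),
                    targets=targets,
                )
            )
        return DrugCatalog(drugs)
    # TSV: one row per (drug, target)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"drug_id", "name", "approval_groups", "ototoxic", "gene_symbol", "organism", "actions"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing drug-catalog columns {sorted(missing)}")
    drugs = []
    for drug_id, grp in df.groupby("drug_id", sort=False):
        first = grp.iloc[0]
        oto_token = str(first["ototoxic"]).strip().lower()
        if oto_token not in {"true", "false", "0", "1"}:
            raise FormatError(f"{path}: drug {drug_id!r}: bad ototoxic flag {first['ototoxic']!r}")
        targets = tuple(
            DrugTarget(
                gene_symbol=row["gene_symbol"],
                organism=row["organism"],
                actions=_parse_actions(str(row["actions"]).split("|")),
            )
            for _, row in grp.iterrows()
            if isinstance(row["gene_symbol"], str) and row["gene_symbol"]
        )
        drugs.append(
            DrugRecord(
                drug_id=str(drug_id),
                name=str(first["name"]),
                approval_groups=frozenset(str(first["approval_groups"]).split("|")),
                ototoxic=oto_token in {"true", "1"},
                targets=targets,
            )
        )
    return DrugCatalog(drugs)


def write_drug_catalog(catalog: DrugCatalog, path: str | Path) -> None:
    payload = {
        "action_vocabulary": sorted(catalog.action_vocabulary),
        "drugs": [
            {
                "drug_id": d.drug_id,
                "name": d.name,
                "approval_groups": sorted(d.approval_groups),
                "ototoxic": d.ototoxic,
                "targets": [
                    {
                        "gene_symbol": t.gene_symbol,
                        "organism": t.organism,
                        "actions": sorted(t.actions),
                    }
                    for t in d.targets
                ],
            }
            for d in catalog
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")


def read_slim_dag(path: str | Path) -> OntologyDag:
    """Read an ontology DAG from a TSV edge list.

    Lines are either ``child<TAB>parent`` edges, ``term<TAB>`` isolated-node
    declarations, or ``#slim<TAB>term`` slim designations.
    """
    edges: list[tuple[str, str]] = []
    nodes: set[str] = set()
    slim: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if fields[0] == "#slim":
                if len(fields) < 2:
                    raise FormatError(f"{path}:{lineno}: #slim line without a term")
                slim.add(fields[1])
            elif len(fields) >= 2 and fields[1]:
                edges.append((fields[0], fields[1]))
                nodes.update(fields[:2])
            else:
                nodes.add(fields[0])
    nodes.update(slim)
    return OntologyDag(nodes, edges, slim)


def write_slim_dag(dag: OntologyDag, path: str | Path) -> None:
    with open(path, "w") as fh:
        for term in sorted(dag.slim_terms):
            fh.write(f"#slim\t{term}\n")
        covered = set()
        for child, parent in sorted(dag.edges):
            fh.write(f"{child}\t{parent}\n")
            covered.update((child, parent))
        for node in sorted(dag.nodes - covered):
            fh.write(f"{node}\t\n")


def read_gene_list(path: str | Path) -> frozenset[str]:
    """Read a one-symbol-per-line gene list; blank lines and #-comments skipped."""
    out = set()
    with open(path) as fh:
        for line in fh:
            token = line.strip()
            if token and not token.startswith("#"):
                out.add(token)
    return frozenset(out)


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(g + "\n")


def read_target_knowledge(path: str | Path) -> dict[str, TargetKnowledge]:
    """Read a target-knowledge TSV (gene_symbol + four boolean evidence flags)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    flags = ["has_approved_drug", "has_active_ligand", "has_go_annotation", "has_disease_phenotype"]
    missing = {"gene_symbol", *flags} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing target-knowledge columns {sorted(missing)}")
    out = {}
    for _, row in df.iterrows():
        gene = str(row["gene_symbol"])
        values = {}
        for f in flags:
            token = str(row[f]).strip().lower()
            if token not in {"true", "false", "0", "1"}:
                raise FormatError(f"{path}: gene {gene!r}: bad flag {f}={row[f]!r}")
            values[f] = token in {"true", "1"}
        out[gene] = TargetKnowledge(gene, **values)
    return out


def write_target_knowledge(knowledge: Mapping[str, TargetKnowledge], path: str | Path) -> None:
    pd.DataFrame(
        {
            "gene_symbol": [k.gene_symbol for k in knowledge.values()],
            "has_approved_drug": [k.has_approved_drug for k in knowledge.values()],
            "has_active_ligand": [k.has_active_ligand for k in knowledge.values()],
            "has_go_annotation": [k.has_go_annotation for k in knowledge.values()],
            "has_disease_phenotype": [k.has_disease_phenotype for k in knowledge.values()],
        }
    ).to_csv(path, sep="\t", index=False)
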