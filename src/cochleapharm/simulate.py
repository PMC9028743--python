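"""Synthetic data with planted ground truth for the full pipeline.

Emulates the statistical structure of a two-substructure, two-age cochlear
RNA-seq study: negative-binomial counts in which substructure explains far
more expression variance than age, gene-set collections with
enriched-by-construction terms, drug catalogs with planted true candidates
and single-violation decoys, and a curated fixture encoding the published
age-related DEG directions and the approved drugs that target them.

All generators are pure functions of (config, seed): reruns are
bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import (
    AgeGroup,
    CountMatrix,
    CuratedGeneLists,
    DrugCatalog,
    DrugRecord,
    DrugTarget,
    GeneSet,
    GeneSetCollection,
    OntologyDag,
    SampleAnnotation,
    Substructure,
    TargetKnowledge,
)

__all__ = [
    "SimulationConfig",
    "simulate_counts",
    "simulate_gene_sets",
    "simulate_drug_catalog",
    "simulate_curated_lists",
    "truth_to_deg_tables",
    "arhl_fixture",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic 2 substructures x 2 ages x n_reps design.

    Baseline expression is log-normal on the log2 scale; dispersion follows
    the standard bulk RNA-seq trend alpha = a0/mu + a1.  Substructure
    effects hit far more genes than age effects (0.30 vs 0.05 by default),
    reproducing the regime where inter-substructure differences dominate
    the variance.  Age effects are drawn independently per substructure
    with a small shared fraction.
    """

    n_genes: int = 5000
    n_reps: int = 3
    baseline_log2_loc: float = 6.0
    baseline_log2_scale: float = 1.5
    dispersion_a0: float = 3.0
    dispersion_a1: float = 0.05
    fraction_de_substructure: float = 0.30
    fraction_de_age: float = 0.05
    shared_age_fraction: float = 0.15
    lfc_substructure: tuple[float, float] = (1.0, 4.0)
    lfc_age: tuple[float, float] = (1.5, 3.0)
    size_factor_range: tuple[float, float] = (0.5, 2.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fraction_de_substructure", "fraction_de_age", "shared_age_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_reps < 2:
            raise ValueError("n_reps must be >= 2")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        lo, hi = self.size_factor_range
        if not 0 < lo <= hi:
            raise ValueError("size_factor_range must be positive and ordered")


def simulate_counts(
    config: SimulationConfig,
) -> tuple[CountMatrix, list[SampleAnnotation], pd.DataFrame]:
    """Draw NB counts for the 2 x 2 x n_reps design with planted effects.

    Returns the count matrix, the sample sheet, and a truth table with the
    per-gene baseline mean, true substructure log2FC, true age log2FC within
    each substructure and the corresponding DE flags.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    genes = [f"g{i:05d}" for i in range(n)]

    baseline = 2.0 ** rng.normal(config.baseline_log2_loc, config.baseline_log2_scale, n)
    alpha = config.dispersion_a0 / baseline + config.dispersion_a1

    de_sub = rng.random(n) < config.fraction_de_substructure
    lfc_sub = np.zeros(n)
    lo, hi = config.lfc_substructure
    lfc_sub[de_sub] = rng.uniform(lo, hi, de_sub.sum()) * rng.choice([-1, 1], de_sub.sum())

    # age effects: independent per substructure, a shared_age_fraction of the
    # first substructure's age-DE genes is also age-DE in the second
    p, s = config.fraction_de_age, config.shared_age_fraction
    de_age_a = rng.random(n) < p
    prob_b = np.where(de_age_a, s, p * (1.0 - s) / max(1.0 - p, 1e-12))
    de_age_b = rng.random(n) < prob_b
    lo, hi = config.lfc_age
    lfc_age = {}
    for key, mask in (("OC_SGN", de_age_a), ("SV_SL", de_age_b)):
        v = np.zeros(n)
        v[mask] = rng.uniform(lo, hi, mask.sum()) * rng.choice([-1, 1], mask.sum())
        lfc_age[key] = v

    annotations: list[SampleAnnotation] = []
    for sub in (Substructure.OC_SGN, Substructure.SV_SL):
        for age in (AgeGroup.young, AgeGroup.old):
            for rep in range(1, config.n_reps + 1):
                annotations.append(
                    SampleAnnotation(f"{sub.value}_{age.value}_r{rep}", sub, age, rep)
                )
    lo_sf, hi_sf = config.size_factor_range
    factors = np.exp(rng.uniform(np.log(lo_sf), np.log(hi_sf), len(annotations)))

    counts = np.empty((n, len(annotations)), dtype=np.int64)
    for j, a in enumerate(annotations):
        log2_mu = np.log2(baseline)
        if a.substructure is Substructure.SV_SL:
            log2_mu = log2_mu + lfc_sub
        if a.age_group is AgeGroup.old:
            log2_mu = log2_mu + lfc_age[a.substructure.value]
        mu = factors[j] * 2.0**log2_mu
        # NB(mean mu, var mu + alpha mu^2) == numpy's (n=1/alpha, p=1/(1+alpha mu))
        counts[:, j] = rng.negative_binomial(1.0 / alpha, 1.0 / (1.0 + alpha * mu))

    truth = pd.DataFrame(
        {
            "baseline_mean": baseline,
            "true_size_factorless_alpha": alpha,
            "lfc_substructure": lfc_sub,
            "de_substructure": de_sub,
            "lfc_age_OC_SGN": lfc_age["OC_SGN"],
            "de_age_OC_SGN": de_age_a,
            "lfc_age_SV_SL": lfc_age["SV_SL"],
            "de_age_SV_SL": de_age_b,
        },
        index=pd.Index(genes, name="gene"),
    )
    truth.attrs["size_factors"] = factors
    return CountMatrix(genes, [a.sample_id for a in annotations], counts), annotations, truth


def truth_to_deg_tables(truth: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Oracle DEG tables (one per substructure) built from planted truth."""
    out = {}
    for sub in ("OC_SGN", "SV_SL"):
        de = truth[f"de_age_{sub}"]
        lfc = truth[f"lfc_age_{sub}"]
        out[sub] = pd.DataFrame(
            {
                "log2fc": lfc,
                "fdr": np.where(de, 0.0, 1.0),
                "direction": np.where(de & (lfc > 0), "up", np.where(de & (lfc < 0), "down", "ns")),
            },
            index=truth.index,
        )
    return out


def simulate_gene_sets(
    truth: pd.DataFrame,
    config: SimulationConfig,
    n_enriched_per_substructure: int = 5,
    n_background: int = 40,
    enriched_de_fraction: float = 0.8,
    term_size_range: tuple[int, int] = (20, 60),
) -> tuple[GeneSetCollection, OntologyDag]:
    """Gene sets with planted enrichment plus a slim DAG covering all terms.

    Enriched terms draw ``enriched_de_fraction`` of their members from one
    substructure's age-DE genes; background terms sample uniformly.  The
    DAG layers every term under an intermediate node and a slim root, so
    each term reaches at least one slim ancestor.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    genes = np.array(truth.index)
    sets: list[GeneSet] = []
    namespaces = ("GO-BP", "GO-MF")
    for si, sub in enumerate(("OC_SGN", "SV_SL")):
        de_genes = genes[truth[f"de_age_{sub}"].to_numpy()]
        for t in range(n_enriched_per_substructure):
            size = int(rng.integers(*term_size_range))
            n_de = min(int(round(enriched_de_fraction * size)), len(de_genes))
            members = set(rng.choice(de_genes, n_de, replace=False)) | set(
                rng.choice(genes, size - n_de, replace=False)
            )
            sets.append(
                GeneSet(
                    f"ENR_{sub}_{t:02d}",
                    f"planted enrichment {sub} {t}",
                    namespaces[si % 2],
                    frozenset(members),
                )
            )
    for t in range(n_background):
        size = int(rng.integers(*term_size_range))
        members = frozenset(rng.choice(genes, size, replace=False))
        sets.append(GeneSet(f"BG_{t:03d}", f"background {t}", namespaces[t % 2], members))

    collection = GeneSetCollection(sets)
    slim = [f"SLIM_{ns}_{i}" for ns in ("BP", "MF") for i in range(3)]
    inter = [f"INT_{i}" for i in range(4)]
    edges = [(inter[i], slim[int(rng.integers(len(slim)))]) for i in range(len(inter))]
    for s in collection:
        if rng.random() < 0.5:
            edges.append((s.term_id, inter[int(rng.integers(len(inter)))]))
        else:
            edges.append((s.term_id, slim[int(rng.integers(len(slim)))]))
    nodes = set(slim) | set(inter) | {s.term_id for s in collection}
    return collection, OntologyDag(nodes, edges, slim)


def simulate_curated_lists(
    truth: pd.DataFrame, config: SimulationConfig, sizes=(60, 50, 55), de_fraction: float = 0.2
) -> CuratedGeneLists:
    """Curated-style ageing/senescence/deafness lists seeded with some DE genes."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    genes = np.array(truth.index)
    de_any = genes[(truth["de_age_OC_SGN"] | truth["de_age_SV_SL"]).to_numpy()]
    out = []
    for size in sizes:
        n_de = min(int(round(de_fraction * size)), len(de_any))
        members = set(rng.choice(de_any, n_de, replace=False)) | set(
            rng.choice(genes, size - n_de, replace=False)
        )
        out.append(frozenset(str(g).upper() for g in members))
    return CuratedGeneLists(*out)


def simulate_drug_catalog(
    truth: pd.DataFrame,
    config: SimulationConfig | None = None,
    n_true_per_substructure: int = 4,
) -> tuple[DrugCatalog, dict[str, TargetKnowledge], list[dict]]:
    """Catalog with planted true candidates and single-violation decoys.

    True candidates are approved, single-target, non-ototoxic drugs with an
    action concordant with their target's planted age-DE direction, each
    targeting a gene age-DE in exactly one substructure.  Decoys violate
    exactly one filter each (unapproved / multi-target / ototoxic /
    discordant action / non-DEG target).  Returns the catalog, a
    target-knowledge table, and the expected candidate set as dicts of
    (drug_id, target_gene, substructure, de_direction).
    """
    seed = 3 if config is None else config.seed
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    sym = lambda g: str(g).upper()  # noqa: E731

    exclusive = {
        "OC_SGN": list(truth.index[truth["de_age_OC_SGN"] & ~truth["de_age_SV_SL"]]),
        "SV_SL": list(truth.index[truth["de_age_SV_SL"] & ~truth["de_age_OC_SGN"]]),
    }
    drugs: list[DrugRecord] = []
    expected: list[dict] = []
    used: set[str] = set()
    for sub, pool in exclusive.items():
        pool = [g for g in pool if g not in used]
        chosen = list(rng.choice(pool, min(n_true_per_substructure, len(pool)), replace=False))
        used.update(chosen)
        for i, gene in enumerate(chosen):
            lfc = truth.loc[gene, f"lfc_age_{sub}"]
            direction = "up" if lfc > 0 else "down"
            action = "inhibitor" if direction == "up" else "agonist"
            drug_id = f"true_{sub.lower()}_{i}"
            drugs.append(
                DrugRecord(
                    drug_id,
                    drug_id,
                    frozenset({"approved"}),
                    False,
                    (DrugTarget(sym(gene), "human", frozenset({action})),),
                )
            )
            expected.append(
                {
                    "drug_id": drug_id,
                    "target_gene": sym(gene),
                    "substructure": sub,
                    "de_direction": direction,
                }
            )

    # decoys: each violates exactly one filter
    pool = [g for g in exclusive["OC_SGN"] if g not in used]
    if len(pool) < 4:
        raise ValueError("too few exclusive age-DE genes to build decoy records")
    d_genes = list(rng.choice(pool, 4, replace=False))

    def action_for(gene, sub="OC_SGN", concordant=True):
        up = truth.loc[gene, f"lfc_age_{sub}"] > 0
        if not concordant:
            up = not up
        return "inhibitor" if up else "agonist"

    drugs.append(
        DrugRecord(
            "decoy_unapproved", "decoy_unapproved", frozenset({"investigational"}), False,
            (DrugTarget(sym(d_genes[0]), "human", frozenset({action_for(d_genes[0])})),),
        )
    )
    drugs.append(
        DrugRecord(
            "decoy_multitarget", "decoy_multitarget", frozenset({"approved"}), False,
            (
                DrugTarget(sym(d_genes[1]), "human", frozenset({action_for(d_genes[1])})),
                DrugTarget(sym(d_genes[2]), "human", frozenset({action_for(d_genes[2])})),
            ),
        )
    )
    drugs.append(
        DrugRecord(
            "decoy_ototoxic", "decoy_ototoxic", frozenset({"approved"}), True,
            (DrugTarget(sym(d_genes[3]), "human", frozenset({action_for(d_genes[3])})),),
        )
    )
    drugs.append(
        DrugRecord(
            "decoy_discordant", "decoy_discordant", frozenset({"approved"}), False,
            (DrugTarget(sym(d_genes[0]), "human", frozenset({action_for(d_genes[0], concordant=False)})),),
        )
    )
    drugs.append(
        DrugRecord(
            "decoy_nondeg", "decoy_nondeg", frozenset({"approved"}), False,
            (DrugTarget("NOT_A_DEG_GENE", "human", frozenset({"inhibitor"})),),
        )
    )

    catalog = DrugCatalog(drugs)
    knowledge: dict[str, TargetKnowledge] = {}
    levels = ["Tclin", "Tchem", "Tbio", "Tdark"]
    de_any = list(truth.index[truth["de_age_OC_SGN"] | truth["de_age_SV_SL"]])
    for i, gene in enumerate(de_any):
        level = levels[i % 4]
        knowledge[sym(gene)] = TargetKnowledge(
            sym(gene),
            has_approved_drug=level == "Tclin",
            has_active_ligand=level == "Tchem",
            has_go_annotation=level == "Tbio",
            has_disease_phenotype=level == "Tbio",
        )
    for e in expected:  # planted candidates are by definition Tclin
        knowledge[e["target_gene"]] = TargetKnowledge(e["target_gene"], True, True, True, True)
    return catalog, knowledge, expected


# ---------------------------------------------------------------------------
# curated in-study fixture
# ---------------------------------------------------------------------------

#: Age-related DEG directions per substructure, as reported for the cochlear
#: substructures, restricted to the drug-targeted genes.
ARHL_DEG_DIRECTIONS: dict[str, dict[str, str]] = {
    "OC_SGN": {"Atp1a1": "up", "Gabra1": "up", "Map2k1": "up", "Srebf1": "up"},
    "SV_SL": {
        "Alox5": "up",
        "Itgal": "up",
        "Itgb3": "up",
        "Elane": "up",
        "Pik3cd": "up",
        "Il4r": "up",
        "Ptgs1": "up",
        "Prg2": "up",
        "Xdh": "up",
        "Pgd": "up",
        "Pth1r": "down",
        "Pdgfra": "down",
        "Abcc9": "down",
    },
}

#: The 27 approved, specific, safe, direction-concordant drug-target pairs.
#: "ptgs1-blocker-unnamed" is a synthetic placeholder: the PTGS1-targeting
#: drug is described in the source material only as an antipyretic and
#: analgesic, never by name.  Olaratumab is an antibody recorded here with
#: an additional agonist-class action so the concordance rule admits its
#: pairing with downregulated PDGFRA (see docs/methods.md).
ARHL_DRUGS: list[tuple[str, str, tuple[str, ...]]] = [
    ("digoxin", "ATP1A1", ("inhibitor",)),
    ("acetyldigitoxin", "ATP1A1", ("inhibitor",)),
    ("deslanoside", "ATP1A1", ("inhibitor",)),
    ("bretylium", "ATP1A1", ("inhibitor",)),
    ("digitoxin", "ATP1A1", ("inhibitor",)),
    ("almitrine", "ATP1A1", ("inhibitor",)),
    ("ethchlorvynol", "GABRA1", ("inhibitor",)),
    ("methohexital", "GABRA1", ("inhibitor",)),
    ("zaleplon", "GABRA1", ("inhibitor",)),
    ("brexanolone", "GABRA1", ("inhibitor",)),
    ("cobimetinib", "MAP2K1", ("inhibitor",)),
    ("omega-3-acid ethyl esters", "SREBF1", ("inhibitor",)),
    ("zileuton", "ALOX5", ("inhibitor",)),
    ("lifitegrast", "ITGAL", ("antagonist",)),
    ("eptifibatide", "ITGB3", ("inhibitor",)),
    ("alpha-1-proteinase inhibitor", "ELANE", ("inhibitor",)),
    ("idelalisib", "PIK3CD", ("inhibitor",)),
    ("dupilumab", "IL4R", ("antibody",)),
    ("ptgs1-blocker-unnamed", "PTGS1", ("inhibitor",)),
    ("chymopapain", "PRG2", ("binder",)),
    ("allopurinol", "XDH", ("inhibitor",)),
    ("febuxostat", "XDH", ("inhibitor",)),
    ("gadopentetic acid", "PGD", ("inhibitor",)),
    ("abaloparatide", "PTH1R", ("agonist",)),
    ("teriparatide", "PTH1R", ("agonist",)),
    ("olaratumab", "PDGFRA", ("antibody", "agonist")),
    ("nicorandil", "ABCC9", ("activator",)),
]


def arhl_fixture() -> tuple[dict[str, pd.DataFrame], DrugCatalog, dict[str, TargetKnowledge]]:
    """Curated fixture: published DEG directions, drug catalog, target knowledge.

    The DEG tables carry synthetic fold-change magnitudes (signs match the
    reported directions); the catalog holds the 27 admissible drugs plus
    five decoy records each violating exactly one selection filter.
    """
    deg_tables: dict[str, pd.DataFrame] = {}
    for sub, dirs in ARHL_DEG_DIRECTIONS.items():
        genes = list(dirs)
        lfc = [
            (1.0 + 0.1 * i) * (1 if dirs[g] == "up" else -1) for i, g in enumerate(genes)
        ]
        deg_tables[sub] = pd.DataFrame(
            {
                "log2fc": lfc,
                "fdr": [0.01] * len(genes),
                "direction": [dirs[g] for g in genes],
            },
            index=pd.Index(genes, name="gene"),
        )

    drugs = [
        DrugRecord(
            name.replace(" ", "-"),
            name,
            frozenset({"approved"}),
            False,
            (DrugTarget(target, "human", frozenset(actions)),),
        )
        for name, target, actions in ARHL_DRUGS
    ]
    drugs += [
        DrugRecord(
            "decoy-unapproved", "decoy-unapproved", frozenset({"investigational"}), False,
            (DrugTarget("ALOX5", "human", frozenset({"inhibitor"})),),
        ),
        DrugRecord(
            "decoy-multitarget", "decoy-multitarget", frozenset({"approved"}), False,
            (
                DrugTarget("XDH", "human", frozenset({"inhibitor"})),
                DrugTarget("PGD", "human", frozenset({"inhibitor"})),
            ),
        ),
        DrugRecord(
            "decoy-ototoxic", "decoy-ototoxic", frozenset({"approved"}), True,
            (DrugTarget("ITGB3", "human", frozenset({"inhibitor"})),),
        ),
        DrugRecord(
            "decoy-discordant", "decoy-discordant", frozenset({"approved"}), False,
            (DrugTarget("ALOX5", "human", frozenset({"agonist"})),),
        ),
        DrugRecord(
            "decoy-nondeg", "decoy-nondeg", frozenset({"approved"}), False,
            (DrugTarget("TP53", "human", frozenset({"inhibitor"})),),
        ),
    ]
    catalog = DrugCatalog(drugs)

    targets = sorted({t for _, t, _ in ARHL_DRUGS})
    knowledge = {
        t: TargetKnowledge(t, True, True, True, True) for t in targets
    }
    knowledge["TP53"] = TargetKnowledge("TP53", True, True, True, True)
    return deg_tables, catalog, knowledge


def arhl_goslim_annotation() -> tuple[GeneSetCollection, OntologyDag]:
    """Small GO-style annotation and slim DAG for the curated fixture targets.

    Hand-assembled high-level annotations (ion transport, neurotransmission,
    immune response, lipid metabolism, signal transduction, oxidoreductase
    and receptor activity) sufficient to build the bipartite target network;
    synthetic, not a GO release.
    """
    bp = {
        "BP:ion_transport": {"ATP1A1", "ABCC9"},
        "BP:neurotransmission": {"GABRA1", "ATP1A1"},
        "BP:immune_response": {"ALOX5", "ITGAL", "ELANE", "PIK3CD", "IL4R", "PRG2", "PTGS1"},
        "BP:lipid_metabolism": {"SREBF1", "ALOX5", "PTGS1"},
        "BP:signal_transduction": {"MAP2K1", "PTH1R", "PDGFRA", "IL4R", "PIK3CD"},
        "BP:cell_adhesion": {"ITGAL", "ITGB3"},
        "BP:oxidative_stress": {"XDH", "PGD"},
    }
    mf = {
        "MF:atpase_activity": {"ATP1A1", "ABCC9"},
        "MF:ion_binding": {"ATP1A1", "XDH", "PGD", "MAP2K1"},
        "MF:oxidoreductase_activity": {"XDH", "PGD", "ALOX5", "PTGS1"},
        "MF:receptor_activity": {"GABRA1", "IL4R", "PTH1R", "PDGFRA"},
        "MF:kinase_activity": {"MAP2K1", "PIK3CD"},
        "MF:protease_or_binding": {"ELANE", "PRG2", "ITGAL", "ITGB3", "SREBF1"},
    }
    sets = [
        GeneSet(tid, tid.split(":", 1)[1].replace("_", " "), "GO-BP", frozenset(m))
        for tid, m in bp.items()
    ] + [
        GeneSet(tid, tid.split(":", 1)[1].replace("_", " "), "GO-MF", frozenset(m))
        for tid, m in mf.items()
    ]
    slim = {"SLIM_BP:metabolic_process", "SLIM_BP:response_to_stimulus",
            "SLIM_BP:transport_and_adhesion", "SLIM_MF:binding", "SLIM_MF:catalytic_activity"}
    edges = [
        ("BP:ion_transport", "SLIM_BP:transport_and_adhesion"),
        ("BP:neurotransmission", "SLIM_BP:response_to_stimulus"),
        ("BP:immune_response", "SLIM_BP:response_to_stimulus"),
        ("BP:lipid_metabolism", "SLIM_BP:metabolic_process"),
        ("BP:signal_transduction", "SLIM_BP:response_to_stimulus"),
        ("BP:cell_adhesion", "SLIM_BP:transport_and_adhesion"),
        ("BP:oxidative_stress", "SLIM_BP:metabolic_process"),
        ("MF:atpase_activity", "SLIM_MF:catalytic_activity"),
        ("MF:ion_binding", "SLIM_MF:binding"),
        ("MF:oxidoreductase_activity", "SLIM_MF:catalytic_activity"),
        ("MF:receptor_activity", "SLIM_MF:binding"),
        ("MF:kinase_activity", "SLIM_MF:catalytic_activity"),
        ("MF:protease_or_binding", "SLIM_MF:binding"),
    ]
    nodes = {s.term_id for s in sets} | slim
    return GeneSetCollection(sets), OntologyDag(nodes, edges, slim)
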