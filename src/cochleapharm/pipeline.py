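"""End-to-end orchestration: QC -> DE -> enrichment -> repurposing -> report.

``run_all`` executes every stage on an on-disk bundle under one output
directory; every stage is also independently invocable through the CLI.
All randomness flows from one root seed recorded in the run log; reruns
with the same config and seed produce byte-identical tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import de as de_mod
from . import enrichment as enr_mod
from . import qc as qc_mod
from . import repurposing as rep_mod
from .data import (
    CountMatrix,
    CuratedGeneLists,
    DrugCatalog,
    GeneSetCollection,
    OntologyDag,
    SampleAnnotation,
    Substructure,
    TargetKnowledge,
    write_count_table,
)
from .repurposing import candidates_to_frame

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_all", "report"]


@dataclass
class PipelineConfig:
    """Thresholds, flags and seed for a full pipeline run."""

    outdir: Path
    fdr: float = 0.05
    enrichment_threshold: float = 0.05
    enrichment_method: str = "bh"
    top_k: int = 20
    abundance_k: int = 1000
    require_exclusive: bool = False
    n_top_genes_pca: int = 500
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        for name in ("fdr", "enrichment_threshold"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")


def run_all(
    config: PipelineConfig,
    counts: CountMatrix,
    annotations: list[SampleAnnotation],
    gene_sets: GeneSetCollection,
    dag: OntologyDag,
    catalog: DrugCatalog,
    curated: CuratedGeneLists,
    knowledge: dict[str, TargetKnowledge],
) -> dict:
    """Run every stage and write the result bundle under ``config.outdir``.

    Returns an in-memory bundle with the per-stage results.  Stage order:
    filter -> normalize -> QC (correlation, PCA, abundance overlap) ->
    per-substructure age DE -> Venn / top tables -> enrichment (directional,
    term-set comparison, curated overlap) -> candidate selection -> TDL ->
    GO-slim networks -> report.
    """
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    (out / "run_config.json").write_text(
        json.dumps(
            {
                "fdr": config.fdr,
                "enrichment_threshold": config.enrichment_threshold,
                "enrichment_method": config.enrichment_method,
                "top_k": config.top_k,
                "abundance_k": config.abundance_k,
                "require_exclusive": config.require_exclusive,
                "seed": config.seed,
            },
            indent=1,
        )
    )
    bundle: dict = {"config": config}

    # --- QC -----------------------------------------------------------------
    counts = qc_mod.drop_unexpressed(counts)
    factors = qc_mod.size_factors(counts, allow_pseudo_reference=True)
    norm = qc_mod.normalize(counts, factors)
    bundle["counts"] = counts
    bundle["size_factors"] = factors
    pd.DataFrame({"sample_id": counts.sample_ids, "size_factor": factors}).to_csv(
        out / "size_factors.tsv", sep="\t", index=False, float_format="%.6g"
    )
    corr, order = qc_mod.sample_correlation(norm)
    corr.to_csv(out / "sample_correlation.tsv", sep="\t", float_format="%.6f")
    pca_res = qc_mod.pca(norm, n_top_genes=config.n_top_genes_pca)
    pca_df = pd.DataFrame(
        pca_res.scores,
        index=pca_res.sample_ids,
        columns=[f"PC{i+1}" for i in range(pca_res.scores.shape[1])],
    )
    pca_df.to_csv(out / "pca_scores.tsv", sep="\t", float_format="%.6f")
    pd.DataFrame(
        {
            "component": [f"PC{i+1}" for i in range(len(pca_res.variance_fraction))],
            "variance_fraction": pca_res.variance_fraction,
        }
    ).to_csv(out / "pca_variance.tsv", sep="\t", index=False, float_format="%.6f")
    bundle["pca"] = pca_res
    bundle["correlation_order"] = order

    # abundance overlap between substructures among young samples
    young = {
        sub: qc_mod.normalize(
            qc_mod.drop_unexpressed(_split_young(annotations, counts, sub)),
            allow_pseudo_reference=True,
        )
        for sub in (Substructure.OC_SGN, Substructure.SV_SL)
    }
    # re-align to the common gene universe before ranking
    common = sorted(
        set(young[Substructure.OC_SGN].gene_ids) & set(young[Substructure.SV_SL].gene_ids)
    )
    aligned = {}
    for sub, n_ in young.items():
        df = n_.to_frame().loc[common]
        aligned[sub] = qc_mod.NormalizedMatrix(common, n_.sample_ids, df.to_numpy(), n_.factors)
    k_ab = min(config.abundance_k, len(common))
    overlap = qc_mod.abundance_overlap(
        aligned[Substructure.OC_SGN], aligned[Substructure.SV_SL], k=k_ab
    )
    (out / "abundance_overlap.json").write_text(json.dumps(overlap, indent=1))
    bundle["abundance_overlap"] = overlap

    # --- per-substructure age DE ---------------------------------------------
    deg_tables: dict[str, pd.DataFrame] = {}
    for sub in (Substructure.OC_SGN, Substructure.SV_SL):
        ids = [a.sample_id for a in annotations if a.substructure == sub]
        sub_counts = counts.subset_samples(ids)
        sub_counts = qc_mod.drop_unexpressed(sub_counts)
        sub_factors = qc_mod.size_factors(sub_counts, allow_pseudo_reference=True)
        ages = np.array(
            [
                next(a for a in annotations if a.sample_id == s).age_group.value
                for s in sub_counts.sample_ids
            ]
        )
        disp = de_mod.estimate_dispersion(sub_counts, sub_factors, ages)
        table = de_mod.wald_de(sub_counts, sub_factors, disp, ages, reference="young")
        table = de_mod.classify_direction(table, fdr_threshold=config.fdr)
        table.to_csv(out / f"de_{sub.value}.tsv", sep="\t", float_format="%.6g")
        deg_tables[sub.value] = table
    bundle["deg_tables"] = deg_tables

    degs = {
        sub: set(t.index[t["direction"].isin(["up", "down"])]) for sub, t in deg_tables.items()
    }
    venn = de_mod.venn_degs(degs["OC_SGN"], degs["SV_SL"])
    (out / "deg_venn.json").write_text(json.dumps(venn, indent=1))
    bundle["venn"] = venn
    for sub, table in deg_tables.items():
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            up, down = de_mod.top_table(table, k=config.top_k)
        up.to_csv(out / f"top_up_{sub}.tsv", sep="\t", float_format="%.6g")
        down.to_csv(out / f"top_down_{sub}.tsv", sep="\t", float_format="%.6g")

    # --- enrichment -----------------------------------------------------------
    enrichment_bundle: dict = {}
    sig_terms: dict[str, set[str]] = {}
    for sub, table in deg_tables.items():
        universe = set(table.index)
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            up_res, down_res = enr_mod.enrich_directional(table, gene_sets, universe)
        adj_kw = dict(
            method=config.enrichment_method,
            threshold=config.enrichment_threshold,
            sets=gene_sets,
            universe=universe,
            seed=config.seed,
        )
        up_res = enr_mod.adjust_enrichment(up_res, **adj_kw)
        down_res = enr_mod.adjust_enrichment(down_res, **adj_kw)
        up_res.to_csv(out / f"enrichment_up_{sub}.tsv", sep="\t", index=False, float_format="%.6g")
        down_res.to_csv(
            out / f"enrichment_down_{sub}.tsv", sep="\t", index=False, float_format="%.6g"
        )
        enrichment_bundle[sub] = {"up": up_res, "down": down_res}
        sig = set()
        for res in (up_res, down_res):
            if len(res):
                sig |= set(res.loc[res["significant"], "term_id"])
        sig_terms[sub] = sig
    term_comparison = enr_mod.compare_term_sets(sig_terms["OC_SGN"], sig_terms["SV_SL"])
    (out / "enrichment_comparison.json").write_text(json.dumps(term_comparison, indent=1))
    curated_report = enr_mod.curated_overlap(deg_tables, curated)
    (out / "curated_overlap.json").write_text(json.dumps(curated_report, indent=1))
    bundle["enrichment"] = enrichment_bundle
    bundle["term_comparison"] = term_comparison
    bundle["curated_overlap"] = curated_report

    # --- drug repurposing -----------------------------------------------------
    candidates, audit = rep_mod.select_candidates(
        deg_tables, catalog, require_exclusive=config.require_exclusive
    )
    cand_df = candidates_to_frame(candidates)
    cand_df.to_csv(out / "candidates.tsv", sep="\t", index=False, float_format="%.6g")
    audit.to_csv(out / "filter_audit.tsv", sep="\t", index=False)
    bundle["candidates"] = candidates
    bundle["audit"] = audit

    deg_symbols = {
        sub: sorted({str(g).upper() for g in genes}) for sub, genes in degs.items()
    }
    tdl = rep_mod.tdl_distribution(deg_symbols, knowledge)
    tdl.to_csv(out / "tdl_distribution.tsv", sep="\t", index=False, float_format="%.4f")
    bundle["tdl"] = tdl

    networks = {}
    for ns in sorted({s.namespace for s in gene_sets}):
        g = rep_mod.goslim_network(candidates, gene_sets, dag, namespace=ns)
        networks[ns] = g
        nx.write_graphml(g, out / f"network_{ns.replace(':', '_')}.graphml")
    bundle["networks"] = networks

    write_count_table(counts, out / "filtered_counts.tsv")
    report_text = report(bundle)
    (out / "report.md").write_text(report_text)
    bundle["report"] = report_text
    return bundle


def _split_young(annotations, counts, sub):
    ids = [
        a.sample_id
        for a in annotations
        if a.substructure == sub and a.age_group.value == "young"
    ]
    return counts.subset_samples(ids)


def report(bundle: dict) -> str:
    """Render the result bundle as a Markdown summary.

    Mirrors the study's figure content: DEG counts and Venn, curated-list
    overlaps, enrichment comparison, the candidate-drug table grouped by
    substructure, and the TDL distribution.
    """
    lines = ["# Cochlear ageing drug-repurposing report", ""]
    venn = bundle.get("venn")
    if venn:
        lines += [
            "## Differentially expressed genes",
            "",
            f"- OC/SGN-only DEGs: {venn['n_unique_a']}",
            f"- SV/SL-only DEGs: {venn['n_unique_b']}",
            f"- shared DEGs: {venn['n_shared']} "
            f"({venn['pct_shared_of_a']:.1f}% of OC/SGN, {venn['pct_shared_of_b']:.1f}% of SV/SL)",
            "",
        ]
    pca = bundle.get("pca")
    if pca is not None:
        pcs = ", ".join(
            f"PC{i+1} {100*v:.1f}%" for i, v in enumerate(pca.variance_fraction[:2])
        )
        lines += ["## Sample structure", "", f"- variance explained: {pcs}", ""]
    overlap = bundle.get("abundance_overlap")
    if overlap:
        lines += [
            "## Abundance overlap between substructures",
            "",
            f"- top-{overlap['k']} shared fraction: {overlap['shared_fraction']:.3f}",
            "",
        ]
    comp = bundle.get("term_comparison")
    if comp:
        lines += [
            "## Enriched term sets",
            "",
            f"- OC/SGN-only: {comp['n_unique_a']}, SV/SL-only: {comp['n_unique_b']}, "
            f"shared: {comp['n_shared']}",
            "",
        ]
    candidates = bundle.get("candidates")
    lines += ["## Candidate drugs", ""]
    if candidates:
        df = candidates_to_frame(candidates)
        n_distinct = df["drug_id"].nunique()
        lines.append(f"Distinct selected drugs: {n_distinct}")
        for sub, grp in df.groupby("substructure"):
            lines.append(f"\n### {sub} ({grp['drug_id'].nunique()} drugs)\n")
            for _, r in grp.sort_values(["target_gene", "drug_name"]).iterrows():
                lines.append(
                    f"- {r.drug_name} -> {r.target_gene} "
                    f"({r.de_direction}, {r.action}, log2FC {r.log2fc:+.2f})"
                )
        lines.append("")
    else:
        lines += ["No candidates passed the filter chain.", ""]
    tdl = bundle.get("tdl")
    if tdl is not None and len(tdl):
        lines += ["## Target development levels", ""]
        for sub, grp in tdl.groupby("substructure"):
            parts = ", ".join(f"{r.level} {r.n} ({r.pct:.0f}%)" for r in grp.itertuples())
            lines.append(f"- {sub}: {parts}")
        lines.append("")
    return "\n".join(lines)
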