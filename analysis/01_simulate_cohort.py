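#!/usr/bin/env python
"""Generate the synthetic cochlear-ageing cohort used by the later steps.

Writes a 2-substructure x 2-age x 3-replicate negative-binomial count
matrix (5000 genes; substructure effects in 30% of genes, age effects in
5% per substructure), gene sets with planted enrichment, a drug catalog
with planted candidates and decoys, curated-style lists, and the truth
table, under results/synthetic/.
"""

import argparse
import json
from pathlib import Path

from cochleapharm.data import (
    write_count_table,
    write_drug_catalog,
    write_gene_list,
    write_gmt,
    write_sample_sheet,
    write_slim_dag,
    write_target_knowledge,
)
from cochleapharm.simulate import (
    SimulationConfig,
    simulate_counts,
    simulate_curated_lists,
    simulate_drug_catalog,
    simulate_gene_sets,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=42)
    parser.add_argument("--outdir", type=Path, default=Path("results/synthetic"))
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    config = SimulationConfig(seed=args.seed)
    counts, annotations, truth = simulate_counts(config)
    sets, dag = simulate_gene_sets(truth, config)
    catalog, knowledge, expected = simulate_drug_catalog(truth, config)
    curated = simulate_curated_lists(truth, config)

    write_count_table(counts, args.outdir / "counts.tsv")
    write_sample_sheet(annotations, args.outdir / "samples.tsv")
    write_gmt(sets, args.outdir / "gene_sets.gmt")
    write_slim_dag(dag, args.outdir / "slim_dag.tsv")
    write_drug_catalog(catalog, args.outdir / "catalog.json")
    write_target_knowledge(knowledge, args.outdir / "target_knowledge.tsv")
    for name, genes in curated.as_dict().items():
        write_gene_list(genes, args.outdir / f"curated_{name}.txt")
    truth.to_csv(args.outdir / "truth.tsv", sep="\t", float_format="%.6g")
    (args.outdir / "expected_candidates.json").write_text(json.dumps(expected, indent=1))

    n_age = int((truth["de_age_OC_SGN"] | truth["de_age_SV_SL"]).sum())
    print(
        f"simulated {counts.n_genes} genes x {counts.n_samples} samples (seed {args.seed}); "
        f"{int(truth['de_substructure'].sum())} substructure-DE genes, "
        f"{n_age} age-DE genes, {len(expected)} planted drug candidates -> {args.outdir}"
    )


if __name__ == "__main__":
    main()
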