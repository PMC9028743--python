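#!/usr/bin/env python
"""Directional over-representation analysis and curated-list overlap.

Runs up/down ORA per substructure against the expressed-gene universe,
compares the significant term sets between substructures, and intersects
the DEGs with the curated ageing / senescence / deafness lists.
"""

import argparse
import json
import warnings
from pathlib import Path

import pandas as pd

from cochleapharm.data import CuratedGeneLists, read_gene_list, read_gmt
from cochleapharm.enrichment import (
    adjust_enrichment,
    compare_term_sets,
    curated_overlap,
    enrich_directional,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--indir", type=Path, default=Path("results/synthetic"))
    parser.add_argument("--dedir", type=Path, default=Path("results/de"))
    parser.add_argument("--outdir", type=Path, default=Path("results/enrichment"))
    parser.add_argument("--method", choices=["bh", "gscs_empirical"], default="bh")
    parser.add_argument("--seed", type=int, default=42)
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    sets = read_gmt(args.indir / "gene_sets.gmt")
    curated = CuratedGeneLists(
        read_gene_list(args.indir / "curated_ageing.txt"),
        read_gene_list(args.indir / "curated_senescence.txt"),
        read_gene_list(args.indir / "curated_deafness.txt"),
    )

    deg_tables, sig_terms = {}, {}
    for sub in ("OC_SGN", "SV_SL"):
        table = pd.read_csv(args.dedir / f"de_{sub}.tsv", sep="\t", index_col=0)
        deg_tables[sub] = table
        universe = set(table.index)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            up, down = enrich_directional(table, sets, universe)
        sig = set()
        for name, res in (("up", up), ("down", down)):
            res = adjust_enrichment(res, method=args.method, sets=sets,
                                    universe=universe, seed=args.seed)
            res.to_csv(args.outdir / f"enrichment_{name}_{sub}.tsv", sep="\t",
                       index=False, float_format="%.6g")
            if len(res):
                sig |= set(res.loc[res["significant"], "term_id"])
            n_sig = int(res["significant"].sum()) if len(res) else 0
            print(f"{sub} {name}: {n_sig} significant terms")
        sig_terms[sub] = sig

    comp = compare_term_sets(sig_terms["OC_SGN"], sig_terms["SV_SL"])
    (args.outdir / "term_comparison.json").write_text(json.dumps(comp, indent=1))
    print(f"term sets: {comp['n_unique_a']} OC/SGN-only, {comp['n_unique_b']} SV/SL-only, "
          f"{comp['n_shared']} shared")

    overlap = curated_overlap(deg_tables, curated)
    (args.outdir / "curated_overlap.json").write_text(json.dumps(overlap, indent=1))
    for name, hits in overlap["shared"].items():
        print(f"curated {name}: {len(hits)} DEGs shared by both substructures "
              f"({sum(h['concordant'] for h in hits.values())} direction-concordant)")


if __name__ == "__main__":
    main()
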