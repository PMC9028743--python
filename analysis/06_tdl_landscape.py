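#!/usr/bin/env python
"""Druggability landscape: TDL distribution of DEGs per substructure.

Cross-references the DEG sets with the target-knowledge table and
classifies each gene product as Tclin (approved drug exists), Tchem
(active ligand), Tbio (GO annotation or disease phenotype) or Tdark,
with strict precedence in that order.
"""

import argparse
from pathlib import Path

import pandas as pd

from cochleapharm.data import read_target_knowledge
from cochleapharm.repurposing import tdl_distribution


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--indir", type=Path, default=Path("results/synthetic"))
    parser.add_argument("--dedir", type=Path, default=Path("results/de"))
    parser.add_argument("--outdir", type=Path, default=Path("results/drugs"))
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    knowledge = read_target_knowledge(args.indir / "target_knowledge.tsv")
    deg_genes = {}
    for sub in ("OC_SGN", "SV_SL"):
        table = pd.read_csv(args.dedir / f"de_{sub}.tsv", sep="\t", index_col=0)
        deg_genes[sub] = sorted(
            {str(g).upper() for g in table.index[table["direction"].isin(["up", "down"])]}
        )

    dist = tdl_distribution(deg_genes, knowledge)
    dist.to_csv(args.outdir / "tdl_distribution.tsv", sep="\t", index=False,
                float_format="%.2f")
    for sub, grp in dist.groupby("substructure"):
        parts = ", ".join(f"{r.level} {r.n} ({r.pct:.0f}%)" for r in grp.itertuples())
        print(f"{sub}: {parts}")
    not_clin = dist[dist["level"] != "Tclin"].groupby("substructure")["pct"].sum()
    for sub, pct in not_clin.items():
        print(f"{sub}: {pct:.0f}% of DEG products lack an approved drug — "
              "druggable landscape largely untapped")


if __name__ == "__main__":
    main()
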