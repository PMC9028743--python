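#!/usr/bin/env python
"""GO-slim bipartite networks of the candidate drug targets.

Propagates each fixture target's annotations to slim ancestors under the
true-path rule and writes one gene<->slim-term graph per GO aspect
(biological process, molecular function) as GraphML, with log2 fold
changes on the gene nodes.  Unconnected targets are omitted.
"""

import argparse
from pathlib import Path

import networkx as nx

from cochleapharm.repurposing import goslim_network, select_candidates
from cochleapharm.simulate import arhl_fixture, arhl_goslim_annotation


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--outdir", type=Path, default=Path("results/network"))
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    deg_tables, catalog, _ = arhl_fixture()
    candidates, _ = select_candidates(deg_tables, catalog)
    sets, dag = arhl_goslim_annotation()

    for ns, label in (("GO-BP", "biological process"), ("GO-MF", "molecular function")):
        graph = goslim_network(candidates, sets, dag, namespace=ns)
        path = args.outdir / f"network_{ns}.graphml"
        nx.write_graphml(graph, path)
        genes = [n for n, d in graph.nodes(data=True) if d.get("bipartite") == "gene"]
        terms = [n for n, d in graph.nodes(data=True) if d.get("bipartite") == "term"]
        hubs = sorted(terms, key=lambda t: -graph.degree(t))[:3]
        print(f"{label}: {len(genes)} target genes, {len(terms)} slim terms, "
              f"{graph.number_of_edges()} edges -> {path}")
        for h in hubs:
            print(f"  hub term {h}: {graph.degree(h)} targets")


if __name__ == "__main__":
    main()
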