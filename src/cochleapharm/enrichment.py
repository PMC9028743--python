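"""Over-representation analysis and gene-set comparisons.

Hypergeometric ORA against an expressed-gene universe, multiple-testing
control (Benjamini-Hochberg, or an empirical experiment-wide threshold
approximating service-style corrections), directional (up/down) enrichment,
term-set comparison between substructures, and curated-list overlap.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .data import CuratedGeneLists, GeneSetCollection
from .de import bh_adjust

__all__ = [
    "ora",
    "adjust_enrichment",
    "enrich_directional",
    "compare_term_sets",
    "curated_overlap",
]


def ora(
    query: set[str],
    sets: GeneSetCollection,
    universe: set[str],
    min_term_size: int = 3,
    max_term_size: int = 2000,
) -> pd.DataFrame:
    """Hypergeometric over-representation of each term in the query set.

    The universe is the set of genes actually expressed/tested, so a term's
    effective size (``term_size``) counts only members inside the universe;
    the full annotated size is reported separately.  Terms with effective
    size outside [min_term_size, max_term_size] are skipped.  The p-value is
    the upper tail P(X >= k) of Hypergeometric(N=universe, K=term_size,
    n=query_size).
    """
    if not universe:
        raise ValueError("empty universe")
    if not query:
        raise ValueError("empty query")
    outside = query - universe
    if outside:
        warnings.warn(
            f"{len(outside)} query genes outside the universe were dropped", stacklevel=2
        )
    query = query & universe
    if not query:
        raise ValueError("no query gene lies in the universe")
    N, n = len(universe), len(query)
    rows = []
    for term in sets:
        members = term.members & universe
        K = len(members)
        if K < min_term_size or K > max_term_size:
            continue
        k = len(members & query)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "term_id": term.term_id,
                "term_name": term.term_name,
                "namespace": term.namespace,
                "overlap": k,
                "term_size": K,
                "full_term_size": len(term.members),
                "query_size": n,
                "universe_size": N,
                "p": min(p, 1.0),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "term_id",
            "term_name",
            "namespace",
            "overlap",
            "term_size",
            "full_term_size",
            "query_size",
            "universe_size",
            "p",
        ],
    )


def adjust_enrichment(
    results: pd.DataFrame,
    method: str = "bh",
    threshold: float = 0.05,
    sets: GeneSetCollection | None = None,
    universe: set[str] | None = None,
    n_random: int = 500,
    seed: int = 0,
    **ora_kw,
) -> pd.DataFrame:
    """Attach adjusted p-values / significance flags to an ORA table.

    method="bh": Benjamini-Hochberg across the tested terms; significant
    iff adj_p < threshold.

    method="gscs_empirical": an experiment-wide threshold in the spirit of
    service-side corrections — draw ``n_random`` random queries of the same
    size from the universe, record each experiment's minimum term p-value,
    and set the cutoff at the ``threshold`` quantile of that null
    distribution, so at most a fraction ``threshold`` of null experiments
    would yield any hit.  Requires ``sets`` and ``universe``.
    """
    out = results.copy()
    if out.empty:
        out["adj_p"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
        out.attrs["method"] = method
        return out
    if method == "bh":
        out["adj_p"] = bh_adjust(out["p"].to_numpy())
        out["significant"] = out["adj_p"] < threshold
    elif method == "gscs_empirical":
        if sets is None or universe is None:
            raise ValueError("gscs_empirical requires the gene-set collection and universe")
        rng = np.random.default_rng(seed)
        uni = sorted(universe)
        n_query = int(out["query_size"].iloc[0])
        min_ps = np.empty(n_random)
        for i in range(n_random):
            rand_query = set(rng.choice(uni, size=n_query, replace=False))
            tab = ora(rand_query, sets, universe, **ora_kw)
            min_ps[i] = tab["p"].min() if len(tab) else 1.0
        cutoff = float(np.quantile(min_ps, threshold))
        out["adj_p"] = out["p"]  # raw p; significance is experiment-wide
        out["significant"] = out["p"] <= cutoff
        out.attrs["empirical_cutoff"] = cutoff
    else:
        raise ValueError(f"unknown adjustment method {method!r}")
    out.attrs["method"] = method
    return out


def enrich_directional(
    de: pd.DataFrame,
    sets: GeneSetCollection,
    universe: set[str] | None = None,
    **kw,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Separate ORA of up- and downregulated DEGs against all tested genes."""
    if "direction" not in de.columns:
        raise ValueError("run classify_direction first")
    if universe is None:
        universe = set(de.index)
    out = []
    for direction in ("up", "down"):
        genes = set(de.index[de["direction"] == direction])
        if not genes:
            warnings.warn(f"no {direction}-regulated genes; empty enrichment", stacklevel=2)
            out.append(
                pd.DataFrame(
                    columns=[
                        "term_id", "term_name", "namespace", "overlap", "term_size",
                        "full_term_size", "query_size", "universe_size", "p",
                    ]
                )
            )
        else:
            out.append(ora(genes, sets, universe, **kw))
    return out[0], out[1]


def compare_term_sets(sig_a: set[str], sig_b: set[str]) -> dict:
    """Set arithmetic over significant term ids from two analyses."""
    shared = sig_a & sig_b
    return {
        "unique_a": sorted(sig_a - sig_b),
        "unique_b": sorted(sig_b - sig_a),
        "shared": sorted(shared),
        "n_unique_a": len(sig_a - sig_b),
        "n_unique_b": len(sig_b - sig_a),
        "n_shared": len(shared),
        "shared_fraction_of_a": len(shared) / len(sig_a) if sig_a else 0.0,
        "shared_fraction_of_b": len(shared) / len(sig_b) if sig_b else 0.0,
    }


def curated_overlap(
    deg_tables: dict[str, pd.DataFrame],
    lists: CuratedGeneLists,
    symbol_map=None,
) -> dict:
    """Overlap of per-substructure DEGs with curated ageing/senescence/deafness lists.

    ``deg_tables`` maps substructure name -> classified DE table.  Symbols
    are compared case-insensitively (or via ``symbol_map``).  Reports, per
    list and substructure, the DEGs found in the list with their direction,
    and the genes DE in BOTH substructures with a direction-agreement
    annotation such as "up/up".
    """
    if symbol_map is None:
        symbol_map = lambda g: str(g).upper()  # noqa: E731
    per_sub: dict[str, dict[str, dict[str, str]]] = {}
    for sub, table in deg_tables.items():
        sig = table[table["direction"].isin(["up", "down"])]
        per_sub[sub] = {
            list_name: {
                symbol_map(g): d
                for g, d in zip(sig.index, sig["direction"])
                if symbol_map(g) in members
            }
            for list_name, members in lists.as_dict().items()
        }
    report: dict = {"per_substructure": {}, "shared": {}}
    for sub, by_list in per_sub.items():
        report["per_substructure"][sub] = {
            list_name: dict(sorted(hits.items())) for list_name, hits in by_list.items()
        }
    subs = list(deg_tables)
    if len(subs) == 2:
        a, b = subs
        for list_name in lists.as_dict():
            hits_a, hits_b = per_sub[a][list_name], per_sub[b][list_name]
            shared_genes = sorted(set(hits_a) & set(hits_b))
            report["shared"][list_name] = {
                g: {
                    a: hits_a[g],
                    b: hits_b[g],
                    "agreement": f"{hits_a[g]}/{hits_b[g]}",
                    "concordant": hits_a[g] == hits_b[g],
                }
                for g in shared_genes
            }
    return report
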