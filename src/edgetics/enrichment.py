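"""Hypergeometric term enrichment with Benjamini-Hochberg FDR.

A generic gene-set over-representation test: for each annotation term at
a chosen hierarchy level, the upper-tail hypergeometric probability of
drawing at least the observed number of term genes when sampling the
query set from the universe.  This is the plain Fisher-style test, not
the EASE-modified score some hosted services apply; term levels are an
input column (no ontology DAG traversal here).
"""

from __future__ import annotations

from typing import Iterable, Set

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def enrich(
    query: Set[str],
    universe: Set[str],
    terms: pd.DataFrame,
    level: int = 3,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Enrichment table for terms at ``level`` with ≥ 1 query gene.

    ``terms`` columns: gene, term, level, namespace ((gene, term) unique).
    Rows with raw p ≤ alpha are flagged significant; BH q-values are
    reported alongside.
    """
    req = {"gene", "term", "level", "namespace"}
    if not req.issubset(terms.columns):
        raise ValueError(f"term map needs columns {sorted(req)}")
    if not query <= universe:
        raise ValueError(f"query genes outside universe: "
                         f"{sorted(query - universe)[:10]}")
    if terms.duplicated(subset=["gene", "term"]).any():
        raise ValueError("duplicate (gene, term) pairs in term map")
    at_level = terms[terms["level"] == level]
    if at_level.empty:
        raise ValueError(f"no terms at level {level}")
    N, n = len(universe), len(query)
    rows = []
    for (term, namespace), grp in at_level.groupby(["term", "namespace"], sort=True):
        term_genes = set(grp["gene"]) & universe
        k = len(term_genes & query)
        if k == 0:
            continue
        K = len(term_genes)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"term": term, "namespace": namespace, "level": level,
                     "k_overlap": k, "K_term": K, "n_query": n,
                     "N_universe": N, "p": p})
    table = pd.DataFrame(rows, columns=["term", "namespace", "level", "k_overlap",
                                        "K_term", "n_query", "N_universe", "p"])
    if not table.empty:
        table["q"] = multipletests(table["p"], method="fdr_bh")[1]
        table["significant"] = table["p"] <= alpha
        table = table.sort_values("p", kind="stable").reset_index(drop=True)
    else:
        table["q"] = pd.Series(dtype=float)
        table["significant"] = pd.Series(dtype=bool)
    return table


def read_term_map(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_term_map(terms: pd.DataFrame, path) -> None:
    terms.to_csv(path, sep="\t", index=False)
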