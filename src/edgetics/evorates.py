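"""Per-gene evolutionary rates (dN/dS) and rank-based gene-set comparison.

A gene's evolutionary rate (ER) is the mean over primate ortholog
organisms of the per-organism dN/dS ratio.  Rows with missing values or
dS = 0 (infinite ratio) are dropped; paralogous groups — several ortholog
rows for one (gene, organism) — are averaged into one organism value.
Only genes with surviving orthologs in more than three organisms are
retained.  Gene sets are compared with a two-sample Wilcoxon rank-sum
(Mann-Whitney) test, making no distributional assumption.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_ORGANISMS = ("macaque", "gorilla", "orangutan", "chimpanzee", "gibbon")

MIN_ORGANISMS = 3  # strict: genes need orthologs in *more than* this many


def gene_er(table: pd.DataFrame) -> pd.DataFrame:
    """Aggregate an ortholog table (gene, organism, dn, ds) into gene ERs.

    Filtering order is fixed: drop invalid rows (missing dn/ds or ds = 0),
    compute per-row dN/dS, average paralog rows per (gene, organism),
    count organisms, keep genes with > 3 organisms, average organisms.
    dn = 0 with ds > 0 is a valid ratio of 0.
    """
    req = {"gene", "organism", "dn", "ds"}
    if not req.issubset(table.columns):
        raise ValueError(f"ortholog table needs columns {sorted(req)}")
    t = table.dropna(subset=["dn", "ds"]).copy()
    t = t[t["ds"] != 0]
    t["ratio"] = t["dn"] / t["ds"]
    per_org = t.groupby(["gene", "organism"], sort=True)["ratio"].mean()
    per_gene = per_org.groupby("gene").agg(er="mean", n_organisms="count")
    per_gene = per_gene[per_gene["n_organisms"] > MIN_ORGANISMS]
    return per_gene.reset_index()


def compare_er(a: pd.DataFrame, b: pd.DataFrame) -> dict:
    """Two-sided rank-sum comparison of two gene sets' ER distributions.

    Sets are compared as given; overlapping membership is allowed and not
    disjointified.
    """
    xa, xb = a["er"].to_numpy(), b["er"].to_numpy()
    if len(xa) < 2 or len(xb) < 2:
        raise ValueError("each gene set needs at least two ER values")
    u, p = stats.mannwhitneyu(xa, xb, alternative="two-sided")
    return {
        "U": float(u),
        "p": float(p),
        "median_a": float(np.median(xa)),
        "median_b": float(np.median(xb)),
        "mad_a": float(stats.median_abs_deviation(xa)),
        "mad_b": float(stats.median_abs_deviation(xb)),
        "n_a": int(len(xa)),
        "n_b": int(len(xb)),
    }


def read_ortholog_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_ortholog_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)
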