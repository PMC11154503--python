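"""Edgetic effect classification from binding-free-energy changes.

A mutation's effect on one protein-protein interaction is summarized by
ΔΔG = ΔG_mut − ΔG_wt (kcal/mol), the change in binding free energy of the
complex.  Effects fall into three classes at the conventional half-kcal
thresholds:

* beneficial:   ΔΔG < −0.5   (binding strengthened)
* neutral:     −0.5 ≤ ΔΔG < 0.5
* detrimental:  ΔΔG ≥ 0.5    (interaction disrupted)

This module classifies per-(variant, interaction) ΔΔG tables, derives
"disruptive" genes (≥ 1 detrimental mutation), per-gene disruptive
mutation rates normalized by protein length, and the genes enriched with
detrimental mutations (rate > mean + 1 sample SD of the proteome-wide
rate distribution).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io import EdgeKey, Interactome, MutationRecord, edge_key

BENEFICIAL = "beneficial"
NEUTRAL = "neutral"
DETRIMENTAL = "detrimental"
EFFECT_CLASSES = (BENEFICIAL, NEUTRAL, DETRIMENTAL)

#: When one (variant, interaction) pair carries ΔΔG values from several
#: structural sources, the value from the highest-priority source wins.
PROVENANCE_PRIORITY = {"native": 0, "full_model": 1, "ddi_model": 2, "unspecified": 3}


def classify_ddg(ddg: float) -> str:
    """Map a finite ΔΔG (kcal/mol) to its edgetic effect class."""
    if not math.isfinite(ddg):
        raise ValueError(f"ΔΔG must be finite, got {ddg!r}")
    if ddg < -0.5:
        return BENEFICIAL
    if ddg < 0.5:
        return NEUTRAL
    return DETRIMENTAL


@dataclass(frozen=True)
class EdgeticAnnotation:
    """One (variant, interaction) pair with its ΔΔG and effect class."""

    variant_id: str
    protein: str
    interaction: EdgeKey
    ddg: float
    effect: str
    provenance: str = "unspecified"


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero, as in reported percentages."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def annotate(
    rows: Iterable[tuple[str, EdgeKey, float, str]],
    interactome: Interactome,
    mutations: Sequence[MutationRecord],
) -> list[EdgeticAnnotation]:
    """Build validated annotations from (variant_id, edge, ΔΔG, provenance) rows.

    Each unique (variant, interaction) pair yields exactly one annotation;
    conflicts are resolved by structural-source priority
    native > full_model > ddi_model > unspecified (first seen wins ties).
    The variant's host protein must be an endpoint of the interaction.
    """
    by_variant = {m.variant_id: m for m in mutations}
    chosen: dict[tuple[str, EdgeKey], tuple[int, int, float, str]] = {}
    unknown_variants: list[str] = []
    unknown_edges: list[EdgeKey] = []
    for order, (vid, raw_edge, ddg, provenance) in enumerate(rows):
        key = edge_key(*raw_edge)
        if vid not in by_variant:
            unknown_variants.append(vid)
            continue
        if key not in interactome:
            unknown_edges.append(key)
            continue
        if provenance not in PROVENANCE_PRIORITY:
            raise ValueError(f"unknown provenance {provenance!r}")
        prio = PROVENANCE_PRIORITY[provenance]
        prev = chosen.get((vid, key))
        if prev is None or prio < prev[0]:
            chosen[(vid, key)] = (prio, order, ddg, provenance)
    if unknown_variants or unknown_edges:
        raise ValueError(
            "annotation rows reference unknown records: "
            f"variants {sorted(set(unknown_variants))[:10]}, "
            f"interactions {sorted(set(unknown_edges))[:10]}"
        )
    out: list[EdgeticAnnotation] = []
    for (vid, key), (_, _, ddg, provenance) in sorted(
        chosen.items(), key=lambda kv: (kv[0][0], kv[0][1])
    ):
        protein = by_variant[vid].protein
        if protein not in key:
            raise ValueError(
                f"variant {vid}: host protein {protein} is not an endpoint "
                f"of interaction {key}"
            )
        out.append(
            EdgeticAnnotation(vid, protein, key, ddg, classify_ddg(ddg), provenance)
        )
    return out


def read_annotation_rows(path) -> list[tuple[str, EdgeKey, float, str]]:
    """Read an annotation TSV into raw rows for :func:`annotate`.

    Columns: variant_id, protein_a, protein_b, ddg, provenance[, effect].
    Any effect column present is ignored — the class is always recomputed
    from ΔΔG.
    """
    import csv

    rows: list[tuple[str, EdgeKey, float, str]] = []
    with open(path, encoding="utf-8") as fh:
        reader = csv.DictReader(
            (l for l in fh if not l.startswith("#")), delimiter="\t")
        for rec in reader:
            rows.append(
                (rec["variant_id"], (rec["protein_a"], rec["protein_b"]),
                 float(rec["ddg"]), rec.get("provenance") or "unspecified")
            )
    return rows


def write_annotation_table(annotations: Sequence[EdgeticAnnotation], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("variant_id\tprotein_a\tprotein_b\tddg\tprovenance\teffect\n")
        for a in annotations:
            fh.write(f"{a.variant_id}\t{a.interaction[0]}\t{a.interaction[1]}\t"
                     f"{a.ddg:g}\t{a.provenance}\t{a.effect}\n")


def disruptive_genes(annotations: Iterable[EdgeticAnnotation]) -> set[str]:
    """Proteins carrying at least one detrimental (PPI-disrupting) mutation."""
    return {a.protein for a in annotations if a.effect == DETRIMENTAL}


def disrupted_edges(annotations: Iterable[EdgeticAnnotation]) -> set[EdgeKey]:
    """Interactions hit by at least one detrimental mutation."""
    return {a.interaction for a in annotations if a.effect == DETRIMENTAL}


def disruptive_rates(
    annotations: Iterable[EdgeticAnnotation], lengths: Mapping[str, int]
) -> pd.DataFrame:
    """Per-gene disruptive mutation rate table.

    The rate is the number of distinct detrimental variants on the protein
    divided by the protein's sequence length (residues).  Proteins with
    annotations but no length entry raise.
    """
    variants: dict[str, set[str]] = {}
    for a in annotations:
        if a.effect == DETRIMENTAL:
            variants.setdefault(a.protein, set()).add(a.variant_id)
    missing = sorted(set(variants) - set(lengths))
    if missing:
        raise ValueError(f"no protein length for: {missing[:10]}")
    rows = [
        {
            "protein": p,
            "detrimental_count": len(vs),
            "protein_length": lengths[p],
            "rate": len(vs) / lengths[p],
        }
        for p, vs in sorted(variants.items())
    ]
    return pd.DataFrame(rows, columns=["protein", "detrimental_count",
                                       "protein_length", "rate"])


def enriched_genes(rates: pd.DataFrame) -> set[str]:
    """Genes whose disruptive rate exceeds mean + 1 sample SD of all rates.

    The background is the gene-weighted mean over the rate table; the
    standard deviation uses the n−1 denominator.  Strict inequality.
    """
    if len(rates) < 2:
        raise ValueError("need at least two genes to define an enrichment cut-off")
    mean = rates["rate"].mean()
    sd = rates["rate"].std(ddof=1)
    if sd == 0:
        warnings.warn("all disruptive rates identical; no gene is enriched",
                      stacklevel=2)
        return set()
    cut = mean + sd
    return set(rates.loc[rates["rate"] > cut, "protein"])


def effect_summary(
    annotations: Sequence[EdgeticAnnotation],
    mutations: Sequence[MutationRecord] | None = None,
) -> pd.DataFrame:
    """Per-class variant counts over the annotated variant set.

    A variant belongs to a class if it has that effect on *at least one*
    interaction, so one variant may count toward several classes and the
    three percentages need not sum to 100.  Percentages are over the
    number of annotated variants, reported rounded half-up to one decimal.
    """
    annotated = {a.variant_id for a in annotations}
    if not annotated:
        raise ValueError("no annotated variants")
    n = len(annotated)
    rows = []
    for cls in EFFECT_CLASSES:
        hit = {a.variant_id for a in annotations if a.effect == cls}
        pct = 100.0 * len(hit) / n
        rows.append(
            {
                "effect": cls,
                "n_variants": len(hit),
                "n_annotated": n,
                "percent": pct,
                "percent_reported": round_half_up(pct, 1),
            }
        )
    return pd.DataFrame(rows)
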