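"""Family-level aggregation of per-gene expression calls.

Each family (or subgroup, as the annotation table labels them) is reported as
total genes, genes expressed (>=95 per 20 M summed), and — among the
ratio-evaluable genes only — counts expressed during elongation, transition,
and secondary wall formation.  Genes above the expression threshold but below
the ratio threshold therefore appear in the expressed total without a class,
which is why the three class counts can sum to less than the expressed count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import pandas as pd

from .expression import ExpressionCall, Tier, WallClass
from .orthology import GeneAnnotation

logger = logging.getLogger(__name__)

UNANNOTATED = "unannotated"


class SummaryInputError(ValueError):
    pass


@dataclass(frozen=True)
class FamilySummary:
    """One family row: total, expressed, and per-class gene counts."""

    label: str
    n_total: int
    n_expressed: int
    n_elongation: int
    n_transitional: int
    n_secondary: int

    def __post_init__(self) -> None:
        classed = self.n_elongation + self.n_transitional + self.n_secondary
        if not (0 <= classed <= self.n_expressed <= self.n_total):
            raise SummaryInputError(
                f"{self.label}: class counts {classed} / expressed "
                f"{self.n_expressed} / total {self.n_total} violate ordering"
            )


def _summarize_genes(label: str, genes: Iterable[str],
                     calls: Mapping[str, ExpressionCall]) -> FamilySummary:
    genes = list(genes)
    n_expressed = 0
    per_class = {WallClass.ELONGATION: 0, WallClass.TRANSITIONAL: 0, WallClass.SECONDARY: 0}
    for g in genes:
        call = calls.get(g)
        if call is None or call.tier is Tier.BELOW_DETECTION:
            continue
        n_expressed += 1
        if call.tier is Tier.RATIO_EVALUABLE:
            per_class[call.wall_class] += 1
    return FamilySummary(
        label=label,
        n_total=len(genes),
        n_expressed=n_expressed,
        n_elongation=per_class[WallClass.ELONGATION],
        n_transitional=per_class[WallClass.TRANSITIONAL],
        n_secondary=per_class[WallClass.SECONDARY],
    )


def summarize_family(
    calls: Mapping[str, ExpressionCall],
    annotations: Mapping[str, GeneAnnotation],
    family: str,
    query_species: Optional[str] = None,
) -> FamilySummary:
    """Aggregate one family's calls into a summary row.

    ``n_total`` counts annotated genes of the family (restricted to
    ``query_species`` when given — reference anchors have no stem counts);
    annotated genes without a call count toward the total only.
    """
    genes = [
        g for g, a in annotations.items()
        if a.family == family and (query_species is None or a.species == query_species)
    ]
    if not any(a.family == family for a in annotations.values()):
        raise SummaryInputError(f"family {family!r} not present in annotations")
    return _summarize_genes(family, genes, calls)


def summarize_all(
    calls: Mapping[str, ExpressionCall],
    annotations: Mapping[str, GeneAnnotation],
    query_species: Optional[str] = None,
) -> tuple[list[FamilySummary], dict]:
    """One summary row per family (annotation order) plus a global report.

    Genes with calls but no annotation are collected into an ``unannotated``
    overflow row with a warning.  The report carries global totals (which
    equal the column sums over rows plus overflow) and per-class gene lists.
    """
    fam_order: list[str] = []
    for a in annotations.values():
        if a.family not in fam_order:
            fam_order.append(a.family)
    rows = [summarize_family(calls, annotations, fam, query_species) for fam in fam_order]

    stray = [g for g in calls if g not in annotations]
    if stray:
        logger.warning("%d genes have calls but no annotation", len(stray))
        rows.append(_summarize_genes(UNANNOTATED, sorted(stray), calls))

    per_class_genes: dict[str, list[str]] = {c.value: [] for c in WallClass}
    for g, call in calls.items():
        per_class_genes[call.wall_class.value].append(g)
    report = {
        "n_total": sum(r.n_total for r in rows),
        "n_expressed": sum(r.n_expressed for r in rows),
        "n_elongation": sum(r.n_elongation for r in rows),
        "n_transitional": sum(r.n_transitional for r in rows),
        "n_secondary": sum(r.n_secondary for r in rows),
        "per_class_genes": {k: sorted(v) for k, v in per_class_genes.items()},
    }
    return rows, report


def summaries_to_frame(rows: Iterable[FamilySummary]) -> pd.DataFrame:
    """Table with the published column shape: label, total(expressed), classes."""
    return pd.DataFrame(
        [
            {
                "family": r.label,
                "n_total": r.n_total,
                "n_expressed": r.n_expressed,
                "elongation": r.n_elongation,
                "transitional": r.n_transitional,
                "secondary": r.n_secondary,
            }
            for r in rows
        ]
    ).set_index("family")


def ratio_ordered_genes(
    calls: Mapping[str, ExpressionCall],
    annotations: Mapping[str, GeneAnnotation],
    family: str,
) -> list[str]:
    """Family genes ordered by descending secondary/primary expression ratio,
    the ordering used for per-family expression dot plots; non-evaluable genes
    follow, ordered by gene id."""
    fam_genes = [g for g, a in annotations.items() if a.family == family]
    evaluable = [g for g in fam_genes if g in calls and calls[g].ratio is not None]
    rest = sorted(g for g in fam_genes if g not in evaluable)
    evaluable.sort(key=lambda g: (-calls[g].ratio, g))  # type: ignore[operator]
    return evaluable + rest
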