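"""Putative orthology by shared developmental context.

Sequence similarity alone is a weak guide to function in highly duplicated
grass genomes, so a maize gene's closest reference-species homolog is called
a putative ortholog only when both act in the same wall-formation context:
maize elongation-class genes match reference genes annotated to primary wall
formation, maize secondary-class genes match secondary-wall references.
Transitional maize genes are reported as indeterminate — homologous, but the
expression evidence does not place them in a single context.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

from .expression import ExpressionCall, Tier, WallClass

logger = logging.getLogger(__name__)


class OrthologyInputError(ValueError):
    pass


class WallContext(str, enum.Enum):
    PRIMARY = "primary"
    SECONDARY = "secondary"
    UNKNOWN = "unknown"


class Verdict(str, enum.Enum):
    PUTATIVE_ORTHOLOG = "putative_ortholog"
    CONTEXT_MISMATCH = "context_mismatch"
    INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class GeneAnnotation:
    """Identity, species, family, and optional subgroup/wall-context labels.

    Reference-species anchors carry a subgroup and/or a wall context; query
    (maize) genes usually carry neither until the pipeline assigns them.
    """

    gene: str
    species: str
    family: str
    subgroup: Optional[str] = None
    wall_context: WallContext = WallContext.UNKNOWN


@dataclass(frozen=True)
class OrthologCall:
    maize_gene: str
    reference_gene: str
    identity: float
    maize_class: WallClass
    reference_context: WallContext
    verdict: Verdict


# context a maize expression class must meet for putative orthology
_MATCHING_CONTEXT = {
    WallClass.ELONGATION: WallContext.PRIMARY,
    WallClass.SECONDARY: WallContext.SECONDARY,
}


def call_ortholog(
    call: ExpressionCall,
    homolog: tuple[str, float],
    annotations: Mapping[str, GeneAnnotation],
) -> OrthologCall:
    """Judge one maize gene against its closest reference-species homolog.

    Requires a ratio-evaluable maize gene.  A reference gene with unknown
    wall context yields an indeterminate verdict with a warning, as does a
    transitional maize class.
    """
    if call.tier is not Tier.RATIO_EVALUABLE:
        raise OrthologyInputError(
            f"{call.gene}: ortholog calls require a ratio-evaluable gene"
        )
    ref_gene, identity = homolog
    ann = annotations.get(ref_gene)
    ref_context = ann.wall_context if ann is not None else WallContext.UNKNOWN
    if ref_context is WallContext.UNKNOWN:
        logger.warning(
            "reference gene %s has unknown wall context; verdict indeterminate", ref_gene
        )
        verdict = Verdict.INDETERMINATE
    elif call.wall_class is WallClass.TRANSITIONAL:
        verdict = Verdict.INDETERMINATE
    elif _MATCHING_CONTEXT.get(call.wall_class) is ref_context:
        verdict = Verdict.PUTATIVE_ORTHOLOG
    else:
        verdict = Verdict.CONTEXT_MISMATCH
    return OrthologCall(
        maize_gene=call.gene,
        reference_gene=ref_gene,
        identity=identity,
        maize_class=call.wall_class,
        reference_context=ref_context,
        verdict=verdict,
    )


@dataclass(frozen=True)
class OrthologFraction:
    fraction: float
    n_putative: int
    n_total: int


def ortholog_fraction(
    calls: Iterable[OrthologCall],
    restrict_to_class: Optional[WallClass] = None,
    include_indeterminate: bool = True,
) -> OrthologFraction:
    """Proportion of putative orthologs, with numerator and denominator.

    ``restrict_to_class`` limits the denominator to one maize expression
    class (e.g. secondary, for the share of secondary-wall genes with a
    same-context reference homolog).  ``include_indeterminate=False`` drops
    indeterminate verdicts from the denominator; both variants are useful
    because transitional genes have no defined context to match.
    """
    pool = [
        c for c in calls
        if restrict_to_class is None or c.maize_class is restrict_to_class
    ]
    if not include_indeterminate:
        pool = [c for c in pool if c.verdict is not Verdict.INDETERMINATE]
    if not pool:
        raise OrthologyInputError("ortholog_fraction over an empty set of calls")
    n_put = sum(1 for c in pool if c.verdict is Verdict.PUTATIVE_ORTHOLOG)
    return OrthologFraction(fraction=n_put / len(pool), n_putative=n_put, n_total=len(pool))
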