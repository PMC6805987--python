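"""Internode expression profiling: normalization, ambiguous-read splitting,
detection/expression thresholds, and the secondary/primary expression ratio.

The stem is sampled at four internodes — 4 and 5 (older, secondary-wall
forming) and 6 and 8 (younger, elongating; internode 7 is excluded upstream
after housekeeping-gene QC).  Counts are scaled to reads per 20 million
library reads.  A gene is *detected* in an internode at >=1 read per million
(20 per 20 M), *expressed* if its summed normalized counts over the four
internodes reach 95 per 20 M, and *ratio-evaluable* at 500 per 20 M.  The
expression ratio (internodes 4+5) / (internodes 6+8) classifies evaluable
genes: >=2 secondary, <1 elongation (primary wall), [1, 2) transitional.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

import pandas as pd

INTERNODES: tuple[int, ...] = (4, 5, 6, 8)
LOWER_INTERNODES: tuple[int, ...] = (4, 5)   # secondary-wall forming
UPPER_INTERNODES: tuple[int, ...] = (6, 8)   # elongating


class InputError(ValueError):
    """Malformed count tables or threshold configurations."""


class ContractError(RuntimeError):
    """An operation was called outside its contract (e.g. ratio on a
    non-evaluable gene)."""


class Tier(str, enum.Enum):
    BELOW_DETECTION = "below_detection"
    EXPRESSED = "expressed"
    RATIO_EVALUABLE = "ratio_evaluable"


class WallClass(str, enum.Enum):
    ELONGATION = "elongation"
    TRANSITIONAL = "transitional"
    SECONDARY = "secondary"
    UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class Thresholds:
    """Detection/expression/ratio thresholds on the reads-per-20M scale.

    Defaults are the study's printed criteria: detection at one read per
    million (20 per 20 M), expression at >=95 per 20 M summed over the four
    internodes, ratio evaluation at >=500 per 20 M, secondary wall at ratio
    >=2 and primary wall (elongation) at ratio <1.
    """

    detect_per_million: float = 1.0
    expressed_min_per20m: float = 95.0
    ratio_min_per20m: float = 500.0
    secondary_min_ratio: float = 2.0
    primary_max_ratio: float = 1.0
    normalization_base: float = 20_000_000.0

    def __post_init__(self) -> None:
        vals = (
            self.detect_per_million, self.expressed_min_per20m,
            self.ratio_min_per20m, self.secondary_min_ratio,
            self.primary_max_ratio, self.normalization_base,
        )
        if any(v <= 0 for v in vals):
            raise InputError("all thresholds must be positive")
        if self.primary_max_ratio > self.secondary_min_ratio:
            raise InputError("primary_max_ratio must be <= secondary_min_ratio")

    @property
    def detect_per20m(self) -> float:
        return self.detect_per_million * self.normalization_base / 1_000_000.0


@dataclass
class InternodeCountMatrix:
    """Raw unique read counts per gene per internode plus ambiguous pairs.

    Parameters
    ----------
    counts
        DataFrame indexed by gene id with integer columns 4, 5, 6, 8.
        Fractional values appear only after ambiguous-read splitting.
    lib_sizes
        Total library reads per internode (Series indexed 4, 5, 6, 8).
    ambiguous
        Reads that mapped exactly to two duplicated loci: one row per
        (gene_a, gene_b, internode) with the shared count.
    simulated_totals
        Set by the synthetic generator only: the true total reads per gene
        before any were diverted to the ambiguous pool.
    """

    counts: pd.DataFrame
    lib_sizes: pd.Series
    ambiguous: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["gene_a", "gene_b", "internode", "count"]
        )
    )
    simulated_totals: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        cols = [int(c) for c in self.counts.columns]
        if sorted(cols) != sorted(INTERNODES):
            raise InputError(
                f"internode columns must be exactly {set(INTERNODES)}, got {sorted(cols)}"
            )
        self.counts = self.counts.copy()
        self.counts.columns = cols
        self.counts = self.counts[list(INTERNODES)]
        if (self.counts.to_numpy() < 0).any():
            raise InputError("negative read counts")
        self.lib_sizes = self.lib_sizes.copy()
        self.lib_sizes.index = [int(i) for i in self.lib_sizes.index]
        if sorted(self.lib_sizes.index) != sorted(INTERNODES):
            raise InputError("lib_sizes must cover internodes {4, 5, 6, 8}")
        if (self.lib_sizes <= 0).any():
            raise InputError("library sizes must be positive")
        amb = self.ambiguous
        if len(amb):
            known = set(self.counts.index)
            bad = set(amb["gene_a"]) | set(amb["gene_b"])
            bad -= known
            if bad:
                raise InputError(f"ambiguous pairs reference unknown genes: {sorted(bad)}")
            if (amb["gene_a"] == amb["gene_b"]).any():
                raise InputError("ambiguous pair with gene_a == gene_b")
            if (amb["count"] < 0).any():
                raise InputError("negative ambiguous counts")

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)


@dataclass
class ExpressionCall:
    """The per-gene result of thresholding and ratio classification."""

    gene: str
    normalized: dict[int, float]
    detected: dict[int, bool]
    tier: Tier
    ratio: Optional[float]
    wall_class: WallClass

    def __post_init__(self) -> None:
        if (self.wall_class is not WallClass.UNCLASSIFIED
                and self.tier is not Tier.RATIO_EVALUABLE):
            raise ContractError("classified gene must be ratio_evaluable")
        if (self.ratio is None) != (self.tier is not Tier.RATIO_EVALUABLE):
            raise ContractError("ratio defined iff tier is ratio_evaluable")


def normalize(icm: InternodeCountMatrix, t: Thresholds = Thresholds()) -> pd.DataFrame:
    """Scale raw counts to reads per ``normalization_base`` (20 M) per internode."""
    libs = icm.lib_sizes.reindex(list(INTERNODES))
    if (libs <= 0).any():
        raise InputError("library sizes must be positive")
    return icm.counts * (t.normalization_base / libs)


def split_ambiguous(icm: InternodeCountMatrix, proportional: bool = False) -> InternodeCountMatrix:
    """Apportion reads that mapped exactly to two duplicated loci.

    Default is an even split: each ambiguous count c for (A, B, internode)
    adds c/2 to both genes (fractional halves are carried downstream).  With
    ``proportional=True`` the split follows the two genes' unique counts in
    that internode (even when both are zero).  Per-internode totals are
    conserved; the pair list of the returned matrix is empty.
    """
    counts = icm.counts.astype(float).copy()
    for row in icm.ambiguous.itertuples(index=False):
        a, b, inode, c = row.gene_a, row.gene_b, int(row.internode), float(row.count)
        if proportional:
            ua, ub = counts.at[a, inode], counts.at[b, inode]
            share_a = c * ua / (ua + ub) if (ua + ub) > 0 else c / 2.0
        else:
            share_a = c / 2.0
        counts.at[a, inode] += share_a
        counts.at[b, inode] += c - share_a
    return InternodeCountMatrix(
        counts=counts,
        lib_sizes=icm.lib_sizes,
        ambiguous=pd.DataFrame(columns=["gene_a", "gene_b", "internode", "count"]),
        simulated_totals=icm.simulated_totals,
    )


def expression_ratio(profile: Mapping[int, float]) -> float:
    """(internode 4 + 5) / (internode 6 + 8) on normalized values.

    A zero denominator with a positive numerator yields +infinity (a gene
    expressed only during secondary wall formation).  0/0 is a contract
    violation: such a gene is never ratio-evaluable.
    """
    num = profile[4] + profile[5]
    den = profile[6] + profile[8]
    if den == 0:
        if num == 0:
            raise ContractError("expression ratio undefined for an all-zero profile")
        return math.inf
    return num / den


def classify(ratio: float, t: Thresholds = Thresholds()) -> WallClass:
    """Map an expression ratio to a wall-formation class.

    ratio >= 2 -> secondary (includes +infinity); ratio < 1 -> elongation
    (primary wall); 1 <= ratio < 2 -> transitional.
    """
    if ratio is None or (isinstance(ratio, float) and math.isnan(ratio)):
        raise ContractError("classify requires a defined ratio")
    if ratio < 0:
        raise InputError("expression ratio cannot be negative")
    if ratio >= t.secondary_min_ratio:
        return WallClass.SECONDARY
    if ratio < t.primary_max_ratio:
        return WallClass.ELONGATION
    return WallClass.TRANSITIONAL


def call_expression(
    gene: str, profile: Mapping[int, float], t: Thresholds = Thresholds()
) -> ExpressionCall:
    """Apply detection, expression, and ratio thresholds to one gene profile.

    ``profile`` holds normalized (per-20M) values for the four internodes.
    Threshold boundaries are inclusive: a summed 95 is expressed, a summed
    500 is ratio-evaluable.
    """
    missing = [i for i in INTERNODES if i not in profile]
    if missing:
        raise InputError(f"profile missing internodes {missing}")
    detected = {i: profile[i] >= t.detect_per20m for i in INTERNODES}
    total = sum(profile[i] for i in INTERNODES)
    if total >= t.ratio_min_per20m:
        tier = Tier.RATIO_EVALUABLE
        ratio = expression_ratio(profile)
        wall_class = classify(ratio, t)
    elif total >= t.expressed_min_per20m:
        tier, ratio, wall_class = Tier.EXPRESSED, None, WallClass.UNCLASSIFIED
    else:
        tier, ratio, wall_class = Tier.BELOW_DETECTION, None, WallClass.UNCLASSIFIED
    return ExpressionCall(
        gene=gene,
        normalized={i: float(profile[i]) for i in INTERNODES},
        detected=detected,
        tier=tier,
        ratio=ratio,
        wall_class=wall_class,
    )


def call_all(
    icm: InternodeCountMatrix,
    t: Thresholds = Thresholds(),
    split: bool = True,
    proportional_split: bool = False,
) -> dict[str, ExpressionCall]:
    """Full per-gene pipeline: split ambiguous reads, normalize, threshold."""
    work = split_ambiguous(icm, proportional=proportional_split) if split else icm
    norm = normalize(work, t)
    return {
        gene: call_expression(gene, {i: float(norm.at[gene, i]) for i in INTERNODES}, t)
        for gene in norm.index
    }


def calls_to_frame(calls: Mapping[str, ExpressionCall]) -> pd.DataFrame:
    """Flatten calls into the output table (one row per gene).

    +infinity ratios serialize as the string "Inf" when written to TSV.
    """
    rows = []
    for gene, c in calls.items():
        rows.append({
            "gene": gene,
            **{f"n{i}": c.normalized[i] for i in INTERNODES},
            "tier": c.tier.value,
            "ratio": c.ratio if c.ratio is not None else float("nan"),
            "wall_class": c.wall_class.value,
        })
    return pd.DataFrame(rows).set_index("gene")
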