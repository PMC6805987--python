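"""Synthetic gene families and internode count matrices with known truth.

The generator emulates the structure of a grass cell-wall gene-family study:
aligned protein families whose clades form subgroups anchored by labeled
reference-species genes (with optionally one grass-only subgroup, the
CslF/CslH pattern), recent maize duplicate pairs that share ambiguously
mapped reads, and four-internode count profiles whose wall-formation class
(elongation / transitional / secondary / not expressed) is known.

Sequences evolve by per-site substitution down a structured guide tree: the
family root splits into subgroup clades over long edges; within a subgroup
each reference gene carries its designated maize copies as close sisters, so
the true closest homolog is recoverable by identity.  Counts are
negative-binomial (mean/dispersion parameterization); dispersion zero is the
deterministic limit in which realized ratios equal the configured ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from .expression import INTERNODES, InternodeCountMatrix
from .phylogeny import Alignment, FamilyTree, Node

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

CLASSES = ("elongation", "transitional", "secondary", "not_expressed")

DEFAULT_SPECIES = ("arabidopsis", "rice", "maize")


class ConfigError(ValueError):
    """A SimConfig field is out of its documented range."""


@dataclass(frozen=True)
class SimConfig:
    """Study-condition knobs for the synthetic generator.

    The defaults describe the emulated study: three species (two anchor
    species plus the maize-like query), four internode libraries near 20 M
    reads, a four-fold expression separation between secondary-wall and
    elongation profiles, and a quarter of duplicated maize genes sharing
    ambiguous reads with their paralog.
    """

    n_families: int = 4
    genes_per_family: int = 12
    n_species: int = 3
    dup_fraction: float = 0.25
    class_mix: dict = field(default_factory=lambda: {
        "elongation": 0.35, "transitional": 0.20,
        "secondary": 0.30, "not_expressed": 0.15,
    })
    lib_sizes: tuple = (21_000_000, 19_000_000, 20_500_000, 18_500_000)
    dispersion: float = 0.05
    effect_size: float = 4.0
    alignment_length: int = 300
    mutation_rate: float = 0.03
    seed: int = 0
    species_absent_subgroup: bool = True
    ambiguous_fraction: float = 0.3
    ortholog_concordance: float = 0.25

    def __post_init__(self) -> None:
        if self.n_families < 1:
            raise ConfigError("n_families must be a positive integer")
        if self.genes_per_family < 1:
            raise ConfigError("genes_per_family must be a positive integer")
        if self.n_species < 1:
            raise ConfigError("n_species must be a positive integer")
        if not 0 <= self.dup_fraction <= 1:
            raise ConfigError("dup_fraction must lie in [0, 1]")
        if set(self.class_mix) != set(CLASSES):
            raise ConfigError(f"class_mix must cover exactly {CLASSES}")
        if abs(sum(self.class_mix.values()) - 1.0) > 1e-9:
            raise ConfigError("class_mix proportions must sum to 1")
        if any(p < 0 for p in self.class_mix.values()):
            raise ConfigError("class_mix proportions must be non-negative")
        if len(self.lib_sizes) != 4 or any(s <= 0 for s in self.lib_sizes):
            raise ConfigError("lib_sizes must be four positive integers")
        if self.dispersion < 0:
            raise ConfigError("dispersion must be non-negative")
        if self.effect_size < 1:
            raise ConfigError("effect_size must be >= 1")
        if self.alignment_length < 1:
            raise ConfigError("alignment_length must be a positive integer")
        if not 0 <= self.mutation_rate < 1:
            raise ConfigError("mutation_rate must lie in [0, 1)")
        if not 0 <= self.ambiguous_fraction <= 1:
            raise ConfigError("ambiguous_fraction must lie in [0, 1]")
        if not 0 <= self.ortholog_concordance <= 1:
            raise ConfigError("ortholog_concordance must lie in [0, 1]")

    @property
    def species_names(self) -> tuple:
        if self.n_species <= len(DEFAULT_SPECIES):
            # query species last; anchors first
            return DEFAULT_SPECIES[-self.n_species:] if self.n_species > 1 else ("maize",)
        extras = tuple(f"species{i}" for i in range(self.n_species - len(DEFAULT_SPECIES)))
        return extras + DEFAULT_SPECIES

    @property
    def query_species(self) -> str:
        return "maize"

    @property
    def reference_species(self) -> str:
        # the eudicot outgroup when present, else the first non-query species
        names = self.species_names
        if "arabidopsis" in names:
            return "arabidopsis"
        non_query = [s for s in names if s != self.query_species]
        return non_query[0] if non_query else self.query_species


@dataclass
class GroundTruth:
    """Per-gene truth plus per-family guide trees.

    ``genes`` has one row per generated gene: gene, species, family, subgroup,
    wall class (query genes only), duplication partner, designated closest
    reference homolog, expected expression ratio, anchor flag, and reference
    wall context (anchor genes only).
    """

    genes: pd.DataFrame
    guide_trees: dict[str, FamilyTree] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.genes["gene"].duplicated().any():
            raise ValueError("duplicate gene ids in ground truth")
        partners = self.genes.set_index("gene")["partner"]
        for g, p in partners.items():
            if isinstance(p, str) and p:
                if partners.get(p) != g:
                    raise ValueError(f"asymmetric duplication partners: {g} / {p}")

    @property
    def query_genes(self) -> pd.DataFrame:
        return self.genes[self.genes["is_query"]]


def _evolve(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Per-site substitution: each site mutates with probability ``rate`` to a
    uniformly chosen different residue."""
    if rate == 0:
        return seq.copy()
    mask = rng.random(seq.size) < rate
    out = seq.copy()
    if mask.any():
        shift = rng.integers(1, len(AMINO_ACIDS), size=int(mask.sum()))
        out[mask] = (out[mask] + shift) % len(AMINO_ACIDS)
    return out


def _star(units: list[tuple[Node, float]], rng: np.random.Generator) -> Node:
    """Join subtree units under one node, in shuffled order.

    The guide tree mirrors the evolution process exactly: children of a node
    all evolved independently from that node's sequence, so the node is a
    genuine multifurcation — a binary caterpillar here would claim splits no
    substitution ever supported.
    """
    units = [units[i] for i in rng.permutation(len(units))]
    return Node(children=units)


def generate_families(config: SimConfig) -> tuple[dict[str, Alignment], GroundTruth]:
    """Simulate aligned families with anchored subgroup structure.

    Returns one alignment per family plus the ground truth (gene table and
    the guide trees the sequences were evolved on).  Deterministic for a
    fixed config including its seed.
    """
    rng = np.random.default_rng(config.seed)
    L = config.alignment_length
    species = config.species_names
    query = config.query_species
    anchor_species = [s for s in species if s != query]

    alignments: dict[str, Alignment] = {}
    guide_trees: dict[str, FamilyTree] = {}
    rows: list[dict] = []

    # edge substitution rates (probability per site); deep edges separate
    # subgroups, shallow edges sit inside a reference gene's own lineage
    rate_in = config.mutation_rate
    rate_deep = min(0.45, 5.0 * config.mutation_rate)
    rate_copy = config.mutation_rate / 3.0

    classes = list(CLASSES)
    probs = np.array([config.class_mix[c] for c in classes])

    for f in range(config.n_families):
        family = f"fam{f + 1}"
        n_subgroups = max(2, config.genes_per_family // 4)
        root_seq = rng.integers(0, len(AMINO_ACIDS), size=L)

        # distribute base genes across subgroups as evenly as possible
        sizes = [config.genes_per_family // n_subgroups] * n_subgroups
        for k in range(config.genes_per_family % n_subgroups):
            sizes[k] += 1

        fam_ids: list[str] = []
        fam_seqs: dict[str, np.ndarray] = {}
        subgroup_units: list[tuple[Node, float]] = []
        fam_rows: list[dict] = []

        for s in range(n_subgroups):
            sub = f"{family}_sg{s + 1}"
            # the last subgroup can lack the reference species entirely
            absent = (
                config.species_absent_subgroup
                and s == n_subgroups - 1
                and len(anchor_species) >= 2
            )
            sub_anchor_species = [
                sp for sp in anchor_species
                if not (absent and sp == config.reference_species)
            ]
            founder = _evolve(root_seq, rate_deep, rng)

            n_anchors = min(len(sub_anchor_species), sizes[s])
            n_query = sizes[s] - n_anchors
            # spread query genes over the anchors of this subgroup
            per_anchor = [n_query // n_anchors + (1 if k < n_query % n_anchors else 0)
                          for k in range(n_anchors)] if n_anchors else []

            lineage_units: list[tuple[Node, float]] = []
            for k in range(n_anchors):
                sp = sub_anchor_species[k]
                aid = f"{sp[:2]}_{family}_sg{s + 1}_{k + 1}"
                anchor_seq = _evolve(founder, rate_in, rng)
                fam_ids.append(aid)
                fam_seqs[aid] = anchor_seq
                fam_rows.append({
                    "gene": aid, "species": sp, "family": family, "subgroup": sub,
                    "wall_class": "", "partner": "", "closest_ref": "",
                    "expected_ratio": math.nan, "is_anchor": True,
                    "is_query": False, "ref_context": "",
                })
                unit_edges: list[tuple[Node, float]] = [(Node(name=aid), 0.0)]
                for q in range(per_anchor[k]):
                    qid = f"zm_{family}_sg{s + 1}_{k + 1}_{q + 1}"
                    qseq = _evolve(anchor_seq, rate_copy, rng)
                    fam_ids.append(qid)
                    fam_seqs[qid] = qseq
                    designated = aid if sp == config.reference_species else ""
                    fam_rows.append({
                        "gene": qid, "species": query, "family": family, "subgroup": sub,
                        "wall_class": "", "partner": "", "closest_ref": designated,
                        "expected_ratio": math.nan, "is_anchor": False,
                        "is_query": True, "ref_context": "",
                    })
                    unit_edges.append((Node(name=qid), rate_copy))
                unit = _star(unit_edges, rng) if len(unit_edges) > 1 else unit_edges[0][0]
                lineage_units.append((unit, rate_in))
            if not lineage_units:  # subgroup of query genes only (n_species == 1)
                for q in range(sizes[s]):
                    qid = f"zm_{family}_sg{s + 1}_0_{q + 1}"
                    fam_ids.append(qid)
                    fam_seqs[qid] = _evolve(founder, rate_in, rng)
                    fam_rows.append({
                        "gene": qid, "species": query, "family": family, "subgroup": sub,
                        "wall_class": "", "partner": "", "closest_ref": "",
                        "expected_ratio": math.nan, "is_anchor": False,
                        "is_query": True, "ref_context": "",
                    })
                    lineage_units.append((Node(name=qid), rate_in))
            sub_node = (_star(lineage_units, rng) if len(lineage_units) > 1
                        else lineage_units[0][0])
            subgroup_units.append((sub_node, rate_deep))

        root = _star(subgroup_units, rng)

        # recent duplicates: near-copies of query genes sharing ambiguous
        # reads; each becomes a sister leaf of its source in the guide tree
        query_ids = [r["gene"] for r in fam_rows if r["is_query"]]
        n_dup = int(round(config.dup_fraction * len(query_ids)))
        dup_targets = [query_ids[i] for i in
                       sorted(rng.choice(len(query_ids), size=n_dup, replace=False))]

        def graft_sister(node: Node, gid: str, did: str) -> bool:
            for k, (child, bl) in enumerate(node.children):
                if child.is_leaf and child.name == gid:
                    cherry = Node(children=[(Node(name=gid), 0.0),
                                            (Node(name=did), rate_copy / 2.0)])
                    node.children[k] = (cherry, bl)
                    return True
                if graft_sister(child, gid, did):
                    return True
            return False

        for gid in dup_targets:
            did = f"{gid}b"
            fam_seqs[did] = _evolve(fam_seqs[gid], rate_copy / 2.0, rng)
            fam_ids.append(did)
            graft_sister(root, gid, did)
            src = next(r for r in fam_rows if r["gene"] == gid)
            src["partner"] = did
            fam_rows.append({
                **src, "gene": did, "partner": gid,
            })
        guide_trees[family] = FamilyTree(root=root)

        # true wall classes for query genes; duplicate pairs share a class
        for r in fam_rows:
            if not r["is_query"] or r["wall_class"]:
                continue
            cls = classes[int(rng.choice(len(classes), p=probs))]
            r["wall_class"] = cls
            if r["partner"]:
                mate = next(x for x in fam_rows if x["gene"] == r["partner"])
                mate["wall_class"] = cls

        # reference wall contexts wired for a configured concordance rate:
        # each reference anchor looks at the classes of its designated copies
        for r in fam_rows:
            if not r["is_anchor"] or r["species"] != config.reference_species:
                continue
            copies = [x for x in fam_rows if x["closest_ref"] == r["gene"]]
            directional = next(
                (x["wall_class"] for x in copies
                 if x["wall_class"] in ("elongation", "secondary")), None)
            if directional is None:
                r["ref_context"] = "primary" if rng.random() < 0.5 else "secondary"
            else:
                match_ctx = "primary" if directional == "elongation" else "secondary"
                other = "secondary" if match_ctx == "primary" else "primary"
                r["ref_context"] = (match_ctx if rng.random() < config.ortholog_concordance
                                    else other)

        alignments[family] = Alignment(
            ids=fam_ids,
            seqs=["".join(AMINO_ACIDS[fam_seqs[g]]) for g in fam_ids],
        )
        rows.extend(fam_rows)

    truth = GroundTruth(genes=pd.DataFrame(rows), guide_trees=guide_trees)
    return alignments, truth


def _nb_sample(mean: np.ndarray, dispersion: float, rng: np.random.Generator) -> np.ndarray:
    """Overdispersed counts: variance = mean + dispersion * mean^2.

    dispersion == 0 is the deterministic limit (rounded means), giving exact
    realized ratios for noise-free tests.
    """
    mean = np.asarray(mean, dtype=float)
    if dispersion == 0:
        return np.rint(mean).astype(int)
    n = 1.0 / dispersion
    p = n / (n + mean)
    out = np.zeros(mean.shape, dtype=int)
    pos = mean > 0
    out[pos] = rng.negative_binomial(n, p[pos])
    return out


def generate_counts(truth: GroundTruth, config: SimConfig) -> InternodeCountMatrix:
    """Simulate unique and ambiguous internode counts for the query genes.

    Expected normalized profiles follow the gene's true class: secondary
    genes have internodes 4+5 at ``effect_size`` times internodes 6+8,
    elongation genes the reciprocal, transitional genes a ratio drawn
    uniformly in (1, 2), and not-expressed genes total under the expression
    threshold.  For each duplicated pair a fixed fraction of reads (from each
    member equally) is emitted as ambiguous pair counts instead of unique
    counts, so each gene's unique counts plus half its pair counts equal its
    simulated total.  The realized expected ratio (after integer rounding of
    the normalized means) is written back into ``truth.genes``.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 7_919]).generate_state(1)[0]
    )
    qgenes = truth.genes[truth.genes["is_query"]].copy()
    libs = pd.Series(list(config.lib_sizes), index=list(INTERNODES), dtype=float)
    base20m = 20_000_000.0

    means = {}
    expected_ratio = {}
    for row in qgenes.itertuples(index=False):
        cls = row.wall_class
        if cls == "not_expressed":
            m = rng.uniform(0.0, 20.0, size=4)  # total < 80 per 20 M in expectation
            mean20m = np.rint(m)
        else:
            if cls == "secondary":
                r = config.effect_size
            elif cls == "elongation":
                r = 1.0 / config.effect_size
            else:
                r = rng.uniform(1.0, 2.0)
            b = int(rng.integers(300, 2001))  # per upper internode, per 20 M
            lower = float(np.rint(b * r))
            # keep the rounded ratio inside the class's own band so the
            # noise-free limit classifies exactly
            if cls == "transitional":
                lower = min(max(lower, float(b)), 2.0 * b - 1.0)
            elif cls == "elongation":
                lower = min(lower, float(b) - 1.0)
            elif cls == "secondary":
                lower = max(lower, 2.0 * float(b))
            mean20m = np.array([lower, lower, float(b), float(b)])
        means[row.gene] = mean20m
        den = mean20m[2] + mean20m[3]
        expected_ratio[row.gene] = (
            (mean20m[0] + mean20m[1]) / den if den > 0 else math.inf
        )

    totals = {}
    for gene, mean20m in means.items():
        mu = mean20m * libs.to_numpy() / base20m
        totals[gene] = _nb_sample(mu, config.dispersion, rng)
    totals_df = pd.DataFrame(totals, index=list(INTERNODES)).T
    totals_df.index.name = "gene"

    unique = totals_df.copy()
    amb_rows = []
    seen = set()
    partners = qgenes.set_index("gene")["partner"]
    for gene in totals_df.index:
        p = partners.get(gene, "")
        if not isinstance(p, str) or not p or gene in seen or p not in totals_df.index:
            continue
        seen.update((gene, p))
        for inode in INTERNODES:
            ta, tb = int(totals_df.at[gene, inode]), int(totals_df.at[p, inode])
            half = int(round(config.ambiguous_fraction * min(ta, tb)))
            if half == 0:
                continue
            unique.at[gene, inode] = ta - half
            unique.at[p, inode] = tb - half
            amb_rows.append({"gene_a": gene, "gene_b": p,
                             "internode": inode, "count": 2 * half})

    truth.genes["expected_ratio"] = truth.genes["gene"].map(expected_ratio).astype(float)

    return InternodeCountMatrix(
        counts=unique.astype(int),
        lib_sizes=pd.Series(list(config.lib_sizes), index=list(INTERNODES)),
        ambiguous=pd.DataFrame(
            amb_rows, columns=["gene_a", "gene_b", "internode", "count"]
        ),
        simulated_totals=totals_df,
    )


def generate(config: SimConfig) -> tuple[dict[str, Alignment], GroundTruth, InternodeCountMatrix]:
    """Families, truth, and counts in one call (single seed)."""
    alignments, truth = generate_families(config)
    icm = generate_counts(truth, config)
    return alignments, truth, icm
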