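"""Neighbor-joining trees with bootstrap support, subgroup assignment, and
closest-homolog search for cell-wall gene families.

Distances are p-distances (proportion of differing residues over comparable,
i.e. non-gap, alignment columns) with pairwise deletion.  Trees are built with
the Saitou–Nei neighbor-joining agglomeration and are unrooted; the root node
of the returned structure is the final degree-3 junction and carries no
biological meaning.  Bootstrap support of an internal edge is the percentage
of column-resampled replicate trees that contain the same leaf bipartition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np

logger = logging.getLogger(__name__)

GAP = "-"


class AlignmentError(ValueError):
    """Raised for ragged or otherwise malformed alignments."""


class TreeInputError(ValueError):
    """Raised when tree construction receives unusable input."""


# ---------------------------------------------------------------------------
# Alignment and distance matrix
# ---------------------------------------------------------------------------


@dataclass
class Alignment:
    """An aligned set of protein sequences (one gene family).

    Parameters
    ----------
    ids
        Gene identifiers, unique, in file order.
    seqs
        Residue strings, all of identical length; ``-`` marks a gap.
    """

    ids: list[str]
    seqs: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise AlignmentError("ids and seqs differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise AlignmentError("duplicate sequence ids in alignment")
        if self.seqs:
            L = len(self.seqs[0])
            for gid, s in zip(self.ids, self.seqs):
                if len(s) != L:
                    raise AlignmentError(
                        f"ragged alignment: sequence {gid!r} has length "
                        f"{len(s)}, expected {L}"
                    )

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def length(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0

    def as_array(self) -> np.ndarray:
        """Return the alignment as an (n_seqs, n_cols) array of single chars."""
        return np.array([list(s) for s in self.seqs], dtype="U1")

    def resample_columns(self, rng: np.random.Generator) -> "Alignment":
        """Bootstrap replicate: columns resampled with replacement."""
        arr = self.as_array()
        cols = rng.integers(0, arr.shape[1], size=arr.shape[1])
        boot = arr[:, cols]
        return Alignment(list(self.ids), ["".join(row) for row in boot])


@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("distance matrix diagonal is not zero")
        if np.any(m < 0):
            raise ValueError("negative distances")
        self.matrix = m

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.ids.index(pair[0])
        j = self.ids.index(pair[1])
        return float(self.matrix[i, j])


def p_distance(aln: Alignment) -> DistanceMatrix:
    """Pairwise p-distances with pairwise deletion of gapped sites.

    Entry (i, j) is the number of differing residues divided by the number of
    columns where neither sequence has a gap.  A pair with zero comparable
    columns gets distance 1.0 (maximal) and a logged warning.
    """
    if len(aln) < 2:
        raise AlignmentError("p_distance needs at least 2 sequences")
    arr = aln.as_array()
    n = arr.shape[0]
    nongap = arr != GAP
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            comparable = nongap[i] & nongap[j]
            n_comp = int(comparable.sum())
            if n_comp == 0:
                logger.warning(
                    "no comparable sites between %s and %s; distance set to 1",
                    aln.ids[i], aln.ids[j],
                )
                dij = 1.0
            else:
                dij = float((arr[i, comparable] != arr[j, comparable]).sum()) / n_comp
            d[i, j] = d[j, i] = dij
    return DistanceMatrix(list(aln.ids), d)


# ---------------------------------------------------------------------------
# Tree structure
# ---------------------------------------------------------------------------


@dataclass
class Node:
    """Tree node; leaves carry a name, internal nodes carry children."""

    name: Optional[str] = None
    children: list[tuple["Node", float]] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]  # type: ignore[list-item]
        out: list[str] = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out


@dataclass
class FamilyTree:
    """An unrooted NJ tree with optional bootstrap supports.

    ``root`` is the final trifurcating junction; bipartition supports (in
    percent) are keyed by the canonical side of each internal edge: the side
    NOT containing the lexicographically smallest leaf id.
    """

    root: Node
    supports: Optional[dict[frozenset, float]] = None

    @property
    def leaf_names(self) -> list[str]:
        return self.root.leaves()

    def bipartitions(self) -> set[frozenset]:
        """Canonical internal-edge bipartitions (non-trivial splits)."""
        all_leaves = set(self.leaf_names)
        ref = min(all_leaves)
        splits: set[frozenset] = set()

        def walk(node: Node) -> set[str]:
            if node.is_leaf:
                return {node.name}  # type: ignore[arg-type]
            below: set[str] = set()
            for child, _ in node.children:
                below |= walk(child)
            if node is not self.root and 2 <= len(below) <= len(all_leaves) - 2:
                side = below if ref not in below else all_leaves - below
                splits.add(frozenset(side))
            return below

        walk(self.root)
        return splits

    def support_of(self, side: Iterable[str]) -> Optional[float]:
        if self.supports is None:
            return None
        all_leaves = set(self.leaf_names)
        side = set(side)
        ref = min(all_leaves)
        key = frozenset(side if ref not in side else all_leaves - side)
        return self.supports.get(key)

    def newick(self, include_support: bool = True) -> str:
        """Serialize to Newick; bootstrap supports become internal labels."""
        all_leaves = set(self.leaf_names)
        ref = min(all_leaves)

        def fmt(node: Node, length: Optional[float]) -> str:
            if node.is_leaf:
                body = node.name or ""
            else:
                inner = ",".join(fmt(c, bl) for c, bl in node.children)
                label = ""
                if include_support and self.supports is not None and node is not self.root:
                    below = set(node.leaves())
                    if 2 <= len(below) <= len(all_leaves) - 2:
                        key = frozenset(below if ref not in below else all_leaves - below)
                        sup = self.supports.get(key)
                        if sup is not None:
                            label = f"{sup:g}"
                body = f"({inner}){label}"
            if length is None:
                return body
            return f"{body}:{length:.6g}"

        return fmt(self.root, None) + ";"

    def path_distance(self, a: str, b: str) -> float:
        """Sum of branch lengths on the path between two leaves."""

        def path_to(target: str) -> list[tuple[Node, float]]:
            stack: list[list[tuple[Node, float]]] = [[(self.root, 0.0)]]
            while stack:
                path = stack.pop()
                node = path[-1][0]
                if node.is_leaf and node.name == target:
                    return path
                for child, bl in node.children:
                    stack.append(path + [(child, bl)])
            raise KeyError(f"leaf not in tree: {target}")

        pa, pb = path_to(a), path_to(b)
        k = 0
        while k < min(len(pa), len(pb)) and pa[k][0] is pb[k][0]:
            k += 1
        return sum(bl for _, bl in pa[k:]) + sum(bl for _, bl in pb[k:])


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    # Negative NJ branch-length estimates are clamped to zero and the deficit
    # moved to the sister branch so the pair sum is preserved.
    if li < 0:
        lj += li
        li = 0.0
    if lj < 0:
        li += lj
        lj = 0.0
    return max(li, 0.0), max(lj, 0.0)


def nj_tree(d: DistanceMatrix) -> FamilyTree:
    """Saitou–Nei neighbor joining.

    Deterministic: when several pairs minimize the Q criterion, the pair with
    the lowest (row, column) index in the current working order is joined.
    Returns an unrooted tree represented with a trifurcating root.
    """
    n = len(d.ids)
    if n < 3:
        raise TreeInputError(f"neighbor joining needs >=3 taxa, got {n}")
    nodes: list[Node] = [Node(name=gid) for gid in d.ids]
    D = d.matrix.astype(float).copy()

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # argmin with row-major order gives the lowest (i, j) among exact ties
        flat = int(np.argmin(Q))
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        dij = D[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        li, lj = _clamp_pair(li, lj)
        new = Node(children=[(nodes[i], li), (nodes[j], lj)])
        dnew = 0.5 * (D[i, :] + D[j, :] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        D2 = np.empty((m - 1, m - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = dnew[keep]
        D2[:-1, -1] = dnew[keep]
        D2[-1, -1] = 0.0
        D = D2
        nodes = [nodes[k] for k in keep] + [new]

    # final 3-star: closed-form pendant lengths
    d12, d13, d23 = D[0, 1], D[0, 2], D[1, 2]
    l1 = max((d12 + d13 - d23) / 2, 0.0)
    l2 = max((d12 + d23 - d13) / 2, 0.0)
    l3 = max((d13 + d23 - d12) / 2, 0.0)
    root = Node(children=[(nodes[0], l1), (nodes[1], l2), (nodes[2], l3)])
    return FamilyTree(root=root)


def bootstrap_support(aln: Alignment, n_reps: int = 1000, seed: int = 0) -> FamilyTree:
    """NJ tree from the full alignment with bootstrap supports attached.

    Columns are resampled with replacement ``n_reps`` times (default 1000);
    each replicate is run through p_distance + nj_tree, and the support of
    each internal edge of the full tree is the percentage of replicates whose
    tree contains the same leaf bipartition.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    tree = nj_tree(p_distance(aln))
    target = tree.bipartitions()
    counts = {bp: 0 for bp in target}
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        rep = aln.resample_columns(rng)
        rep_bps = nj_tree(p_distance(rep)).bipartitions()
        for bp in target:
            if bp in rep_bps:
                counts[bp] += 1
    tree.supports = {bp: 100.0 * c / n_reps for bp, c in counts.items()}
    return tree


# ---------------------------------------------------------------------------
# Subgroup assignment and closest homolog
# ---------------------------------------------------------------------------


@dataclass
class SubgroupAssignment:
    """Per-gene subgroup labels plus the supporting clade's bootstrap value.

    ``species_absent`` maps each subgroup label to the species with no member
    in that subgroup (the pattern of grass-only CslF/CslH versus the
    eudicot-only CslB subgroup), when a species map is supplied.
    """

    labels: dict[str, str]
    supports: dict[str, Optional[float]]
    species_absent: dict[str, set] = field(default_factory=dict)


def assign_subgroups(
    tree: FamilyTree,
    anchors: Mapping[str, str],
    min_support: float = 50.0,
    species_of: Optional[Mapping[str, str]] = None,
) -> SubgroupAssignment:
    """Assign each gene the subgroup of its smallest well-supported anchored clade.

    A non-anchor gene gets label L if the smallest bipartition side that
    contains the gene and at least one anchor, among sides whose edge has
    bootstrap support >= ``min_support`` (trees built without bootstrapping
    are treated as fully supported), holds anchors of only label L.  A gene
    with no supported anchored clade, or whose smallest such clade mixes
    labels, is "unassigned".  Anchors always keep their own label.
    """
    leaves = set(tree.leaf_names)
    missing = [a for a in anchors if a not in leaves]
    if missing:
        raise TreeInputError(f"anchor ids absent from tree: {sorted(missing)}")
    if not anchors:
        raise TreeInputError("at least one anchor is required")

    # both sides of every internal edge, with the edge's support
    sides: list[tuple[set, Optional[float]]] = []
    for bp in tree.bipartitions():
        sup = tree.support_of(bp)
        sides.append((set(bp), sup))
        sides.append((leaves - set(bp), sup))

    labels: dict[str, str] = {}
    supports: dict[str, Optional[float]] = {}
    for gene in sorted(leaves):
        if gene in anchors:
            labels[gene] = anchors[gene]
            supports[gene] = None
            continue
        candidates = [
            (len(side), tuple(sorted(side)), side, 100.0 if sup is None else sup)
            for side, sup in sides
            if gene in side and any(a in side for a in anchors)
            and (100.0 if sup is None else sup) >= min_support
        ]
        label, sup_val = "unassigned", None
        if candidates:
            _, _, side, eff_sup = min(candidates, key=lambda c: (c[0], c[1]))
            in_labels = {anchors[a] for a in anchors if a in side}
            if len(in_labels) == 1:
                label = next(iter(in_labels))
                sup_val = eff_sup
        labels[gene] = label
        supports[gene] = sup_val

    species_absent: dict[str, set] = {}
    if species_of is not None:
        all_species = set(species_of.values())
        for lab in sorted(set(labels.values()) - {"unassigned"}):
            present = {
                species_of[g] for g, l in labels.items() if l == lab and g in species_of
            }
            gone = all_species - present
            if gone:
                species_absent[lab] = gone
    return SubgroupAssignment(labels=labels, supports=supports, species_absent=species_absent)


def closest_homolog(
    query: str,
    aln: Alignment,
    species_of: Mapping[str, str],
    reference_species: str,
) -> tuple[str, float]:
    """The reference-species gene with maximum pairwise identity to the query.

    Identity is 1 - p-distance (pairwise deletion).  Exact ties are broken by
    lexicographic gene id and logged.
    """
    if query not in aln.ids:
        raise TreeInputError(f"query {query!r} not in alignment")
    refs = [g for g in aln.ids if g != query and species_of.get(g) == reference_species]
    if not refs:
        raise TreeInputError(f"no {reference_species!r} sequences in alignment")
    d = p_distance(aln)
    scored = sorted(((1.0 - d[query, ref], ref) for ref in refs), key=lambda t: (-t[0], t[1]))
    best_ident, best_ref = scored[0]
    if len(scored) > 1 and scored[1][0] == best_ident:
        logger.warning(
            "closest_homolog tie for %s at identity %.4f; choosing %s",
            query, best_ident, best_ref,
        )
    return best_ref, best_ident
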