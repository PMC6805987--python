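"""Neighbor joining, bootstrap supports, subgroup assignment, closest homolog."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stemwall.phylogeny import (
    Alignment,
    AlignmentError,
    DistanceMatrix,
    TreeInputError,
    assign_subgroups,
    bootstrap_support,
    closest_homolog,
    nj_tree,
    p_distance,
)

from conftest import random_additive_distances


# ---------------------------------------------------------------------------
# p-distance
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "seqs, pair, expected",
    [
        (["AAAA", "AAAA"], ("s0", "s1"), 0.0),        # identical sequences
        (["AAAA", "AAAT"], ("s0", "s1"), 0.25),       # 1 mismatch / 4 sites
        (["AA--", "AAGG"], ("s0", "s1"), 0.0),        # gaps excluded pairwise
        (["A-CT", "AG-T"], ("s0", "s1"), 0.0),        # only sites 0 and 3 compared
        (["ACGT", "TGCA"], ("s0", "s1"), 1.0),        # all sites differ
    ],
)
def test_p_distance_pairwise_deletion(seqs, pair, expected):
    aln = Alignment([f"s{i}" for i in range(len(seqs))], seqs)
    assert p_distance(aln)[pair] == pytest.approx(expected)

def test_p_distance_no_comparable_sites_is_maximal(caplog):
    aln = Alignment(["a", "b"], ["AA--", "--AA"])
    with caplog.at_level("WARNING"):
        d = p_distance(aln)
    assert d["a", "b"] == 1.0
    assert "no comparable sites" in caplog.text

def test_ragged_alignment_rejected():
    with pytest.raises(AlignmentError, match="ragged"):
        Alignment(["a", "b"], ["AAA", "AAAA"])

@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1), st.integers(3, 7), st.integers(5, 40))
def test_p_distance_symmetric_bounded(seed, n, length):
    rng = np.random.default_rng(seed)
    chars = np.array(list("ACDEFG-"))
    seqs = ["".join(rng.choice(chars, size=length)) for _ in range(n)]
    d = p_distance(Alignment([f"s{i}" for i in range(n)], seqs))
    m = d.matrix
    assert np.allclose(m, m.T)
    assert np.all((m >= 0) & (m <= 1))
    assert np.all(np.diag(m) == 0)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------


def test_three_taxa_closed_form():
    # pendant lengths x = (d12 + d13 - d23)/2 etc.
    d = DistanceMatrix(list("abc"), np.array([[0, 0.3, 0.5],
                                              [0.3, 0, 0.6],
                                              [0.5, 0.6, 0]]))
    tree = nj_tree(d)
    lengths = {child.name: bl for child, bl in tree.root.children}
    assert lengths == pytest.approx({"a": 0.1, "b": 0.2, "c": 0.4})

def test_four_taxa_additive_exact_recovery():
    # hand-made tree ((A:1,B:2):1,(C:3,D:4)) -> additive distances
    ids = list("ABCD")
    d = np.array([
        [0, 3, 5, 6],
        [3, 0, 6, 7],
        [5, 6, 0, 7],
        [6, 7, 7, 0],
    ], dtype=float)
    tree = nj_tree(DistanceMatrix(ids, d))
    assert tree.bipartitions() == {frozenset({"C", "D"})}
    for i in range(4):
        for j in range(i + 1, 4):
            assert tree.path_distance(ids[i], ids[j]) == pytest.approx(d[i, j])

def test_random_additive_matrices_recovered():
    # NJ is exact on additive matrices; the generating tree is the oracle
    rng = np.random.default_rng(42)
    for _ in range(100):
        d = random_additive_distances(8, rng)
        ids = [f"t{i}" for i in range(8)]
        tree = nj_tree(DistanceMatrix(ids, d))
        for i in range(8):
            for j in range(i + 1, 8):
                assert abs(tree.path_distance(ids[i], ids[j]) - d[i, j]) < 1e-9

def test_nj_matches_independent_implementation():
    # cross-check the topology against scikit-bio's neighbor joining
    from skbio import DistanceMatrix as SkDM
    from skbio.tree import nj as sknj

    rng = np.random.default_rng(7)
    ids = [f"t{i}" for i in range(8)]
    for _ in range(10):
        d = random_additive_distances(8, rng)
        mine = nj_tree(DistanceMatrix(ids, d)).bipartitions()
        sk = sknj(SkDM(d, ids))
        ref, all_l = min(ids), set(ids)
        theirs = set()
        for node in sk.non_tips(include_self=False):
            below = {t.name for t in node.tips()}
            if 2 <= len(below) <= len(all_l) - 2:
                theirs.add(frozenset(below if ref not in below else all_l - below))
        assert mine == theirs

def test_nj_requires_three_taxa():
    with pytest.raises(TreeInputError, match=">=3"):
        nj_tree(DistanceMatrix(["a", "b"], np.array([[0, 1.0], [1.0, 0]])))

def test_branch_lengths_never_negative():
    rng = np.random.default_rng(3)
    for _ in range(20):
        m = rng.uniform(0.01, 1.0, size=(6, 6))
        d = (m + m.T) / 2
        np.fill_diagonal(d, 0)
        tree = nj_tree(DistanceMatrix([f"t{i}" for i in range(6)], d))

        def walk(node):
            for child, bl in node.children:
                assert bl >= 0
                walk(child)

        walk(tree.root)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------


CONGRUENT = Alignment(
    ["a", "b", "c", "d", "e", "f"],
    ["A" * 20 + "C" * 20,
     "A" * 20 + "C" * 20,
     "A" * 10 + "G" * 10 + "C" * 20,
     "A" * 10 + "G" * 10 + "C" * 20,
     "T" * 20 + "C" * 10 + "G" * 10,
     "T" * 20 + "C" * 10 + "G" * 10],
)

def test_congruent_alignment_full_support():
    # every column supports the same splits, so resampling cannot break them
    tree = bootstrap_support(CONGRUENT, n_reps=100, seed=3)
    assert tree.supports and all(s == 100.0 for s in tree.supports.values())

def test_bootstrap_supports_in_range_and_deterministic(small_sim):
    _, alignments, _, _ = small_sim
    aln = next(iter(alignments.values()))
    t1 = bootstrap_support(aln, n_reps=50, seed=9)
    t2 = bootstrap_support(aln, n_reps=50, seed=9)
    assert t1.supports == t2.supports
    assert all(0 <= s <= 100 for s in t1.supports.values())
    assert t1.newick() == t2.newick()

def test_default_reps_is_one_thousand():
    import inspect
    assert inspect.signature(bootstrap_support).parameters["n_reps"].default == 1000

def test_column_duplication_keeps_full_support():
    # duplicating all columns k times cannot decrease a 100-support edge
    k = 3
    dup = Alignment(CONGRUENT.ids, [s * k for s in CONGRUENT.seqs])
    tree = bootstrap_support(dup, n_reps=100, seed=3)
    assert all(s == 100.0 for s in tree.supports.values())


# ---------------------------------------------------------------------------
# subgroup assignment
# ---------------------------------------------------------------------------


def _star_family_alignment():
    # two clean clades: {anchorA, g1} vs {anchorB, g2}, plus outlier root
    return Alignment(
        ["anchorA", "g1", "anchorB", "g2", "out"],
        ["A" * 30 + "C" * 10,
         "A" * 29 + "G" + "C" * 10,
         "T" * 30 + "C" * 10,
         "T" * 29 + "G" + "C" * 10,
         "C" * 40],
    )

def test_single_anchor_clade_assigns_label():
    aln = _star_family_alignment()
    tree = bootstrap_support(aln, n_reps=100, seed=1)
    asg = assign_subgroups(tree, {"anchorA": "CesA", "anchorB": "CslF"}, 50.0)
    assert asg.labels["g1"] == "CesA"
    assert asg.labels["g2"] == "CslF"
    assert asg.labels["anchorA"] == "CesA"  # anchors keep their own label

def test_mixed_label_clade_is_unassigned():
    # both anchors carry different labels inside the only anchored clade
    aln = Alignment(
        ["anchorA", "anchorB", "g1", "far1", "far2"],
        ["A" * 30 + "C" * 10,
         "A" * 30 + "C" * 10,
         "A" * 29 + "G" + "C" * 10,
         "T" * 40,
         "T" * 39 + "G"],
    )
    tree = bootstrap_support(aln, n_reps=100, seed=1)
    asg = assign_subgroups(tree, {"anchorA": "CslF", "anchorB": "CslH"}, 50.0)
    assert asg.labels["g1"] == "unassigned"

def test_missing_anchor_rejected():
    aln = _star_family_alignment()
    tree = bootstrap_support(aln, n_reps=10, seed=1)
    with pytest.raises(TreeInputError, match="ghost"):
        assign_subgroups(tree, {"ghost": "CesA"}, 50.0)

def test_assignment_is_total_function(small_sim):
    _, alignments, truth, _ = small_sim
    tg = truth.genes.set_index("gene")
    aln = alignments["fam1"]
    tree = bootstrap_support(aln, n_reps=50, seed=5)
    anchors = {g: tg.at[g, "subgroup"] for g in aln.ids if tg.at[g, "is_anchor"]}
    asg = assign_subgroups(tree, anchors, 50.0)
    assert set(asg.labels) == set(aln.ids)  # every gene exactly one label

def test_synthetic_subgroups_recovered(small_sim):
    _, alignments, truth, _ = small_sim
    tg = truth.genes.set_index("gene")
    total = correct = 0
    for fam, aln in alignments.items():
        tree = bootstrap_support(aln, n_reps=50, seed=5)
        anchors = {g: tg.at[g, "subgroup"] for g in aln.ids if tg.at[g, "is_anchor"]}
        species_of = {g: tg.at[g, "species"] for g in aln.ids}
        asg = assign_subgroups(tree, anchors, 50.0, species_of)
        for g, lab in asg.labels.items():
            if tg.at[g, "is_anchor"]:
                continue
            total += 1
            correct += lab == tg.at[g, "subgroup"]
    assert correct / total >= 0.95

def test_species_absent_subgroup_flagged(small_sim):
    # the grass-only subgroup pattern: last subgroup has no arabidopsis member
    _, alignments, truth, _ = small_sim
    tg = truth.genes.set_index("gene")
    aln = alignments["fam1"]
    tree = bootstrap_support(aln, n_reps=50, seed=5)
    anchors = {g: tg.at[g, "subgroup"] for g in aln.ids if tg.at[g, "is_anchor"]}
    species_of = {g: tg.at[g, "species"] for g in aln.ids}
    asg = assign_subgroups(tree, anchors, 50.0, species_of)
    assert asg.species_absent.get("fam1_sg3") == {"arabidopsis"}


# ---------------------------------------------------------------------------
# closest homolog
# ---------------------------------------------------------------------------


def test_identical_reference_found_with_identity_one():
    aln = Alignment(["q", "AT1", "AT2"], ["AAAA", "AAAA", "TTTT"])
    sp = {"q": "maize", "AT1": "arabidopsis", "AT2": "arabidopsis"}
    assert closest_homolog("q", aln, sp, "arabidopsis") == ("AT1", 1.0)

def test_equidistant_references_tie_break_lexicographic(caplog):
    aln = Alignment(["q", "AT2", "AT1"], ["AAAA", "AAAT", "AATA"])
    sp = {"q": "maize", "AT1": "arabidopsis", "AT2": "arabidopsis"}
    with caplog.at_level("WARNING"):
        ref, ident = closest_homolog("q", aln, sp, "arabidopsis")
    assert (ref, ident) == ("AT1", 0.75)
    assert "tie" in caplog.text

def test_no_reference_sequences_rejected():
    aln = Alignment(["q", "zm2"], ["AAAA", "AAAT"])
    with pytest.raises(TreeInputError, match="arabidopsis"):
        closest_homolog("q", aln, {"q": "maize", "zm2": "maize"}, "arabidopsis")

def test_designated_reference_recovered(recovery_sim):
    # the generator copies each maize gene from a designated reference
    _, alignments, truth, _ = recovery_sim
    tg = truth.genes.set_index("gene")
    total = hits = 0
    for fam, aln in alignments.items():
        species_of = {g: tg.at[g, "species"] for g in aln.ids}
        for g in aln.ids:
            if tg.at[g, "species"] != "maize" or not tg.at[g, "closest_ref"]:
                continue
            ref, _ = closest_homolog(g, aln, species_of, "arabidopsis")
            total += 1
            hits += ref == tg.at[g, "closest_ref"]
    assert total >= 40
    assert hits / total >= 0.99
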