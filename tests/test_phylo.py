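"""Unit tests for trees, clade assignment, screening and congruence."""

import numpy as np
import pytest
from skbio import TreeNode

from rtcrispr.phylo import (
    CladeInfo,
    CladePartition,
    SupportTree,
    assign_clades,
    build_tree,
    fit_clade_models,
    monophyly,
    partition_congruence,
    screen_membership,
    split_subclades,
)
from rtcrispr.sequence import ProteinRecord
from rtcrispr.synth import (
    AA20,
    generate_clade_alignment,
    generate_clade_tree,
    generate_protein_family,
    mutate_protein,
)

from .oracles import monophyly_oracle


def stree(newick, metadata=None):
    return SupportTree.from_newick(newick, metadata or {})


# --- SupportTree -------------------------------------------------------------


def test_newick_roundtrip_preserves_supports():
    t = stree("((a:1,b:1)0.95:1,(c:1,d:1)0.5:1);")
    again = SupportTree.from_newick(t.to_newick())
    supports = sorted(
        s for n in again.tree.non_tips() if (s := getattr(n, "support", None)) is not None
    )
    assert supports == [0.5, 0.95]
    assert sorted(again.leaf_names()) == ["a", "b", "c", "d"]


def test_duplicate_leaves_rejected():
    with pytest.raises(ValueError):
        stree("((a,a),b);")


def test_out_of_range_support_rejected():
    with pytest.raises(ValueError):
        stree("((a,b)7.5,c);")


# --- build_tree --------------------------------------------------------------


def _pair_alignment():
    rng = np.random.default_rng(0)
    base1 = "".join(rng.choice(list(AA20), size=120))
    base2 = "".join(rng.choice(list(AA20), size=120))
    return [
        ("a1", mutate_protein(rng, base1, 5)),
        ("a2", mutate_protein(rng, base1, 5)),
        ("b1", mutate_protein(rng, base2, 5)),
        ("b2", mutate_protein(rng, base2, 5)),
    ]


def test_three_leaves_unique_topology_full_support():
    aln = _pair_alignment()[:3]
    t = build_tree(aln, bootstrap_n=50, seed=1)
    assert sorted(t.leaf_names()) == ["a1", "a2", "b1"]
    for node in t.tree.non_tips():
        assert node.support is None or node.support == 1.0


def test_two_pairs_recovered_with_high_support():
    t = build_tree(_pair_alignment(), bootstrap_n=100, seed=1)
    pair_node = t.tree.lca(["a1", "a2"])
    names = {x.name for x in pair_node.tips()}
    if names == {"a1", "a2"}:
        assert pair_node.support >= 0.9
    else:  # the pairing bipartition may appear as the complement side
        other = t.tree.lca(["b1", "b2"])
        assert {x.name for x in other.tips()} == {"b1", "b2"}
        assert other.support >= 0.9


def test_degenerate_equal_distances_do_not_crash():
    aln = [("x", "AAAA"), ("y", "AAAA"), ("z", "AAAA"), ("w", "AAAA")]
    t = build_tree(aln, bootstrap_n=10, seed=0)
    assert sorted(t.leaf_names()) == ["w", "x", "y", "z"]


def test_build_tree_size_errors():
    with pytest.raises(ValueError):
        build_tree([("a", "AC"), ("b", "AC")])
    with pytest.raises(ValueError):
        build_tree([("a", ""), ("b", ""), ("c", "")])


def test_build_tree_deterministic():
    aln = _pair_alignment()
    t1 = build_tree(aln, bootstrap_n=50, seed=7)
    t2 = build_tree(aln, bootstrap_n=50, seed=7)
    assert t1.to_newick() == t2.to_newick()


# --- assign_clades -----------------------------------------------------------


def test_star_tree_low_support_gives_no_clades():
    t = stree("((a,b)0.5,(c,d)0.5,e);")
    part = assign_clades(t)
    assert set(part.labels.values()) == {"unassigned"}


def test_unsupported_tree_rejected():
    with pytest.raises(ValueError):
        assign_clades(stree("((a,b),c);"))


def test_nested_qualifying_nodes_keep_only_maximal():
    t = stree("(((a,b)0.95,c)0.95,(d,e)0.5);")
    part = assign_clades(t)
    sets = {frozenset(info.leaves) for info in part.clades.values()}
    assert sets == {frozenset({"a", "b", "c"})}


def test_clades_require_crispr_flag_purity():
    meta = {x: {"phylum": "P", "crispr_associated": x != "c"} for x in "abcde"}
    t = stree("(((a,b)0.95,c)0.95,(d,e)0.5);", meta)
    part = assign_clades(t)
    sets = {frozenset(info.leaves) for info in part.clades.values()}
    assert sets == {frozenset({"a", "b"})}


def test_planted_clades_recovered_exactly():
    tree, truth = generate_clade_tree(40, {"A": 6, "B": 5, "C": 4}, seed=3)
    part = assign_clades(tree)
    assert part.leaf_sets().keys() == {"1", "2", "3"}
    assert set(part.leaf_sets().values()) == set(truth.leaf_sets().values())


def test_raising_support_min_never_adds_leaves():
    tree, _ = generate_clade_tree(40, {"A": 6, "B": 5, "C": 4}, seed=4)
    assigned = []
    for smin in (0.92, 0.94, 0.96):
        part = assign_clades(tree, support_min=smin)
        assigned.append(sum(1 for v in part.labels.values() if v != "unassigned"))
    assert assigned == sorted(assigned, reverse=True)


# --- split_subclades ---------------------------------------------------------


def test_single_phylum_clade_is_not_split():
    tree, _ = generate_clade_tree(20, {"A": 8}, seed=5)
    part = assign_clades(tree)
    refined = split_subclades(part, tree)
    assert set(refined.labels.values()) == set(part.labels.values())


def _two_phylum_tree():
    meta = {}
    for leaf in ("a1", "a2", "a3"):
        meta[leaf] = {"phylum": "PhA", "crispr_associated": True}
    for leaf in ("b1", "b2", "b3"):
        meta[leaf] = {"phylum": "PhB", "crispr_associated": True}
    for leaf in ("out1", "out2"):
        meta[leaf] = {"phylum": "Other", "crispr_associated": False}
    # two outgroup leaves keep the ingroup bipartition non-trivial
    nwk = "(((a1,(a2,a3)0.95)0.95,(b1,(b2,b3)0.95)0.95)0.95,(out1,out2)0.5);"
    return stree(nwk, meta)


def test_two_pure_children_become_lettered_subclades():
    t = _two_phylum_tree()
    part = assign_clades(t)
    assert len(part.clades) == 1
    refined = split_subclades(part, t)
    labels = set(refined.labels.values()) - {"unassigned"}
    assert labels == {"1A", "1B"}


def test_purity_below_threshold_blocks_split():
    t = _two_phylum_tree()
    part = assign_clades(t)
    refined = split_subclades(part, t, phylum_purity=1.01)
    assert set(refined.labels.values()) - {"unassigned"} == {"1"}


# --- clade models and screening ---------------------------------------------


@pytest.fixture(scope="module")
def clade_models():
    records, clusters = generate_protein_family(
        n=3, identity_ladder=(1.0, 0.92, 0.86, 0.8), seed=9, founder_len=260
    )
    members = {}
    for rec in records:
        members.setdefault(str(clusters[rec.id] + 1), []).append(rec)
    return members, fit_clade_models(members)


def test_member_screens_into_its_own_clade(clade_models):
    members, models = clade_models
    for label, recs in members.items():
        got, evalue = screen_membership(recs[-1].sequence, models)
        assert got == label
        assert evalue < 1e-10


def test_shuffled_query_screens_to_none(clade_models):
    members, models = clade_models
    rng = np.random.default_rng(10)
    residues = list(members["1"][0].sequence)
    rng.shuffle(residues)
    got, _evalue = screen_membership("".join(residues), models)
    assert got is None


def test_screen_membership_requires_models():
    with pytest.raises(ValueError):
        screen_membership("ACDEF", [])


# --- monophyly ---------------------------------------------------------------


def test_cherry_is_monophyletic():
    t = stree("((a,b)0.9,(c,d)0.9);")
    result = monophyly(t, {"a": "x", "b": "x"})
    assert result["x"][0] is True


def test_scattered_label_is_not_monophyletic():
    t = stree("((a,b)0.9,(c,d)0.9);")
    result = monophyly(t, {"a": "x", "c": "x", "b": "y"})
    assert result["x"][0] is False


def test_monophyly_unknown_leaf_rejected():
    t = stree("((a,b)0.9,c);")
    with pytest.raises(ValueError):
        monophyly(t, {"zz": "x"})


def test_monophyly_matches_oracle_on_small_tree():
    t = stree("(((a,b)0.9,(c,d)0.8)0.7,((e,f)0.6,g)0.5);")
    labels = {"a": "p", "b": "p", "c": "q", "e": "q", "d": "r", "f": "r", "g": "r"}
    got = monophyly(t, labels)
    for label in ("p", "q", "r"):
        leafset = frozenset(k for k, v in labels.items() if v == label)
        assert got[label][0] == monophyly_oracle(t.tree, leafset)


# --- partition_congruence ----------------------------------------------------


def _partition(labels, tree=None):
    clades = {}
    for leaf, lab in labels.items():
        if lab == "unassigned":
            continue
        clades.setdefault(lab, set()).add(leaf)
    infos = {
        lab: CladeInfo(lab, frozenset(leaves), 1.0, {}) for lab, leaves in clades.items()
    }
    return CladePartition(labels, infos, tree)


def test_identical_partitions_have_ari_one():
    t = stree("((a,b)0.9,(c,d)0.9);")
    labels = {"a": "1", "b": "1", "c": "2", "d": "2"}
    p = _partition(labels, t)
    ari, report = partition_congruence(p, p)
    assert ari == 1.0
    assert all(entry["agree"] for entry in report.values())


def test_disjoint_partitions_rejected():
    p1 = _partition({"a": "1", "b": "1"})
    p2 = _partition({"c": "1", "d": "1"})
    with pytest.raises(ValueError):
        partition_congruence(p1, p2)


def test_permutation_null_ari_is_near_zero():
    rng = np.random.default_rng(11)
    leaves = [f"L{i}" for i in range(60)]
    labels = {leaf: str(i % 6) for i, leaf in enumerate(leaves)}
    p1 = _partition(labels)
    aris = []
    for _ in range(50):
        perm = rng.permutation(leaves)
        p2 = _partition({leaf: labels[perm[i]] for i, leaf in enumerate(leaves)})
        ari, _ = partition_congruence(p1, p2)
        aris.append(ari)
    assert abs(float(np.mean(aris))) < 0.1


# --- NJ round trip on clade-structured alignments ----------------------------


def test_nj_tree_recovers_clade_partition():
    aln, truth_labels, metadata = generate_clade_alignment(
        n_clades=3, members_per_clade=4, n_background=4, seed=12
    )
    tree = build_tree(aln, bootstrap_n=100, seed=1, metadata=metadata)
    part = assign_clades(tree)
    truth_sets = {}
    for leaf, lab in truth_labels.items():
        if lab != "unassigned":
            truth_sets.setdefault(lab, set()).add(leaf)
    assert set(map(frozenset, truth_sets.values())) == set(part.leaf_sets().values())
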