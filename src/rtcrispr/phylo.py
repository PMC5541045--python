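"""Tree construction, clade assignment and coevolution testing.

A desk-scale neighbor-joining builder (Poisson-corrected p-distances,
bootstrap bipartition supports) stands in for external maximum-likelihood
inference; externally computed Newick trees with support values can be
supplied instead.  Clades are extracted as the maximal internal nodes with
local support >= 0.92 whose leaves are all CRISPR-associated; phylum-pure,
well-supported children become lettered subclades.  Consensus-based
membership screening rejects queries above a per-clade e-value exclusion
threshold calibrated between the member and non-member e-value
distributions.  Monophyly and adjusted-Rand congruence of two leaf
partitions (e.g. an RT tree vs the matching Cas1 tree) quantify
coevolution of the two protein families.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj
from sklearn.metrics import adjusted_rand_score

from .sequence import ProteinRecord, SearchParams, build_consensus, local_search

SUPPORT_MIN = 0.92


@dataclass
class SupportTree:
    """A (possibly unrooted) tree with node supports and leaf metadata.

    ``metadata`` maps leaf id to a dict with optional keys ``phylum`` and
    ``crispr_associated``; absent leaves default to CRISPR-associated with
    an empty phylum.
    """

    tree: TreeNode
    metadata: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [t.name for t in self.tree.tips()]
        if len(names) != len(set(names)):
            raise ValueError("leaf ids must be unique")
        for node in self.tree.non_tips(include_self=True):
            s = getattr(node, "support", None)
            if s is not None and not (0.0 <= s <= 1.0):
                raise ValueError(f"support {s} outside [0, 1]")

    # -- metadata accessors -------------------------------------------------
    def crispr_associated(self, leaf: str) -> bool:
        return bool(self.metadata.get(leaf, {}).get("crispr_associated", True))

    def phylum(self, leaf: str) -> str:
        return str(self.metadata.get(leaf, {}).get("phylum", ""))

    def leaf_names(self) -> list[str]:
        return [t.name for t in self.tree.tips()]

    # -- IO -----------------------------------------------------------------
    @classmethod
    def from_newick(
        cls, source: str | Path, metadata: dict[str, dict] | None = None
    ) -> "SupportTree":
        if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source and Path(source).exists()):
            tree = TreeNode.read(str(source))
        else:
            tree = TreeNode.read(io.StringIO(str(source)))
        for node in tree.non_tips(include_self=True):
            support = None
            if node.name is not None:
                try:
                    support = float(node.name)
                except ValueError:
                    support = None
            node.support = support
            if support is not None:
                node.name = None
        return cls(tree, metadata or {})

    def to_newick(self) -> str:
        t = self.tree.copy()
        for node in t.non_tips(include_self=True):
            s = getattr(node, "support", None)
            node.name = f"{s:g}" if s is not None else None
            # clear the attribute so the writer does not also emit "support:name"
            node.support = None
        out = io.StringIO()
        t.write(out)
        return out.getvalue().strip()


def read_leaf_metadata(path: str | Path) -> dict[str, dict]:
    """Read a leaf metadata TSV with columns id, phylum, crispr_associated."""
    meta: dict[str, dict] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            flag = parts[idx["crispr_associated"]].strip().lower()
            meta[parts[idx["id"]]] = {
                "phylum": parts[idx["phylum"]],
                "crispr_associated": flag in ("1", "true", "yes"),
            }
    return meta


# ---------------------------------------------------------------------------
# tree construction


def _encode_alignment(alignment: Sequence[tuple[str, str]]) -> tuple[list[str], np.ndarray]:
    ids = [i for i, _ in alignment]
    seqs = [s for _, s in alignment]
    if len(seqs) < 3:
        raise ValueError("tree construction requires at least 3 sequences")
    L = len(seqs[0])
    if L == 0:
        raise ValueError("zero-length alignment")
    if any(len(s) != L for s in seqs):
        raise ValueError("aligned sequences must have equal length")
    arr = np.frombuffer("".join(seqs).encode(), dtype="S1").reshape(len(seqs), L)
    return ids, arr


def _poisson_distances(arr: np.ndarray) -> np.ndarray:
    gap = np.isin(arr, [b"-", b"."])
    n = arr.shape[0]
    valid = ~gap[:, None, :] & ~gap[None, :, :]
    diff = (arr[:, None, :] != arr[None, :, :]) & valid
    denom = valid.sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(denom > 0, diff.sum(axis=2) / np.maximum(denom, 1), 0.0)
    p = np.clip(p, 0.0, 0.99)
    d = -np.log(1.0 - p)
    np.fill_diagonal(d, 0.0)
    return (d + d.T) / 2.0


def _nj_tree(ids: list[str], dists: np.ndarray) -> TreeNode:
    dm = DistanceMatrix(dists, ids)
    return nj(dm)


def _canonical_bipartitions(tree: TreeNode) -> dict[frozenset, object]:
    """Map of canonical bipartition (the side not holding the reference
    leaf) to the defining node, for every non-trivial internal edge."""
    all_tips = frozenset(t.name for t in tree.tips())
    ref = min(all_tips)
    out: dict[frozenset, object] = {}
    for node in tree.non_tips():
        side = frozenset(t.name for t in node.tips())
        if ref in side:
            side = all_tips - side
        if 2 <= len(side) <= len(all_tips) - 2:
            out[side] = node
    return out


def build_tree(
    alignment: Sequence[tuple[str, str]],
    bootstrap_n: int = 100,
    seed: int = 0,
    metadata: dict[str, dict] | None = None,
) -> SupportTree:
    """Neighbor-joining tree with bootstrap bipartition supports.

    Distances are Poisson-corrected p-distances over mutually ungapped
    columns.  Node supports are the fraction of ``bootstrap_n`` column
    resamples whose NJ tree contains the same bipartition.  The tree is
    midpoint-rooted before supports are attached (NJ output is arbitrarily
    rooted, and a root landing inside a genuine clade would stop that clade
    from being a rooted subtree).  Deterministic for fixed (alignment, seed).
    """
    ids, arr = _encode_alignment(alignment)
    base = _nj_tree(ids, _poisson_distances(arr))
    try:
        base = base.root_at_midpoint()
    except Exception:
        pass  # degenerate (e.g. all-zero) branch lengths: keep NJ rooting
    base_biparts = _canonical_bipartitions(base)
    counts = {bp: 0 for bp in base_biparts}
    rng = np.random.default_rng(seed)
    L = arr.shape[1]
    for _ in range(bootstrap_n):
        cols = rng.integers(0, L, size=L)
        rep = _nj_tree(ids, _poisson_distances(arr[:, cols]))
        for bp in _canonical_bipartitions(rep):
            if bp in counts:
                counts[bp] += 1
    for node in base.non_tips(include_self=True):
        node.support = None
    if bootstrap_n > 0:
        for bp, node in base_biparts.items():
            node.support = counts[bp] / bootstrap_n
    else:
        for node in base_biparts.values():
            node.support = None
    if len(base.children) == 2:
        # a binary root's two children subtend the same unrooted edge
        a, b = base.children
        if not a.is_tip() and not b.is_tip():
            shared = a.support if a.support is not None else b.support
            a.support = b.support = shared
    return SupportTree(base, metadata or {})


# ---------------------------------------------------------------------------
# clade assignment


@dataclass
class CladeInfo:
    label: str
    leaves: frozenset
    support: float | None
    phyla: dict[str, int]
    node: TreeNode | None = None


@dataclass
class CladePartition:
    """Leaf-to-clade labeling of a support tree."""

    labels: dict[str, str]
    clades: dict[str, CladeInfo]
    tree: SupportTree | None = None

    def label_of(self, leaf: str) -> str:
        return self.labels.get(leaf, "unassigned")

    def leaf_sets(self) -> dict[str, frozenset]:
        return {lab: info.leaves for lab, info in self.clades.items()}


def _support_reroot_at_leaf(stree: SupportTree, leaf_name: str) -> SupportTree:
    """Reroot at the parent of a leaf, carrying supports across as edge
    attributes (keyed by bipartition)."""
    # Supports are looked up by the node's rooted tip set first (preserved
    # for every node off the rerooting path), falling back to the unrooted
    # bipartition for nodes whose orientation flipped.  With a binary root
    # both root children describe the same unrooted edge; the rooted lookup
    # keeps each child's own label in that case.
    all_tips = frozenset(t.name for t in stree.tree.tips())
    ref = min(all_tips)
    rooted: dict[frozenset, float | None] = {}
    biparts: dict[frozenset, float | None] = {}
    for node in stree.tree.non_tips():
        side = frozenset(t.name for t in node.tips())
        s = getattr(node, "support", None)
        rooted[side] = s
        canon = all_tips - side if ref in side else side
        if 2 <= len(canon) <= len(all_tips) - 2 and (
            canon not in biparts or biparts[canon] is None
        ):
            biparts[canon] = s
    t = stree.tree.copy()
    tip = next(x for x in t.tips() if x.name == leaf_name)
    new = t.root_at(tip.parent)
    all_tips = frozenset(x.name for x in new.tips())
    ref = min(all_tips)
    for node in new.non_tips(include_self=True):
        side = frozenset(x.name for x in node.tips())
        if side in rooted:
            node.support = rooted[side]
        else:
            canon = all_tips - side if ref in side else side
            node.support = biparts.get(canon)
    return SupportTree(new, stree.metadata)


def assign_clades(
    stree: SupportTree, support_min: float = SUPPORT_MIN, min_size: int = 2
) -> CladePartition:
    """Extract clades: maximal internal nodes with support >= ``support_min``
    whose leaves are all CRISPR-associated and number at least ``min_size``.

    Labels are assigned in leaf-order of appearance ("1", "2", ...).  If
    the tree carries any non-CRISPR-associated leaf, it is rerooted at one
    such leaf first so clades spanning the original (arbitrary) root are
    still recovered.
    """
    if all(
        getattr(node, "support", None) is None
        for node in stree.tree.non_tips(include_self=True)
    ):
        raise ValueError("tree carries no support values")
    work = stree
    outgroups = sorted(l for l in stree.leaf_names() if not stree.crispr_associated(l))
    if outgroups:
        work = _support_reroot_at_leaf(stree, outgroups[0])

    candidates: list[TreeNode] = []

    def descend(node: TreeNode) -> None:
        for child in node.children:
            if child.is_tip():
                continue
            tips = [t.name for t in child.tips()]
            support = getattr(child, "support", None)
            flagged = [t for t in tips if work.crispr_associated(t)]
            if (
                support is not None
                and support >= support_min
                and len(flagged) == len(tips)
                and len(flagged) >= min_size
            ):
                candidates.append(child)
            else:
                descend(child)

    # the root itself can qualify only if every leaf is flagged
    root = work.tree
    root_support = getattr(root, "support", None)
    root_tips = [t.name for t in root.tips()]
    if (
        root_support is not None
        and root_support >= support_min
        and all(work.crispr_associated(t) for t in root_tips)
        and len(root_tips) >= min_size
    ):
        candidates.append(root)
    else:
        descend(root)

    tip_order = {t.name: i for i, t in enumerate(work.tree.tips())}
    candidates.sort(key=lambda n: min(tip_order[t.name] for t in n.tips()))
    labels: dict[str, str] = {}
    clades: dict[str, CladeInfo] = {}
    for k, node in enumerate(candidates, start=1):
        label = str(k)
        leaves = frozenset(t.name for t in node.tips())
        phyla: dict[str, int] = {}
        for leaf in leaves:
            ph = work.phylum(leaf)
            phyla[ph] = phyla.get(ph, 0) + 1
        clades[label] = CladeInfo(label, leaves, getattr(node, "support", None), phyla, node)
        for leaf in leaves:
            labels[leaf] = label
    for leaf in work.leaf_names():
        labels.setdefault(leaf, "unassigned")
    return CladePartition(labels, clades, work)


def split_subclades(
    partition: CladePartition,
    stree: SupportTree | None = None,
    phylum_purity: float = 0.9,
    min_size: int = 3,
    support_min: float = SUPPORT_MIN,
) -> CladePartition:
    """Refine clades into lettered phylum-restricted subclades.

    Within each clade that is not already phylum-pure, maximal child nodes
    with support >= ``support_min``, at least ``min_size`` leaves and a
    fraction >= ``phylum_purity`` of leaves from a single phylum become
    lettered subclades (8A, 8B, ...); remaining leaves keep the parent
    label.
    """
    stree = stree or partition.tree
    if stree is None:
        raise ValueError("split_subclades needs the tree the partition came from")
    labels = dict(partition.labels)
    clades = dict(partition.clades)

    def purity(leaves: Iterable[str]) -> float:
        counts: dict[str, int] = {}
        total = 0
        for leaf in leaves:
            counts[stree.phylum(leaf)] = counts.get(stree.phylum(leaf), 0) + 1
            total += 1
        return max(counts.values()) / total if total else 0.0

    for label, info in sorted(partition.clades.items()):
        if info.node is None:
            continue
        if purity(info.leaves) >= phylum_purity:
            continue  # a single-phylum clade needs no splitting
        found: list[TreeNode] = []

        def descend(node: TreeNode) -> None:
            for child in node.children:
                if child.is_tip():
                    continue
                tips = [t.name for t in child.tips()]
                support = getattr(child, "support", None)
                if (
                    support is not None
                    and support >= support_min
                    and len(tips) >= min_size
                    and purity(tips) >= phylum_purity
                ):
                    found.append(child)
                else:
                    descend(child)

        descend(info.node)
        if not found:
            continue
        tip_order = {t.name: i for i, t in enumerate(info.node.tips())}
        found.sort(key=lambda n: min(tip_order[t.name] for t in n.tips()))
        for k, node in enumerate(found):
            letter = chr(ord("A") + k)
            sub_label = f"{label}{letter}"
            leaves = frozenset(t.name for t in node.tips())
            phyla: dict[str, int] = {}
            for leaf in leaves:
                phyla[stree.phylum(leaf)] = phyla.get(stree.phylum(leaf), 0) + 1
            clades[sub_label] = CladeInfo(
                sub_label, leaves, getattr(node, "support", None), phyla, node
            )
            for leaf in leaves:
                labels[leaf] = sub_label
    return CladePartition(labels, clades, stree)


# ---------------------------------------------------------------------------
# consensus membership screening


@dataclass
class CladeModel:
    """Per-clade consensus with an e-value exclusion threshold."""

    label: str
    member_ids: list[str]
    consensus: str
    evalue_window: tuple[float, float]
    exclusion_threshold: float


def fit_clade_models(
    clades: Mapping[str, Sequence[ProteinRecord]],
    background: Sequence[ProteinRecord] = (),
    params: SearchParams | None = None,
) -> list[CladeModel]:
    """Build one consensus model per clade and calibrate its exclusion
    threshold.

    The threshold is the geometric midpoint (in log10 e-value space)
    between the worst member self-hit and the best non-member hit against
    the clade consensus; with no non-members available it falls back to
    three orders of magnitude above the worst member.
    """
    models = []
    for label in sorted(clades):
        members = list(clades[label])
        consensus = build_consensus(members, params=params)
        member_evs = [
            local_search(m.sequence, [(label, consensus)], params)[0].evalue
            for m in members
        ]
        others = [r for other, recs in clades.items() if other != label for r in recs]
        others += list(background)
        nonmember_evs = [
            local_search(r.sequence, [(label, consensus)], params)[0].evalue
            for r in others
        ]
        # long near-identical self-hits can underflow to an e-value of
        # exactly 0.0; floor before taking logs
        worst_member = max(max(member_evs), 1e-300)
        if nonmember_evs:
            best_non = max(min(nonmember_evs), 1e-300)
            thr = 10 ** ((math.log10(worst_member) + math.log10(best_non)) / 2.0)
        else:
            thr = worst_member * 1e3
        models.append(
            CladeModel(
                label=label,
                member_ids=[m.id for m in members],
                consensus=consensus,
                evalue_window=(min(member_evs), worst_member),
                exclusion_threshold=thr,
            )
        )
    return models


def screen_membership(
    query: str,
    models: Sequence[CladeModel],
    params: SearchParams | None = None,
) -> tuple[str | None, float]:
    """Assign a query to the best-matching clade model, or none.

    The model with the lowest e-value wins iff that e-value is at or below
    its exclusion threshold; exact ties between models are ambiguous and
    return no assignment.
    """
    if not models:
        raise ValueError("screen_membership requires at least one model")
    hits = local_search(query, [(m.label, m.consensus) for m in models], params)
    best = hits[0]
    if len(hits) > 1 and hits[1].evalue == best.evalue:
        return None, best.evalue
    model = next(m for m in models if m.label == best.target_id)
    if best.evalue <= model.exclusion_threshold:
        return best.target_id, best.evalue
    return None, best.evalue


# ---------------------------------------------------------------------------
# monophyly and congruence


def _is_monophyletic(tree: TreeNode, leafset: frozenset) -> tuple[bool, float | None]:
    all_tips = frozenset(t.name for t in tree.tips())
    missing = leafset - all_tips
    if missing:
        raise ValueError(f"leaves not in tree: {sorted(missing)}")
    if leafset == all_tips or len(leafset) == 1:
        return True, None
    complement = all_tips - leafset
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if side == leafset or side == complement:
            return True, getattr(node, "support", None)
    return False, None


def monophyly(
    stree: SupportTree, labels: Mapping[str, str]
) -> dict[str, tuple[bool, float | None]]:
    """Per-label monophyly on the unrooted tree.

    A label is monophyletic iff some edge of the tree separates exactly its
    leaves from the rest (equivalently, the minimal spanning subtree of the
    labeled leaves, rooted with the label-complement as outgroup, contains
    no other leaf).  Returns label -> (monophyletic, support of the
    defining edge).
    """
    all_tips = {t.name for t in stree.tree.tips()}
    sets: dict[str, set] = {}
    for leaf, label in labels.items():
        if leaf not in all_tips:
            raise ValueError(f"unknown leaf {leaf!r}")
        sets.setdefault(label, set()).add(leaf)
    if not sets:
        raise ValueError("no labeled leaves")
    return {
        label: _is_monophyletic(stree.tree, frozenset(leaves))
        for label, leaves in sorted(sets.items())
    }


def partition_congruence(
    p1: CladePartition, p2: CladePartition
) -> tuple[float, dict[str, dict]]:
    """Congruence of two clade partitions over their shared leaves.

    Returns the adjusted Rand index of the two labelings plus, for every
    clade label of the first partition, whether its (shared) leaf set is
    monophyletic in each tree.  Coevolving protein pairs give high ARI and
    both-monophyletic labels; independently reassorting clades fail
    monophyly in the second tree.
    """
    shared = sorted(set(p1.labels) & set(p2.labels))
    if len(shared) < 2:
        raise ValueError("partitions share fewer than 2 leaves")
    ari = float(
        adjusted_rand_score(
            [p1.labels[l] for l in shared], [p2.labels[l] for l in shared]
        )
    )
    report: dict[str, dict] = {}
    for label, info in sorted(p1.clades.items()):
        leaves = frozenset(info.leaves) & set(shared)
        if not leaves:
            continue
        entry: dict[str, object] = {}
        for key, part in (("tree1", p1), ("tree2", p2)):
            if part.tree is None:
                entry[key] = None
                continue
            mono, support = _is_monophyletic(part.tree.tree, leaves)
            entry[key] = mono
            entry[f"{key}_support"] = support
        entry["agree"] = bool(entry.get("tree1")) and bool(entry.get("tree2"))
        report[label] = entry
    return ari, report
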