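"""Bipartition-based branch support: Internode Certainty and Tree Certainty.

Internode Certainty (IC) measures, for one internal branch of a reference
tree, how decisively a set of bootstrap (or gene) trees favours that
branch's bipartition over its strongest rival.  With ``p1`` the frequency
of the reference bipartition in the tree set and ``p2`` the frequency of
the most prevalent bipartition conflicting with it,

    q1 = p1 / (p1 + p2),   q2 = p2 / (p1 + p2)
    ic = 1 + q1*log2(q1) + q2*log2(q2)

with the sign negated when the rival is the more frequent of the two
(``p2 > p1``).  IC is 1 for an unopposed branch, 0 for a 50/50 split, and
approaches -1 when a conflicting bipartition dominates an absent reference
branch.  Tree Certainty (TC) is the sum of IC over internal branches;
relative TC divides by the number of internal branches of a fully resolved
unrooted tree (``n_leaves - 3``), giving a tree-level statistic in [-1, 1].

Only observed bipartitions enter the calculation (the "observed-only" IC
variant): ``p2`` is taken from the single strongest conflicting bipartition
actually present in the tree set, and the reference tree itself is not
added to the sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping, Sequence

import dendropy

Bipartition = frozenset
# A bipartition is canonically encoded as the frozenset of leaf labels on
# the side NOT containing the reference leaf (the lexicographically smallest
# label), making the encoding invariant to tree rotation and re-rooting.


class LeafSetMismatchError(ValueError):
    """Trees being compared do not share one leaf set."""


def _leaf_labels(tree: dendropy.Tree) -> frozenset[str]:
    return frozenset(lf.taxon.label for lf in tree.leaf_node_iter())


def canonical_bipartition(side: Iterable[str], universe: frozenset[str]) -> Bipartition:
    """Canonicalize one side of a split against the full leaf set."""
    side = frozenset(side)
    ref = min(universe)
    if ref in side:
        side = universe - side
    return side


def extract_bipartitions(tree: dendropy.Tree) -> set[Bipartition]:
    """Nontrivial bipartitions of a tree, one per internal edge.

    Trivial splits (one leaf against the rest) are excluded.  Works on
    rooted and unrooted trees alike; the two root-adjacent edges of a
    rooted binary tree induce the same split and are reported once.
    """
    universe = _leaf_labels(tree)
    n = len(universe)
    if n < 4:
        raise ValueError(f"need >=4 leaves for bipartition analysis, got {n}")
    splits: set[Bipartition] = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if len(below) <= 1 or len(below) >= n - 1:
            continue
        splits.add(canonical_bipartition(below, universe))
    return splits


def are_conflicting(b1: Bipartition, b2: Bipartition, universe: frozenset[str]) -> bool:
    """True iff the two bipartitions cannot coexist in any single tree.

    Two splits A1|A2 and B1|B2 are compatible iff at least one of the four
    pairwise side intersections is empty.
    """
    for side in (b1, universe - b1):
        if not (side <= universe):
            raise LeafSetMismatchError("bipartition leaves outside the leaf universe")
    for side in (b2, universe - b2):
        if not (side <= universe):
            raise LeafSetMismatchError("bipartition leaves outside the leaf universe")
    a1, a2 = b1, universe - b1
    c1, c2 = b2, universe - b2
    return not (not (a1 & c1) or not (a1 & c2) or not (a2 & c1) or not (a2 & c2))


def internode_certainty(p1: float, p2: float) -> float:
    """IC of a branch from the frequencies of its split and its top rival."""
    if p1 < 0 or p2 < 0:
        raise ValueError("frequencies must be nonnegative")
    tot = p1 + p2
    if tot == 0:
        raise ValueError("p1 and p2 cannot both be zero")
    q1 = p1 / tot
    q2 = p2 / tot
    ent = 0.0
    for q in (q1, q2):
        if q > 0:
            ent += q * math.log2(q)
    ic = 1.0 + ent
    if p2 > p1:
        ic = -ic
    return ic


@dataclass
class ICRecord:
    bipartition: Bipartition
    p1: float
    p2: float
    ic: float
    absent_from_sample: bool = False  # reference split never observed (p1 == 0)


@dataclass
class SupportReport:
    records: list[ICRecord]
    tc_sum: float
    tc_rel: float
    n_leaves: int
    n_boot_trees: int

    def as_dict(self) -> dict:
        return {
            "tc_sum": self.tc_sum,
            "tc_rel": self.tc_rel,
            "n_leaves": self.n_leaves,
            "n_boot_trees": self.n_boot_trees,
            "branches": [
                {
                    "bipartition": sorted(r.bipartition),
                    "p1": r.p1,
                    "p2": r.p2,
                    "ic": r.ic,
                    "absent_from_sample": r.absent_from_sample,
                }
                for r in self.records
            ],
        }


def bipartition_frequencies(
    trees: Sequence[dendropy.Tree], universe: frozenset[str] | None = None
) -> dict[Bipartition, float]:
    """Frequency of every nontrivial bipartition across a tree set."""
    if not trees:
        raise ValueError("empty tree set")
    counts: dict[Bipartition, int] = {}
    for t in trees:
        labels = _leaf_labels(t)
        if universe is not None and labels != universe:
            raise LeafSetMismatchError(
                f"tree leaf set {sorted(labels)[:5]}... differs from reference"
            )
        for bp in extract_bipartitions(t):
            counts[bp] = counts.get(bp, 0) + 1
    n = len(trees)
    return {bp: c / n for bp, c in counts.items()}


def tree_certainty(
    ref_tree: dendropy.Tree, boot_trees: Sequence[dendropy.Tree]
) -> SupportReport:
    """IC per reference branch and (relative) TC against a bootstrap set."""
    universe = _leaf_labels(ref_tree)
    if len(boot_trees) < 2:
        raise ValueError("need at least 2 bootstrap trees")
    freqs = bipartition_frequencies(boot_trees, universe)
    records: list[ICRecord] = []
    for bp in sorted(extract_bipartitions(ref_tree), key=sorted):
        p1 = freqs.get(bp, 0.0)
        p2 = 0.0
        for other, f in freqs.items():
            if f > p2 and are_conflicting(bp, other, universe):
                p2 = f
        if p1 == 0.0 and p2 == 0.0:
            # Branch unopposed but also never sampled: treat as uninformative.
            ic = 0.0
        else:
            ic = internode_certainty(p1, p2)
        records.append(ICRecord(bp, p1, p2, ic, absent_from_sample=p1 == 0.0))
    tc_sum = sum(r.ic for r in records)
    n = len(universe)
    tc_rel = tc_sum / (n - 3)
    return SupportReport(records, tc_sum, tc_rel, n, len(boot_trees))


# ---------------------------------------------------------------------------
# Rooting


class NonMonophyleticOutgroupError(ValueError):
    def __init__(self, intruders: Iterable[str]):
        self.intruders = sorted(intruders)
        super().__init__(
            "outgroup is not monophyletic on the unrooted tree; "
            f"intruding leaves: {', '.join(self.intruders)}"
        )


def root_tree(tree: dendropy.Tree, outgroup_leaves: Iterable[str]) -> dendropy.Tree:
    """Root an (unrooted) tree on the edge separating the outgroup.

    The outgroup must form one side of an existing bipartition; the split
    edge's length is divided equally between the two new root children.
    """
    outgroup = frozenset(outgroup_leaves)
    tree = tree.clone(depth=1)
    universe = _leaf_labels(tree)
    missing = outgroup - universe
    if missing:
        raise ValueError(f"outgroup leaves not in tree: {sorted(missing)}")
    if outgroup == universe:
        raise ValueError("outgroup cannot be the entire leaf set")

    target = None
    if len(outgroup) == 1:
        (label,) = outgroup
        target = next(
            lf for lf in tree.leaf_node_iter() if lf.taxon.label == label
        )
    else:
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            below = frozenset(lf.taxon.label for lf in node.leaf_iter())
            if below == outgroup or below == universe - outgroup:
                target = node
                break
    if target is None:
        # Identify which leaves break monophyly: leaves of the smallest clade
        # containing the outgroup that are not outgroup members.
        tree.is_rooted = True  # clone; silence dendropy's unrooted-MRCA warning
        mrca = tree.mrca(taxon_labels=sorted(outgroup))
        inside = frozenset(lf.taxon.label for lf in mrca.leaf_iter())
        raise NonMonophyleticOutgroupError(inside - outgroup)

    edge = target.edge
    half = (edge.length or 0.0) / 2.0
    tree.reroot_at_edge(edge, length1=half, length2=half)
    tree.is_rooted = True
    return tree
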