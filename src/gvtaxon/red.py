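"""Relative evolutionary divergence (RED) and rank delineation.

RED places every node of a rooted tree on a 0-to-1 scale — 0 at the root,
1 at every leaf — so that taxonomic ranks can be delineated at comparable
phylogenetic depths.  With ``x`` a node's branch length to its parent and
``ybar`` the mean path length from the node to its descendant tips,

    red(node) = red(parent) + x / (x + ybar) * (1 - red(parent))

computed in pre-order with the root fixed at 0; polytomies are handled
natively (``ybar`` averages over all descendant tips).

Ranks are delineated by nonoverlapping half-open RED windows, each rank's
window lying above the previous rank's: descending from the root, a clade
is cut at the shallowest node whose RED falls in a rank's window.  Groups
below the per-rank minimum size (3 members for families) are dissolved
and their genomes flagged incertae sedis at that rank, as are leaves
whose path skips the window entirely.  Windows can be derived from anchor
taxa of known rank (midpoint boundaries between adjacent rank RED ranges)
or supplied directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .synthetic import RANKS, TrueTaxonomy

DEFAULT_MIN_MEMBERS = {"class": 1, "order": 1, "family": 3, "genus": 1}
INCERTAE_SEDIS = "incertae_sedis"


class WindowError(ValueError):
    pass


def compute_red(tree: dendropy.Tree) -> dict[dendropy.Node, float]:
    """RED value per node of a rooted tree (also stored as ``node.red``)."""
    if not tree.is_rooted:
        raise ValueError("RED requires a rooted tree")
    leaves = list(tree.leaf_node_iter())
    if len(leaves) < 2:
        raise ValueError("need at least 2 leaves")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ValueError("negative branch length")

    # Mean node-to-tip path length, bottom-up.
    ntips: dict[dendropy.Node, int] = {}
    ybar: dict[dendropy.Node, float] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            ntips[node] = 1
            ybar[node] = 0.0
        else:
            total = 0.0
            n = 0
            for ch in node.child_nodes():
                total += (ybar[ch] + (ch.edge.length or 0.0)) * ntips[ch]
                n += ntips[ch]
            ntips[node] = n
            ybar[node] = total / n

    red: dict[dendropy.Node, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            red[node] = 0.0
        elif node.is_leaf():
            red[node] = 1.0
        else:
            x = node.edge.length or 0.0
            denom = x + ybar[node]
            frac = x / denom if denom > 0 else 0.0
            p = red[node.parent_node]
            red[node] = p + frac * (1.0 - p)
        node.red = red[node]
    return red


@dataclass(frozen=True)
class RankWindows:
    """Half-open RED interval per rank, disjoint and increasing with depth."""

    windows: Mapping[str, tuple[float, float]]

    def __post_init__(self):
        prev_hi = None
        for rank in RANKS:
            if rank not in self.windows:
                raise WindowError(f"missing window for rank {rank!r}")
            lo, hi = self.windows[rank]
            if not lo < hi:
                raise WindowError(f"{rank}: window [{lo}, {hi}) is empty")
            if prev_hi is not None and lo < prev_hi:
                raise WindowError(
                    f"{rank}: window overlaps the previous rank "
                    f"({lo} < {prev_hi})"
                )
            prev_hi = hi

    def rank_of(self, red_value: float) -> str | None:
        for rank in RANKS:
            lo, hi = self.windows[rank]
            if lo <= red_value < hi:
                return rank
        return None

    def as_dict(self) -> dict:
        return {r: list(self.windows[r]) for r in RANKS}


def rank_red_ranges(
    tree: dendropy.Tree,
    red_values: Mapping[dendropy.Node, float],
    anchors: Mapping[str, tuple[str, str]],
) -> dict[str, tuple[float, float]]:
    """[min, max] RED of the anchored taxa's MRCAs, per rank.

    ``anchors`` maps genome id -> (rank, taxon name); genomes sharing a
    (rank, name) pair define one anchored taxon whose MRCA is evaluated.
    """
    leaf_labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    by_taxon: dict[tuple[str, str], list[str]] = {}
    for genome, (rank, name) in anchors.items():
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}")
        if genome not in leaf_labels:
            raise ValueError(f"anchor genome {genome!r} not in tree")
        by_taxon.setdefault((rank, name), []).append(genome)
    ranges: dict[str, tuple[float, float]] = {}
    for (rank, name), genomes in sorted(by_taxon.items()):
        if len(genomes) == 1:
            (label,) = genomes
            node = next(lf for lf in tree.leaf_node_iter()
                        if lf.taxon.label == label)
        else:
            node = tree.mrca(taxon_labels=genomes)
        r = red_values[node]
        lo, hi = ranges.get(rank, (r, r))
        ranges[rank] = (min(lo, r), max(hi, r))
    return ranges


def derive_rank_windows(
    tree: dendropy.Tree,
    red_values: Mapping[dendropy.Node, float],
    anchors: Mapping[str, tuple[str, str]] | None = None,
    defaults: Mapping[str, tuple[float, float]] | None = None,
) -> RankWindows:
    """Disjoint per-rank RED windows, from anchors or from configured defaults.

    With anchors, each rank's core interval spans the anchored MRCAs'
    [min, max] RED, and boundaries between adjacent ranks sit at the
    midpoint between one rank's max and the next rank's min; the class
    window opens at the midpoint to the root (RED 0) and the genus window
    closes at the midpoint to the leaves (RED 1).  Overlapping anchored
    rank ranges are an error (manual windows are then required).
    """
    if anchors:
        ranges = rank_red_ranges(tree, red_values, anchors)
        missing = [r for r in RANKS if r not in ranges]
        if missing:
            raise WindowError(f"no anchors for ranks: {missing}")
        for a, b in zip(RANKS, RANKS[1:]):
            if ranges[a][1] >= ranges[b][0]:
                raise WindowError(
                    f"anchored RED ranges overlap between {a} "
                    f"({ranges[a]}) and {b} ({ranges[b]}); "
                    "supply windows manually"
                )
        bounds = [ranges[RANKS[0]][0] / 2.0]
        for a, b in zip(RANKS, RANKS[1:]):
            bounds.append((ranges[a][1] + ranges[b][0]) / 2.0)
        bounds.append((ranges[RANKS[-1]][1] + 1.0) / 2.0)
        windows = {
            rank: (bounds[i], bounds[i + 1]) for i, rank in enumerate(RANKS)
        }
        return RankWindows(windows)
    if defaults is None:
        raise WindowError("neither anchors nor default windows supplied")
    return RankWindows({r: tuple(defaults[r]) for r in RANKS})


# ---------------------------------------------------------------------------
# Delineation


@dataclass
class Clade:
    clade_id: str
    rank: str
    members: list[str]
    red: float
    order_index: int  # pre-order appearance, for deterministic numbering
    name: str | None = None
    anchored: bool = False


@dataclass
class TaxonomyAssignment:
    """Per-genome rank labels with incertae sedis bookkeeping.

    ``labels[genome][rank]`` is a clade/display name, or the literal
    ``incertae_sedis`` marker when the genome could not be placed in an
    accepted clade at that rank.
    """

    clades: dict[str, Clade]  # clade_id -> Clade
    membership: dict[str, dict[str, str | None]]  # genome -> rank -> clade_id

    def label(self, genome: str, rank: str) -> str:
        cid = self.membership[genome][rank]
        if cid is None:
            return INCERTAE_SEDIS
        clade = self.clades[cid]
        return clade.name if clade.name else cid

    def is_incertae_sedis(self, genome: str, rank: str) -> bool:
        return self.membership[genome][rank] is None

    def clades_at(self, rank: str) -> list[Clade]:
        return sorted(
            (c for c in self.clades.values() if c.rank == rank),
            key=lambda c: c.order_index,
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for genome in sorted(self.membership):
            row = {"genome_id": genome}
            for rank in RANKS:
                row[rank] = self.label(genome, rank)
                row[f"{rank}_incertae_sedis"] = self.is_incertae_sedis(genome, rank)
            rows.append(row)
        return pd.DataFrame(rows)


def delineate(
    tree: dendropy.Tree,
    red_values: Mapping[dendropy.Node, float],
    windows: RankWindows,
    min_members: Mapping[str, int] | None = None,
) -> TaxonomyAssignment:
    """Cut rank clades at the shallowest in-window node along each path.

    Pre-order traversal; a node whose RED falls inside a rank's window
    starts a clade of that rank unless an ancestor already did at the same
    rank.  Cut clades smaller than ``min_members[rank]`` are dissolved and
    their leaves flagged incertae sedis at that rank, as are leaves not
    covered by any in-window node (e.g. a long branch skipping a window).
    Rank decisions are independent: a genome can be family-incertae-sedis
    yet belong to a genus clade.
    """
    mins = dict(DEFAULT_MIN_MEMBERS)
    if min_members:
        mins.update(min_members)

    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    membership: dict[str, dict[str, str | None]] = {
        g: {r: None for r in RANKS} for g in leaves
    }
    clades: dict[str, Clade] = {}
    counters = {r: 0 for r in RANKS}

    # Pre-order with the set of ranks already cut on the path to each node.
    order_index = 0
    stack: list[tuple[dendropy.Node, frozenset[str]]] = [
        (tree.seed_node, frozenset())
    ]
    preorder: list[tuple[dendropy.Node, frozenset[str]]] = []
    while stack:
        node, cut_ranks = stack.pop()
        rank = windows.rank_of(red_values[node])
        new_cut = cut_ranks
        if rank is not None and rank not in cut_ranks:
            order_index += 1
            members = sorted(lf.taxon.label for lf in node.leaf_iter())
            if len(members) >= mins.get(rank, 1):
                counters[rank] += 1
                cid = f"{rank}-{counters[rank]:03d}"
                clades[cid] = Clade(cid, rank, members, red_values[node],
                                    order_index)
                for g in members:
                    membership[g][rank] = cid
            # Undersized groups dissolve: members stay incertae sedis and
            # no deeper node may re-cut this rank inside the clade.
            new_cut = cut_ranks | {rank}
        for ch in reversed(node.child_nodes()):
            stack.append((ch, new_cut))

    return TaxonomyAssignment(clades, membership)


class AnchorConflictError(ValueError):
    pass


def apply_anchors(
    assignment: TaxonomyAssignment,
    anchors: Mapping[str, tuple[str, str]],
) -> TaxonomyAssignment:
    """Name delineated clades after the anchor genomes they contain.

    A clade holding anchors of two different names at its own rank is a
    conflict error; clades without anchors keep their automatic ids until
    :func:`assign_identifiers` runs.
    """
    for genome, (rank, name) in sorted(anchors.items()):
        if genome not in assignment.membership:
            raise ValueError(f"anchor genome {genome!r} not in assignment")
        cid = assignment.membership[genome][rank]
        if cid is None:
            continue  # anchor fell in an incertae sedis leaf; nothing to name
        clade = assignment.clades[cid]
        if clade.name is not None and clade.name != name:
            raise AnchorConflictError(
                f"clade {cid} ({rank}) holds anchors for both "
                f"{clade.name!r} and {name!r}"
            )
        clade.name = name
        clade.anchored = True
    return assignment


def assign_identifiers(
    assignment: TaxonomyAssignment,
    order_prefix_map: Mapping[str, str],
    rank: str = "family",
) -> TaxonomyAssignment:
    """Order-prefixed identifiers (e.g. ``IM_01``) for unanchored clades.

    Within each order, unanchored clades of ``rank`` are numbered in
    pre-order appearance; anchored clades keep their names and consume no
    number.  Numbering is therefore stable under permutations of the
    input files.  An order label with no prefix entry is an error.
    """
    counters: dict[str, int] = {}
    for clade in assignment.clades_at(rank):
        if clade.anchored:
            continue
        member_orders = {
            assignment.label(g, "order") for g in clade.members
        } - {INCERTAE_SEDIS}
        if not member_orders:
            continue  # order unassigned; keep the automatic id
        if len(member_orders) > 1:
            raise ValueError(
                f"clade {clade.clade_id} spans orders {sorted(member_orders)}"
            )
        (order_label,) = member_orders
        if order_label not in order_prefix_map:
            raise KeyError(f"no identifier prefix for order {order_label!r}")
        prefix = order_prefix_map[order_label]
        counters[prefix] = counters.get(prefix, 0) + 1
        clade.name = f"{prefix}_{counters[prefix]:02d}"
    return assignment


# ---------------------------------------------------------------------------
# Recovery scoring


def recovery_score(
    truth: TrueTaxonomy,
    inferred: TaxonomyAssignment,
    rank: str,
) -> tuple[float, float]:
    """(ARI, exact-match fraction) of the inferred vs true rank partition.

    Incertae sedis genomes each form their own singleton in the inferred
    partition, so a true singleton genus flagged incertae sedis still
    counts as recovered.
    """
    true_labels = truth.labels_at(rank)
    genomes = sorted(true_labels)
    if set(genomes) != set(inferred.membership):
        raise ValueError("genome sets differ between truth and inference")
    t = [true_labels[g] for g in genomes]
    i = [
        inferred.membership[g][rank]
        if inferred.membership[g][rank] is not None
        else f"__is__{g}"
        for g in genomes
    ]
    ari = float(adjusted_rand_score(t, i))

    t_groups: dict[str, set[str]] = {}
    i_groups: dict[str, set[str]] = {}
    for g, lab in zip(genomes, t):
        t_groups.setdefault(lab, set()).add(g)
    for g, lab in zip(genomes, i):
        i_groups.setdefault(lab, set()).add(g)
    exact = sum(
        1
        for g, tl, il in zip(genomes, t, i)
        if t_groups[tl] == i_groups[il]
    ) / len(genomes)
    return ari, float(exact)
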