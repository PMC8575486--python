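"""Synthetic data with known ground truth for the whole pipeline.

Emulates the statistical structure the taxonomy procedure relies on:

* a four-rank taxonomy (class / order / family / genus) imprinted on a
  rooted tree whose rank ancestors sit at controlled depths, so that
  relative evolutionary divergence (RED) windows per rank are recoverable
  by construction;
* per-marker amino-acid alignments evolved along that tree under an
  equal-rates (Jukes–Cantor-style) substitution model, with controlled
  marker loss (emulating incomplete metagenome-assembled genomes) and
  paralog duplication (emulating multi-copy markers such as MCP);
* nucleotide genome sets with controlled divergence from a common
  ancestor, as fixtures for MinHash sketch dereplication;
* bootstrap tree sets with planted per-branch concordances, as fixtures
  for Internode/Tree-Certainty evaluation.

No indels are simulated, so marker outputs are valid alignments as
generated and external aligners stay out of the test path.  Every
generator is deterministic under its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .io import derive_seed
from .tree_support import Bipartition, canonical_bipartition

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
NUCLEOTIDES = np.array(list("ACGT"))

RANKS = ("class", "order", "family", "genus")


class ParameterError(ValueError):
    """A simulation parameter is outside its valid range."""


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic study system.

    ``rank_depth_fractions`` place the most recent common ancestor of each
    class/order/family/genus at that fraction of the root-to-tip distance
    (strictly increasing, all in (0, 1)); ``branch_noise`` is the
    coefficient of variation of a mean-preserving log-normal factor applied
    per branch; ``subst_rate`` is in expected substitutions per site per
    unit branch length.
    """

    n_classes: int = 2
    orders_per_class: int = 2
    families_per_order: int = 2
    genera_per_family: int = 2
    genomes_per_genus: int = 3
    rank_depth_fractions: tuple[float, float, float, float] = (0.05, 0.2, 0.6, 0.85)
    branch_noise: float = 0.2
    marker_loss_prob: float = 0.1
    paralog_prob: float = 0.05
    subst_rate: float = 1.0
    genome_length: int = 20000
    divergence_grid: tuple[float, ...] = (0.0, 0.01, 0.02, 0.05, 0.1, 0.2)
    seed: int = 0

    def __post_init__(self):
        counts = (self.n_classes, self.orders_per_class, self.families_per_order,
                  self.genera_per_family, self.genomes_per_genus)
        if any(c < 1 for c in counts):
            raise ParameterError(f"all rank counts must be >= 1, got {counts}")
        for p_name in ("marker_loss_prob", "paralog_prob"):
            p = getattr(self, p_name)
            if not 0.0 <= p <= 1.0:
                raise ParameterError(f"{p_name} must be in [0, 1], got {p}")
        fr = self.rank_depth_fractions
        if len(fr) != 4 or any(not 0.0 < f < 1.0 for f in fr) or not all(
            a < b for a, b in zip(fr, fr[1:])
        ):
            raise ParameterError(
                "rank_depth_fractions must be 4 strictly increasing values in (0,1), "
                f"got {fr}"
            )
        if self.branch_noise < 0:
            raise ParameterError("branch_noise must be >= 0")
        if self.subst_rate < 0:
            raise ParameterError("subst_rate must be >= 0")
        if any(g > 0.5 or g < 0 for g in self.divergence_grid):
            raise ParameterError(
                "divergences must lie in [0, 0.5]; beyond 0.5 the k-mer identity "
                f"signal saturates (got {self.divergence_grid})"
            )

    @property
    def n_genomes(self) -> int:
        return (self.n_classes * self.orders_per_class * self.families_per_order
                * self.genera_per_family * self.genomes_per_genus)


@dataclass
class TrueTaxonomy:
    """Ground-truth rank labels: genome_id -> (class, order, family, genus)."""

    assignments: dict[str, tuple[str, str, str, str]]

    def labels_at(self, rank: str) -> dict[str, str]:
        idx = RANKS.index(rank)
        return {g: labels[idx] for g, labels in self.assignments.items()}

    def counts(self) -> dict[str, int]:
        return {
            rank: len(set(self.labels_at(rank).values())) for rank in RANKS
        }

    def taxa_at(self, rank: str) -> dict[str, list[str]]:
        """Taxon label -> member genome ids, sorted."""
        out: dict[str, list[str]] = {}
        for g, lab in sorted(self.labels_at(rank).items()):
            out.setdefault(lab, []).append(g)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"genome_id": g, **dict(zip(RANKS, labels))}
            for g, labels in sorted(self.assignments.items())
        ]
        return pd.DataFrame(rows)


def simulate_taxonomy(config: SimulationConfig) -> TrueTaxonomy:
    """Enumerate the nested rank labels of the configured study system."""
    assignments: dict[str, tuple[str, str, str, str]] = {}
    g_id = 0
    cl_i = or_i = fa_i = ge_i = 0
    for _ in range(config.n_classes):
        cl_i += 1
        cl = f"CL{cl_i:02d}"
        for _ in range(config.orders_per_class):
            or_i += 1
            orr = f"OR{or_i:02d}"
            for _ in range(config.families_per_order):
                fa_i += 1
                fa = f"FA{fa_i:02d}"
                for _ in range(config.genera_per_family):
                    ge_i += 1
                    ge = f"GE{ge_i:02d}"
                    for _ in range(config.genomes_per_genus):
                        g_id += 1
                        assignments[f"g{g_id:04d}"] = (cl, orr, fa, ge)
    return TrueTaxonomy(assignments)


def simulate_tree(taxonomy: TrueTaxonomy, config: SimulationConfig) -> dendropy.Tree:
    """Rooted tree with each rank ancestor at its configured relative depth.

    The noiseless root-to-tip distance is 1.  Each true taxon at each rank
    is monophyletic by construction.  With ``branch_noise > 0`` every
    branch length is multiplied by an independent mean-preserving
    log-normal factor with that coefficient of variation.
    """
    if not taxonomy.assignments:
        raise ParameterError("taxonomy is empty")
    d1, d2, d3, d4 = config.rank_depth_fractions

    taxa = dendropy.TaxonNamespace(sorted(taxonomy.assignments))
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.is_rooted = True

    by_class = {}
    for g, (cl, orr, fa, ge) in sorted(taxonomy.assignments.items()):
        by_class.setdefault(cl, {}).setdefault(orr, {}).setdefault(fa, {}) \
            .setdefault(ge, []).append(g)

    for cl, orders in sorted(by_class.items()):
        cl_node = tree.seed_node.new_child(edge_length=d1)
        cl_node.label = cl
        for orr, fams in sorted(orders.items()):
            or_node = cl_node.new_child(edge_length=d2 - d1)
            or_node.label = orr
            for fa, genera in sorted(fams.items()):
                fa_node = or_node.new_child(edge_length=d3 - d2)
                fa_node.label = fa
                for ge, genomes in sorted(genera.items()):
                    ge_node = fa_node.new_child(edge_length=d4 - d3)
                    ge_node.label = ge
                    for g in genomes:
                        leaf = ge_node.new_child(edge_length=1.0 - d4)
                        leaf.taxon = taxa.get_taxon(g)

    if config.branch_noise > 0:
        rng = np.random.default_rng(derive_seed(config.seed, "tree-noise"))
        sigma2 = np.log1p(config.branch_noise ** 2)
        sigma = np.sqrt(sigma2)
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= float(np.exp(rng.normal(-sigma2 / 2.0, sigma)))

    # Collapse unary chains produced by rank counts of 1; branch lengths add,
    # so rank depths are unaffected.
    tree.suppress_unifurcations()
    return tree


# ---------------------------------------------------------------------------
# Marker evolution


def _evolve(seq_idx: np.ndarray, t: float, n_states: int, rng) -> np.ndarray:
    """Jukes–Cantor evolution of an index-encoded sequence for time t."""
    if t <= 0:
        return seq_idx.copy()
    k = n_states
    p_diff = (k - 1) / k * (1.0 - np.exp(-k / (k - 1) * t))
    hit = rng.random(seq_idx.size) < p_diff
    out = seq_idx.copy()
    if hit.any():
        # Uniform draw over the k-1 other states.
        shift = rng.integers(1, k, size=int(hit.sum()))
        out[hit] = (out[hit] + shift) % k
    return out


@dataclass
class MarkerSimulation:
    """Per-marker alignments plus the presence/paralogy truth table.

    ``alignments[marker]`` maps sequence ids to aligned sequences; the
    ortholog of genome *g* is named ``g`` and paralogs ``g|p1``, ``g|p2``…
    ``truth`` has one row per (genome, marker) with columns ``present`` and
    ``paralog_ids`` (comma-joined, empty if none).
    """

    alignments: dict[str, dict[str, str]]
    truth: pd.DataFrame


def simulate_marker_alignments(
    tree: dendropy.Tree,
    marker_names: Sequence[str],
    lengths: Sequence[int],
    config: SimulationConfig,
) -> MarkerSimulation:
    if not marker_names:
        raise ParameterError("empty marker list")
    if len(marker_names) != len(lengths):
        raise ParameterError("need exactly one length per marker")

    alignments: dict[str, dict[str, str]] = {}
    rows = []
    k = len(AMINO_ACIDS)
    for marker, length in zip(marker_names, lengths):
        rng = np.random.default_rng(derive_seed(config.seed, f"marker:{marker}"))
        root_seq = rng.integers(0, k, size=int(length))
        node_seq: dict[int, np.ndarray] = {id(tree.seed_node): root_seq}
        leaf_seqs: dict[str, np.ndarray] = {}
        leaf_brlen: dict[str, float] = {}
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            parent_seq = node_seq[id(node.parent_node)]
            t = (node.edge.length or 0.0) * config.subst_rate
            seq = _evolve(parent_seq, t, k, rng)
            node_seq[id(node)] = seq
            if node.is_leaf():
                leaf_seqs[node.taxon.label] = seq
                leaf_brlen[node.taxon.label] = node.edge.length or 0.0

        aln: dict[str, str] = {}
        for genome in sorted(leaf_seqs):
            present = rng.random() >= config.marker_loss_prob
            paralog_ids = []
            if present:
                aln[genome] = "".join(AMINO_ACIDS[leaf_seqs[genome]])
                if rng.random() < config.paralog_prob:
                    # Re-evolve the ortholog with an extra divergence of
                    # twice the terminal branch length, so paralog scores
                    # fall below ortholog scores in expectation.
                    extra = 2.0 * leaf_brlen[genome] * config.subst_rate
                    pseq = _evolve(leaf_seqs[genome], extra, k, rng)
                    pid = f"{genome}|p1"
                    aln[pid] = "".join(AMINO_ACIDS[pseq])
                    paralog_ids.append(pid)
            rows.append(
                {
                    "genome_id": genome,
                    "marker": marker,
                    "present": present,
                    "paralog_ids": ",".join(paralog_ids),
                }
            )
        alignments[marker] = aln
    truth = pd.DataFrame(rows)
    return MarkerSimulation(alignments, truth)


# ---------------------------------------------------------------------------
# Genome sets for dereplication


@dataclass
class GenomeSetSimulation:
    """Nucleotide genomes diverged from one ancestor, with true divergences."""

    genomes: dict[str, str]
    truth: pd.DataFrame  # genome_id, true_divergence (to the ancestor)


def simulate_genome_set(config: SimulationConfig) -> GenomeSetSimulation:
    if config.genome_length < 1000:
        raise ParameterError("genome_length must be >= 1000")
    rng = np.random.default_rng(derive_seed(config.seed, "genomes"))
    k = len(NUCLEOTIDES)
    anc = rng.integers(0, k, size=config.genome_length)
    genomes = {"ancestor": "".join(NUCLEOTIDES[anc])}
    rows = [{"genome_id": "ancestor", "true_divergence": 0.0}]
    for i, g in enumerate(config.divergence_grid):
        hit = rng.random(anc.size) < g
        mut = anc.copy()
        if hit.any():
            shift = rng.integers(1, k, size=int(hit.sum()))
            mut[hit] = (mut[hit] + shift) % k
        gid = f"mut{i:02d}"
        genomes[gid] = "".join(NUCLEOTIDES[mut])
        rows.append({"genome_id": gid, "true_divergence": float(g)})
    return GenomeSetSimulation(genomes, pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Bootstrap tree sets with planted concordance


def _deterministic_nni(node: dendropy.Node) -> None:
    """Swap the alphabetically first child of ``node`` with its first sibling.

    Replaces the bipartition below ``node`` with a conflicting one; the
    choice of swap partners is deterministic so every rearrangement of a
    given branch yields the same rival bipartition.
    """
    parent = node.parent_node

    def sort_key(n):
        return min(lf.taxon.label for lf in n.leaf_iter())

    children = sorted(node.child_nodes(), key=sort_key)
    siblings = sorted(
        (c for c in parent.child_nodes() if c is not node), key=sort_key
    )
    x, s = children[0], siblings[0]
    node.remove_child(x)
    parent.remove_child(s)
    node.add_child(s)
    parent.add_child(x)


def simulate_bootstrap_trees(
    ref_tree: dendropy.Tree,
    concordance: float | Mapping[Bipartition, float],
    n_reps: int,
    seed: int,
) -> list[dendropy.Tree]:
    """Bootstrap-like replicates preserving each branch with its concordance.

    ``concordance`` is either a single fraction applied to every internal
    branch or a mapping from canonical bipartitions (frozenset of the leaf
    side not containing the smallest label) to per-branch fractions;
    unmapped branches default to 1.0.  A branch that is not preserved
    undergoes a deterministic nearest-neighbour interchange, producing the
    same conflicting bipartition in every replicate where it fires.
    """
    if n_reps < 1:
        raise ParameterError("n_reps must be >= 1")
    universe = frozenset(lf.taxon.label for lf in ref_tree.leaf_node_iter())
    if isinstance(concordance, Mapping):
        conc_map = dict(concordance)
        default = 1.0
    else:
        c = float(concordance)
        if not 0.0 <= c <= 1.0:
            raise ParameterError("concordance must be in [0, 1]")
        conc_map = {}
        default = c
    for c in conc_map.values():
        if not 0.0 <= c <= 1.0:
            raise ParameterError("concordance must be in [0, 1]")

    # Identify rearrangeable internal edges on the reference once.
    internal = []
    for node in ref_tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if len(below) <= 1 or len(below) >= len(universe) - 1:
            continue
        internal.append(canonical_bipartition(below, universe))

    rng = np.random.default_rng(seed)
    reps: list[dendropy.Tree] = []
    for _ in range(n_reps):
        rep = ref_tree.clone(depth=1)
        # Locate nodes by bipartition on the pristine clone before editing.
        targets = []
        for node in rep.preorder_node_iter():
            if node.parent_node is None or node.is_leaf():
                continue
            below = frozenset(lf.taxon.label for lf in node.leaf_iter())
            if len(below) <= 1 or len(below) >= len(universe) - 1:
                continue
            bp = canonical_bipartition(below, universe)
            c = conc_map.get(bp, default)
            if rng.random() >= c:
                targets.append(node)
        for node in targets:
            _deterministic_nni(node)
        reps.append(rep)
    return reps
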