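"""Phylogenetic marker extraction, concatenation, and set benchmarking.

Marker hits are filtered by per-marker bit-score cutoffs calibrated to the
fifth percentile of each marker's best-hit score distribution, so that
poorly matching proteins are excluded; per genome the highest-scoring
survivor is the presumed ortholog and any further above-cutoff copies are
flagged as extra (paralogous) copies.  Concatenation assembles one row per
genome in canonical (alphabetical) marker order, gap-filling markers a
genome lacks, and records partition boundaries.  Benchmarking scores
candidate marker sets by relative Tree Certainty: for each set a reference
tree is inferred several times (with independently resampled bootstrap
sets), and the run with the highest TC is reported — low TC for a
concatenation indicates markers with incongruent phylogenetic signal.

The built-in tree backend is neighbour joining on Poisson-corrected
pairwise distances; an external maximum-likelihood backend can be plugged
in as a callable, and the backend used is stamped into every result.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from skbio.tree import nj

from .io import derive_seed, tree_from_string
from .tree_support import SupportReport, tree_certainty

TreeBackend = Callable[[Mapping[str, str], int], dendropy.Tree]


# ---------------------------------------------------------------------------
# Cutoffs and ortholog selection


def calibrate_cutoff(
    best_hit_scores: Sequence[float],
    percentile: float = 5.0,
    method: str = "nearest-rank",
) -> float:
    """Score cutoff at the given percentile of best-hit scores.

    The default nearest-rank estimator takes the value at rank
    ``ceil(p/100 * n)`` (1-indexed, ascending); ``method="linear"`` uses
    interpolated percentiles instead.
    """
    if len(best_hit_scores) == 0:
        raise ValueError("no scores to calibrate against")
    scores = sorted(best_hit_scores)
    if method == "linear":
        return float(np.percentile(scores, percentile))
    if method != "nearest-rank":
        raise ValueError(f"unknown percentile method {method!r}")
    n = len(scores)
    rank = max(1, math.ceil(percentile / 100.0 * n))
    return float(scores[rank - 1])


def select_orthologs(
    hits: pd.DataFrame, cutoffs: Mapping[str, float]
) -> pd.DataFrame:
    """Apply cutoffs and flag the best hit and extra copies per (genome, marker).

    ``hits`` columns: genome_id, marker, protein_id, bitscore.  Hits below
    their marker's cutoff are dropped; per (genome, marker) the highest
    bit score wins ``is_best`` (ties broken by lexicographic protein_id)
    and all other survivors are marked ``is_extra_copy``.
    """
    required = {"genome_id", "marker", "protein_id", "bitscore"}
    missing = required - set(hits.columns)
    if missing:
        raise KeyError(f"hit table lacks columns: {sorted(missing)}")
    rows = []
    kept = hits[
        hits.apply(lambda r: r.bitscore >= cutoffs.get(r.marker, -math.inf), axis=1)
    ] if len(hits) else hits
    for (genome, marker), grp in kept.groupby(["genome_id", "marker"], sort=True):
        grp = grp.sort_values(["bitscore", "protein_id"],
                              ascending=[False, True], kind="mergesort")
        for i, (_, r) in enumerate(grp.iterrows()):
            rows.append(
                {
                    "genome_id": genome,
                    "marker": marker,
                    "protein_id": r.protein_id,
                    "bitscore": r.bitscore,
                    "is_best": i == 0,
                    "is_extra_copy": i > 0,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["genome_id", "marker", "protein_id", "bitscore",
                 "is_best", "is_extra_copy"],
    )


# ---------------------------------------------------------------------------
# Concatenation


@dataclass
class ConcatAlignment:
    """Concatenated marker alignment with partition bookkeeping.

    ``partitions`` maps marker -> (start, end), 0-based half-open columns;
    markers appear in canonical alphabetical order and tile every row
    exactly.  ``missing`` records which markers each genome lacked (those
    stretches are gap runs of the marker's full width).
    """

    rows: dict[str, str]
    partitions: dict[str, tuple[int, int]]
    missing: dict[str, list[str]]

    @property
    def width(self) -> int:
        return max((end for _, end in self.partitions.values()), default=0)

    def partition_text(self) -> str:
        """RAxML-style partition lines (1-based inclusive columns)."""
        lines = []
        for marker, (start, end) in sorted(self.partitions.items()):
            lines.append(f"PROT, {marker} = {start + 1}-{end}")
        return "\n".join(lines) + "\n"


def concatenate(
    per_marker_alignments: Mapping[str, Mapping[str, str]],
    genome_set: Sequence[str] | None = None,
    marker_subset: Sequence[str] | None = None,
) -> ConcatAlignment:
    """Concatenate per-marker alignments into one row per genome.

    Each per-marker alignment maps genome id -> aligned sequence (at most
    one per genome: the selected ortholog).  A genome missing a marker is
    gap-filled across that marker's partition; a genome absent from every
    marker is excluded with a warning.
    """
    markers = sorted(marker_subset if marker_subset is not None
                     else per_marker_alignments)
    if not markers:
        raise ValueError("no markers to concatenate")
    widths = {}
    for m in markers:
        aln = per_marker_alignments[m]
        if not aln:
            raise ValueError(f"marker {m!r}: empty alignment")
        w = {len(s) for s in aln.values()}
        if len(w) != 1:
            raise ValueError(f"marker {m!r}: ragged alignment")
        widths[m] = w.pop()

    if genome_set is None:
        genome_set = sorted({g for m in markers
                             for g in per_marker_alignments[m]})
    partitions: dict[str, tuple[int, int]] = {}
    pos = 0
    for m in markers:
        partitions[m] = (pos, pos + widths[m])
        pos += widths[m]

    rows: dict[str, str] = {}
    missing: dict[str, list[str]] = {}
    for genome in sorted(genome_set):
        pieces = []
        absent = []
        for m in markers:
            seq = per_marker_alignments[m].get(genome)
            if seq is None:
                pieces.append("-" * widths[m])
                absent.append(m)
            else:
                pieces.append(seq)
        if len(absent) == len(markers):
            warnings.warn(
                f"genome {genome!r} absent from all markers; excluded",
                stacklevel=2,
            )
            continue
        rows[genome] = "".join(pieces)
        missing[genome] = absent
    return ConcatAlignment(rows, partitions, missing)


# ---------------------------------------------------------------------------
# Built-in neighbour-joining backend


def _poisson_distance_matrix(alignment: Mapping[str, str]) -> tuple[np.ndarray, list[str]]:
    """Pairwise distances from identity with a 20-state Poisson correction.

    ``d = -(19/20) * ln(1 - 20/19 * p)`` is the equal-rates multiple-hit
    correction for amino acids; p is computed over columns where both
    sequences have residues and capped just below saturation (p = 19/20)
    so distances stay finite.
    """
    names = sorted(alignment)
    seqs = np.array([list(alignment[n]) for n in names])
    mats = (seqs != "-") & (seqs != ".")
    p_cap = 0.94
    n = len(names)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = mats[i] & mats[j]
            overlap = int(both.sum())
            if overlap == 0:
                p = p_cap
            else:
                diffs = int((seqs[i][both] != seqs[j][both]).sum())
                p = min(diffs / overlap, p_cap)
            dist = -(19.0 / 20.0) * math.log(1.0 - 20.0 / 19.0 * p)
            d[i, j] = d[j, i] = dist
    return d, names


def nj_tree(alignment: Mapping[str, str], seed: int = 0) -> dendropy.Tree:
    """Neighbour-joining tree from Poisson-corrected identity distances.

    Deterministic (the seed is accepted for backend-interface uniformity
    but unused).  Returns an unrooted dendropy tree.
    """
    if len(alignment) < 3:
        raise ValueError("need at least 3 sequences for NJ")
    d, names = _poisson_distance_matrix(alignment)
    dm = DistanceMatrix(d, ids=names)
    skb = nj(dm)
    tree = tree_from_string(str(skb))
    tree.is_rooted = False
    # NJ can emit tiny negative branch lengths; clamp for downstream use.
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            edge.length = 0.0
    return tree


def bootstrap_trees(
    concat: ConcatAlignment,
    n_boot: int,
    seed: int,
    tree_backend: TreeBackend = nj_tree,
) -> list[dendropy.Tree]:
    """Site-resampled bootstrap trees, resampling within each partition."""
    rng = np.random.default_rng(seed)
    names = sorted(concat.rows)
    mat = np.array([list(concat.rows[n]) for n in names])
    trees = []
    for _ in range(n_boot):
        cols = []
        for marker, (start, end) in sorted(concat.partitions.items()):
            cols.append(rng.integers(start, end, size=end - start))
        idx = np.concatenate(cols)
        resampled = {
            n: "".join(mat[i, idx]) for i, n in enumerate(names)
        }
        trees.append(tree_backend(resampled, int(rng.integers(0, 2 ** 31))))
    return trees


# ---------------------------------------------------------------------------
# Benchmarking


@dataclass
class MarkerSetResult:
    name: str
    markers: list[str]
    tc_values: list[float]  # relative TC per run
    tc_sums: list[float]
    best_index: int
    trees: list[str]  # newick per run
    backend: str
    n_boot: int
    error: str | None = None

    @property
    def best_tc(self) -> float:
        return self.tc_values[self.best_index]


def benchmark_marker_sets(
    candidate_sets: Mapping[str, Sequence[str]],
    per_marker_alignments: Mapping[str, Mapping[str, str]],
    tree_backend: TreeBackend = nj_tree,
    n_runs: int = 5,
    n_boot: int = 1000,
    seed: int = 0,
    genome_set: Sequence[str] | None = None,
) -> list[MarkerSetResult]:
    """Relative TC of each candidate marker set, best of ``n_runs`` runs.

    For each set the markers are concatenated, a reference tree is built
    per run together with an independently seeded bootstrap set, and the
    run with the highest relative TC is flagged — the multi-run protocol
    guards against run-to-run variability of the tree search.
    """
    backend_name = getattr(tree_backend, "__name__", repr(tree_backend))
    results = []
    for name in sorted(candidate_sets):
        markers = sorted(candidate_sets[name])
        try:
            concat = concatenate(per_marker_alignments, genome_set, markers)
            tc_rels, tc_sums, newicks = [], [], []
            for run in range(n_runs):
                run_seed = derive_seed(seed, f"benchmark:{name}:{run}")
                ref = tree_backend(concat.rows, run_seed)
                boots = bootstrap_trees(concat, n_boot, run_seed,
                                        tree_backend)
                report = tree_certainty(ref, boots)
                tc_rels.append(report.tc_rel)
                tc_sums.append(report.tc_sum)
                newicks.append(
                    ref.as_string(schema="newick",
                                  unquoted_underscores=True).strip()
                )
            best = int(np.argmax(tc_rels))
            results.append(
                MarkerSetResult(name, markers, tc_rels, tc_sums, best,
                                newicks, backend_name, n_boot)
            )
        except Exception as exc:  # record and continue with other sets
            results.append(
                MarkerSetResult(name, markers, [], [], 0, [], backend_name,
                                n_boot, error=str(exc))
            )
    return results


# ---------------------------------------------------------------------------
# Monophyly


def monophyly_check(
    tree: dendropy.Tree, leaf_labels: Mapping[str, str]
) -> dict[str, bool]:
    """Per-group monophyly on a rooted or unrooted tree.

    On a rooted tree a group is monophyletic iff the MRCA of its leaves
    subtends no other leaves; on an unrooted tree iff some edge separates
    the group exactly (which the same MRCA test detects on each of the
    tree's two root-adjacent orientations, so we test both sides).
    """
    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    unknown = set(leaf_labels) - leaves
    if unknown:
        raise KeyError(f"labels for unknown leaves: {sorted(unknown)}")
    unlabeled = leaves - set(leaf_labels)
    if unlabeled:
        raise KeyError(f"unlabeled leaves: {sorted(unlabeled)}")
    groups: dict[str, set[str]] = {}
    for leaf, grp in leaf_labels.items():
        groups.setdefault(grp, set()).add(leaf)

    # Collect the leaf set below every node once.
    clades: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        clades.add(below)

    universe = frozenset(leaves)
    out = {}
    for grp, members in groups.items():
        members = frozenset(members)
        if tree.is_rooted:
            out[grp] = members in clades
        else:
            out[grp] = members in clades or (universe - members) in clades
    return out
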