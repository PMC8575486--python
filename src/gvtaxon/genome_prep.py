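"""Genome dereplication, decontamination, and marker-completeness screening.

Dereplication follows the MinHash sketch procedure: bottom-``s`` sketches
of canonical k-mers (defaults k=16, s=300), Mash distance
``d = -(1/k) * ln(2j / (1+j))`` with ``j`` the Jaccard index estimated
from the merged bottom-``s`` sketch, single-linkage clustering at
``d <= 0.05``, and the highest-N50 member as each cluster's
representative.  Decontamination consumes an external per-contig score
table (contigs with negative scores are dropped, along with contigs of
10 kbp or less); completeness screening requires the PolB marker plus at
least 3 of A32, SFII, VLTF3 and MCP.

The k-mer hash is a keyed 64-bit hash (the hash seed is recorded on every
sketch); only the distance semantics of the cited MinHash method are
reproduced, not its exact hash values or binary sketch format.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

DEFAULT_K = 16
DEFAULT_SKETCH_SIZE = 300
DEFAULT_DEREP_THRESHOLD = 0.05
DEFAULT_MIN_CONTIG_LEN = 10000

SCREEN_MANDATORY = "PolB"
SCREEN_ACCESSORY = ("A32", "SFII", "VLTF3", "MCP")
SCREEN_MIN_ACCESSORY = 3

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


class EmptySketchError(ValueError):
    """No contig long enough to yield a single k-mer."""


@dataclass
class GenomeRecord:
    genome_id: str
    contigs: list[tuple[str, str]]  # (contig_id, sequence)
    source: str = "isolate"  # MAG | isolate
    external_contig_scores: dict[str, float] | None = None

    @property
    def n50(self) -> int:
        return compute_n50([len(s) for _, s in self.contigs])

    @property
    def length(self) -> int:
        return sum(len(s) for _, s in self.contigs)


@dataclass(frozen=True)
class Sketch:
    genome_id: str
    k: int
    s: int
    hashes: tuple[int, ...]  # strictly increasing, len <= s
    hash_seed: int = 0

    def as_dict(self) -> dict:
        return {
            "genome_id": self.genome_id,
            "k": self.k,
            "s": self.s,
            "hash_seed": self.hash_seed,
            "hashes": list(self.hashes),
        }


@dataclass(frozen=True)
class SketchDistance:
    id1: str
    id2: str
    j: float
    d: float
    k: int


def _canonical_kmers(seq: str, k: int) -> Iterable[str]:
    seq = seq.upper()
    rc = seq.translate(_COMPLEMENT)[::-1]
    n = len(seq)
    for i in range(n - k + 1):
        fwd = seq[i : i + k]
        rev = rc[n - k - i : n - i]
        yield fwd if fwd <= rev else rev


def _hash_kmer(kmer: str, hash_seed: int) -> int:
    h = hashlib.blake2b(
        kmer.encode(), digest_size=8, key=hash_seed.to_bytes(8, "big")
    )
    return int.from_bytes(h.digest(), "big")


def sketch_genome(
    genome: GenomeRecord,
    k: int = DEFAULT_K,
    s: int = DEFAULT_SKETCH_SIZE,
    hash_seed: int = 0,
) -> Sketch:
    """Bottom-``s`` MinHash sketch over the genome's canonical k-mers."""
    if k < 1:
        raise ValueError("k must be >= 1")
    hashes: set[int] = set()
    for _, seq in genome.contigs:
        if len(seq) < k:
            continue
        for kmer in _canonical_kmers(seq, k):
            hashes.add(_hash_kmer(kmer, hash_seed))
    if not hashes:
        raise EmptySketchError(
            f"genome {genome.genome_id!r}: no contig of length >= k={k}"
        )
    bottom = tuple(sorted(hashes)[:s])
    return Sketch(genome.genome_id, k, s, bottom, hash_seed)


def mash_distance(a: Sketch, b: Sketch, cap: float = 1.0) -> SketchDistance:
    """Mash distance between two sketches via the merged bottom-s estimator.

    The Jaccard index is estimated as the fraction of the ``s`` smallest
    hashes of the union that occur in both sketches.  ``j == 0`` maps to
    the finite ``cap`` value instead of infinity.
    """
    if a.k != b.k:
        raise ValueError(f"k-mer sizes differ: {a.k} vs {b.k}")
    s = min(a.s, b.s)
    ha, hb = set(a.hashes), set(b.hashes)
    merged = sorted(ha | hb)[:s]
    shared = sum(1 for h in merged if h in ha and h in hb)
    j = shared / len(merged) if merged else 0.0
    if j <= 0.0:
        d = cap
    elif j >= 1.0:
        d = 0.0
    else:
        d = min(cap, -(1.0 / a.k) * math.log(2.0 * j / (1.0 + j)))
    return SketchDistance(a.genome_id, b.genome_id, j, d, a.k)


def pairwise_distances(sketches: Sequence[Sketch], cap: float = 1.0) -> list[SketchDistance]:
    out = []
    for i in range(len(sketches)):
        for jx in range(i + 1, len(sketches)):
            out.append(mash_distance(sketches[i], sketches[jx], cap=cap))
    return out


def distances_to_frame(distances: Iterable[SketchDistance]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"id1": d.id1, "id2": d.id2, "j": d.j, "d": d.d} for d in distances]
    )


def compute_n50(lengths: Sequence[int]) -> int:
    """Smallest length L with contigs >= L summing to at least half the total."""
    if not lengths:
        raise ValueError("empty length list")
    if any(l <= 0 for l in lengths):
        raise ValueError("contig lengths must be positive")
    total = sum(lengths)
    acc = 0
    for l in sorted(lengths, reverse=True):
        acc += l
        if 2 * acc >= total:
            return l
    raise AssertionError("unreachable")


def single_linkage_clusters(
    distances: Iterable[SketchDistance],
    threshold: float = DEFAULT_DEREP_THRESHOLD,
    genome_ids: Iterable[str] | None = None,
) -> list[list[str]]:
    """Connected components of the graph linking pairs with ``d <= threshold``.

    ``genome_ids`` may add isolated genomes that appear in no distance pair.
    Clusters and their members are sorted for determinism.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    g = nx.Graph()
    for d in distances:
        g.add_node(d.id1)
        g.add_node(d.id2)
        if d.d <= threshold:
            g.add_edge(d.id1, d.id2)
    if genome_ids is not None:
        g.add_nodes_from(genome_ids)
    clusters = [sorted(c) for c in nx.connected_components(g)]
    return sorted(clusters)


def pick_representative(
    cluster: Sequence[str], records: Mapping[str, GenomeRecord]
) -> str:
    """Highest-N50 member; ties broken lexicographically by genome id."""
    if not cluster:
        raise ValueError("empty cluster")
    missing = [g for g in cluster if g not in records]
    if missing:
        raise KeyError(f"unknown genome ids: {missing}")
    return min(cluster, key=lambda g: (-records[g].n50, g))


def dereplicate(
    records: Mapping[str, GenomeRecord],
    k: int = DEFAULT_K,
    s: int = DEFAULT_SKETCH_SIZE,
    threshold: float = DEFAULT_DEREP_THRESHOLD,
    hash_seed: int = 0,
) -> tuple[list[list[str]], list[str], list[SketchDistance]]:
    """Sketch, cluster, and pick representatives for a genome set."""
    sketches = [sketch_genome(records[g], k=k, s=s, hash_seed=hash_seed)
                for g in sorted(records)]
    dists = pairwise_distances(sketches)
    clusters = single_linkage_clusters(dists, threshold, genome_ids=records.keys())
    reps = sorted(pick_representative(c, records) for c in clusters)
    return clusters, reps, dists


def filter_contigs(
    genome: GenomeRecord, min_len: int = DEFAULT_MIN_CONTIG_LEN
) -> GenomeRecord:
    """Drop contigs of ``min_len`` bp or less and contigs with negative scores.

    Scores come from an external per-contig table (their computation is an
    upstream tool's concern); contigs absent from the table are retained,
    and "negative" is strict — a score of exactly 0 passes.
    """
    scores = genome.external_contig_scores or {}
    kept = []
    for cid, seq in genome.contigs:
        if len(seq) <= min_len:
            continue
        if cid in scores and scores[cid] < 0:
            continue
        kept.append((cid, seq))
    return GenomeRecord(genome.genome_id, kept, genome.source,
                        genome.external_contig_scores)


def screen_marker_completeness(hits: pd.DataFrame) -> list[str]:
    """Genomes with PolB plus at least 3 of A32, SFII, VLTF3, MCP.

    ``hits`` is a per-genome presence table with a ``genome_id`` column and
    one boolean (or 0/1) column per marker.
    """
    needed = [SCREEN_MANDATORY, *SCREEN_ACCESSORY]
    missing = [m for m in needed if m not in hits.columns]
    if missing:
        raise KeyError(f"hit table lacks marker columns: {missing}")
    retained = []
    for _, row in hits.iterrows():
        if not bool(row[SCREEN_MANDATORY]):
            continue
        if sum(bool(row[m]) for m in SCREEN_ACCESSORY) >= SCREEN_MIN_ACCESSORY:
            retained.append(row["genome_id"])
    return sorted(retained)
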