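"""GVOG-style protein families: orthogroup inference, merging, annotation.

The pipeline mirrors how giant-virus orthologous groups are built: remove
proteins truncated at contig edges, cluster the remainder into orthogroups
by reciprocal near-best-hit similarity (e-value <= 1e-5, identity >= 25%,
mutual coverage >= 50%, similarity factor 0.80), build one profile per
group from its trimmed alignment, cross-search every group's proteins
against every other group's profile (hits kept at the configured e-value
and only if >= 30% of the query aligned), and merge groups reciprocally
linked through more than half of their members.  Annotation transfers a
reference-family label to a group when strictly more than half of its
members hit the same reference family.

Orthogroup inference approximates the reciprocal-best-hit graph +
connected-components strategy of standard orthology tools (no spectral
partitioning); the all-vs-all search backend is pluggable and defaults to
Biopython's Gotoh local aligner with BLOSUM62 scoring.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from Bio import Align

from .profiles import Profile, ProfileHit, build_profile, search_profile

# Gapped BLOSUM62 Karlin-Altschul parameters (BLAST defaults) used to turn
# raw Gotoh scores into bit scores for thresholding.
_KA_LAMBDA = 0.267
_KA_K = 0.041

DEFAULT_EVALUE = 1e-5
DEFAULT_MIN_IDENTITY = 25.0
DEFAULT_MIN_COVERAGE = 50.0
DEFAULT_SIM_FACTOR = 0.80
DEFAULT_MERGE_EVALUE = 1e-20
DEFAULT_MERGE_QAF = 0.30
DEFAULT_MERGE_FRACTION = 0.5


@dataclass
class ProteinRecord:
    protein_id: str
    genome_id: str
    sequence: str
    contig_id: str = ""
    start: int = 0  # 0-based half-open on the contig
    end: int = 0
    has_start_codon: bool = True
    has_stop_codon: bool = True
    at_contig_edge: bool = False

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"{self.protein_id}: empty sequence")
        if self.end and not self.start < self.end:
            raise ValueError(f"{self.protein_id}: start must be < end")


@dataclass
class OrthoGroup:
    og_id: str
    protein_ids: list[str]

    def genome_counts(self, proteins: Mapping[str, ProteinRecord]) -> dict[str, int]:
        counts: dict[str, int] = {}
        for pid in self.protein_ids:
            g = proteins[pid].genome_id
            counts[g] = counts.get(g, 0) + 1
        return counts


def remove_edge_fragments(proteins: Iterable[ProteinRecord]) -> list[ProteinRecord]:
    """Drop proteins at contig edges that lack a start or a stop codon.

    Interior proteins are kept regardless of their codon flags: the filter
    targets genes truncated by the end of a contig, which would otherwise
    contaminate orthogroup inference with fragments.
    """
    return [
        p
        for p in proteins
        if not (p.at_contig_edge and not (p.has_start_codon and p.has_stop_codon))
    ]


# ---------------------------------------------------------------------------
# All-vs-all pairwise search


@dataclass
class PairHit:
    query: str
    target: str
    bitscore: float
    evalue: float
    identity: float  # percent
    query_coverage: float  # percent
    target_coverage: float  # percent


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner(scoring="blastp")
    aligner.mode = "local"
    return aligner


def _pair_stats(aligner, qa: str, ta: str) -> tuple[float, float, float, float]:
    """Score, %identity and mutual coverage of the best local alignment."""
    alns = aligner.align(qa, ta)
    if len(alns) == 0:
        return 0.0, 0.0, 0.0, 0.0
    aln = alns[0]
    score = float(aln.score)
    matches = 0
    aligned = 0
    qcov_res = 0
    tcov_res = 0
    for (qs, qe), (ts, te) in zip(*aln.aligned):
        block = qe - qs
        aligned += block
        qcov_res += block
        tcov_res += te - ts
        for i in range(block):
            if qa[qs + i] == ta[ts + i]:
                matches += 1
    ident = 100.0 * matches / aligned if aligned else 0.0
    qcov = 100.0 * qcov_res / len(qa)
    tcov = 100.0 * tcov_res / len(ta)
    return score, ident, qcov, tcov


def _bitscore(raw: float) -> float:
    return (_KA_LAMBDA * raw - math.log(_KA_K)) / math.log(2.0)


def _evalue(bits: float, m: int, n: int) -> float:
    return m * n * 2.0 ** (-bits)


def all_vs_all_hits(
    proteins: Sequence[ProteinRecord],
    search_backend: Callable[[str, str], tuple[float, float, float, float]] | None = None,
) -> list[PairHit]:
    """Pairwise local-alignment hits between all protein pairs.

    ``search_backend(seq_a, seq_b)`` must return (raw score, %identity,
    %query coverage, %target coverage); the default is a BLOSUM62 Gotoh
    local aligner.  Self-hits are included (needed for the similarity
    factor of the reciprocal near-best-hit rule).
    """
    if not proteins:
        raise ValueError("empty protein set")
    if search_backend is None:
        aligner = _make_aligner()
        search_backend = lambda a, b: _pair_stats(aligner, a, b)
    total_len = sum(len(p.sequence) for p in proteins)
    hits: list[PairHit] = []
    for i, p in enumerate(proteins):
        for q in proteins[i:]:
            raw, ident, qcov, tcov = search_backend(p.sequence, q.sequence)
            bits = _bitscore(raw)
            ev = _evalue(bits, len(p.sequence), total_len)
            hits.append(PairHit(p.protein_id, q.protein_id, bits, ev, ident, qcov, tcov))
            if p.protein_id != q.protein_id:
                hits.append(
                    PairHit(q.protein_id, p.protein_id, bits, ev, ident, tcov, qcov)
                )
    return hits


def infer_orthogroups(
    proteins: Sequence[ProteinRecord],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    evalue_cutoff: float = DEFAULT_EVALUE,
    sim_factor: float = DEFAULT_SIM_FACTOR,
    hits: Sequence[PairHit] | None = None,
    search_backend=None,
) -> list[OrthoGroup]:
    """Orthogroups as connected components of the reciprocal near-best-hit graph.

    An edge joins two proteins of different genomes when their hit passes
    the e-value/identity/mutual-coverage thresholds in both directions and
    each direction scores within ``sim_factor`` of the query's best hit
    into the target's genome.  Proteins of the same genome join a group
    only through shared neighbours (co-orthologs), mirroring standard
    orthology-graph practice.
    """
    if not proteins:
        raise ValueError("empty protein set")
    by_id = {p.protein_id: p for p in proteins}
    if hits is None:
        hits = all_vs_all_hits(proteins, search_backend)

    # Best bit score from each query into each target genome.
    best: dict[tuple[str, str], float] = {}
    kept: dict[tuple[str, str], PairHit] = {}
    for h in hits:
        if h.query == h.target:
            continue
        if (h.evalue > evalue_cutoff or h.identity < min_identity
                or h.query_coverage < min_coverage
                or h.target_coverage < min_coverage):
            continue
        tg = by_id[h.target].genome_id
        key = (h.query, tg)
        if h.bitscore > best.get(key, -math.inf):
            best[key] = h.bitscore
        kept[(h.query, h.target)] = h

    g = nx.Graph()
    g.add_nodes_from(by_id)
    for (q, t), h in kept.items():
        if q >= t:
            continue
        back = kept.get((t, q))
        if back is None:
            continue
        qg = by_id[q].genome_id
        tg = by_id[t].genome_id
        if qg == tg:
            continue
        if (h.bitscore >= sim_factor * best[(q, tg)]
                and back.bitscore >= sim_factor * best[(t, qg)]):
            g.add_edge(q, t)

    comps = sorted(sorted(c) for c in nx.connected_components(g))
    return [
        OrthoGroup(f"OG{i:04d}", members) for i, members in enumerate(comps, start=1)
    ]


# ---------------------------------------------------------------------------
# Cross-search and merging


def cross_search(
    ogs: Sequence[OrthoGroup],
    profiles: Mapping[str, Profile],
    proteins: Mapping[str, ProteinRecord],
    evalue_cutoff: float = DEFAULT_MERGE_EVALUE,
    min_qaf: float = DEFAULT_MERGE_QAF,
) -> dict[tuple[str, str], set[str]]:
    """Proteins of each group with retained hits to every other group's profile.

    Returns ``{(og_id, other_og_id): {protein ids with retained hits}}``;
    a hit is retained when its e-value passes the cutoff and at least
    ``min_qaf`` of the query aligned to the profile.
    """
    out: dict[tuple[str, str], set[str]] = {}
    for og in ogs:
        for other in ogs:
            if other.og_id == og.og_id:
                continue
            prof = profiles[other.og_id]
            found = set()
            for pid in og.protein_ids:
                hit = search_profile(pid, proteins[pid].sequence, prof)
                if hit.evalue <= evalue_cutoff and hit.query_aligned_fraction >= min_qaf:
                    found.add(pid)
            out[(og.og_id, other.og_id)] = found
    return out


def merge_orthogroups(
    ogs: Sequence[OrthoGroup],
    cross_hits: Mapping[tuple[str, str], set[str]],
    merge_fraction: float = DEFAULT_MERGE_FRACTION,
) -> list[OrthoGroup]:
    """Merge groups reciprocally linked through > ``merge_fraction`` of members.

    An undirected edge joins groups A and B iff strictly more than the
    merge fraction of A's proteins hit B's profile AND vice versa; merged
    groups are the connected components (a single pass — merging is not
    iterated to a fixpoint).  Membership is conserved: every protein of
    the input appears in exactly one output group.
    """
    g = nx.Graph()
    sizes = {og.og_id: len(og.protein_ids) for og in ogs}
    members = {og.og_id: og.protein_ids for og in ogs}
    g.add_nodes_from(sizes)
    ids = sorted(sizes)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            fa = len(cross_hits.get((a, b), ())) / sizes[a]
            fb = len(cross_hits.get((b, a), ())) / sizes[b]
            if fa > merge_fraction and fb > merge_fraction:
                g.add_edge(a, b)
    merged = []
    for comp in sorted(sorted(c) for c in nx.connected_components(g)):
        pooled = sorted(pid for og_id in comp for pid in members[og_id])
        merged.append((comp[0], pooled))
    return [
        OrthoGroup(f"GVOG{i:04d}", pooled)
        for i, (_, pooled) in enumerate(sorted(merged), start=1)
    ]


def annotate_gvog(
    gvog: OrthoGroup,
    reference_hits: Mapping[str, str],
    consensus_fraction: float = 0.5,
) -> str | None:
    """Reference-family label if > half the members hit the same family.

    ``reference_hits`` maps protein id -> reference family (proteins with
    no hit are simply absent).  Strict majority of ALL members, not just
    those with hits.
    """
    votes: dict[str, int] = {}
    for pid in gvog.protein_ids:
        fam = reference_hits.get(pid)
        if fam is not None:
            votes[fam] = votes.get(fam, 0) + 1
    n = len(gvog.protein_ids)
    for fam in sorted(votes):
        if votes[fam] / n > consensus_fraction:
            return fam
    return None


def prevalence(
    gvog_hits: Mapping[str, set[str]],
    genomes: Sequence[str],
    threshold: float = 0.70,
) -> tuple[dict[str, float], list[str]]:
    """Per-GVOG fraction of genomes with >= 1 hit, and the > threshold list.

    ``gvog_hits`` maps gvog id -> set of genome ids with at least one
    retained hit.  The candidate-marker rule is strict: a prevalence of
    exactly the threshold does not qualify.
    """
    if not genomes:
        raise ValueError("empty genome set")
    n = len(set(genomes))
    fracs = {g: len(set(hits)) / n for g, hits in gvog_hits.items()}
    candidates = sorted(g for g, f in fracs.items() if f > threshold)
    return fracs, candidates


def functional_profile(
    genome_families: Mapping[str, str],
    protein_genomes: Mapping[str, str],
    protein_hits: Mapping[str, str],
    gvog_categories: Mapping[str, str],
) -> pd.DataFrame:
    """Family x category matrix: percent of each family's proteins per category.

    ``protein_genomes`` maps every protein (assigned or not) to its genome;
    the denominator for a family is the total protein count over that
    family's genomes, so percentages are comparable across families.
    """
    fam_total: dict[str, int] = {}
    fam_cat: dict[tuple[str, str], int] = {}
    for pid, genome in protein_genomes.items():
        fam = genome_families.get(genome)
        if fam is None:
            continue
        fam_total[fam] = fam_total.get(fam, 0) + 1
        gvog = protein_hits.get(pid)
        cat = gvog_categories.get(gvog) if gvog is not None else None
        if cat is not None:
            fam_cat[(fam, cat)] = fam_cat.get((fam, cat), 0) + 1
    empties = [f for f in set(genome_families.values()) if fam_total.get(f, 0) == 0]
    if empties:
        raise ValueError(f"families with zero proteins: {sorted(empties)}")
    families = sorted(fam_total)
    categories = sorted({c for (_, c) in fam_cat})
    data = {
        c: [100.0 * fam_cat.get((f, c), 0) / fam_total[f] for f in families]
        for c in categories
    }
    return pd.DataFrame(data, index=families)
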