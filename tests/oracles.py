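"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own data structures and algorithms:
tree topologies are enumerated by leaf insertion into explicit edge lists,
splits are collected by graph search, and split compatibility is decided
by exhaustive coexistence (does any enumerated topology contain both?).
"""

from __future__ import annotations

import itertools
import math
from functools import lru_cache


def enumerate_topology_splits(leaves: tuple[str, ...]) -> list[frozenset[frozenset[str]]]:
    """Split sets of every unrooted binary topology on the given leaves.

    Each topology is represented purely by its set of nontrivial splits,
    each split canonicalized as the side not containing the first leaf.
    """
    leaves = tuple(leaves)
    first = leaves[0]

    def canonical(side: frozenset[str], universe: frozenset[str]) -> frozenset[str]:
        return universe - side if first in side else side

    def splits_of(edges: list[tuple], universe: frozenset[str]) -> frozenset:
        adj: dict = {}
        for u, v in edges:
            adj.setdefault(u, []).append(v)
            adj.setdefault(v, []).append(u)
        out = set()
        for u, v in edges:
            # leaves on v's side when edge (u, v) is removed
            seen = {u, v}
            stack = [v]
            side = set()
            while stack:
                node = stack.pop()
                if isinstance(node, str):
                    side.add(node)
                for nb in adj[node]:
                    if nb not in seen:
                        seen.add(nb)
                        stack.append(nb)
            if 2 <= len(side) <= len(universe) - 2:
                out.add(canonical(frozenset(side), universe))
        return frozenset(out)

    universe = frozenset(leaves)
    trees: list[list[tuple]] = [[(0, leaves[0]), (0, leaves[1]), (0, leaves[2])]]
    next_internal = 1
    for leaf in leaves[3:]:
        new_trees = []
        for edges in trees:
            for i, (u, v) in enumerate(edges):
                w = next_internal
                new_edges = edges[:i] + edges[i + 1:] + [(u, w), (w, v), (w, leaf)]
                new_trees.append(new_edges)
        next_internal += 1
        trees = new_trees
    return [splits_of(edges, universe) for edges in trees]


def splits_coexist(
    s1: frozenset[str], s2: frozenset[str], leaves: tuple[str, ...],
    all_split_sets: list[frozenset] | None = None,
) -> bool:
    """True iff some unrooted binary topology contains both splits."""
    if all_split_sets is None:
        all_split_sets = enumerate_topology_splits(leaves)
    return any(s1 in ss and s2 in ss for ss in all_split_sets)


def brute_force_tc(
    ref_splits: frozenset,
    boot_split_sets: list[frozenset],
    leaves: tuple[str, ...],
    all_split_sets: list[frozenset],
) -> float:
    """TC sum by exhaustive bipartition-pair enumeration.

    For every reference split: p1 = its frequency across the bootstrap
    split sets; p2 = the max frequency of any observed split that cannot
    coexist with it (coexistence decided by topology enumeration).
    """
    n_boot = len(boot_split_sets)
    freq: dict[frozenset[str], int] = {}
    for ss in boot_split_sets:
        for s in ss:
            freq[s] = freq.get(s, 0) + 1
    tc = 0.0
    for ref in ref_splits:
        p1 = freq.get(ref, 0) / n_boot
        p2 = 0.0
        for other, c in freq.items():
            if other == ref:
                continue
            if not splits_coexist(ref, other, leaves, all_split_sets):
                p2 = max(p2, c / n_boot)
        if p1 == 0.0 and p2 == 0.0:
            continue
        tot = p1 + p2
        q1, q2 = p1 / tot, p2 / tot
        ic = 1.0
        for q in (q1, q2):
            if q > 0:
                ic += q * math.log2(q)
        if p2 > p1:
            ic = -ic
        tc += ic
    return tc


def brute_force_n50(lengths: list[int]) -> int:
    """Descending cumulative-sum N50."""
    total = sum(lengths)
    acc = 0
    for l in sorted(lengths, reverse=True):
        acc += l
        if acc >= total / 2:
            return l
    raise AssertionError


def exact_jaccard_kmers(seq_a: str, seq_b: str, k: int) -> float:
    """Brute-force Jaccard index of canonical k-mer sets."""
    comp = str.maketrans("ACGT", "TGCA")

    def kmers(s: str) -> set[str]:
        rc = s.translate(comp)[::-1]
        out = set()
        for i in range(len(s) - k + 1):
            f = s[i:i + k]
            r = rc[len(s) - k - i: len(s) - i]
            out.add(min(f, r))
        return out

    ka, kb = kmers(seq_a), kmers(seq_b)
    return len(ka & kb) / len(ka | kb)


def brute_force_components(n: int, edges: list[tuple[int, int]]) -> list[list[int]]:
    """Connected components by plain depth-first search."""
    adj = {i: [] for i in range(n)}
    for u, v in edges:
        adj[u].append(v)
        adj[v].append(u)
    seen: set[int] = set()
    comps = []
    for start in range(n):
        if start in seen:
            continue
        stack = [start]
        comp = []
        seen.add(start)
        while stack:
            u = stack.pop()
            comp.append(u)
            for v in adj[u]:
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        comps.append(sorted(comp))
    return sorted(comps)


def enumerate_topology_newicks(leaves: tuple[str, ...]) -> list[tuple[str, frozenset]]:
    """(newick, split set) for every unrooted binary topology on the leaves."""
    leaves = tuple(leaves)
    first = leaves[0]

    def canonical(side, universe):
        return universe - side if first in side else frozenset(side)

    universe = frozenset(leaves)
    trees = [[(0, leaves[0]), (0, leaves[1]), (0, leaves[2])]]
    next_internal = 1
    for leaf in leaves[3:]:
        new_trees = []
        for edges in trees:
            for i, (u, v) in enumerate(edges):
                w = next_internal
                new_trees.append(edges[:i] + edges[i + 1:]
                                 + [(u, w), (w, v), (w, leaf)])
        next_internal += 1
        trees = new_trees

    out = []
    for edges in trees:
        adj: dict = {}
        for u, v in edges:
            adj.setdefault(u, []).append(v)
            adj.setdefault(v, []).append(u)

        def newick_of(node, parent):
            if isinstance(node, str):
                return node
            parts = [newick_of(nb, node) for nb in adj[node] if nb != parent]
            return "(" + ",".join(parts) + ")"

        nwk = newick_of(0, None) + ";"

        splits = set()
        for u, v in edges:
            seen = {u, v}
            stack = [v]
            side = set()
            while stack:
                n = stack.pop()
                if isinstance(n, str):
                    side.add(n)
                for nb in adj[n]:
                    if nb not in seen:
                        seen.add(nb)
                        stack.append(nb)
            if 2 <= len(side) <= len(universe) - 2:
                splits.add(canonical(frozenset(side), universe))
        out.append((nwk, frozenset(splits)))
    return out
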