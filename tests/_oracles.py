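"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package: a quadratic-space Gotoh
dynamic program for global affine-gap alignment scores, exhaustive set
partition enumeration with a self-contained weighted-modularity formula, and
a direct edge-count implementation of the membership score.
"""

from __future__ import annotations

import itertools
from typing import Iterable, Iterator, Sequence

from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")

NEG = float("-inf")


def affine_dp_score(a: str, b: str, open_cost: float = -11.0,
                    extend_cost: float = -1.0) -> float:
    """Global alignment score, affine gaps where a length-k gap costs
    ``open + (k-1)*extend``; terminal gaps penalized."""
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (a residue unmatched)
    Iy = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a
    M[0][0] = 0.0
    for i in range(1, n + 1):
        Ix[i][0] = open_cost + (i - 1) * extend_cost
    for j in range(1, m + 1):
        Iy[0][j] = open_cost + (j - 1) * extend_cost
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _B62[a[i - 1], b[j - 1]]
            best_prev = max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1])
            M[i][j] = best_prev + s
            Ix[i][j] = max(M[i - 1][j] + open_cost,
                           Ix[i - 1][j] + extend_cost,
                           Iy[i - 1][j] + open_cost)
            Iy[i][j] = max(M[i][j - 1] + open_cost,
                           Iy[i][j - 1] + extend_cost,
                           Ix[i][j - 1] + open_cost)
    return max(M[n][m], Ix[n][m], Iy[n][m])


def set_partitions(items: Sequence) -> Iterator[list[list]]:
    """All partitions of a finite set (Bell-number many)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def weighted_modularity(edges: Iterable[tuple, ], partition: Sequence[Iterable]) -> float:
    """Newman-Girvan modularity of a partition for an undirected weighted
    edge list ``(u, v, w)``."""
    edges = list(edges)
    two_m = sum(2.0 * w for _, _, w in edges)
    if two_m == 0:
        return 0.0
    comm = {}
    for ci, c in enumerate(partition):
        for node in c:
            comm[node] = ci
    internal = [0.0] * len(partition)
    degree = [0.0] * len(partition)
    for u, v, w in edges:
        degree[comm[u]] += w
        degree[comm[v]] += w
        if comm[u] == comm[v]:
            internal[comm[u]] += w
    return sum(2.0 * internal[c] / two_m - (degree[c] / two_m) ** 2
               for c in range(len(partition)))


def best_partition_exhaustive(nodes: Sequence, edges: Iterable[tuple]) -> tuple[float, list]:
    """Modularity-maximal partition by exhaustive enumeration."""
    edges = list(edges)
    best_q, best_p = NEG, None
    for p in set_partitions(nodes):
        q = weighted_modularity(edges, p)
        if q > best_q + 1e-12:
            best_q, best_p = q, p
    return best_q, best_p


def membership_score_oracle(node, community: set, directed_edges: set,
                            tot_genes_in_og: int) -> float:
    """MS recomputed straight from the directed edge set."""
    others = [u for u in community if u != node]
    in_deg = sum(1 for u in others if (u, node) in directed_edges)
    out_deg = sum(1 for v in others if (node, v) in directed_edges)
    recip = sum(1 for v in others
                if (node, v) in directed_edges and (v, node) in directed_edges)
    species = node[0]
    tot_exons = len(community)
    species_exons = sum(1 for u in community if u[0] == species)
    species_genes = len({u[1] for u in community if u[0] == species})
    denom = 2 * (tot_exons - species_exons) + (tot_genes_in_og - species_genes)
    if denom <= 0:
        return 0.0
    return (in_deg + out_deg + recip) / denom
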