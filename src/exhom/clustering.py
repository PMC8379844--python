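"""Multi-species exon orthogroups by edge-betweenness community detection.

Within each gene orthogroup, cross-species exon orthopairs form a directed
graph (two antiparallel edges for a reciprocal pair).  For community
detection the directed multigraph is collapsed to an undirected weighted
graph - weight 1 or 2 encoding reciprocity - and Girvan-Newman edge removal
(most-central edge first, betweenness computed with distance = 1/weight)
builds a dendrogram; the partition with the highest weighted Newman-Girvan
modularity along that dendrogram is the returned set of communities.  Ties
prefer fewer communities, then the lexicographically smallest partition.

Each exon's Membership Score (MS) normalizes its connectivity inside its
community:

    MS = (IN_degree + OUT_degree + N_reciprocals)
         / (2*(TOT_exons_in_OG - SPECIES_exons_in_OG)
            + (TOT_genes_in_OG - SPECIES_genes_in_exOG))

where TOT_genes_in_OG counts genes of the *gene* orthogroup and
SPECIES_genes_in_exOG counts same-species genes contributing exons to the
exon orthogroup.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Iterable, Optional, Sequence

import networkx as nx
from networkx.algorithms.community import modularity

from .scoring import Orthopair

#: graph node: (species, gene_id, exon_id)
Node = tuple[str, str, str]


def build_exon_graph(orthopairs: Iterable[Orthopair]) -> nx.DiGraph:
    """Directed exon graph for one gene orthogroup.

    Only passing orthopairs contribute edges; edges never connect exons of
    the same species and self-loops are impossible by construction."""
    g = nx.DiGraph()
    for r in orthopairs:
        if r.status != "orthopair":
            continue
        if r.query_species == r.target_species:
            raise ValueError("orthopairs must be cross-species")
        u: Node = (r.query_species, r.query_gene, r.query_exon)
        v: Node = (r.target_species, r.target_gene, r.target_exon)
        g.add_edge(u, v, source=r.source)
    return g


def _undirected_weighted(g: nx.DiGraph) -> nx.Graph:
    u = nx.Graph()
    u.add_nodes_from(g.nodes)
    for a, b in g.edges:
        if u.has_edge(a, b):
            u[a][b]["weight"] = 2.0
        else:
            u.add_edge(a, b, weight=1.0)
    # betweenness treats stronger links as shorter paths
    for a, b, d in u.edges(data=True):
        d["distance"] = 1.0 / d["weight"]
    return u


def _partition_key(partition: Sequence[set]) -> list:
    return sorted(tuple(sorted(c)) for c in partition)


def girvan_newman_partition(u: nx.Graph) -> list[set]:
    """Best-modularity cut of the Girvan-Newman dendrogram (weighted)."""
    if u.number_of_edges() == 0:
        return [{n} for n in u.nodes]
    partitions = [[set(c) for c in nx.connected_components(u)]]
    work = u.copy()
    while work.number_of_edges():
        bt = nx.edge_betweenness_centrality(work, weight="distance")
        edge = max(sorted(bt), key=lambda e: bt[e])
        work.remove_edge(*edge)
        comps = [set(c) for c in nx.connected_components(work)]
        if len(comps) > len(partitions[-1]):
            partitions.append(comps)
    scored = [(modularity(u, p, weight="weight"), -len(p), p) for p in partitions]
    best_q, best_neg_len, _ = max(scored, key=lambda t: (t[0], t[1]))
    tied = [p for q, nl, p in scored
            if abs(q - best_q) < 1e-12 and nl == best_neg_len]
    return min(tied, key=_partition_key)


@dataclass
class ExonOrthogroup:
    og_id: str
    gene_orthogroup_id: str
    members: list[dict] = field(default_factory=list)  # species, gene_id, exon_id, membership_score

    def species_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for m in self.members:
            counts[m["species"]] = counts.get(m["species"], 0) + 1
        return counts


def membership_score(node: Node, community: set, graph: nx.DiGraph,
                     tot_genes_in_og: int) -> float:
    """MS of one exon within its community (0, flagged implicitly, when the
    denominator degenerates to zero)."""
    others = community - {node}
    in_deg = sum(1 for u in others if graph.has_edge(u, node))
    out_deg = sum(1 for v in others if graph.has_edge(node, v))
    recip = sum(1 for v in others
                if graph.has_edge(node, v) and graph.has_edge(v, node))
    species = node[0]
    tot_exons = len(community)
    species_exons = sum(1 for n in community if n[0] == species)
    species_genes = len({n[1] for n in community if n[0] == species})
    denom = 2 * (tot_exons - species_exons) + (tot_genes_in_og - species_genes)
    if denom <= 0:
        return 0.0
    return (in_deg + out_deg + recip) / denom


def cluster_exons(graph: nx.DiGraph, gene_orthogroup_id: str,
                  tot_genes_in_og: int) -> list[ExonOrthogroup]:
    """Split one gene orthogroup's exon graph into exon orthogroups and score
    every member.  Orthogroup ids are ordinals by smallest member exon id."""
    undirected = _undirected_weighted(graph)
    partition = girvan_newman_partition(undirected)
    partition = sorted(partition, key=lambda c: min(n[2] for n in c))
    out = []
    for ordinal, community in enumerate(partition, start=1):
        og = ExonOrthogroup(og_id=f"{gene_orthogroup_id}.{ordinal}",
                            gene_orthogroup_id=gene_orthogroup_id)
        for node in sorted(community):
            og.members.append({
                "species": node[0], "gene_id": node[1], "exon_id": node[2],
                "membership_score": membership_score(node, community, graph,
                                                     tot_genes_in_og)})
        out.append(og)
    return out


def species_pattern(og: ExonOrthogroup, species_list: Sequence[str]) -> str:
    counts = og.species_counts()
    return ":".join(str(counts.get(sp, 0)) for sp in species_list)


def orthogroup_stats(orthogroups: Sequence[ExonOrthogroup], species_list: Sequence[str]):
    """Species-pattern tally over orthogroups (for example ``1:1:1`` exon
    triplets, or groups with a missing species)."""
    import pandas as pd

    rows = []
    for og in orthogroups:
        counts = og.species_counts()
        missing = [sp for sp in species_list if counts.get(sp, 0) == 0]
        rows.append({
            "og_id": og.og_id,
            "gene_og_id": og.gene_orthogroup_id,
            "pattern": species_pattern(og, species_list),
            "n_exons": len(og.members),
            "n_species": len([sp for sp in species_list if counts.get(sp, 0)]),
            "missing_species": ",".join(missing),
        })
    table = pd.DataFrame(rows, columns=["og_id", "gene_og_id", "pattern",
                                        "n_exons", "n_species", "missing_species"])
    tally = (table.groupby("pattern").size().rename("n_orthogroups").reset_index()
             if len(table) else pd.DataFrame(columns=["pattern", "n_orthogroups"]))
    if len(tally):
        tally["fraction"] = tally["n_orthogroups"] / tally["n_orthogroups"].sum()
    return table, tally


def two_species_restriction(orthopairs: Sequence[Orthopair],
                            gene_orthopairs: Iterable[tuple[str, str]],
                            gene_orthogroup_of: dict[str, str],
                            genes_per_orthogroup: dict[str, int]) -> tuple[list[ExonOrthogroup], list[str]]:
    """Re-cluster on the subgraph induced by user-supplied two-species gene
    pairs only.  Unknown genes are skipped with a warning."""
    warnings = []
    allowed: set[frozenset] = set()
    for g1, g2 in gene_orthopairs:
        if g1 not in gene_orthogroup_of or g2 not in gene_orthogroup_of:
            warnings.append(f"gene pair {g1}/{g2} references unknown genes; skipped")
            continue
        allowed.add(frozenset((g1, g2)))
    keep = [r for r in orthopairs
            if frozenset((r.query_gene, r.target_gene)) in allowed and r.status == "orthopair"]
    by_og: dict[str, list[Orthopair]] = {}
    for r in keep:
        og = gene_orthogroup_of[r.query_gene]
        by_og.setdefault(og, []).append(r)
    out: list[ExonOrthogroup] = []
    for og_id in sorted(by_og):
        graph = build_exon_graph(by_og[og_id])
        out.extend(cluster_exons(graph, og_id, genes_per_orthogroup.get(og_id, 0)))
    return out, warnings
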