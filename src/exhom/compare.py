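"""Cross-species comparison of regulated exon sets.

Given two species' sets of regulated exons (for example exons responding to
depletion of one splicing factor in each species) plus the outputs of a main
homology run, this module reports:

* gene-level conservation - how many regulated exons sit in genes with
  orthologs in the other species, and how many of those orthologs also
  harbor regulated exons;
* exon-level conservation - Genome conservation (G): the exon has an exon
  ortholog in the other species; Regulation conservation (R): that ortholog
  is itself regulated;
* a pairwise classification of regulated exon pairs inside shared-regulated
  gene orthogroups: ortholog / best_hit / non_ortholog / unclear;
* a one-sided hypergeometric enrichment of the gene-orthogroup overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd
from scipy.stats import hypergeom


def hypergeometric_enrichment(q: int, m: int, n: int, k: int) -> float:
    """Upper-tail P(X >= q) for X ~ Hypergeometric(m successes, n failures,
    k draws) - the classic over-representation test of a gene-set overlap."""
    for name, val in (("q", q), ("m", m), ("n", n), ("k", k)):
        if val < 0 or int(val) != val:
            raise ValueError(f"{name} must be a non-negative integer")
    if q > k or q > m:
        raise ValueError("q cannot exceed m or k")
    return float(hypergeom.sf(q - 1, m + n, m, k))


@dataclass
class RegulatedExonSet:
    species: str
    exons: list[str]                       # resolved exon ids
    genes: dict[str, str]                  # exon_id -> gene_id
    labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if len(set(self.exons)) != len(self.exons):
            raise ValueError("duplicate exons in regulated set")


def resolve_exon_set(species: str, records: Iterable[tuple[str, Optional[str]]],
                     exon_table: pd.DataFrame) -> tuple[RegulatedExonSet, list[str]]:
    """Resolve raw (exon_id_or_coordinate, label) records against the
    per-species exon reference table; unresolvable records are reported."""
    known = dict(zip(exon_table["exon_id"], exon_table["gene_id"]))
    exons, genes, labels, unresolved = [], {}, {}, []
    seen = set()
    for exon_id, label in records:
        if exon_id not in known:
            unresolved.append(exon_id)
            continue
        if exon_id in seen:
            continue
        seen.add(exon_id)
        exons.append(exon_id)
        genes[exon_id] = known[exon_id]
        if label:
            labels[exon_id] = label
    return RegulatedExonSet(species, exons, genes, labels), unresolved


def _gene_orthogroup_map(gene_orthogroups: pd.DataFrame) -> dict[str, str]:
    return dict(zip(gene_orthogroups["gene_id"], gene_orthogroups["cluster_id"]))


def gene_level_conservation(set_a: RegulatedExonSet, set_b: RegulatedExonSet,
                            gene_orthogroups: pd.DataFrame) -> pd.DataFrame:
    """Per query exon of set A: does its gene have an ortholog in species B,
    and does that ortholog also harbor a regulated exon?"""
    og_of = _gene_orthogroup_map(gene_orthogroups)
    genes_by_og_b = (gene_orthogroups[gene_orthogroups["species"] == set_b.species]
                     .groupby("cluster_id")["gene_id"].apply(set).to_dict())
    regulated_ogs_b = {og_of[g] for g in set_b.genes.values() if g in og_of}
    rows = []
    for exon in set_a.exons:
        gene = set_a.genes[exon]
        og = og_of.get(gene)
        has_orth = bool(og and genes_by_og_b.get(og))
        rows.append({
            "exon_id": exon, "gene_id": gene, "orthogroup": og or "",
            "has_gene_ortholog": has_orth,
            "gene_ortholog_regulated": has_orth and og in regulated_ogs_b,
        })
    return pd.DataFrame(rows, columns=["exon_id", "gene_id", "orthogroup",
                                       "has_gene_ortholog", "gene_ortholog_regulated"])


def exon_level_conservation(set_a: RegulatedExonSet, set_b: RegulatedExonSet,
                            exon_orthogroups: pd.DataFrame) -> pd.DataFrame:
    """G-conservation: the query exon shares an exon orthogroup with at least
    one species-B exon.  R-conservation: one such ortholog is regulated."""
    og_of_exon = {(sp, ex): og for sp, ex, og in zip(
        exon_orthogroups["species"], exon_orthogroups["exon_id"], exon_orthogroups["og_id"])}
    partners: dict[str, set[str]] = {}
    for sp, ex, og in zip(exon_orthogroups["species"], exon_orthogroups["exon_id"],
                          exon_orthogroups["og_id"]):
        if sp == set_b.species:
            partners.setdefault(og, set()).add(ex)
    regulated_b = set(set_b.exons)
    rows = []
    for exon in set_a.exons:
        og = og_of_exon.get((set_a.species, exon))
        orths = partners.get(og, set()) if og else set()
        rows.append({
            "exon_id": exon, "gene_id": set_a.genes[exon],
            "exon_orthogroup": og or "",
            "g_conserved": bool(orths),
            "r_conserved": bool(orths & regulated_b),
        })
    return pd.DataFrame(rows, columns=["exon_id", "gene_id", "exon_orthogroup",
                                       "g_conserved", "r_conserved"])


def classify_pairs(set_a: RegulatedExonSet, set_b: RegulatedExonSet,
                   gene_orthogroups: pd.DataFrame,
                   exon_orthogroups: pd.DataFrame,
                   orthopairs: pd.DataFrame,
                   best_hits: pd.DataFrame,
                   representatives: Optional[dict[tuple[str, str], str]] = None) -> pd.DataFrame:
    """Classify every cross-species regulated exon pair within gene
    orthogroups regulated in both species.

    ortholog      same exon orthogroup;
    best_hit      a recorded best-hit relation links the two exons (either
                  direction);
    non_ortholog  both exons have affirmative, distinct placements (each is
                  in an exon orthogroup or has a best hit) and neither points
                  to the other;
    unclear       anything else (typically an exon without alignment
                  evidence).
    """
    if representatives:
        map_a = lambda e: representatives.get((set_a.species, e), e)
        map_b = lambda e: representatives.get((set_b.species, e), e)
    else:
        map_a = map_b = lambda e: e

    og_of = _gene_orthogroup_map(gene_orthogroups)
    exog_of = {(sp, ex): og for sp, ex, og in zip(
        exon_orthogroups["species"], exon_orthogroups["exon_id"], exon_orthogroups["og_id"])}
    bh_links = set()
    bh_has = set()
    for _, r in best_hits.iterrows():
        bh_links.add((r["species1"], r["exon1"], r["species2"], r["exon2"]))
        bh_has.add((r["species1"], r["exon1"]))
    op_has = set()
    for _, r in orthopairs.iterrows():
        op_has.add((r["species1"], r["exon1"]))
        op_has.add((r["species2"], r["exon2"]))

    regulated_by_og_a: dict[str, set[str]] = {}
    for exon in set_a.exons:
        og = og_of.get(set_a.genes[exon])
        if og:
            regulated_by_og_a.setdefault(og, set()).add(map_a(exon))
    regulated_by_og_b: dict[str, set[str]] = {}
    for exon in set_b.exons:
        og = og_of.get(set_b.genes[exon])
        if og:
            regulated_by_og_b.setdefault(og, set()).add(map_b(exon))

    rows = []
    for og in sorted(set(regulated_by_og_a) & set(regulated_by_og_b)):
        for ex_a in sorted(regulated_by_og_a[og]):
            for ex_b in sorted(regulated_by_og_b[og]):
                ka, kb = (set_a.species, ex_a), (set_b.species, ex_b)
                og_a, og_b = exog_of.get(ka), exog_of.get(kb)
                linked_bh = ((*ka, *kb) in bh_links or (*kb, *ka) in bh_links)
                if og_a and og_a == og_b:
                    cls, why = "ortholog", "same exon orthogroup"
                elif linked_bh:
                    cls, why = "best_hit", "best-hit relation between the pair"
                else:
                    placed_a = bool(og_a) or ka in bh_has or ka in op_has
                    placed_b = bool(og_b) or kb in bh_has or kb in op_has
                    if placed_a and placed_b:
                        cls, why = "non_ortholog", "both exons affirmatively placed elsewhere"
                    else:
                        cls, why = "unclear", "missing alignment evidence for one exon"
                rows.append({"gene_orthogroup": og,
                             "species1": set_a.species, "exon1": ex_a,
                             "species2": set_b.species, "exon2": ex_b,
                             "classification": cls, "criterion": why})
    return pd.DataFrame(rows, columns=["gene_orthogroup", "species1", "exon1",
                                       "species2", "exon2", "classification", "criterion"])


@dataclass
class ConservationReport:
    gene_level_a: pd.DataFrame
    gene_level_b: pd.DataFrame
    exon_level_a: pd.DataFrame
    exon_level_b: pd.DataFrame
    pair_classification: pd.DataFrame
    enrichment_p: float
    enrichment_args: tuple[int, int, int, int]   # (q, m, n, k)

    def summary(self) -> dict:
        q, m, n, k = self.enrichment_args
        counts = (self.pair_classification["classification"].value_counts().to_dict()
                  if len(self.pair_classification) else {})
        def frac(df, col):
            return float(df[col].mean()) if len(df) else 0.0
        return {
            "n_regulated_a": len(self.gene_level_a),
            "n_regulated_b": len(self.gene_level_b),
            "gene_conserved_frac_a": frac(self.gene_level_a, "has_gene_ortholog"),
            "gene_regulated_frac_a": frac(self.gene_level_a, "gene_ortholog_regulated"),
            "g_conserved_frac_a": frac(self.exon_level_a, "g_conserved"),
            "r_conserved_frac_a": frac(self.exon_level_a, "r_conserved"),
            "pair_counts": counts,
            "enrichment_p": self.enrichment_p,
            "q": q, "m": m, "n": n, "k": k,
        }


def compare_exon_sets(set_a: RegulatedExonSet, set_b: RegulatedExonSet,
                      gene_orthogroups: pd.DataFrame,
                      exon_orthogroups: pd.DataFrame,
                      orthopairs: pd.DataFrame,
                      best_hits: pd.DataFrame,
                      representatives: Optional[dict[tuple[str, str], str]] = None) -> ConservationReport:
    """Full two-species comparison; the enrichment universe is the set of
    gene orthogroups, with q counting orthogroups regulated in both
    species."""
    og_of = _gene_orthogroup_map(gene_orthogroups)
    all_ogs = set(gene_orthogroups["cluster_id"])
    ogs_a = {og_of[g] for g in set_a.genes.values() if g in og_of}
    ogs_b = {og_of[g] for g in set_b.genes.values() if g in og_of}
    q = len(ogs_a & ogs_b)
    m = len(ogs_a)
    n = len(all_ogs) - m
    k = len(ogs_b)
    p = hypergeometric_enrichment(q, m, n, k) if m and k else 1.0
    report = ConservationReport(
        gene_level_a=gene_level_conservation(set_a, set_b, gene_orthogroups),
        gene_level_b=gene_level_conservation(set_b, set_a, gene_orthogroups),
        exon_level_a=exon_level_conservation(set_a, set_b, exon_orthogroups),
        exon_level_b=exon_level_conservation(set_b, set_a, exon_orthogroups),
        pair_classification=classify_pairs(set_a, set_b, gene_orthogroups,
                                           exon_orthogroups, orthopairs, best_hits,
                                           representatives),
        enrichment_p=p,
        enrichment_args=(q, m, n, k))
    return report
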