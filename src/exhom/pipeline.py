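"""End-to-end orchestration: per-species preprocessing, per-species-pair
alignment and scoring, joint clustering, and TSV output.

The run is an in-process job graph: species-pair computations are mutually
independent (results do not depend on execution order) and all tie-breaks
are fixed, so two runs on identical inputs produce byte-identical tables.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from . import annotation, clustering, scoring
from .alignment import Aligner, AlignmentCache, inject_intron_markers
from .annotation import GeneModel
from .clustering import ExonOrthogroup
from .scoring import DEFAULT_CONFIGS, DistanceConfig, Orthopair

logger = logging.getLogger(__name__)


class InputError(ValueError):
    pass


def load_gene_orthogroups(path: str | Path, max_genes: int = 20) -> pd.DataFrame:
    """Read a gene orthogroup table (cluster id, species, gene id; TSV).

    Clusters with more than ``max_genes`` members are dropped (large,
    paralog-heavy clusters are uninformative and quadratically expensive)."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3 or any(not f.strip() for f in fields[:3]):
                raise InputError(f"{path}:{ln}: expected 3 tab-separated fields "
                                 "(cluster_id, species, gene_id)")
            rows.append({"cluster_id": fields[0].strip(), "species": fields[1].strip(),
                         "gene_id": fields[2].strip()})
    if not rows:
        raise InputError(f"{path}: empty gene orthogroup file")
    df = pd.DataFrame(rows)
    sizes = df.groupby("cluster_id")["gene_id"].nunique()
    big = set(sizes[sizes > max_genes].index)
    if big:
        logger.info("dropping %d gene orthogroups with more than %d genes", len(big), max_genes)
        df = df[~df["cluster_id"].isin(big)].reset_index(drop=True)
    return df


def check_consistency(models_by_species: dict[str, dict[str, GeneModel]],
                      orthogroups: pd.DataFrame) -> None:
    for _, row in orthogroups.iterrows():
        sp, gene = row["species"], row["gene_id"]
        if sp not in models_by_species:
            raise InputError(f"orthogroup species {sp!r} has no annotation")
        if gene not in models_by_species[sp]:
            raise InputError(
                f"gene {gene!r} ({sp}) is in the orthogroups but absent from the annotation")


def resolve_ranges(species: Sequence[str],
                   ranges: dict[frozenset, str | DistanceConfig],
                   overrides: Optional[dict[str, DistanceConfig]] = None) -> dict[frozenset, DistanceConfig]:
    configs = dict(DEFAULT_CONFIGS)
    if overrides:
        configs.update(overrides)
    resolved = {}
    for sp1, sp2 in itertools.combinations(sorted(species), 2):
        key = frozenset((sp1, sp2))
        if key not in ranges:
            raise InputError(f"no evolutionary distance range declared for {sp1}-{sp2}")
        val = ranges[key]
        resolved[key] = val if isinstance(val, DistanceConfig) else configs[val]
    return resolved


@dataclass
class PipelineResult:
    orthopairs: pd.DataFrame
    best_hits: pd.DataFrame
    orthogroups: list[ExonOrthogroup]
    orthogroups_table: pd.DataFrame
    stats_table: pd.DataFrame
    stats_tally: pd.DataFrame
    representatives: dict[tuple[str, str], str]
    records: list[Orthopair] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


def _ipa_for(aligner: Aligner, iso_a, iso_b):
    gq, gt, score = aligner.align(iso_a.protein, iso_b.protein,
                                  iso_a.isoform_id, iso_b.isoform_id)
    return inject_intron_markers(
        gq, gt,
        [(i.residue_offset, i.phase) for i in iso_a.introns],
        [(i.residue_offset, i.phase) for i in iso_b.introns],
        iso_a.isoform_id, iso_b.isoform_id, score)


def score_species_pair(models_a: dict[str, GeneModel], models_b: dict[str, GeneModel],
                       orthogroups: pd.DataFrame, cfg: DistanceConfig,
                       aligner: Optional[Aligner] = None) -> list[scoring.ExonMatchCandidate]:
    """All exon match candidates for one species pair, both directions."""
    aligner = aligner or Aligner()
    sp_a = next(iter(models_a.values())).species if models_a else "a"
    sp_b = next(iter(models_b.values())).species if models_b else "b"
    candidates: list[scoring.ExonMatchCandidate] = []
    for cluster_id, sub in orthogroups.groupby("cluster_id"):
        genes_a = sorted(sub[sub["species"] == sp_a]["gene_id"].unique())
        genes_b = sorted(sub[sub["species"] == sp_b]["gene_id"].unique())
        for ga_id in genes_a:
            for gb_id in genes_b:
                ga, gb = models_a[ga_id], models_b[gb_id]
                for iso_a_id in sorted(ga.isoforms):
                    for iso_b_id in sorted(gb.isoforms):
                        iso_a, iso_b = ga.isoforms[iso_a_id], gb.isoforms[iso_b_id]
                        ipa = _ipa_for(aligner, iso_a, iso_b)
                        if not scoring.admit_isoform_pair(ipa.stats, cfg):
                            continue
                        candidates.extend(scoring.build_candidates(
                            ipa, ga, gb, iso_a, iso_b, cfg))
                        candidates.extend(scoring.build_candidates(
                            ipa.swapped(), gb, ga, iso_b, iso_a, cfg))
    return candidates


def finalize(candidates: Sequence[scoring.ExonMatchCandidate],
             models_by_species: dict[str, dict[str, GeneModel]],
             orthogroups: pd.DataFrame,
             bonafide: Sequence[tuple[str, str, str, str]] = (),
             cluster: bool = True) -> PipelineResult:
    """Reduce candidates to orthopairs/best-hits, pick overlap-group
    representatives, integrate bona-fide pairs, and cluster."""
    records = scoring.select_best_match(candidates)
    representatives: dict[tuple[str, str], str] = {}
    for sp, models in models_by_species.items():
        sp_records = [r for r in records if r.query_species == sp]
        for exon, rep in scoring.select_overlap_representatives(models, sp_records).items():
            representatives[(sp, exon)] = rep

    def is_rep(sp: str, exon: str) -> bool:
        return representatives.get((sp, exon), exon) == exon

    rep_records = [r for r in records
                   if is_rep(r.query_species, r.query_exon)
                   and is_rep(r.target_species, r.target_exon)]
    warnings: list[str] = []
    if bonafide:
        rep_records, warnings = scoring.apply_bonafide(rep_records, bonafide,
                                                       models_by_species)
    scoring.mark_reciprocal(rep_records)

    gene_og = dict(zip(orthogroups["gene_id"], orthogroups["cluster_id"]))
    genes_per_og = orthogroups.groupby("cluster_id")["gene_id"].nunique().to_dict()
    exon_ogs: list[ExonOrthogroup] = []
    if cluster:
        by_og: dict[str, list[Orthopair]] = {}
        for r in rep_records:
            if r.status != "orthopair":
                continue
            og = gene_og.get(r.query_gene)
            if og is None or gene_og.get(r.target_gene) != og:
                continue  # cross-orthogroup pairs cannot arise by construction
            by_og.setdefault(og, []).append(r)
        for og_id in sorted(by_og):
            graph = clustering.build_exon_graph(by_og[og_id])
            exon_ogs.extend(clustering.cluster_exons(graph, og_id,
                                                     genes_per_og.get(og_id, 0)))

    species_list = sorted(models_by_species)
    stats_table, stats_tally = clustering.orthogroup_stats(exon_ogs, species_list)
    og_rows = [{"og_id": og.og_id, "gene_og_id": og.gene_orthogroup_id, **m}
               for og in exon_ogs for m in og.members]
    orthogroups_table = pd.DataFrame(
        og_rows, columns=["og_id", "gene_og_id", "species", "gene_id", "exon_id",
                          "membership_score"])

    def row(r: Orthopair) -> dict:
        g1 = gene_og.get(r.query_gene, "")
        return {"species1": r.query_species, "exon1": r.query_exon, "gene1": r.query_gene,
                "species2": r.target_species, "exon2": r.target_exon, "gene2": r.target_gene,
                "gene_orthogroup": g1,
                "s1": r.s1, "s2": r.s2, "s3": r.s3, "s4": r.s4, "s5": r.s5,
                "global_score": r.global_score, "reciprocal": r.reciprocal,
                "source": r.source}

    op_rows = [row(r) for r in rep_records if r.status == "orthopair"]
    bh_rows = [dict(row(r), fail_reasons=",".join(r.fail_reasons))
               for r in rep_records if r.status == "best_hit"]
    columns = ["species1", "exon1", "gene1", "species2", "exon2", "gene2",
               "gene_orthogroup", "s1", "s2", "s3", "s4", "s5", "global_score",
               "reciprocal", "source"]
    return PipelineResult(
        orthopairs=pd.DataFrame(op_rows, columns=columns),
        best_hits=pd.DataFrame(bh_rows, columns=columns + ["fail_reasons"]),
        orthogroups=exon_ogs, orthogroups_table=orthogroups_table,
        stats_table=stats_table, stats_tally=stats_tally,
        representatives=representatives, records=rep_records, warnings=warnings)


def infer_orthologies(models_by_species: dict[str, dict[str, GeneModel]],
                      orthogroups: pd.DataFrame,
                      ranges: dict[frozenset, str | DistanceConfig],
                      overrides: Optional[dict[str, DistanceConfig]] = None,
                      aligner: Optional[Aligner] = None,
                      bonafide: Sequence[tuple[str, str, str, str]] = ()) -> PipelineResult:
    """The full inference: candidates for every species pair, then joint
    best-match selection and clustering."""
    check_consistency(models_by_species, orthogroups)
    species = sorted(models_by_species)
    resolved = resolve_ranges(species, ranges, overrides)
    aligner = aligner or Aligner()
    candidates: list[scoring.ExonMatchCandidate] = []
    for sp1, sp2 in itertools.combinations(species, 2):
        cfg = resolved[frozenset((sp1, sp2))]
        sub = orthogroups[orthogroups["species"].isin((sp1, sp2))]
        candidates.extend(score_species_pair(models_by_species[sp1],
                                             models_by_species[sp2],
                                             sub, cfg, aligner))
    return finalize(candidates, models_by_species, orthogroups, bonafide)


# ---------------------------------------------------------------------------
# file-level entry points


@dataclass
class SpeciesInput:
    species: str
    gtf: Path
    fasta: Path
    extra_exons: Optional[Path] = None


@dataclass
class RunConfig:
    species: list[SpeciesInput]
    orthogroups_path: Path
    ranges: dict[frozenset, str]
    output_dir: Path
    overrides: dict[str, DistanceConfig] = field(default_factory=dict)
    bonafide_path: Optional[Path] = None
    cache_dir: Optional[Path] = None
    max_og_genes: int = 20


def load_species(spec: SpeciesInput) -> dict[str, GeneModel]:
    models = annotation.parse_annotation(spec.gtf, spec.fasta, spec.species)
    for gene in models.values():
        annotation.collapse_redundant_isoforms(gene)
    if spec.extra_exons:
        genome = annotation._read_fasta(spec.fasta)
        records = annotation.read_extra_exons(spec.extra_exons)
        models, unplaced = annotation.integrate_extra_exons(models, records, genome)
        for rec, reason in unplaced:
            logger.warning("extra exon %s (%s): %s", rec.exon, rec.gene_id, reason)
        for gene in models.values():
            annotation.collapse_redundant_isoforms(gene)
    return models


def read_bonafide(path: str | Path) -> list[tuple[str, str, str, str]]:
    pairs = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) >= 4:
                pairs.append((f[0], f[1], f[2], f[3]))
    return pairs


def run_main(config: RunConfig) -> Path:
    """Execute the pipeline from files and write all output tables."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    models_by_species = {s.species: load_species(s) for s in config.species}
    orthogroups = load_gene_orthogroups(config.orthogroups_path, config.max_og_genes)
    aligner = Aligner(AlignmentCache(config.cache_dir) if config.cache_dir else None)
    bonafide = read_bonafide(config.bonafide_path) if config.bonafide_path else ()
    result = infer_orthologies(models_by_species, orthogroups, config.ranges,
                               config.overrides, aligner, bonafide)
    fmt = dict(sep="\t", index=False, float_format="%.6g")
    result.orthopairs.to_csv(out / "exon_orthopairs.tsv", **fmt)
    result.best_hits.to_csv(out / "best_hits.tsv", **fmt)
    result.orthogroups_table.to_csv(out / "exon_orthogroups.tsv", **fmt)
    result.stats_table.to_csv(out / "orthogroup_stats.tsv", **fmt)
    result.stats_tally.to_csv(out / "orthogroup_pattern_tally.tsv", **fmt)
    for sp, models in models_by_species.items():
        annotation.exon_reference_table(models).to_csv(
            out / f"{sp}.exon_reference.tsv", sep="\t", index=False)
    for w in result.warnings:
        logger.warning("%s", w)
    logger.info("alignments computed: %d", aligner.n_computed)
    return out


# ---------------------------------------------------------------------------
# IPA retrieval


def format_ipa(ipa, width: int = 60) -> str:
    """Human-readable IPA alignment: phases printed above/below the row at
    each intron's boundary column."""
    def marker_line(markers, n):
        line = [" "] * n
        for m in markers:
            col = min(m.column, n - 1)
            line[col] = str(m.phase)
        return "".join(line)

    n = len(ipa.aligned_query)
    top = marker_line(ipa.query_markers, n)
    bottom = marker_line(ipa.target_markers, n)
    blocks = []
    for i in range(0, n, width):
        blocks.append("\n".join([
            top[i:i + width],
            ipa.aligned_query[i:i + width],
            ipa.aligned_target[i:i + width],
            bottom[i:i + width]]))
    header = (f"# query {ipa.query_isoform_id}  target {ipa.target_isoform_id}  "
              f"score {ipa.score:.1f}  similarity {ipa.stats.similarity_pct_q:.1f}%"
              f"/{ipa.stats.similarity_pct_t:.1f}%")
    return header + "\n" + "\n\n".join(blocks) + "\n"


def retrieve_ipa(models_by_species: dict[str, dict[str, GeneModel]],
                 species_q: str, exon_q: str, species_t: str, exon_t: str,
                 aligner: Optional[Aligner] = None) -> str:
    """The best-scoring IPA alignment (by global exon match score) among all
    isoform pairs containing the two exons."""
    aligner = aligner or Aligner()
    gene_q = next((g for g in models_by_species[species_q].values() if exon_q in g.exons), None)
    gene_t = next((g for g in models_by_species[species_t].values() if exon_t in g.exons), None)
    if gene_q is None or gene_t is None:
        raise InputError("exon not found in the annotation")
    cfg = DEFAULT_CONFIGS["long"]
    best = None
    for iso_q in sorted(gene_q.isoforms):
        if exon_q not in gene_q.isoforms[iso_q].exon_ids:
            continue
        for iso_t in sorted(gene_t.isoforms):
            if exon_t not in gene_t.isoforms[iso_t].exon_ids:
                continue
            ipa = _ipa_for(aligner, gene_q.isoforms[iso_q], gene_t.isoforms[iso_t])
            for cand in scoring.build_candidates(ipa, gene_q, gene_t,
                                                 gene_q.isoforms[iso_q],
                                                 gene_t.isoforms[iso_t], cfg):
                if cand.query_exon == exon_q and cand.target_exon == exon_t:
                    if best is None or cand.global_score > best[0]:
                        best = (cand.global_score, ipa)
    if best is None:
        raise InputError(f"no IPA alignment matches {exon_q} to {exon_t}")
    return format_ipa(best[1])
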