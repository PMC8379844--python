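"""Exon homology scoring: intron-conservation rating, the five partial
scores, the global score, the distance-range filter cascade, and best-match
selection.

For a query exon matched to a target exon inside one IPA alignment, five
partial scores summarize the conservation of the local exon-intron context:

* s1 / s2 - conservation of the upstream / downstream intron position and
  phase, 0.025 x an intron rating in [-10, 10] (so each in [-0.25, 0.25]);
* s3     - query-exon sequence similarity, scaled to [0, 0.2];
* s4 / s5 - upstream / downstream neighbor-exon similarity, scaled to
  [0, 0.15].

Their sum is the global score in [0, 1]; first/last exons lack one intron and
one neighbor, so their sum is divided by 0.6 to restore the [0, 1] range.
Homology itself is decided not by the global score but by per-feature
cut-offs that depend on the evolutionary distance range of the species pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .alignment import GAP, Aligner, IntronMarker, IpaAlignment, realign_exon_pair, residues_similar
from .annotation import GeneModel, Isoform


@dataclass(frozen=True)
class DistanceConfig:
    """The four conservation cut-offs for one evolutionary distance range.

    prot_sim - (a) minimum global protein similarity (fraction) for an
               isoform pair to be considered;
    int_num  - (b) how many of the two neighboring intron positions must be
               conserved (0, 1 or 2);
    ex_seq   - (c) minimum exon sequence similarity (fraction);
    ex_len   - (d) minimum exon length ratio, shortest/longest.
    """

    range_name: str
    prot_sim: float
    int_num: int
    ex_seq: float
    ex_len: float

    def __post_init__(self):
        if not (0 <= self.prot_sim <= 1 and 0 <= self.ex_seq <= 1 and 0 <= self.ex_len <= 1):
            raise ValueError("cut-off fractions must lie in [0, 1]")
        if self.int_num not in (0, 1, 2):
            raise ValueError("int_num must be 0, 1 or 2")


#: calibrated defaults per evolutionary distance range
DEFAULT_CONFIGS = {
    "short": DistanceConfig("short", prot_sim=0.25, int_num=2, ex_seq=0.5, ex_len=0.6),
    "medium": DistanceConfig("medium", prot_sim=0.20, int_num=2, ex_seq=0.3, ex_len=0.6),
    "long": DistanceConfig("long", prot_sim=0.15, int_num=2, ex_seq=0.1, ex_len=0.4),
}

_EPS = 1e-9


def admit_isoform_pair(stats, cfg: DistanceConfig) -> bool:
    """Keep an isoform alignment if global similarity reaches cut-off (a) for
    both species, or twice the cut-off for one of them."""
    a = cfg.prot_sim
    sim_q = stats.similarity_pct_q / 100.0
    sim_t = stats.similarity_pct_t / 100.0
    return ((sim_q >= a - _EPS and sim_t >= a - _EPS)
            or sim_q >= 2 * a - _EPS or sim_t >= 2 * a - _EPS)


# ---------------------------------------------------------------------------
# intron conservation


def window_width(similarity_pct: float, gap_pct: float,
                 gaps_left: int = 0, gaps_right: int = 0) -> int:
    """Search-window half-width for matching a query intron to a target
    intron, from the local alignment quality, widened by the rounded mean gap
    count within ten columns on either side."""
    if similarity_pct <= 30 or gap_pct >= 30:
        base = 10
    elif similarity_pct < 50:
        base = 8
    elif similarity_pct < 70:
        base = 6
    elif similarity_pct < 80:
        base = 4
    elif similarity_pct < 90:
        base = 3
    else:
        base = 2
    bonus = math.floor((gaps_left + gaps_right) / 2.0 + 0.5)  # round half-up
    return base + bonus


def local_alignment_context(ipa: IpaAlignment, column: int,
                            span: int = 10) -> tuple[float, float, int, int]:
    """Local % similarity and % gaps over ``2*span`` columns centered on a
    marker column, plus the raw gap-character counts on each side.

    Denominator for both percentages is the number of columns actually inside
    the alignment.  Gap characters are counted over both rows.
    """
    n = len(ipa.aligned_query)
    lo = max(0, column - span)
    hi = min(n, column + span)
    ncols = hi - lo
    if ncols == 0:
        return 0.0, 100.0, 0, 0
    similar = gap_chars = 0
    gaps_left = gaps_right = 0
    for i in range(lo, hi):
        a, b = ipa.aligned_query[i], ipa.aligned_target[i]
        here = (a == GAP) + (b == GAP)
        gap_chars += here
        if i < column:
            gaps_left += here
        else:
            gaps_right += here
        if a != GAP and b != GAP and residues_similar(a, b):
            similar += 1
    return 100.0 * similar / ncols, 100.0 * gap_chars / (2 * ncols), gaps_left, gaps_right


@dataclass(frozen=True)
class IntronConservation:
    """Rating of one query intron against the target's introns.

    10 = perfectly aligned, equal phase; each column of positional offset is
    subtracted.  A phase mismatch rates -10 (the offset subtraction is clamped
    so the value never drops below -10).  No target intron inside the search
    window rates 0.
    """

    value: float
    matched_target_intron: Optional[int]
    column_offset: int


def score_intron_conservation(ipa: IpaAlignment, query_intron_index: int) -> IntronConservation:
    qm = ipa.query_markers[query_intron_index]
    sim, gaps, g_left, g_right = local_alignment_context(ipa, qm.column)
    width = window_width(sim, gaps, g_left, g_right)
    best: Optional[IntronMarker] = None
    best_offset = 0
    for tm in ipa.target_markers:
        offset = abs(tm.column - qm.column)
        if offset > width:
            continue
        if best is None or (offset, tm.column) < (best_offset, best.column):
            best, best_offset = tm, offset
    if best is None:
        return IntronConservation(0.0, None, 0)
    if best.phase == qm.phase:
        value = 10.0 - best_offset
    else:
        value = -10.0
    return IntronConservation(max(value, -10.0), best.intron_index, best_offset)


# ---------------------------------------------------------------------------
# exon matching within one IPA alignment


def _residue_columns(gapped: str) -> list[int]:
    return [i for i, c in enumerate(gapped) if c != GAP]


def _span_columns(positions: list[int], span: tuple[int, int]) -> Optional[tuple[int, int]]:
    lo, hi = span
    hi = min(hi, len(positions))
    if hi <= lo:
        return None
    return positions[lo], positions[hi - 1] + 1


def exon_sequence(iso: Isoform, index: int) -> str:
    lo, hi = iso.exon_residue_spans[index]
    return iso.protein[lo:hi]


def match_exons(ipa: IpaAlignment, query_iso: Isoform, target_iso: Isoform) -> list[tuple[int, int, float]]:
    """For each query exon pick the matching target exon in this isoform pair.

    Target exons are ranked by how much of the query exon's residue span they
    cover in the alignment.  When two or more targets each cover >= 15% of the
    query exon, every such pair is realigned and the most similar target wins;
    otherwise the majority-coverage target is kept.

    Returns ``(query_exon_index, target_exon_index, exon_similarity_pct)``
    triples (similarity from the dedicated exon-pair realignment).
    """
    pos_q = _residue_columns(ipa.aligned_query)
    pos_t = _residue_columns(ipa.aligned_target)
    target_cols = []
    for t_idx in range(len(target_iso.exon_ids)):
        cols = _span_columns(pos_t, target_iso.exon_residue_spans[t_idx])
        target_cols.append(cols)
    matches = []
    for q_idx in range(len(query_iso.exon_ids)):
        lo, hi = query_iso.exon_residue_spans[q_idx]
        hi = min(hi, len(pos_q))
        if hi <= lo:
            continue
        q_res_cols = pos_q[lo:hi]
        n_q = len(q_res_cols)
        coverage = []
        for t_idx, cols in enumerate(target_cols):
            if cols is None:
                continue
            covered = sum(1 for c in q_res_cols if cols[0] <= c < cols[1])
            if covered:
                coverage.append((t_idx, covered / n_q))
        if not coverage:
            continue
        big = [tc for tc in coverage if tc[1] >= 0.15]
        qseq = exon_sequence(query_iso, q_idx)
        if len(big) >= 2:
            scored = []
            for t_idx, cov in big:
                sim = realign_exon_pair(qseq, exon_sequence(target_iso, t_idx))
                scored.append((sim, cov, -t_idx))
            sim, cov, neg_idx = max(scored)
            matches.append((q_idx, -neg_idx, sim))
        else:
            t_idx, cov = max(coverage, key=lambda tc: (tc[1], -tc[0]))
            sim = realign_exon_pair(qseq, exon_sequence(target_iso, t_idx))
            matches.append((q_idx, t_idx, sim))
    return matches


# ---------------------------------------------------------------------------
# candidates, scores, filters


@dataclass
class ExonMatchCandidate:
    query_exon: str
    query_gene: str
    query_species: str
    target_exon: str
    target_gene: str
    target_species: str
    query_isoform: str
    target_isoform: str
    position_class: str               # of the query exon in this isoform
    s1: Optional[float]               # None where the side does not exist
    s2: Optional[float]
    s3: float
    s4: Optional[float]
    s5: Optional[float]
    global_score: float
    query_len_nt: int
    target_len_nt: int
    intron_up: Optional[IntronConservation] = None
    intron_down: Optional[IntronConservation] = None
    filter_verdicts: dict = field(default_factory=dict)
    passes: bool = False

    def scores(self) -> dict:
        return {"s1": self.s1, "s2": self.s2, "s3": self.s3,
                "s4": self.s4, "s5": self.s5}


def global_score(s1: Optional[float], s2: Optional[float], s3: float,
                 s4: Optional[float], s5: Optional[float],
                 position_class: str) -> float:
    """Sum of the partial scores; first/last exons divide by 0.6, a
    single-exon (intron-less) isoform is scored on sequence alone.  Negative
    intron contributions are clamped so the result stays in [0, 1]."""
    if position_class == "internal":
        total = (s1 or 0.0) + (s2 or 0.0) + s3 + (s4 or 0.0) + (s5 or 0.0)
    elif position_class == "first":
        total = ((s2 or 0.0) + s3 + (s5 or 0.0)) / 0.6
    elif position_class == "last":
        total = ((s1 or 0.0) + s3 + (s4 or 0.0)) / 0.6
    elif position_class == "single":
        total = s3 / 0.2
    else:
        raise ValueError(f"unknown position class {position_class!r}")
    return min(1.0, max(0.0, total))


def apply_filters(candidate: ExonMatchCandidate, cfg: DistanceConfig) -> dict:
    """Evaluate the filter cascade; only sides that exist for the exon's
    position class are checked."""
    pc = candidate.position_class
    intron_sides = []
    if pc in ("internal", "last") and candidate.s1 is not None:
        intron_sides.append(candidate.s1)
    if pc in ("internal", "first") and candidate.s2 is not None:
        intron_sides.append(candidate.s2)
    if cfg.int_num == 0 or not intron_sides:
        intron_ok = True
    elif cfg.int_num == 2:
        intron_ok = all(s > 0 for s in intron_sides)
    else:
        intron_ok = any(s > 0 for s in intron_sides)
    seq_ok = candidate.s3 >= cfg.ex_seq * 0.2 - _EPS
    neighbor_sides = []
    if pc in ("internal", "last"):
        neighbor_sides.append(candidate.s4 or 0.0)
    if pc in ("internal", "first"):
        neighbor_sides.append(candidate.s5 or 0.0)
    neighbor_ok = all(s >= cfg.ex_seq * 0.15 - _EPS for s in neighbor_sides)
    ratio = (min(candidate.query_len_nt, candidate.target_len_nt)
             / max(candidate.query_len_nt, candidate.target_len_nt))
    length_ok = ratio >= cfg.ex_len - _EPS
    verdicts = {"intron": intron_ok, "ex_seq": seq_ok,
                "neighbor_seq": neighbor_ok, "ex_len": length_ok}
    candidate.filter_verdicts = verdicts
    candidate.passes = all(verdicts.values())
    return verdicts


def build_candidates(ipa: IpaAlignment, query_gene: GeneModel, target_gene: GeneModel,
                     query_iso: Isoform, target_iso: Isoform,
                     cfg: DistanceConfig) -> list[ExonMatchCandidate]:
    """Score every query exon of one isoform pair against its matched target
    exon."""
    out = []
    n_q = len(query_iso.exon_ids)
    n_t = len(target_iso.exon_ids)
    for q_idx, t_idx, exon_sim in match_exons(ipa, query_iso, target_iso):
        pc = query_iso.position_class(q_idx)
        s3 = 0.2 * exon_sim / 100.0
        s1 = s2 = s4 = s5 = None
        up = down = None
        if q_idx > 0:
            up = score_intron_conservation(ipa, q_idx - 1)
            s1 = 0.025 * up.value
            s4 = 0.15 * realign_exon_pair(
                exon_sequence(query_iso, q_idx - 1),
                exon_sequence(target_iso, t_idx - 1) if t_idx > 0 else "") / 100.0
        if q_idx < n_q - 1:
            down = score_intron_conservation(ipa, q_idx)
            s2 = 0.025 * down.value
            s5 = 0.15 * realign_exon_pair(
                exon_sequence(query_iso, q_idx + 1),
                exon_sequence(target_iso, t_idx + 1) if t_idx < n_t - 1 else "") / 100.0
        q_exon = query_iso.exon_ids[q_idx]
        t_exon = target_iso.exon_ids[t_idx]
        cand = ExonMatchCandidate(
            query_exon=q_exon, query_gene=query_gene.gene_id, query_species=query_gene.species,
            target_exon=t_exon, target_gene=target_gene.gene_id, target_species=target_gene.species,
            query_isoform=query_iso.isoform_id, target_isoform=target_iso.isoform_id,
            position_class=pc, s1=s1, s2=s2, s3=s3, s4=s4, s5=s5,
            global_score=global_score(s1, s2, s3, s4, s5, pc),
            query_len_nt=query_gene.exons[q_exon].cds_len,
            target_len_nt=target_gene.exons[t_exon].cds_len,
            intron_up=up, intron_down=down)
        apply_filters(cand, cfg)
        out.append(cand)
    return out


# ---------------------------------------------------------------------------
# best-match selection


@dataclass
class Orthopair:
    query_species: str
    query_exon: str
    query_gene: str
    target_species: str
    target_exon: str
    target_gene: str
    s1: Optional[float]
    s2: Optional[float]
    s3: float
    s4: Optional[float]
    s5: Optional[float]
    global_score: float
    status: str                       # "orthopair" or "best_hit"
    position_class: str
    reciprocal: bool = False
    source: str = "inferred"
    fail_reasons: tuple = ()


def select_best_match(candidates: Sequence[ExonMatchCandidate]) -> list[Orthopair]:
    """Reduce isoform-level candidates to one record per (query exon, target
    gene): passing candidates outrank failing ones, then highest global
    score, then higher s3, then lexicographic target exon id."""
    groups: dict[tuple[str, str], list[ExonMatchCandidate]] = {}
    for c in candidates:
        groups.setdefault((c.query_exon, c.target_gene), []).append(c)
    records = []
    for (q_exon, t_gene) in sorted(groups):
        pool = groups[(q_exon, t_gene)]
        best = max(pool, key=lambda c: (c.passes, c.global_score, c.s3, _desc_str(c.target_exon)))
        records.append(Orthopair(
            query_species=best.query_species, query_exon=best.query_exon,
            query_gene=best.query_gene, target_species=best.target_species,
            target_exon=best.target_exon, target_gene=best.target_gene,
            s1=best.s1, s2=best.s2, s3=best.s3, s4=best.s4, s5=best.s5,
            global_score=best.global_score,
            status="orthopair" if best.passes else "best_hit",
            position_class=best.position_class,
            fail_reasons=() if best.passes else tuple(
                k for k, v in best.filter_verdicts.items() if not v)))
    return records


class _desc_str(str):
    """String with inverted ordering, for use inside max() keys."""

    def __lt__(self, other):
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)


def select_overlap_representatives(models: dict[str, GeneModel],
                                   records: Sequence[Orthopair]) -> dict[str, str]:
    """Pick one representative exon per overlap group: the variant with the
    most (passing) matches over all target genes; ties go to the longer CDS,
    then the lexicographically smallest exon id.

    Returns exon_id -> representative exon_id for every exon of every gene.
    """
    match_counts: dict[str, int] = {}
    for r in records:
        if r.status == "orthopair":
            match_counts[r.query_exon] = match_counts.get(r.query_exon, 0) + 1
    reps: dict[str, str] = {}
    for gene in models.values():
        groups: dict[str, list[str]] = {}
        for exon_id, gid in gene.overlap_groups.items():
            groups.setdefault(gid, []).append(exon_id)
        for gid, members in groups.items():
            rep = max(members, key=lambda e: (match_counts.get(e, 0),
                                              gene.exons[e].cds_len, _desc_str(e)))
            for e in members:
                reps[e] = rep
    return reps


def apply_bonafide(records: list[Orthopair], bonafide: Sequence[tuple[str, str, str, str]],
                   models_by_species: dict[str, dict[str, GeneModel]]) -> tuple[list[Orthopair], list[str]]:
    """Merge curated exon orthopairs: ``(species1, exon1, species2, exon2)``
    tuples override inferred records for the same (query exon, target gene)
    and are added in both directions with source ``bonafide``.  Pairs whose
    exons are not in the annotation are skipped with a warning message."""
    warnings: list[str] = []

    def locate(species: str, exon_id: str):
        genes = models_by_species.get(species, {})
        for gene in genes.values():
            if exon_id in gene.exons:
                return gene
        return None

    overrides: list[Orthopair] = []
    for sp1, ex1, sp2, ex2 in bonafide:
        g1 = locate(sp1, ex1)
        g2 = locate(sp2, ex2)
        if g1 is None or g2 is None:
            warnings.append(f"bona-fide pair {ex1}/{ex2}: exon not found in annotation; skipped")
            continue
        for (sa, ea, ga), (sb, eb, gb) in (((sp1, ex1, g1), (sp2, ex2, g2)),
                                           ((sp2, ex2, g2), (sp1, ex1, g1))):
            overrides.append(Orthopair(
                query_species=sa, query_exon=ea, query_gene=ga.gene_id,
                target_species=sb, target_exon=eb, target_gene=gb.gene_id,
                s1=None, s2=None, s3=0.0, s4=None, s5=None, global_score=1.0,
                status="orthopair", position_class="bonafide", source="bonafide"))
    keyed = {(r.query_species, r.query_exon, r.target_gene): r for r in records}
    for r in overrides:
        keyed[(r.query_species, r.query_exon, r.target_gene)] = r
    merged = sorted(keyed.values(),
                    key=lambda r: (r.query_species, r.query_exon, r.target_species, r.target_gene))
    return merged, warnings


def mark_reciprocal(records: Sequence[Orthopair]) -> None:
    """A pair is reciprocal when the reverse direction selected the mirrored
    exons (both as passing orthopairs)."""
    passing = {(r.query_species, r.query_exon, r.target_species, r.target_exon)
               for r in records if r.status == "orthopair"}
    for r in records:
        r.reciprocal = (r.status == "orthopair" and
                        (r.target_species, r.target_exon, r.query_species, r.query_exon) in passing)
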