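"""Gene models with exon-intron structure and phased intron positions.

Parses genome FASTA + GTF (CDS features) into per-gene catalogues of coding
exons and translated isoforms.  Every intron of an isoform is recorded as a
residue offset (complete codons upstream) plus a phase: 0 if it falls between
codons, 1/2 if it splits a codon after the first/second nucleotide.

Coordinate conventions: GTF is 1-based inclusive; everything internal is
0-based half-open; exon identifiers are rendered 1-based inclusive as
``chrom:start-end:strand``.  Exons are identified by their CDS interval, so
the same coding exon shared by several isoforms is a single entity.  The stop
codon is excluded from the protein and from the last exon's residue span.
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, TextIO

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)


class AnnotationError(ValueError):
    pass


@dataclass(frozen=True)
class IntronPosition:
    residue_offset: int          # complete codons upstream of the intron
    phase: int                   # 0, 1 or 2
    side_exons: tuple[str, str]  # (upstream exon_id, downstream exon_id)


@dataclass
class CodingExon:
    exon_id: str
    chrom: str
    start: int        # 0-based half-open, == CDS interval (CDS-only parsing)
    end: int
    strand: str
    cds_start: int
    cds_end: int
    gene_id: str

    @property
    def cds_len(self) -> int:
        return self.cds_end - self.cds_start


def exon_identifier(chrom: str, cds_start: int, cds_end: int, strand: str) -> str:
    """Display identifier, 1-based inclusive."""
    return f"{chrom}:{cds_start + 1}-{cds_end}:{strand}"


@dataclass
class Isoform:
    isoform_id: str
    gene_id: str
    exon_ids: list[str]                  # transcript 5'->3' order
    protein: str
    introns: list[IntronPosition]
    is_novel: bool = False
    exon_residue_spans: list[tuple[int, int]] = field(default_factory=list)

    def position_class(self, index: int) -> str:
        n = len(self.exon_ids)
        if n == 1:
            return "single"
        if index == 0:
            return "first"
        if index == n - 1:
            return "last"
        return "internal"

    def exon_index(self, exon_id: str) -> int:
        return self.exon_ids.index(exon_id)


@dataclass
class GeneModel:
    gene_id: str
    species: str
    isoforms: dict[str, Isoform] = field(default_factory=dict)
    exons: dict[str, CodingExon] = field(default_factory=dict)
    orthogroup_id: Optional[str] = None
    overlap_groups: dict[str, str] = field(default_factory=dict)

    def span(self) -> tuple[int, int]:
        starts = [e.cds_start for e in self.exons.values()]
        ends = [e.cds_end for e in self.exons.values()]
        return min(starts), max(ends)


# ---------------------------------------------------------------------------
# parsing


def _read_fasta(path: str | Path) -> dict[str, str]:
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _residue_spans(cds_lengths: Sequence[int], protein_len: int) -> list[tuple[int, int]]:
    """Residue interval (half-open) covered by each exon; split codons belong
    to both flanking exons.  The trailing stop codon is excluded."""
    coding_nt = 3 * protein_len
    spans = []
    cum = 0
    for ln in cds_lengths:
        lo = min(cum, coding_nt)
        hi = min(cum + ln, coding_nt)
        spans.append((lo // 3, -(-hi // 3)))  # floor / ceil division
        cum += ln
    return spans


def _build_isoform(isoform_id: str, gene_id: str, cds_parts: list[tuple[int, int]],
                   chrom: str, strand: str, genome_seq: str,
                   is_novel: bool = False) -> tuple[Optional[Isoform], list[CodingExon], Optional[str]]:
    """Assemble an isoform from sorted genomic CDS intervals.

    Returns (isoform, exons, problem); isoform is None when the transcript is
    rejected (frame violation or internal stop), with the reason in problem.
    """
    parts = sorted(cds_parts)
    if strand == "-":
        tx_parts = parts[::-1]
    else:
        tx_parts = parts
    segs = []
    for s, e in tx_parts:
        seg = genome_seq[s:e]
        segs.append(_revcomp(seg) if strand == "-" else seg)
    cds = "".join(segs)
    if len(cds) % 3 != 0:
        return None, [], f"CDS length {len(cds)} not a multiple of 3"
    protein = str(Seq(cds).translate())
    if protein.endswith("*"):
        protein = protein[:-1]
    if "*" in protein:
        return None, [], "internal stop codon"
    if not protein:
        return None, [], "empty protein"
    exons = [CodingExon(exon_id=exon_identifier(chrom, s, e, strand), chrom=chrom,
                        start=s, end=e, strand=strand, cds_start=s, cds_end=e,
                        gene_id=gene_id)
             for s, e in tx_parts]
    lengths = [e.cds_len for e in exons]
    coding_nt = 3 * len(protein)
    introns = []
    cum = 0
    for i in range(len(exons) - 1):
        cum += lengths[i]
        nt = min(cum, coding_nt)
        introns.append(IntronPosition(residue_offset=nt // 3, phase=nt % 3,
                                      side_exons=(exons[i].exon_id, exons[i + 1].exon_id)))
    iso = Isoform(isoform_id=isoform_id, gene_id=gene_id,
                  exon_ids=[e.exon_id for e in exons], protein=protein,
                  introns=introns, is_novel=is_novel,
                  exon_residue_spans=_residue_spans(lengths, len(protein)))
    return iso, exons, None


def parse_annotation(gtf_path: str | Path, genome: str | Path | dict[str, str],
                     species_id: str) -> dict[str, GeneModel]:
    """Parse a GTF (CDS features) plus genome FASTA into gene models.

    Transcripts with out-of-frame CDS or internal stop codons are excluded
    with a logged warning.  A CDS on a chromosome missing from the FASTA is a
    hard error naming the chromosome.
    """
    seqs = genome if isinstance(genome, dict) else _read_fasta(genome)
    db = gffutils.create_db(str(gtf_path), ":memory:", force=True,
                            disable_infer_genes=True, disable_infer_transcripts=True,
                            merge_strategy="create_unique", keep_order=True)
    transcripts: dict[tuple[str, str], dict] = {}
    for feat in db.features_of_type("CDS"):
        try:
            gene_id = feat["gene_id"][0]
            tx_id = feat["transcript_id"][0]
        except KeyError as exc:
            raise AnnotationError(f"CDS feature missing {exc} attribute") from None
        if feat.seqid not in seqs:
            raise AnnotationError(
                f"chromosome {feat.seqid!r} referenced by {gene_id} is missing from the genome FASTA")
        rec = transcripts.setdefault((gene_id, tx_id), {
            "chrom": feat.seqid, "strand": feat.strand, "parts": []})
        rec["parts"].append((feat.start - 1, feat.end))  # to 0-based half-open
    models: dict[str, GeneModel] = {}
    for (gene_id, tx_id), rec in sorted(transcripts.items()):
        iso, exons, problem = _build_isoform(
            tx_id, gene_id, rec["parts"], rec["chrom"], rec["strand"],
            seqs[rec["chrom"]])
        if iso is None:
            logger.warning("excluding transcript %s of %s: %s", tx_id, gene_id, problem)
            continue
        gene = models.setdefault(gene_id, GeneModel(gene_id=gene_id, species=species_id))
        gene.isoforms[tx_id] = iso
        for ex in exons:
            gene.exons.setdefault(ex.exon_id, ex)
    for gene in models.values():
        group_overlapping_exons(gene)
    return models


# ---------------------------------------------------------------------------
# model operations


def collapse_redundant_isoforms(gene: GeneModel) -> GeneModel:
    """Collapse isoforms with identical (protein, intron position/phase
    profile) to the lexicographically smallest isoform id."""
    by_profile: dict[tuple, str] = {}
    keep: dict[str, Isoform] = {}
    for iso_id in sorted(gene.isoforms):
        iso = gene.isoforms[iso_id]
        profile = (iso.protein, tuple((i.residue_offset, i.phase) for i in iso.introns))
        if profile not in by_profile:
            by_profile[profile] = iso_id
            keep[iso_id] = iso
    gene.isoforms = keep
    return gene


def group_overlapping_exons(gene: GeneModel) -> dict[str, str]:
    """Assign overlap groups: connected components of CDS-interval overlap on
    the same strand (transitive closure).  Group ids are ordinals by smallest
    member start."""
    by_strand: dict[str, list[CodingExon]] = {}
    for ex in gene.exons.values():
        by_strand.setdefault(ex.strand, []).append(ex)
    components: list[list[CodingExon]] = []
    for strand, exons in by_strand.items():
        exons.sort(key=lambda e: (e.cds_start, e.cds_end))
        current: list[CodingExon] = []
        reach = -1
        for ex in exons:
            if current and ex.cds_start < reach:  # overlap (half-open intervals)
                current.append(ex)
                reach = max(reach, ex.cds_end)
            else:
                if current:
                    components.append(current)
                current = [ex]
                reach = ex.cds_end
        if current:
            components.append(current)
    components.sort(key=lambda c: (min(e.cds_start for e in c), c[0].chrom))
    gene.overlap_groups = {}
    for n, comp in enumerate(components, start=1):
        gid = f"{gene.gene_id}.og{n}"
        for ex in comp:
            gene.overlap_groups[ex.exon_id] = gid
    return gene.overlap_groups


@dataclass(frozen=True)
class ExtraExonRecord:
    """A non-annotated exon with its two neighbor exons, all as genomic
    intervals (parsed from ``chrom:start-end`` 1-based strings)."""

    gene_id: str
    exon: tuple[str, int, int]
    upstream: tuple[str, int, int]
    downstream: tuple[str, int, int]


_COORD_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+)$")


def parse_coord(text: str) -> tuple[str, int, int]:
    m = _COORD_RE.match(text.strip())
    if not m:
        raise AnnotationError(f"malformed coordinate {text!r} (expected chrom:start-end)")
    return m.group("chrom"), int(m.group("start")) - 1, int(m.group("end"))


def read_extra_exons(path: str | Path) -> list[ExtraExonRecord]:
    records = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise AnnotationError(f"{path}:{ln}: expected 4 tab-separated fields")
            records.append(ExtraExonRecord(fields[0], parse_coord(fields[1]),
                                           parse_coord(fields[2]), parse_coord(fields[3])))
    return records


def _interval_overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def integrate_extra_exons(models: dict[str, GeneModel], records: Iterable[ExtraExonRecord],
                          genome: dict[str, str]) -> tuple[dict[str, GeneModel], list[tuple[ExtraExonRecord, str]]]:
    """Insert each non-annotated exon as a novel isoform of its gene.

    The template transcript is the annotated isoform whose consecutive exons
    exactly match both neighbors; the fallback accepts a single exact neighbor
    match, then plain coordinate overlap.  Novel isoforms are kept only when
    the resulting CDS stays in frame and stop-free; failures are returned as
    ``(record, reason)`` pairs.
    """
    unplaced: list[tuple[ExtraExonRecord, str]] = []
    counters: dict[str, int] = {}
    for rec in records:
        gene = models.get(rec.gene_id)
        if gene is None:
            unplaced.append((rec, "unknown gene"))
            continue
        chrom, ex_start, ex_end = rec.exon
        lo, hi = gene.span()
        if ex_end <= lo or ex_start >= hi:
            unplaced.append((rec, "exon coordinates outside gene span"))
            continue
        template = _find_template(gene, rec)
        if template is None:
            unplaced.append((rec, "no template transcript"))
            continue
        iso = gene.isoforms[template]
        parts = [(gene.exons[e].cds_start, gene.exons[e].cds_end) for e in iso.exon_ids]
        if any(_interval_overlap((ex_start, ex_end), p) for p in parts):
            unplaced.append((rec, "exon overlaps template exons"))
            continue
        new_parts = sorted(parts + [(ex_start, ex_end)])
        counters[rec.gene_id] = counters.get(rec.gene_id, 0) + 1
        novel_id = f"{rec.gene_id}.novel{counters[rec.gene_id]}"
        strand = gene.exons[iso.exon_ids[0]].strand
        new_iso, exons, problem = _build_isoform(novel_id, rec.gene_id, new_parts,
                                                 chrom, strand, genome[chrom],
                                                 is_novel=True)
        if new_iso is None:
            unplaced.append((rec, problem or "translation failed"))
            continue
        gene.isoforms[novel_id] = new_iso
        for ex in exons:
            gene.exons.setdefault(ex.exon_id, ex)
        group_overlapping_exons(gene)
    return models, unplaced


def _find_template(gene: GeneModel, rec: ExtraExonRecord) -> Optional[str]:
    up = rec.upstream[1:]
    down = rec.downstream[1:]
    exact_both, exact_one, overlapping = [], [], []
    for iso_id in sorted(gene.isoforms):
        iso = gene.isoforms[iso_id]
        if iso.is_novel:
            continue
        ivs = [(gene.exons[e].cds_start, gene.exons[e].cds_end) for e in iso.exon_ids]
        genomic = sorted(ivs)
        has_up_exact = up in genomic
        has_down_exact = down in genomic
        # exact-both additionally requires the neighbors to be genomically adjacent
        if has_up_exact and has_down_exact:
            iu, idn = genomic.index(min(up, down)), genomic.index(max(up, down))
            if idn == iu + 1:
                exact_both.append(iso_id)
                continue
        if has_up_exact or has_down_exact:
            exact_one.append(iso_id)
        elif any(_interval_overlap(up, iv) or _interval_overlap(down, iv) for iv in genomic):
            overlapping.append(iso_id)
    for pool in (exact_both, exact_one, overlapping):
        if pool:
            return pool[0]
    return None


# ---------------------------------------------------------------------------
# output


def write_gtf(models: dict[str, GeneModel], out: str | Path | TextIO) -> None:
    """Emit all isoforms as CDS features (round-trippable by
    :func:`parse_annotation`)."""
    own = isinstance(out, (str, Path))
    fh = open(out, "w") if own else out
    try:
        for gene_id in sorted(models):
            gene = models[gene_id]
            for iso_id in sorted(gene.isoforms):
                iso = gene.isoforms[iso_id]
                cum = 0
                for exon_id in iso.exon_ids:
                    ex = gene.exons[exon_id]
                    frame = (3 - cum % 3) % 3
                    cum += ex.cds_len
                    attrs = f'gene_id "{gene_id}"; transcript_id "{iso_id}";'
                    fh.write("\t".join([ex.chrom, "exhom", "CDS", str(ex.cds_start + 1),
                                        str(ex.cds_end), ".", ex.strand, str(frame),
                                        attrs]) + "\n")
    finally:
        if own:
            fh.close()


def exon_reference_table(models: dict[str, GeneModel]):
    """Per-species exon reference rows: exon_id, gene_id, position classes
    observed across isoforms, overlap group."""
    import pandas as pd

    rows = []
    for gene_id in sorted(models):
        gene = models[gene_id]
        classes: dict[str, set] = {e: set() for e in gene.exons}
        for iso in gene.isoforms.values():
            for i, exon_id in enumerate(iso.exon_ids):
                classes[exon_id].add(iso.position_class(i))
        for exon_id in sorted(gene.exons):
            rows.append({
                "exon_id": exon_id,
                "gene_id": gene_id,
                "position_class": ",".join(sorted(classes[exon_id])) or "unused",
                "overlap_group_id": gene.overlap_groups.get(exon_id, ""),
            })
    return pd.DataFrame(rows, columns=["exon_id", "gene_id", "position_class", "overlap_group_id"])
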