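"""Annotation parsing: phases, strands, redundancy, overlap groups, extra
exons, and round-trips."""

import random

import pytest
from Bio.Seq import Seq

from exhom import annotation
from exhom.annotation import (AnnotationError, collapse_redundant_isoforms,
                              group_overlapping_exons, integrate_extra_exons,
                              parse_annotation, write_gtf)

from conftest import build_species, codons, write_gtf_fasta


def parse(tmp_path, genome, gtf, species="toy"):
    gtf_path, fasta = write_gtf_fasta(tmp_path, genome, gtf)
    return parse_annotation(gtf_path, fasta, species)


def test_two_exon_gene_phase_arithmetic(tmp_path):
    # CDS lengths 100 + 50 nt -> 50-residue protein, one intron of phase 100 mod 3 = 1
    cds = codons("M" + "A" * 49)
    genome, gtf = build_species([{"gene_id": "g1", "exons": [cds[:100], cds[100:]]}])
    models = parse(tmp_path, genome, gtf)
    iso = models["g1"].isoforms["g1.t1"]
    assert len(iso.protein) == 50
    assert [(i.residue_offset, i.phase) for i in iso.introns] == [(33, 1)]
    assert iso.position_class(0) == "first" and iso.position_class(1) == "last"


def test_single_exon_transcript(tmp_path):
    genome, gtf = build_species([{"gene_id": "g1", "exons": [codons("MHELLQ")]}])
    models = parse(tmp_path, genome, gtf)
    iso = models["g1"].isoforms["g1.t1"]
    assert iso.introns == []
    assert iso.position_class(0) == "single"
    assert iso.protein == "MHELLQ"


def test_minus_strand_gene_matches_plus_strand(tmp_path):
    """A three-exon gene placed on either strand yields the same protein and
    phases; the hand oracle translates the spliced CDS directly."""
    protein = "MKPGFTDHELWRN"  # 13 aa, 39 nt
    cds = codons(protein)
    exons = [cds[:8], cds[8:21], cds[21:]]  # phases 8%3=2, 21%3=0
    results = {}
    for strand in "+-":
        genome, gtf = build_species([{"gene_id": "g1", "strand": strand, "exons": exons}])
        models = parse(tmp_path / strand.replace("-", "m").replace("+", "p"), genome, gtf)
        iso = models["g1"].isoforms["g1.t1"]
        results[strand] = (iso.protein, [(i.residue_offset, i.phase) for i in iso.introns])
    oracle = str(Seq("".join(exons)).translate())
    assert results["+"] == (oracle, [(2, 2), (7, 0)])
    assert results["-"] == results["+"]


def test_out_of_frame_and_internal_stop_transcripts_excluded(tmp_path, caplog):
    ok = codons("MAAAG")
    frameshift = ok[:-1]                      # 14 nt, not a multiple of 3
    stopped = codons("MA") + "TAA" + codons("AG")
    genome, gtf = build_species([
        {"gene_id": "g1", "exons": [ok]},
        {"gene_id": "g2", "exons": [frameshift]},
        {"gene_id": "g3", "exons": [stopped]},
    ])
    with caplog.at_level("WARNING"):
        models = parse(tmp_path, genome, gtf)
    assert set(models) == {"g1"}
    assert "multiple of 3" in caplog.text and "stop" in caplog.text


def test_missing_chromosome_is_hard_error(tmp_path):
    genome, gtf = build_species([{"gene_id": "g1", "exons": [codons("MAAAG")]}])
    gtf = gtf.replace("chr1", "chrX")
    with pytest.raises(AnnotationError, match="chrX"):
        parse(tmp_path, genome, gtf)


def test_collapse_redundant_isoforms(tmp_path):
    cds = codons("M" + "A" * 20)
    half = len(cds) // 2 // 3 * 3  # split on a codon boundary (phase 0)
    genome, gtf = build_species([{
        "gene_id": "g1",
        "exons": [cds[:half], cds[half:]],
        "transcripts": {"g1.t1": [0, 1], "g1.t2": [0, 1]},
    }])
    models = parse(tmp_path, genome, gtf)
    gene = collapse_redundant_isoforms(models["g1"])
    assert list(gene.isoforms) == ["g1.t1"]  # identical profiles -> smallest id kept

    # same protein but a different intron profile must be retained
    genome2, gtf2 = build_species([
        {"gene_id": "g2", "exons": [cds[:half], cds[half:]],
         "transcripts": {"g2.t1": [0, 1]}},
        {"gene_id": "g2x", "exons": [cds[:half - 3], cds[half - 3:]],
         "transcripts": {"g2.t9": [0, 1]}},
    ])
    gtf2 = gtf2.replace('gene_id "g2x"', 'gene_id "g2"')
    models2 = parse(tmp_path / "b", genome2, gtf2)
    gene2 = collapse_redundant_isoforms(models2["g2"])
    assert len(gene2.isoforms) == 2


def _overlap_components_bruteforce(intervals):
    n = len(intervals)
    adj = {i: set() for i in range(n)}
    for i in range(n):
        for j in range(i + 1, n):
            a, b = intervals[i], intervals[j]
            if min(a[1], b[1]) > max(a[0], b[0]):
                adj[i].add(j)
                adj[j].add(i)
    seen, comps = set(), []
    for i in range(n):
        if i in seen:
            continue
        stack, comp = [i], set()
        while stack:
            k = stack.pop()
            if k in comp:
                continue
            comp.add(k)
            stack.extend(adj[k])
        seen |= comp
        comps.append(frozenset(comp))
    return set(comps)


@pytest.mark.parametrize("intervals,expected_groups", [
    ([(100, 200), (100, 230)], 1),
    ([(100, 200), (300, 400)], 2),
    ([(100, 200), (190, 260), (250, 300)], 1),  # transitive chain of 3
    ([(100, 200), (190, 260), (250, 300), (500, 520)], 2),
])
def test_overlap_groups_match_bruteforce_closure(intervals, expected_groups):
    gene = annotation.GeneModel(gene_id="g", species="s")
    for k, (s, e) in enumerate(intervals):
        ex = annotation.CodingExon(exon_id=f"e{k}", chrom="chr1", start=s, end=e,
                                   strand="+", cds_start=s, cds_end=e, gene_id="g")
        gene.exons[ex.exon_id] = ex
    groups = group_overlapping_exons(gene)
    got = {}
    for k in range(len(intervals)):
        got.setdefault(groups[f"e{k}"], set()).add(k)
    assert len(got) == expected_groups
    assert {frozenset(c) for c in got.values()} == _overlap_components_bruteforce(intervals)


def test_gtf_round_trip_preserves_proteins_and_phases(tmp_path, zero_div_run):
    data, models, _, _ = zero_div_run
    sp_models = models["alpha"]
    out = tmp_path / "roundtrip.gtf"
    write_gtf(sp_models, out)
    genome = data.genomes["alpha"]
    reparsed = parse_annotation(out, genome, "alpha")
    assert set(reparsed) == set(sp_models)
    for gene_id, gene in sp_models.items():
        for iso_id, iso in gene.isoforms.items():
            iso2 = reparsed[gene_id].isoforms[iso_id]
            assert iso2.protein == iso.protein
            assert [(i.residue_offset, i.phase) for i in iso2.introns] == \
                   [(i.residue_offset, i.phase) for i in iso.introns]


def test_phase_invariant_naive_rescan(zero_div_run):
    """Independent re-scan: every intron phase equals the cumulative CDS
    length mod 3, and isoform CDS totals are multiples of 3."""
    _, models, _, _ = zero_div_run
    for gene in models["beta"].values():
        for iso in gene.isoforms.values():
            lengths = [gene.exons[e].cds_len for e in iso.exon_ids]
            assert sum(lengths) % 3 == 0
            cum = 0
            for i, intron in enumerate(iso.introns):
                cum += lengths[i]
                assert intron.phase == cum % 3
                assert intron.residue_offset == cum // 3


def test_strand_symmetry(tmp_path):
    """Reverse-complementing the genome and flipping all strands leaves
    proteins and intron profiles unchanged."""
    from exhom import simulate

    data = simulate.generate(simulate.EvolutionScenario(seed=3, n_genes=6))
    paths = data.write(tmp_path)
    models = parse_annotation(paths["alpha"]["gtf"], paths["alpha"]["fasta"], "alpha")

    genome = data.genomes["alpha"]
    flipped_genome = {c: str(Seq(s).reverse_complement()) for c, s in genome.items()}
    lengths = {c: len(s) for c, s in genome.items()}
    flipped_lines = []
    for line in data.gtfs["alpha"].splitlines():
        f = line.split("\t")
        L = lengths[f[0]]
        s, e = int(f[3]), int(f[4])
        f[3], f[4] = str(L - e + 1), str(L - s + 1)
        f[6] = "-" if f[6] == "+" else "+"
        flipped_lines.append("\t".join(f))
    gtf_path, fasta = write_gtf_fasta(tmp_path / "flip", flipped_genome,
                                      "\n".join(flipped_lines) + "\n")
    flipped = parse_annotation(gtf_path, fasta, "alpha")
    assert set(flipped) == set(models)
    for gene_id in models:
        for iso_id, iso in models[gene_id].isoforms.items():
            iso2 = flipped[gene_id].isoforms[iso_id]
            assert iso2.protein == iso.protein
            assert [(i.residue_offset, i.phase) for i in iso2.introns] == \
                   [(i.residue_offset, i.phase) for i in iso.introns]


class TestExtraExons:
    def _gene(self, tmp_path, novel_len_aa=7):
        protein = "M" + "A" * 9 + "G" * 10 + "L" * 10
        cds = codons(protein)
        exons = [cds[:30], cds[30:60], cds[60:]]
        genome, gtf = build_species([{"gene_id": "g1", "exons": exons, "intron_len": 60}])
        models = parse(tmp_path, genome, gtf)
        return models, genome

    def test_exact_neighbor_template(self, tmp_path):
        models, genome = self._gene(tmp_path)
        gene = models["g1"]
        ex = [gene.exons[e] for e in gene.isoforms["g1.t1"].exon_ids]
        novel_cds = codons("WWWWWWW", seed=5)  # 21 nt, frame preserved
        start = ex[0].cds_end + 10
        genome["chr1"] = (genome["chr1"][:start] + novel_cds
                          + genome["chr1"][start + len(novel_cds):])
        rec = annotation.ExtraExonRecord(
            gene_id="g1", exon=("chr1", start, start + 21),
            upstream=("chr1", ex[0].cds_start, ex[0].cds_end),
            downstream=("chr1", ex[1].cds_start, ex[1].cds_end))
        models, unplaced = integrate_extra_exons(models, [rec], genome)
        assert unplaced == []
        novel = [i for i in models["g1"].isoforms.values() if i.is_novel]
        assert len(novel) == 1
        assert "WWWWWWW" in novel[0].protein
        assert len(novel[0].exon_ids) == 4

    def test_frame_breaking_exon_unplaced(self, tmp_path):
        models, genome = self._gene(tmp_path)
        gene = models["g1"]
        ex = [gene.exons[e] for e in gene.isoforms["g1.t1"].exon_ids]
        start = ex[0].cds_end + 10
        rec = annotation.ExtraExonRecord(
            gene_id="g1", exon=("chr1", start, start + 20),  # 20 nt breaks frame
            upstream=("chr1", ex[0].cds_start, ex[0].cds_end),
            downstream=("chr1", ex[1].cds_start, ex[1].cds_end))
        models, unplaced = integrate_extra_exons(models, [rec], genome)
        assert len(unplaced) == 1 and "multiple of 3" in unplaced[0][1]
        assert not any(i.is_novel for i in models["g1"].isoforms.values())

    def test_exon_outside_gene_span_rejected(self, tmp_path):
        models, genome = self._gene(tmp_path)
        gene = models["g1"]
        ex = [gene.exons[e] for e in gene.isoforms["g1.t1"].exon_ids]
        rec = annotation.ExtraExonRecord(
            gene_id="g1", exon=("chr1", 1, 10),
            upstream=("chr1", ex[0].cds_start, ex[0].cds_end),
            downstream=("chr1", ex[1].cds_start, ex[1].cds_end))
        _, unplaced = integrate_extra_exons(models, [rec], genome)
        assert len(unplaced) == 1 and "outside gene span" in unplaced[0][1]
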