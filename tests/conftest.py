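import random
from pathlib import Path

import pytest

from exhom import pipeline, simulate


def build_species(genes, spacer=100):
    """Assemble a toy single-chromosome annotation.

    ``genes``: list of dicts with gene_id, strand, exons (list of CDS nt
    strings in transcript order), intron_len, and optional transcripts
    mapping tx_id -> list of exon indices (default: one using all exons).
    Returns (genome_dict, gtf_text).
    """
    rng = random.Random(123)
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    chrom_parts, gtf_lines = [], []
    pos = 0
    for gene in genes:
        pos += spacer
        chrom_parts.append("".join(rng.choice("ACGT") for _ in range(spacer)))
        intron_len = gene.get("intron_len", 50)
        region_parts, exon_spans, rpos = [], [], 0
        for i, seq in enumerate(gene["exons"]):
            exon_spans.append((rpos, rpos + len(seq)))
            region_parts.append(seq)
            rpos += len(seq)
            if i < len(gene["exons"]) - 1:
                region_parts.append("".join(rng.choice("ACGT") for _ in range(intron_len)))
                rpos += intron_len
        region = "".join(region_parts)
        strand = gene.get("strand", "+")
        if strand == "+":
            genomic = [(pos + a, pos + b) for a, b in exon_spans]
            chrom_parts.append(region)
        else:
            rlen = len(region)
            genomic = [(pos + rlen - b, pos + rlen - a) for a, b in exon_spans]
            chrom_parts.append("".join(comp[c] for c in reversed(region)))
        pos += len(region)
        transcripts = gene.get("transcripts") or {f"{gene['gene_id']}.t1": list(range(len(gene["exons"])))}
        for tx_id, idxs in transcripts.items():
            cum = 0
            for i in idxs:
                s, e = genomic[i]
                frame = (3 - cum % 3) % 3
                cum += e - s
                gtf_lines.append("\t".join([
                    "chr1", "test", "CDS", str(s + 1), str(e), ".", strand,
                    str(frame), f'gene_id "{gene["gene_id"]}"; transcript_id "{tx_id}";']))
    return {"chr1": "".join(chrom_parts)}, "\n".join(gtf_lines) + "\n"


def codons(protein, seed=0):
    """Deterministic codon encoding of a protein (no stop codon appended)."""
    from Bio.Data import CodonTable

    back = {}
    for codon, aa in sorted(CodonTable.unambiguous_dna_by_id[1].forward_table.items()):
        back.setdefault(aa, []).append(codon)
    rng = random.Random(seed)
    return "".join(rng.choice(back[aa]) for aa in protein)


def write_gtf_fasta(tmp_path: Path, genome: dict, gtf: str, prefix="sp"):
    tmp_path.mkdir(parents=True, exist_ok=True)
    fasta = tmp_path / f"{prefix}.fasta"
    with open(fasta, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n{seq}\n")
    gtf_path = tmp_path / f"{prefix}.gtf"
    gtf_path.write_text(gtf)
    return gtf_path, fasta


def run_on_fixture(data: simulate.SimulatedData, tmp_path: Path, ranges=None,
                   **infer_kwargs):
    paths = data.write(tmp_path)
    species = [name for name, _ in data.scenario.species]
    models = {sp: pipeline.load_species(pipeline.SpeciesInput(sp, paths[sp]["gtf"], paths[sp]["fasta"]))
              for sp in species}
    og = pipeline.load_gene_orthogroups(paths["shared"]["orthogroups"])
    if ranges is None:
        import itertools
        ranges = {frozenset(p): "short" for p in itertools.combinations(species, 2)}
    result = pipeline.infer_orthologies(models, og, ranges, **infer_kwargs)
    return models, og, result


ZERO_DIV_SCENARIO = simulate.EvolutionScenario(seed=11, n_genes=50)

MODERATE_SCENARIO = simulate.EvolutionScenario(
    seed=7, n_genes=50, species=(("alpha", 0.05), ("beta", 0.05)),
    intron_gain_rate=0.02, intron_loss_rate=0.02, exon_dup_rate=0.02,
    exon_loss_rate=0.02, splice_shift_rate=0.05)


@pytest.fixture(scope="session")
def zero_div_run(tmp_path_factory):
    data = simulate.generate(ZERO_DIV_SCENARIO)
    tmp = tmp_path_factory.mktemp("zero_div")
    models, og, result = run_on_fixture(data, tmp)
    return data, models, og, result


@pytest.fixture(scope="session")
def moderate_run(tmp_path_factory):
    data = simulate.generate(MODERATE_SCENARIO)
    tmp = tmp_path_factory.mktemp("moderate")
    models, og, result = run_on_fixture(data, tmp)
    return data, models, og, result
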