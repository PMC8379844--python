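"""Synthetic multi-species genomes with planted exon homologies.

The generator builds ancestral multi-exon coding genes (a random protein,
intron positions with phases), evolves each terminal branch of a star
species tree independently (amino-acid substitutions plus structural events:
intron gain/loss, in-tandem exon duplication, exon loss, splice-site
shifts), and emits per-species genome FASTA + GTF + a gene orthogroup table
+ a truth table of planted exon homologies keyed by ancestral exon identity.

Mutation acts at the amino-acid level and is re-encoded through uniformly
chosen codons of the target residue - the homology method only ever sees
proteins and intron phases, so nucleotide-level realism is deliberately out
of scope.  Structural events are restricted to phase-0 exon flanks, which
keeps every emitted CDS frame-intact and stop-free by construction.

Truth bookkeeping: an exon keeps its ancestral identity through substitution
and duplication (both tandem copies map to the same ancestor); intron gain
or loss *redefines* the affected exons, which therefore receive fresh
identities with no cross-species ortholog.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
from Bio.Data import CodonTable

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_BACK_TABLE: dict[str, list[str]] = {}
for _codon, _aa in sorted(CodonTable.unambiguous_dna_by_id[1].forward_table.items()):
    _BACK_TABLE.setdefault(_aa, []).append(_codon)


class ScenarioError(ValueError):
    pass


@dataclass(frozen=True)
class EvolutionScenario:
    """Study conditions for one synthetic data set.

    Branch substitution probabilities are per residue per terminal branch;
    event rates are per gene per branch probabilities.
    """

    seed: int = 0
    n_genes: int = 50
    exons_per_gene: tuple[int, int] = (3, 8)        # uniform inclusive
    exon_len_aa: tuple[int, int] = (20, 60)         # residues per exon
    species: tuple[tuple[str, float], ...] = (("alpha", 0.0), ("beta", 0.0))
    intron_gain_rate: float = 0.0
    intron_loss_rate: float = 0.0
    exon_dup_rate: float = 0.0
    exon_loss_rate: float = 0.0
    splice_shift_rate: float = 0.0
    skip_isoform_prob: float = 0.5                  # exon-skipping second isoform
    intron_len: tuple[int, int] = (80, 200)
    spacer_len: int = 200
    minus_strand_prob: float = 0.3

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ScenarioError("n_genes must be positive")
        if self.exons_per_gene[0] < 1 or self.exons_per_gene[0] > self.exons_per_gene[1]:
            raise ScenarioError("invalid exons_per_gene range")
        if self.exon_len_aa[0] < 3:
            raise ScenarioError("exons shorter than 3 residues are not supported")
        if len(self.species) < 2:
            raise ScenarioError("at least two species required")
        if self.exon_loss_rate > 0 and self.exons_per_gene[1] < 3:
            raise ScenarioError("exon loss requires genes with internal exons")
        for name, rate in [("intron_gain_rate", self.intron_gain_rate),
                           ("intron_loss_rate", self.intron_loss_rate),
                           ("exon_dup_rate", self.exon_dup_rate),
                           ("exon_loss_rate", self.exon_loss_rate),
                           ("splice_shift_rate", self.splice_shift_rate),
                           ("skip_isoform_prob", self.skip_isoform_prob)]:
            if not 0 <= rate <= 1:
                raise ScenarioError(f"{name} must lie in [0, 1]")
        for _, sub in self.species:
            if not 0 <= sub <= 1:
                raise ScenarioError("substitution probabilities must lie in [0, 1]")
        if self.intron_len[0] < 10:
            raise ScenarioError("introns must be at least 10 nt")


@dataclass
class _GeneState:
    protein: str
    introns: list[tuple[int, int]]       # (residue_offset, phase), sorted
    exon_anc: list[str]                  # ancestral identity per segment
    events: list[str] = field(default_factory=list)
    shift: Optional[tuple[int, str]] = None  # (exon index, extra residue)

    def copy(self) -> "_GeneState":
        return _GeneState(self.protein, list(self.introns), list(self.exon_anc),
                          list(self.events), self.shift)


def _segment_bounds(state: _GeneState) -> list[tuple[int, int]]:
    """Residue offsets flanking each exon segment (phase ignored)."""
    offs = [0] + [o for o, _ in state.introns] + [len(state.protein)]
    return list(zip(offs[:-1], offs[1:]))


def _phase0_internal_candidates(state: _GeneState) -> list[int]:
    out = []
    for j in range(1, len(state.exon_anc) - 1):
        if state.introns[j - 1][1] == 0 and state.introns[j][1] == 0:
            out.append(j)
    return out


def _mutate_protein(protein: str, rate: float, rng: random.Random) -> str:
    if rate <= 0:
        return protein
    out = []
    for aa in protein:
        if rng.random() < rate:
            choices = AMINO_ACIDS.replace(aa, "")
            out.append(rng.choice(choices))
        else:
            out.append(aa)
    return "".join(out)


def _evolve_branch(state: _GeneState, sub_rate: float, sc: EvolutionScenario,
                   rng: random.Random, fresh: list[int]) -> _GeneState:
    st = state.copy()
    st.protein = _mutate_protein(st.protein, sub_rate, rng)

    def fresh_id() -> str:
        fresh[0] += 1
        return f"n{fresh[0]}"

    if rng.random() < sc.intron_gain_rate and len(st.protein) > 2:
        taken = {o for o, _ in st.introns}
        spots = [x for x in range(1, len(st.protein)) if x not in taken]
        if spots:
            x = rng.choice(spots)
            phase = rng.randrange(3)
            j = sum(1 for o, _ in st.introns if o < x)
            st.introns.insert(j, (x, phase))
            st.exon_anc[j:j + 1] = [fresh_id(), fresh_id()]
            st.events.append(f"intron_gain@{x}.{phase}")

    if rng.random() < sc.intron_loss_rate and st.introns:
        j = rng.randrange(len(st.introns))
        st.introns.pop(j)
        st.exon_anc[j:j + 2] = [fresh_id()]
        st.events.append(f"intron_loss@{j}")

    if rng.random() < sc.exon_dup_rate:
        cands = _phase0_internal_candidates(st)
        if cands:
            j = rng.choice(cands)
            o1, o2 = st.introns[j - 1][0], st.introns[j][0]
            seg = st.protein[o1:o2]
            st.protein = st.protein[:o2] + seg + st.protein[o2:]
            shift = o2 - o1
            st.introns = (st.introns[:j] + [(o2, 0)]
                          + [(o + shift, p) for o, p in st.introns[j:]])
            st.exon_anc.insert(j + 1, st.exon_anc[j])
            st.events.append(f"exon_dup@{j}")

    if rng.random() < sc.exon_loss_rate:
        cands = _phase0_internal_candidates(st)
        if cands:
            j = rng.choice(cands)
            o1, o2 = st.introns[j - 1][0], st.introns[j][0]
            shift = o2 - o1
            st.protein = st.protein[:o1] + st.protein[o2:]
            st.introns = (st.introns[:j - 1] + [(o1, 0)]
                          + [(o - shift, p) for o, p in st.introns[j + 1:]])
            st.exon_anc.pop(j)
            st.events.append(f"exon_loss@{j}")

    if rng.random() < sc.splice_shift_rate:
        cands = [j for j in range(1, len(st.exon_anc) - 1) if st.introns[j - 1][1] == 0]
        if cands:
            j = cands[-1]
            st.shift = (j, rng.choice(AMINO_ACIDS))
            st.events.append(f"splice_shift@{j}")

    return st


def _encode(protein: str, rng: random.Random) -> str:
    return "".join(rng.choice(_BACK_TABLE[aa]) for aa in protein)


def _random_nt(n: int, rng: random.Random) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


@dataclass
class TruthTable:
    """Planted homologies: ancestral identity of every emitted exon."""

    ancestry: dict[tuple[str, str], str]            # (species, exon_id) -> ancestor
    events: dict[tuple[str, str], tuple[str, ...]]  # (species, gene_id) -> events
    gene_orthogroups: pd.DataFrame

    def shared_ancestors(self, species_a: str, species_b: str) -> set[str]:
        anc_a = {a for (sp, _), a in self.ancestry.items() if sp == species_a}
        anc_b = {a for (sp, _), a in self.ancestry.items() if sp == species_b}
        return anc_a & anc_b

    def orthopairs(self, species_a: str, species_b: str) -> set[tuple[str, str]]:
        by_anc_a: dict[str, list[str]] = {}
        by_anc_b: dict[str, list[str]] = {}
        for (sp, exon), anc in self.ancestry.items():
            if sp == species_a:
                by_anc_a.setdefault(anc, []).append(exon)
            elif sp == species_b:
                by_anc_b.setdefault(anc, []).append(exon)
        pairs = set()
        for anc in set(by_anc_a) & set(by_anc_b):
            for ea in by_anc_a[anc]:
                for eb in by_anc_b[anc]:
                    pairs.add((ea, eb))
        return pairs


@dataclass
class SimulatedData:
    scenario: EvolutionScenario
    genomes: dict[str, dict[str, str]]   # species -> {chrom: sequence}
    gtfs: dict[str, str]                 # species -> GTF text
    gene_orthogroups: pd.DataFrame
    truth: TruthTable

    def write(self, outdir: str | Path) -> dict[str, dict[str, Path]]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, dict[str, Path]] = {}
        for sp in self.genomes:
            fa = outdir / f"{sp}.fasta"
            with open(fa, "w") as fh:
                for chrom, seq in self.genomes[sp].items():
                    fh.write(f">{chrom}\n")
                    for i in range(0, len(seq), 80):
                        fh.write(seq[i:i + 80] + "\n")
            gtf = outdir / f"{sp}.gtf"
            gtf.write_text(self.gtfs[sp])
            paths[sp] = {"fasta": fa, "gtf": gtf}
        og = outdir / "gene_orthogroups.tsv"
        self.gene_orthogroups.to_csv(og, sep="\t", header=False, index=False)
        truth = outdir / "truth_exon_ancestry.tsv"
        rows = [{"species": sp, "exon_id": ex, "ancestor": anc}
                for (sp, ex), anc in sorted(self.truth.ancestry.items())]
        pd.DataFrame(rows).to_csv(truth, sep="\t", index=False)
        paths["shared"] = {"orthogroups": og, "truth": truth}
        return paths


def _emit_species(species: str, genes: list[_GeneState], sc: EvolutionScenario,
                  rng: random.Random, skip_genes: set[int],
                  truth: TruthTable) -> tuple[dict[str, str], str]:
    chrom = "chr1"
    genome: list[str] = []
    pos = 0
    gtf_lines: list[str] = []

    def add(seq: str) -> int:
        nonlocal pos
        genome.append(seq)
        start = pos
        pos += len(seq)
        return start

    for gi, state in enumerate(genes):
        gene_id = f"{species}_g{gi}"
        add(_random_nt(sc.spacer_len, rng))
        cds = _encode(state.protein, rng)
        cuts = [3 * o + p for o, p in state.introns]
        segs = [cds[a:b] for a, b in zip([0] + cuts, cuts + [len(cds)])]
        shift_exon, shift_aa = state.shift if state.shift else (None, None)
        intron_seqs = []
        for j in range(len(segs) - 1):
            iseq = _random_nt(rng.randint(*sc.intron_len), rng)
            if shift_exon is not None and j == shift_exon - 1:
                iseq = iseq[:-3] + rng.choice(_BACK_TABLE[shift_aa])
            intron_seqs.append(iseq)
        # transcript-orientation region
        region_parts = []
        exon_spans = []  # within region, transcript order
        rpos = 0
        for j, seg in enumerate(segs):
            exon_spans.append((rpos, rpos + len(seg)))
            region_parts.append(seg)
            rpos += len(seg)
            if j < len(intron_seqs):
                region_parts.append(intron_seqs[j])
                rpos += len(intron_seqs[j])
        region = "".join(region_parts)
        strand = "-" if rng.random() < sc.minus_strand_prob else "+"
        if strand == "+":
            off = add(region)
            genomic = [(off + a, off + b) for a, b in exon_spans]
        else:
            comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
            off = add("".join(comp[c] for c in reversed(region)))
            rlen = len(region)
            genomic = [(off + rlen - b, off + rlen - a) for a, b in exon_spans]

        def exon_id(iv: tuple[int, int]) -> str:
            return f"{chrom}:{iv[0] + 1}-{iv[1]}:{strand}"

        def emit_tx(tx_id: str, intervals: list[tuple[int, int]]) -> None:
            cum = 0
            for iv in intervals:
                frame = (3 - cum % 3) % 3
                cum += iv[1] - iv[0]
                gtf_lines.append("\t".join([
                    chrom, "exhom_sim", "CDS", str(iv[0] + 1), str(iv[1]), ".",
                    strand, str(frame),
                    f'gene_id "{gene_id}"; transcript_id "{tx_id}";']))

        emit_tx(f"{gene_id}.t1", genomic)
        for j, iv in enumerate(genomic):
            truth.ancestry[(species, exon_id(iv))] = f"g{gi}.{state.exon_anc[j]}"
        if gi in skip_genes:
            cands = _phase0_internal_candidates(state)
            if cands:
                jskip = cands[0]
                emit_tx(f"{gene_id}.t2", [iv for j, iv in enumerate(genomic) if j != jskip])
        if shift_exon is not None:
            s, e = genomic[shift_exon]
            ext = (s - 3, e) if strand == "+" else (s, e + 3)
            variants = list(genomic)
            variants[shift_exon] = ext
            emit_tx(f"{gene_id}.t3", variants)
            truth.ancestry[(species, exon_id(ext))] = f"g{gi}.{state.exon_anc[shift_exon]}"
        truth.events[(species, gene_id)] = tuple(state.events)
    return {chrom: "".join(genome)}, "\n".join(gtf_lines) + "\n"


def generate(scenario: EvolutionScenario) -> SimulatedData:
    """Deterministically generate per-species FASTA + GTF + gene orthogroups
    and the planted-homology truth table."""
    sc = scenario
    sc.validate()
    root_rng = random.Random(sc.seed)

    ancestors: list[_GeneState] = []
    for gi in range(sc.n_genes):
        n_ex = root_rng.randint(*sc.exons_per_gene)
        lens = [root_rng.randint(*sc.exon_len_aa) for _ in range(n_ex)]
        protein = "".join(root_rng.choice(AMINO_ACIDS) for _ in range(sum(lens)))
        offsets = []
        cum = 0
        for ln in lens[:-1]:
            cum += ln
            offsets.append(cum)
        introns = [(o, root_rng.randrange(3)) for o in offsets]
        ancestors.append(_GeneState(protein=protein, introns=introns,
                                    exon_anc=[f"e{k}" for k in range(n_ex)]))

    skip_genes = {gi for gi in range(sc.n_genes)
                  if root_rng.random() < sc.skip_isoform_prob}

    truth = TruthTable(ancestry={}, events={}, gene_orthogroups=pd.DataFrame())
    genomes: dict[str, dict[str, str]] = {}
    gtfs: dict[str, str] = {}
    fresh = [0]
    og_rows = []
    for si, (name, sub_rate) in enumerate(sc.species):
        branch_rng = random.Random((sc.seed * 9973 + si * 613 + 17) % (2 ** 31))
        evolved = [_evolve_branch(g, sub_rate, sc, branch_rng, fresh) for g in ancestors]
        genomes[name], gtfs[name] = _emit_species(name, evolved, sc, branch_rng,
                                                  skip_genes, truth)
        og_rows.extend({"cluster_id": f"OG{gi:04d}", "species": name,
                        "gene_id": f"{name}_g{gi}"} for gi in range(sc.n_genes))
    orthogroups = pd.DataFrame(og_rows, columns=["cluster_id", "species", "gene_id"])
    truth.gene_orthogroups = orthogroups
    return SimulatedData(scenario=sc, genomes=genomes, gtfs=gtfs,
                         gene_orthogroups=orthogroups, truth=truth)


# ---------------------------------------------------------------------------
# recovery


def recovery_report(orthopairs: pd.DataFrame, orthogroups: pd.DataFrame,
                    truth: TruthTable, species_a: str, species_b: str) -> dict:
    """Precision/recall of inferred orthopairs and orthogroup agreement
    (adjusted Rand index) against the planted truth.

    Pairs are evaluated at the ancestral-entity level: an inferred pair is
    correct when both exons descend from the same ancestral exon; a planted
    homology is recovered when some inferred pair covers its ancestor in both
    species.
    """
    from sklearn.metrics import adjusted_rand_score

    anc = truth.ancestry
    inferred: set[tuple[str, str]] = set()
    for _, r in orthopairs.iterrows():
        sp1, sp2 = r["species1"], r["species2"]
        if {sp1, sp2} != {species_a, species_b}:
            continue
        if sp1 == species_a:
            inferred.add((r["exon1"], r["exon2"]))
        else:
            inferred.add((r["exon2"], r["exon1"]))
    correct = {(ea, eb) for ea, eb in inferred
               if anc.get((species_a, ea)) is not None
               and anc.get((species_a, ea)) == anc.get((species_b, eb))}
    shared = truth.shared_ancestors(species_a, species_b)
    covered = {anc[(species_a, ea)] for ea, eb in correct}
    precision = len(correct) / len(inferred) if inferred else 1.0
    recall = len(covered) / len(shared) if shared else 1.0

    pred_label: dict[tuple[str, str], str] = {}
    for _, r in orthogroups.iterrows():
        if r["species"] in (species_a, species_b):
            pred_label[(r["species"], r["exon_id"])] = r["og_id"]
    keys = sorted(k for k in anc if k[0] in (species_a, species_b))
    y_true = [anc[k] for k in keys]
    y_pred = [pred_label.get(k, f"singleton:{k[1]}") for k in keys]
    ari = adjusted_rand_score(y_true, y_pred) if keys else 1.0
    return {"precision": precision, "recall": recall, "ari": ari,
            "n_inferred": len(inferred), "n_truth_ancestors": len(shared)}
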