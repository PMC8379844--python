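"""Intron-position-aware (IPA) pairwise protein alignments.

A pairwise global protein alignment is decorated with *intron markers*: for
every intron of either isoform, the alignment column of its residue boundary
plus its phase (0/1/2).  Downstream scoring operates purely on this annotated
alignment; intron sequence and length are never consulted.

The aligner is Needleman-Wunsch with BLOSUM62 and affine gaps (open 11,
extend 1), provided by Biopython's :class:`PairwiseAligner`.  A gap of length
``k`` costs ``11 + (k - 1)``; terminal gaps are penalized (true global mode).
An adapter hook (:func:`set_aligner_backend`) lets callers substitute an
external pairwise aligner while keeping the IPA layer unchanged.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

from Bio.Align import PairwiseAligner, substitution_matrices

logger = logging.getLogger(__name__)

BLOSUM62 = substitution_matrices.load("BLOSUM62")

#: residues accepted in input proteins (20 canonical amino acids plus X)
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

GAP_OPEN = -11.0
GAP_EXTEND = -1.0
GAP = "-"


def _build_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.substitution_matrix = BLOSUM62
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    aligner.mode = "global"
    return aligner

_ALIGNER = _build_aligner()

# pluggable backend: (protein_q, protein_t) -> (gapped_q, gapped_t, score)
_backend: Optional[Callable[[str, str], tuple[str, str, float]]] = None


def set_aligner_backend(backend: Optional[Callable[[str, str], tuple[str, str, float]]]) -> None:
    """Install an alternative pairwise alignment backend (``None`` restores
    the built-in Needleman-Wunsch)."""
    global _backend
    _backend = backend


def validate_protein(seq: str, name: str = "sequence") -> None:
    if not seq:
        raise ValueError(f"{name}: empty protein sequence")
    bad = set(seq) - PROTEIN_ALPHABET
    if bad:
        raise ValueError(
            f"{name}: illegal residue(s) {''.join(sorted(bad))!r} "
            "(allowed: 20 amino acids plus X)"
        )


def align_proteins(protein_q: str, protein_t: str,
                   name_q: str = "query", name_t: str = "target") -> tuple[str, str, float]:
    """Global alignment of two proteins.

    Returns ``(gapped_q, gapped_t, score)``; deterministic for fixed inputs.
    """
    validate_protein(protein_q, name_q)
    validate_protein(protein_t, name_t)
    if _backend is not None:
        return _backend(protein_q, protein_t)
    aln = _ALIGNER.align(protein_q, protein_t)[0]
    return str(aln[0]), str(aln[1]), float(aln.score)


def residues_similar(a: str, b: str) -> bool:
    """Two residues count as similar if identical or BLOSUM62-positive."""
    if a == b:
        return True
    try:
        return BLOSUM62[a, b] > 0
    except KeyError:
        return False


@dataclass(frozen=True)
class AlignmentStats:
    """Species-wise identity / similarity / gap percentages.

    All percentages use the *ungapped* length of the respective sequence as
    denominator.  ``gaps_pct_q`` counts alignment columns where the query has
    a residue opposite a target gap, relative to the query length (and vice
    versa), so each side measures how much of its own sequence is unaligned.
    """

    identity_pct_q: float
    identity_pct_t: float
    similarity_pct_q: float
    similarity_pct_t: float
    gaps_pct_q: float
    gaps_pct_t: float


def compute_stats(gapped_q: str, gapped_t: str) -> AlignmentStats:
    if len(gapped_q) != len(gapped_t):
        raise ValueError("aligned sequences differ in length")
    n_q = sum(1 for c in gapped_q if c != GAP)
    n_t = sum(1 for c in gapped_t if c != GAP)
    ident = simil = gaps_q = gaps_t = 0
    for a, b in zip(gapped_q, gapped_t):
        if a != GAP and b != GAP:
            if a == b:
                ident += 1
            if residues_similar(a, b):
                simil += 1
        elif a != GAP:  # query residue opposite a target gap
            gaps_q += 1
        elif b != GAP:
            gaps_t += 1
    pct = lambda x, n: 100.0 * x / n if n else 0.0
    return AlignmentStats(
        identity_pct_q=pct(ident, n_q), identity_pct_t=pct(ident, n_t),
        similarity_pct_q=pct(simil, n_q), similarity_pct_t=pct(simil, n_t),
        gaps_pct_q=pct(gaps_q, n_q), gaps_pct_t=pct(gaps_t, n_t),
    )


@dataclass(frozen=True)
class IntronMarker:
    """An intron projected onto the alignment: column of its residue
    boundary, phase (0/1/2), and its index along the isoform."""

    column: int
    phase: int
    intron_index: int


def marker_columns(gapped: str, residue_offsets: Sequence[int]) -> list[int]:
    """Map residue boundaries (counts of complete upstream codons) to
    alignment columns.

    The boundary after ``r`` residues is the column following the r-th
    ungapped residue; ``r == 0`` maps to column 0.  At a gap run the boundary
    is left-aligned (placed at the start of the run).
    """
    positions = [i for i, c in enumerate(gapped) if c != GAP]
    cols = []
    for r in residue_offsets:
        if r < 0 or r > len(positions):
            raise ValueError(f"residue offset {r} outside protein of length {len(positions)}")
        cols.append(0 if r == 0 else positions[r - 1] + 1)
    return cols


@dataclass
class IpaAlignment:
    """A pairwise protein alignment with injected intron markers."""

    query_isoform_id: str
    target_isoform_id: str
    aligned_query: str
    aligned_target: str
    query_markers: list[IntronMarker]
    target_markers: list[IntronMarker]
    stats: AlignmentStats
    score: float = 0.0

    def swapped(self) -> "IpaAlignment":
        """The same alignment viewed with query and target exchanged."""
        s = self.stats
        return IpaAlignment(
            query_isoform_id=self.target_isoform_id,
            target_isoform_id=self.query_isoform_id,
            aligned_query=self.aligned_target,
            aligned_target=self.aligned_query,
            query_markers=self.target_markers,
            target_markers=self.query_markers,
            stats=AlignmentStats(
                identity_pct_q=s.identity_pct_t, identity_pct_t=s.identity_pct_q,
                similarity_pct_q=s.similarity_pct_t, similarity_pct_t=s.similarity_pct_q,
                gaps_pct_q=s.gaps_pct_t, gaps_pct_t=s.gaps_pct_q,
            ),
            score=self.score,
        )


def inject_intron_markers(gapped_q: str, gapped_t: str,
                          introns_q: Sequence[tuple[int, int]],
                          introns_t: Sequence[tuple[int, int]],
                          query_isoform_id: str = "query",
                          target_isoform_id: str = "target",
                          score: float = 0.0) -> IpaAlignment:
    """Build an :class:`IpaAlignment` from a gapped pair and the two intron
    lists given as ``(residue_offset, phase)`` tuples."""
    cols_q = marker_columns(gapped_q, [r for r, _ in introns_q])
    cols_t = marker_columns(gapped_t, [r for r, _ in introns_t])
    return IpaAlignment(
        query_isoform_id=query_isoform_id,
        target_isoform_id=target_isoform_id,
        aligned_query=gapped_q,
        aligned_target=gapped_t,
        query_markers=[IntronMarker(c, p, i) for i, (c, (_, p)) in enumerate(zip(cols_q, introns_q))],
        target_markers=[IntronMarker(c, p, i) for i, (c, (_, p)) in enumerate(zip(cols_t, introns_t))],
        stats=compute_stats(gapped_q, gapped_t),
        score=score,
    )


def realign_exon_pair(exon_seq_q: str, exon_seq_t: str) -> float:
    """Global alignment of two exon amino-acid substrings; returns the
    similarity percentage with the query-side denominator.

    Empty input on either side yields 0 (no alignable sequence)."""
    if not exon_seq_q or not exon_seq_t:
        return 0.0
    gq, gt, _ = align_proteins(exon_seq_q, exon_seq_t, "query exon", "target exon")
    simil = sum(1 for a, b in zip(gq, gt)
                if a != GAP and b != GAP and residues_similar(a, b))
    return 100.0 * simil / len(exon_seq_q)


class AlignmentCache:
    """Persist pairwise alignments keyed by a content hash of both proteins.

    Entries are small versioned text files; a corrupt entry is discarded with
    a warning and recomputed."""

    _MAGIC = "#exhom-aln v1"

    def __init__(self, store_dir: str | Path):
        self.dir = Path(store_dir)
        self.dir.mkdir(parents=True, exist_ok=True)

    @staticmethod
    def _key(protein_q: str, protein_t: str) -> str:
        h = hashlib.sha256()
        h.update(protein_q.encode())
        h.update(b"|")
        h.update(protein_t.encode())
        return h.hexdigest()[:32]

    def _path(self, key: str) -> Path:
        return self.dir / f"{key}.aln"

    def get(self, protein_q: str, protein_t: str) -> Optional[tuple[str, str, float]]:
        path = self._path(self._key(protein_q, protein_t))
        if not path.exists():
            return None
        try:
            lines = path.read_text().splitlines()
            if lines[0] != self._MAGIC:
                raise ValueError("bad header")
            score = float(lines[1])
            gq, gt = lines[2], lines[3]
            if gq.replace(GAP, "") != protein_q or gt.replace(GAP, "") != protein_t:
                raise ValueError("stale content")
            return gq, gt, score
        except (IndexError, ValueError) as exc:
            logger.warning("corrupt alignment cache entry %s (%s); recomputing", path.name, exc)
            return None

    def put(self, protein_q: str, protein_t: str, gapped_q: str, gapped_t: str,
            score: float) -> None:
        path = self._path(self._key(protein_q, protein_t))
        path.write_text("\n".join([self._MAGIC, repr(score), gapped_q, gapped_t]) + "\n")


class Aligner:
    """Alignment front end with an optional persistent cache and a counter of
    alignments actually computed (cache hits perform zero alignments)."""

    def __init__(self, cache: Optional[AlignmentCache] = None):
        self.cache = cache
        self.n_computed = 0

    def align(self, protein_q: str, protein_t: str,
              name_q: str = "query", name_t: str = "target") -> tuple[str, str, float]:
        if self.cache is not None:
            hit = self.cache.get(protein_q, protein_t)
            if hit is not None:
                return hit
        gq, gt, score = align_proteins(protein_q, protein_t, name_q, name_t)
        self.n_computed += 1
        if self.cache is not None:
            self.cache.put(protein_q, protein_t, gq, gt, score)
        return gq, gt, score
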