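"""Detection of intronization signatures for candidate gained introns.

If a human intron arose by intronization, orthologs that lack the intron
should retain the ancestral exonic sequence: searching the two human exon
flanks separately against such an ortholog yields two matches separated by
a gap of extra residues, and the gap length should be close to 1/3 of the
intron's nucleotide length. Additionally the human intron DNA, translated
in all three frames, may still resemble the ortholog's gap segment.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

from .align import local_align
from .errors import NotFoundError
from .gene_model import MarkedProtein, expected_gap_residues

DEFAULT_FLANK_LEN = 50
DEFAULT_LEN_TOL_ABS = 5
DEFAULT_LEN_TOL_FRAC = 0.2
DEFAULT_EVALUE = 1e-6


@dataclass(frozen=True)
class SimilarityResult:
    """Best three-frame translation similarity against a gap segment."""

    frame: int | None  #: 0/1/2, or None when no frame has similarity
    bits: float
    evalue: float
    no_similarity: bool = False


@dataclass
class IntronizationCandidate:
    gene: str
    ordinal: int
    ortholog: str
    species: str
    left_span: tuple[int, int]  #: left-flank match on the ortholog (0-based half-open)
    right_span: tuple[int, int]
    gap: int  #: residues between the two matches on the ortholog
    expected_gap: int
    length_match: bool
    gap_segment: str
    similarity: SimilarityResult | None = None

    def __post_init__(self) -> None:
        if self.right_span[0] < self.left_span[1]:
            raise ValueError("right-flank match must start after the left-flank match ends")


def length_tolerance(expected: int, tol_abs: int = DEFAULT_LEN_TOL_ABS,
                     tol_frac: float = DEFAULT_LEN_TOL_FRAC) -> float:
    """Allowed |gap - expected| slack: max(5 residues, 20% of expected)."""
    return max(tol_abs, tol_frac * expected)


def flanking_exon_scan(focal: MarkedProtein, ordinal: int,
                       orthologs: list[tuple[str, str, str]], *,
                       flank_len: int = DEFAULT_FLANK_LEN,
                       threshold: float = DEFAULT_EVALUE,
                       tol_abs: int = DEFAULT_LEN_TOL_ABS,
                       tol_frac: float = DEFAULT_LEN_TOL_FRAC) -> list[IntronizationCandidate]:
    """Search the two flanks of one focal intron in intron-lacking orthologs.

    ``orthologs`` is a list of ``(accession, species, raw protein)`` for
    orthologs already known to lack the intron (presence filtering is the
    caller's job). Each flank (up to ``flank_len`` residues, truncated at
    protein ends) is locally aligned on its own; a candidate is kept when
    both flanks hit with significance <= ``threshold``, in order, with a
    positive gap ``g`` between the matches. ``length_match`` records whether
    ``g`` is within tolerance of 1/3 of the intron's nucleotide length.
    """
    marks = {m.ordinal: m for m in focal.marks}
    if ordinal not in marks:
        raise NotFoundError(f"intron ordinal {ordinal} not in {focal.accession}")
    mark = marks[ordinal]
    idx = mark.protein_index - 1  # insertion point in the raw protein
    left = focal.raw[max(0, idx - flank_len):idx]
    right = focal.raw[idx:idx + flank_len]
    expected = expected_gap_residues(mark.intron_length)
    tol = length_tolerance(expected, tol_abs, tol_frac)
    candidates: list[IntronizationCandidate] = []
    for accession, species, seq in orthologs:
        if not left or not right or not seq:
            continue
        lh = local_align(left, seq)
        rh = local_align(right, seq)
        if lh.evalue > threshold or rh.evalue > threshold:
            continue
        gap = rh.subject_span[0] - lh.subject_span[1]
        if gap <= 0:
            continue
        candidates.append(
            IntronizationCandidate(
                gene=focal.accession, ordinal=ordinal, ortholog=accession,
                species=species, left_span=lh.subject_span, right_span=rh.subject_span,
                gap=gap, expected_gap=expected,
                length_match=abs(gap - expected) <= tol,
                gap_segment=seq[lh.subject_span[1]:rh.subject_span[0]],
            )
        )
    return candidates


def translate_intron_frames(intron_dna: str) -> tuple[str, str, str]:
    """Translate an intron in frames 0, 1, 2, each up to the first stop.

    ``N`` is tolerated and translates to X; other non-ACGT characters raise
    ``ValueError``.
    """
    dna = intron_dna.upper()
    if len(dna) < 3:
        raise ValueError("intron sequence must be at least 3 nt")
    if set(dna) - set("ACGTN"):
        raise ValueError(
            f"invalid characters in intron sequence: {sorted(set(dna) - set('ACGTN'))}"
        )
    peptides = []
    for frame in range(3):
        sub = dna[frame:]
        sub = sub[: len(sub) - len(sub) % 3]
        if not sub:
            peptides.append("")
            continue
        aa = str(Seq(sub).translate())
        peptides.append(aa.split("*")[0])
    return tuple(peptides)


def intron_translation_similarity(peptides: tuple[str, str, str],
                                  gap_segment: str) -> SimilarityResult:
    """Best local-alignment similarity of the three frames to the gap segment.

    Ties go to the lowest frame index. If every peptide is empty the result
    is flagged ``no_similarity`` rather than raising.
    """
    if not gap_segment:
        raise ValueError("gap segment must be nonempty")
    best: SimilarityResult | None = None
    for frame, peptide in enumerate(peptides):
        if not peptide:
            continue
        hit = local_align(peptide, gap_segment)
        if best is None or hit.bits > best.bits:
            best = SimilarityResult(frame=frame, bits=hit.bits, evalue=hit.evalue)
    if best is None:
        return SimilarityResult(frame=None, bits=0.0, evalue=float("inf"),
                                no_similarity=True)
    return best


def scan_with_similarity(focal: MarkedProtein, ordinal: int,
                         orthologs: list[tuple[str, str, str]], intron_dna: str,
                         **kwargs) -> list[IntronizationCandidate]:
    """Flanking scan plus three-frame similarity for each candidate's gap."""
    candidates = flanking_exon_scan(focal, ordinal, orthologs, **kwargs)
    peptides = translate_intron_frames(intron_dna)
    for cand in candidates:
        if cand.gap_segment:
            cand.similarity = intron_translation_similarity(peptides, cand.gap_segment)
    return candidates


def candidates_to_frame(candidates: list[IntronizationCandidate]):
    """Candidates as a DataFrame matching the candidates.tsv layout."""
    import pandas as pd

    rows = []
    for c in candidates:
        rows.append(
            {
                "gene": c.gene,
                "intron_ordinal": c.ordinal,
                "ortholog": c.ortholog,
                "species": c.species,
                "gap": c.gap,
                "expected": c.expected_gap,
                "length_match": c.length_match,
                "frame": None if c.similarity is None else c.similarity.frame,
                "bits": None if c.similarity is None else round(c.similarity.bits, 2),
                "significance": None if c.similarity is None else c.similarity.evalue,
            }
        )
    return pd.DataFrame(rows)
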