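"""Gene models, intron positions in protein coordinates, and X-marked proteins.

An intron that interrupts the coding sequence after ``c`` coding nucleotides
has phase ``c mod 3``. Its position is projected into protein space by
inserting an ``X`` marker immediately to the left of the (1-based) residue
``floor(c/3) + 1``: for a phase-0 intron this places the marker between
residues ``c/3`` and ``c/3 + 1``; for a mid-codon intron (phase 1 or 2) the
marker sits just left of the residue whose codon the intron interrupts.
Markers from orthologous proteins that land in the same alignment column
then witness a shared intron position.

Coordinates are 0-based half-open internally; GFF3 I/O is 1-based inclusive.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from Bio.Seq import Seq

from .errors import MalformedModelError, OutOfRangeError, TableParseError

logger = logging.getLogger(__name__)

Interval = tuple[int, int]  # 0-based half-open


@dataclass
class GeneModel:
    """One transcript's exon/CDS structure in one species.

    ``exons`` and ``cds`` are 0-based half-open genomic intervals in
    *transcription order* (descending genomic coordinate on the minus strand).
    """

    species: str
    gene_id: str
    transcript_id: str
    chrom: str
    strand: str  # '+' or '-'
    exons: list[Interval]
    cds: list[Interval]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise MalformedModelError(f"{self.transcript_id}: strand must be + or -")
        for seq_name, ivs in (("exons", self.exons), ("CDS", self.cds)):
            for start, end in ivs:
                if end <= start:
                    raise MalformedModelError(
                        f"{self.transcript_id}: empty or inverted {seq_name} interval [{start},{end})"
                    )
            genomic = sorted(ivs) if self.strand == "+" else sorted(ivs, reverse=True)
            if list(ivs) != genomic:
                raise MalformedModelError(
                    f"{self.transcript_id}: {seq_name} not in transcription order"
                )
            ordered = sorted(ivs)
            for (s1, e1), (s2, e2) in zip(ordered, ordered[1:]):
                if s2 < e1:
                    raise MalformedModelError(
                        f"{self.transcript_id}: overlapping {seq_name} intervals"
                    )
        if self.cds_length % 3 != 0:
            raise MalformedModelError(
                f"{self.transcript_id}: CDS length {self.cds_length} not divisible by 3"
            )

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    def splice_cds(self, chrom_seq: str) -> str:
        """Extract the spliced coding sequence from the chromosome sequence."""
        parts = []
        for start, end in self.cds:
            piece = chrom_seq[start:end]
            if self.strand == "-":
                piece = str(Seq(piece).reverse_complement())
            parts.append(piece)
        return "".join(parts)

    def translate_cds(self, chrom_seq: str) -> str:
        """Translate the spliced CDS; a single trailing stop is dropped."""
        protein = str(Seq(self.splice_cds(chrom_seq)).translate())
        if protein.endswith("*"):
            protein = protein[:-1]
        return protein


@dataclass(frozen=True)
class IntronMark:
    """One intron's projection into protein coordinates."""

    ordinal: int  #: 1-based index among the transcript's coding introns
    coding_offset: int  #: coding nucleotides preceding the intron (c)
    protein_index: int  #: 1-based residue the X is inserted to the left of
    phase: int  #: c mod 3
    intron_length: int  #: genomic length in nt
    genomic_interval: Interval

    def __post_init__(self) -> None:
        if self.phase != self.coding_offset % 3:
            raise ValueError("phase must equal coding_offset mod 3")
        if self.protein_index != self.coding_offset // 3 + 1:
            raise ValueError("protein_index must equal floor(c/3) + 1")


@dataclass
class MarkedProtein:
    """A protein sequence with X markers recording intron positions."""

    species: str
    accession: str
    raw: str
    marked: str
    marks: list[IntronMark] = field(default_factory=list)

    def __post_init__(self) -> None:
        if unmark(self.marked) != self.raw:
            raise ValueError(f"{self.accession}: removing X does not recover the raw sequence")
        n_x = self.marked.count("X")
        if n_x != len(self.marks):
            raise ValueError(f"{self.accession}: {n_x} X characters but {len(self.marks)} marks")


def unmark(marked: str) -> str:
    """Remove all X markers, recovering the raw protein sequence."""
    return marked.replace("X", "")


def intron_marks(model: GeneModel) -> list[IntronMark]:
    """Compute one mark per junction between consecutive CDS-bearing exons.

    ``coding_offset`` counts only coding nucleotides; junctions outside the
    CDS (UTR-only introns) produce no mark. The intron length is the genomic
    gap between the flanking CDS segments.
    """
    marks: list[IntronMark] = []
    offset = 0
    ordinal = 0
    for (s1, e1), (s2, e2) in zip(model.cds, model.cds[1:]):
        offset += e1 - s1
        if model.strand == "+":
            interval = (e1, s2)
        else:
            interval = (e2, s1)
        length = interval[1] - interval[0]
        if length <= 0:
            raise MalformedModelError(
                f"{model.transcript_id}: CDS segments abut or overlap at offset {offset}"
            )
        ordinal += 1
        marks.append(
            IntronMark(
                ordinal=ordinal,
                coding_offset=offset,
                protein_index=offset // 3 + 1,
                phase=offset % 3,
                intron_length=length,
                genomic_interval=interval,
            )
        )
    return marks


def mark_protein(protein: str, marks: list[IntronMark], *, species: str = "",
                 accession: str = "") -> MarkedProtein:
    """Insert one X per mark just left of the residue each intron interrupts.

    The protein must not itself contain X (markers would be ambiguous), and
    every mark must point at an existing residue — a mark at or beyond the
    stop codon raises :class:`OutOfRangeError`.
    """
    if "X" in protein:
        raise ValueError("raw protein contains X; markers would be ambiguous")
    if any(marks[i].coding_offset >= marks[i + 1].coding_offset for i in range(len(marks) - 1)):
        raise ValueError("marks must be sorted by coding offset")
    length = len(protein)
    chunks = []
    prev = 0
    for mark in marks:
        idx = mark.protein_index - 1  # 0-based insertion point
        if idx < 0 or idx >= length:
            raise OutOfRangeError(
                f"{accession or 'protein'}: mark at coding offset {mark.coding_offset} "
                f"falls at residue {mark.protein_index} of a {length}-residue protein"
            )
        chunks.append(protein[prev:idx])
        chunks.append("X")
        prev = idx
    chunks.append(protein[prev:])
    return MarkedProtein(
        species=species, accession=accession, raw=protein,
        marked="".join(chunks), marks=list(marks),
    )


def expected_gap_residues(intron_length: int) -> int:
    """Residues an intronization event removes: 1/3 of the intron's nt length.

    Exact for lengths divisible by 3; otherwise rounded to nearest (ties to
    even, numpy/python convention) — downstream length-match tolerances
    absorb the sub-residue remainder.
    """
    if intron_length <= 0:
        raise ValueError(f"intron length must be positive, got {intron_length}")
    return round(intron_length / 3)


def write_marked_fasta(proteins, path: str | Path) -> Path:
    """Write marked proteins as FASTA (X is a legal protein character)."""
    path = Path(path)
    with open(path, "w") as handle:
        for p in proteins:
            handle.write(f">{p.accession} {p.species}\n{p.marked}\n")
    return path


# ---------------------------------------------------------------------------
# GFF3 / exon-table I/O


def parse_gff(path: str | Path, species: str | None = None) -> list[GeneModel]:
    """Parse a GFF3 file into gene models (one per mRNA/transcript feature).

    Coordinates are converted from 1-based inclusive to 0-based half-open and
    minus-strand features are reordered into transcription order. Transcripts
    without CDS are skipped with a warning; a CDS total not divisible by 3
    raises :class:`MalformedModelError` naming the transcript.
    """
    import gffutils

    path = Path(path)
    if species is None:
        species = path.stem
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        db = gffutils.create_db(
            str(path), ":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
    models: list[GeneModel] = []
    transcripts = list(db.features_of_type(("mRNA", "transcript")))
    for tx in transcripts:
        exons = []
        cds = []
        for child in db.children(tx, featuretype="exon", order_by="start"):
            exons.append((child.start - 1, child.end))
        for child in db.children(tx, featuretype="CDS", order_by="start"):
            cds.append((child.start - 1, child.end))
        if not cds:
            logger.warning("transcript %s has no CDS; skipped", tx.id)
            continue
        if not exons:
            exons = list(cds)
        if tx.strand == "-":
            exons = exons[::-1]
            cds = cds[::-1]
        parents = list(db.parents(tx, featuretype="gene"))
        gene_id = parents[0].id if parents else tx.attributes.get("Parent", [tx.id])[0]
        models.append(
            GeneModel(
                species=species,
                gene_id=gene_id,
                transcript_id=tx.id,
                chrom=tx.seqid,
                strand=tx.strand,
                exons=exons,
                cds=cds,
            )
        )
    return models


_EXON_TABLE_COLUMNS = 7


def parse_exon_table(path: str | Path, species: str | None = None) -> list[GeneModel]:
    """Read a simple tab-separated exon table into gene models.

    Columns: transcript, chrom, strand, exon_start, exon_end, cds_start,
    cds_end — one row per exon, coordinates 1-based inclusive, ``.`` for the
    CDS columns of non-coding exons.
    """
    path = Path(path)
    if species is None:
        species = path.stem
    rows: dict[str, dict] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != _EXON_TABLE_COLUMNS:
                raise TableParseError(
                    f"expected {_EXON_TABLE_COLUMNS} columns, got {len(fields)}", lineno
                )
            tx, chrom, strand, es, ee, cs, ce = fields
            try:
                exon = (int(es) - 1, int(ee))
                cds_iv = None if cs == "." else (int(cs) - 1, int(ce))
            except ValueError as exc:
                raise TableParseError(f"non-numeric coordinate: {exc}", lineno) from None
            entry = rows.setdefault(tx, {"chrom": chrom, "strand": strand,
                                         "exons": [], "cds": []})
            entry["exons"].append(exon)
            if cds_iv is not None:
                entry["cds"].append(cds_iv)
    models = []
    for tx, entry in rows.items():
        exons = sorted(entry["exons"])
        cds = sorted(entry["cds"])
        if entry["strand"] == "-":
            exons = exons[::-1]
            cds = cds[::-1]
        if not cds:
            logger.warning("transcript %s has no CDS; skipped", tx)
            continue
        models.append(
            GeneModel(
                species=species, gene_id=tx, transcript_id=tx,
                chrom=entry["chrom"], strand=entry["strand"],
                exons=exons, cds=cds,
            )
        )
    return models
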