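"""Best-hit-per-species ortholog identification over a protein collection.

Emulates a BLASTP screen with an internal Smith–Waterman search: each
query/subject pair is scored under BLOSUM62 (gaps 11/1, X neutral) and
assigned an E-value-like significance from the ungapped Karlin–Altschul
formula. One best hit is kept per species, and hits with significance above
the threshold (default 1e-6, read as "E <= 1e-6") are dropped. A tabular
import hook accepts real BLAST outfmt-6 output for full-scale runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .align import local_align
from .errors import TableParseError

DEFAULT_EVALUE = 1e-6

#: (accession, species, sequence)
Subject = tuple[str, str, str]


@dataclass(frozen=True)
class HitRecord:
    """One query/subject alignment with its score and significance."""

    query: str
    subject: str
    subject_species: str
    bits: float
    evalue: float
    query_span: tuple[int, int]  #: 0-based half-open
    subject_span: tuple[int, int]

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("significance must be non-negative")


@dataclass
class OrthologSet:
    """The single best hit for each species for one query protein."""

    query: str
    by_species: dict[str, HitRecord] = field(default_factory=dict)

    def species(self) -> list[str]:
        return sorted(self.by_species)

    def __len__(self) -> int:
        return len(self.by_species)


def score_pair(query_seq: str, subject_seq: str, *, query: str = "query",
               subject: str = "subject", subject_species: str = "") -> HitRecord:
    """Score one pair of proteins by local alignment.

    Raises ``ValueError`` on an empty sequence.
    """
    hit = local_align(query_seq, subject_seq)
    return HitRecord(
        query=query,
        subject=subject,
        subject_species=subject_species,
        bits=hit.bits,
        evalue=hit.evalue,
        query_span=hit.query_span,
        subject_span=hit.subject_span,
    )


def _hit_rank(hit: HitRecord) -> tuple:
    # minimal significance, then maximal bits, then lexicographic accession
    return (hit.evalue, -hit.bits, hit.subject)


def best_hit_per_species(query_seq: str, subjects: Iterable[Subject], *,
                         query: str = "query",
                         threshold: float = DEFAULT_EVALUE) -> OrthologSet:
    """Keep the single best hit for each species, dropping sub-threshold hits."""
    best: dict[str, HitRecord] = {}
    for accession, species, seq in subjects:
        hit = score_pair(query_seq, seq, query=query, subject=accession,
                         subject_species=species)
        if hit.evalue > threshold:
            continue
        incumbent = best.get(species)
        if incumbent is None or _hit_rank(hit) < _hit_rank(incumbent):
            best[species] = hit
    return OrthologSet(query=query, by_species=best)


def find_paralogs(query_seq: str, species_subjects: Iterable[Subject], *,
                  exclude: str, query: str = "query",
                  threshold: float = DEFAULT_EVALUE) -> list[HitRecord]:
    """All passing hits in one species except the already-selected ortholog.

    Returned sorted by significance (best first).
    """
    hits = []
    for accession, species, seq in species_subjects:
        if accession == exclude:
            continue
        hit = score_pair(query_seq, seq, query=query, subject=accession,
                         subject_species=species)
        if hit.evalue <= threshold:
            hits.append(hit)
    hits.sort(key=_hit_rank)
    return hits


def read_species_map(path: str | Path) -> dict[str, str]:
    """Read an accession → species map (two tab-separated columns)."""
    mapping: dict[str, str] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise TableParseError("species map rows need 2 columns", lineno)
            mapping[fields[0]] = fields[1]
    return mapping


def import_hit_table(path: str | Path,
                     species_map: dict[str, str] | str | Path) -> list[HitRecord]:
    """Parse a 12-column tab-separated hit table (BLAST outfmt-6 dialect).

    Columns: query, subject, pident, length, mismatch, gapopen, qstart, qend,
    sstart, send, evalue, bitscore. Aligned intervals are converted from
    1-based inclusive to 0-based half-open. Malformed rows raise
    :class:`TableParseError` with the line number.
    """
    if not isinstance(species_map, dict):
        species_map = read_species_map(species_map)
    records: list[HitRecord] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise TableParseError(f"expected 12 columns, got {len(fields)}", lineno)
            query, subject = fields[0], fields[1]
            try:
                qstart, qend = int(fields[6]), int(fields[7])
                sstart, send = int(fields[8]), int(fields[9])
                evalue = float(fields[10])
                bits = float(fields[11])
            except ValueError as exc:
                raise TableParseError(f"malformed numeric field: {exc}", lineno) from None
            records.append(
                HitRecord(
                    query=query,
                    subject=subject,
                    subject_species=species_map.get(subject, ""),
                    bits=bits,
                    evalue=evalue,
                    query_span=(qstart - 1, qend),
                    subject_span=(sstart - 1, send),
                )
            )
    return records
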