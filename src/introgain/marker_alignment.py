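"""Multiple alignment of X-marked proteins and intron presence/absence calls.

A deterministic progressive aligner stands in for an external MSA tool:
pairwise distances (1 - fractional identity) feed a UPGMA guide tree, and
profiles are merged by affine-gap profile–profile alignment under BLOSUM62
with the X marker scored 0 against everything. Externally produced aligned
FASTA (e.g. MUSCLE output) can be imported instead and is validated against
the in-memory marked proteins.

From the alignment, each focal (human) X column is compared across rows:
an ortholog is *present* if it has an X in the same column (within an
optional column tolerance), *uncovered* if it has no residues flanking the
column (the ortholog does not span the position — the situation behind the
"beyond the annotated start or end" exclusion), and *absent* otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import edlib
import numpy as np
from Bio import SeqIO
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from ._gotoh import gotoh_global
from .align import GAP_EXTEND, GAP_OPEN, PROFILE_ALPHABET, encode_profile_sequence, profile_score_matrix
from .errors import ConsistencyError, NotFoundError
from .gene_model import MarkedProtein

Status = Literal["present", "absent", "uncovered"]

PRESENT: Status = "present"
ABSENT: Status = "absent"
UNCOVERED: Status = "uncovered"


@dataclass
class AlignedRow:
    species: str
    accession: str
    aligned: str


@dataclass
class MarkedAlignment:
    """A multiple alignment of marked proteins (rows in input order)."""

    rows: list[AlignedRow]

    def __post_init__(self) -> None:
        lengths = {len(r.aligned) for r in self.rows}
        if len(lengths) > 1:
            raise ConsistencyError("alignment rows have unequal lengths")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0].aligned) if self.rows else 0

    def row(self, accession: str) -> AlignedRow:
        for r in self.rows:
            if r.accession == accession:
                return r
        raise NotFoundError(f"accession {accession!r} not in alignment")

    def x_columns(self, accession: str) -> dict[int, int]:
        """Map mark ordinal (1-based) to alignment column for one row."""
        return {
            k: col
            for k, col in enumerate(
                (i for i, c in enumerate(self.row(accession).aligned) if c == "X"), start=1
            )
        }

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            for r in self.rows:
                handle.write(f">{r.accession} {r.species}\n{r.aligned}\n")


@dataclass
class PresenceCell:
    status: Status
    #: column offset of the matched X relative to the focal column (present only)
    matched_offset: int | None = None


@dataclass
class PresenceMatrix:
    """Species × focal-intron grid of present/absent/uncovered statuses."""

    focal_species: str
    focal_accession: str
    ordinals: list[int]
    species: list[str]  #: row order, focal first
    cells: dict[tuple[int, str], PresenceCell] = field(default_factory=dict)

    def status(self, ordinal: int, species: str) -> Status:
        return self.cells[(ordinal, species)].status

    def vector(self, ordinal: int) -> dict[str, Status]:
        """Per-species statuses for one focal intron (focal species included)."""
        return {sp: self.cells[(ordinal, sp)].status for sp in self.species}

    def to_frame(self):
        import pandas as pd

        data = {
            sp: [self.cells[(k, sp)].status for k in self.ordinals] for sp in self.species
        }
        return pd.DataFrame(data, index=self.ordinals).T


# ---------------------------------------------------------------------------
# Progressive alignment


def _identity_distance(a: str, b: str) -> float:
    """1 - fractional identity, from a fast global edit-distance alignment."""
    if a == b:
        return 0.0
    d = edlib.align(a, b, task="distance")["editDistance"]
    return d / max(len(a), len(b))


class _Profile:
    __slots__ = ("members", "aligned", "counts")

    def __init__(self, members: list[int], aligned: list[str]):
        self.members = members
        self.aligned = aligned
        self.counts = _count_matrix(aligned)


def _count_matrix(aligned: list[str]) -> np.ndarray:
    ncols = len(aligned[0])
    counts = np.zeros((ncols, len(PROFILE_ALPHABET)), dtype=np.float64)
    for row in aligned:
        arr = np.frombuffer(row.encode("ascii"), dtype=np.uint8)
        nongap = arr != ord("-")
        cols = np.nonzero(nongap)[0]
        sym = encode_profile_sequence(row.replace("-", ""))
        np.add.at(counts, (cols, sym), 1.0)
    return counts


def _merge(a: _Profile, b: _Profile) -> _Profile:
    S = profile_score_matrix()
    pair_scores = (a.counts @ S @ b.counts.T) / (len(a.members) * len(b.members))
    _, path = gotoh_global(pair_scores, GAP_OPEN, GAP_EXTEND)
    a_rows = [[] for _ in a.members]
    b_rows = [[] for _ in b.members]
    for i, j in path:
        for r, row in enumerate(a_rows):
            row.append(a.aligned[r][i] if i >= 0 else "-")
        for r, row in enumerate(b_rows):
            row.append(b.aligned[r][j] if j >= 0 else "-")
    merged_aligned = ["".join(r) for r in a_rows] + ["".join(r) for r in b_rows]
    return _Profile(a.members + b.members, merged_aligned)


def build_msa(marked: Iterable[MarkedProtein]) -> MarkedAlignment:
    """Progressively align marked proteins over a UPGMA guide tree.

    Deterministic for a fixed input order (guide-tree ties resolve by input
    index). A single sequence is returned trivially; empty input raises
    ``ValueError``.
    """
    proteins = list(marked)
    if not proteins:
        raise ValueError("build_msa requires at least one sequence")
    if len(proteins) == 1:
        p = proteins[0]
        return MarkedAlignment([AlignedRow(p.species, p.accession, p.marked)])
    n = len(proteins)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = _identity_distance(proteins[i].marked, proteins[j].marked)
    merges = linkage(squareform(dist, checks=False), method="average")
    clusters: dict[int, _Profile] = {
        i: _Profile([i], [proteins[i].marked]) for i in range(n)
    }
    next_id = n
    for left, right, _, _ in merges:
        a = clusters.pop(int(left))
        b = clusters.pop(int(right))
        clusters[next_id] = _merge(a, b)
        next_id += 1
    final = clusters[next_id - 1]
    by_member = dict(zip(final.members, final.aligned))
    rows = [
        AlignedRow(proteins[i].species, proteins[i].accession, by_member[i]) for i in range(n)
    ]
    return MarkedAlignment(rows)


def import_alignment(path: str | Path, marked: Iterable[MarkedProtein]) -> MarkedAlignment:
    """Load an externally produced aligned FASTA and validate it.

    Every marked protein must appear (matched by accession) and each row must
    ungap to exactly that protein's marked sequence; otherwise a
    :class:`ConsistencyError` naming the accession is raised. Rows are
    returned in the order of ``marked``.
    """
    proteins = list(marked)
    records = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    rows = []
    for p in proteins:
        if p.accession not in records:
            raise ConsistencyError(f"accession {p.accession!r} missing from {path}")
        aligned = records[p.accession]
        if aligned.replace("-", "") != p.marked:
            raise ConsistencyError(
                f"row {p.accession!r} does not ungap to its marked sequence"
            )
        rows.append(AlignedRow(p.species, p.accession, aligned))
    return MarkedAlignment(rows)


# ---------------------------------------------------------------------------
# Presence calls


def presence_matrix(alignment: MarkedAlignment, focal_accession: str,
                    tolerance: int = 0) -> PresenceMatrix:
    """Call present/absent/uncovered for every focal X column and species.

    A species is *present* at a focal intron if its row has an X within
    ``tolerance`` columns of the focal X column (default 0 = exact column),
    *uncovered* if its row lacks non-gap characters either before or after
    the column (the ortholog does not span the position), else *absent*.
    """
    focal_row = alignment.row(focal_accession)
    columns = alignment.x_columns(focal_accession)
    matrix = PresenceMatrix(
        focal_species=focal_row.species,
        focal_accession=focal_accession,
        ordinals=sorted(columns),
        species=[focal_row.species] + [r.species for r in alignment.rows
                                       if r.accession != focal_accession],
    )
    for k in matrix.ordinals:
        matrix.cells[(k, focal_row.species)] = PresenceCell(PRESENT, 0)
    for row in alignment.rows:
        if row.accession == focal_accession:
            continue
        arr = np.frombuffer(row.aligned.encode("ascii"), dtype=np.uint8)
        x_cols = np.nonzero(arr == ord("X"))[0]
        nongap_cols = np.nonzero(arr != ord("-"))[0]
        for k, col in columns.items():
            cell = PresenceCell(ABSENT)
            if x_cols.size:
                deltas = x_cols - col
                nearest = int(deltas[np.argmin(np.abs(deltas))])
                if abs(nearest) <= tolerance:
                    cell = PresenceCell(PRESENT, nearest)
            if cell.status is ABSENT:
                spans = (
                    nongap_cols.size > 0
                    and nongap_cols[0] < col
                    and nongap_cols[-1] > col
                )
                if not spans:
                    cell = PresenceCell(UNCOVERED)
            matrix.cells[(k, row.species)] = cell
    return matrix
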