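"""Protein alignment primitives shared across the pipeline.

Local (Smith–Waterman) alignment with BLOSUM62 is used for ortholog search
and for the intronization similarity checks; an affine-gap profile–profile
global alignment (Gotoh) drives the progressive multiple aligner.

The intron marker character ``X`` is treated as an unknown residue: it
scores 0 against every amino acid and against itself, so markers neither
attract nor repel an alignment — coincident intron positions co-align
because their flanking residues do.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices

#: 20 amino acids plus the intron marker; column order of the profile matrices.
PROFILE_ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"

#: Ungapped Karlin–Altschul constants for the BLOSUM62 scoring system.
#: Used to turn raw local-alignment scores into bit scores and an
#: E-value-like significance E = K * m * n * exp(-lambda * S). The constants
#: are the ungapped ones even though gaps are allowed; the significance is a
#: ranking/threshold device, not a calibrated statistic.
KA_LAMBDA = 0.3176
KA_K = 0.134

GAP_OPEN = 11.0
GAP_EXTEND = 1.0


@lru_cache(maxsize=None)
def blosum62_x_neutral():
    """BLOSUM62 with the X row/column (and X vs X) set to 0."""
    mat = substitution_matrices.load("BLOSUM62").copy()
    xi = mat.alphabet.index("X")
    mat[xi, :] = 0.0
    mat[:, xi] = 0.0
    return mat


@lru_cache(maxsize=None)
def profile_score_matrix() -> np.ndarray:
    """BLOSUM62 (X-neutral) as a dense array over :data:`PROFILE_ALPHABET`."""
    mat = blosum62_x_neutral()
    idx = [mat.alphabet.index(c) for c in PROFILE_ALPHABET]
    arr = np.asarray(mat)[np.ix_(idx, idx)].astype(np.float64)
    return arr


def encode_profile_sequence(seq: str) -> np.ndarray:
    """Map a protein sequence to indices into :data:`PROFILE_ALPHABET`.

    Unknown characters (e.g. ``B``/``Z``/``U``) are mapped to X.
    """
    lut = np.full(128, PROFILE_ALPHABET.index("X"), dtype=np.int64)
    for i, c in enumerate(PROFILE_ALPHABET):
        lut[ord(c)] = i
    return lut[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]


def _make_local_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = blosum62_x_neutral()
    aligner.open_gap_score = -GAP_OPEN
    aligner.extend_gap_score = -GAP_EXTEND
    return aligner


_LOCAL_ALIGNER = _make_local_aligner()


@dataclass(frozen=True)
class LocalHit:
    """Result of a Smith–Waterman alignment of two proteins."""

    raw_score: float
    bits: float
    evalue: float
    query_span: tuple[int, int]  #: 0-based half-open on the query
    subject_span: tuple[int, int]  #: 0-based half-open on the subject


def raw_to_bits(raw_score: float) -> float:
    return (KA_LAMBDA * raw_score - math.log(KA_K)) / math.log(2.0)


def evalue_from_raw(raw_score: float, m: int, n: int) -> float:
    # exp() underflows to 0.0 for very strong hits, which is fine here.
    return KA_K * m * n * math.exp(-KA_LAMBDA * raw_score)


def local_align(query: str, subject: str) -> LocalHit:
    """Locally align two protein sequences (BLOSUM62, gaps 11/1, X neutral).

    Raises ``ValueError`` on empty input.
    """
    if not query or not subject:
        raise ValueError("cannot align an empty sequence")
    alignments = _LOCAL_ALIGNER.align(query, subject)
    score = alignments.score
    if score <= 0:
        # No positively scoring local alignment exists.
        return LocalHit(0.0, raw_to_bits(0.0), evalue_from_raw(0.0, len(query), len(subject)),
                        (0, 0), (0, 0))
    best = alignments[0]
    qblocks, sblocks = best.aligned
    qspan = (int(qblocks[0][0]), int(qblocks[-1][1]))
    sspan = (int(sblocks[0][0]), int(sblocks[-1][1]))
    return LocalHit(
        raw_score=float(score),
        bits=raw_to_bits(float(score)),
        evalue=evalue_from_raw(float(score), len(query), len(subject)),
        query_span=qspan,
        subject_span=sspan,
    )
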