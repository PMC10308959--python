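"""Protein pairwise alignment with BLAST-like statistics.

This is the search engine behind domain detection and OBU clustering.  Local
(Smith-Waterman) alignment stands in for a production aligner such as DIAMOND
or blastp; global (Needleman-Wunsch) alignment defines the sequence identity
used for clustering full-length, end-to-end homologous domains.

Scoring defaults follow blastp: BLOSUM62 with affine gap penalties of
11 (open) + 1 per residue.  Bit scores use fixed gapped Karlin-Altschul
constants (lambda = 0.267, K = 0.041) and E-values the standard
E = m * n * 2**(-bitscore) with m the query length and n the total number of
residues in the searched collection.  ``X`` aligns but never counts as an
identity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

KA_LAMBDA = 0.267
KA_K = 0.041

# blastp-style "open 11, extend 1": a gap of length k costs 11 + k
_OPEN = -12
_EXTEND = -1


@dataclass
class AlignmentResult:
    """Score, significance and coordinate summary of one pairwise alignment.

    Coordinates are 1-based inclusive.  ``identity_fraction`` is
    matches / alignment columns; gap columns count toward the denominator and
    ``X`` never matches.
    """

    raw_score: float
    bitscore: float
    evalue: float
    identity_fraction: float
    aln_columns: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int


@lru_cache(maxsize=4)
def get_aligner(mode: str = "local") -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = _OPEN
    aligner.extend_gap_score = _EXTEND
    aligner.mode = mode
    return aligner


def bitscore_from_raw(raw_score: float) -> float:
    return (KA_LAMBDA * raw_score - math.log(KA_K)) / math.log(2.0)


def evalue_from_bitscore(bitscore: float, m: int, n: int) -> float:
    return m * n * 2.0 ** (-bitscore)


def _column_stats(alignment, query: str, subject: str, global_mode: bool):
    """Matches, columns and endpoint coordinates from an alignment's block list."""
    q_blocks, s_blocks = alignment.aligned
    matches = 0
    block_cols = 0
    for (qs, qe), (ss, se) in zip(q_blocks, s_blocks):
        block_cols += qe - qs
        for cq, cs in zip(query[qs:qe], subject[ss:se]):
            if cq == cs and cq != "X":
                matches += 1
    # gap columns between consecutive aligned blocks
    gap_cols = 0
    for i in range(1, len(q_blocks)):
        gap_cols += (q_blocks[i][0] - q_blocks[i - 1][1]) + (s_blocks[i][0] - s_blocks[i - 1][1])
    columns = block_cols + gap_cols
    q_start, q_end = int(q_blocks[0][0]) + 1, int(q_blocks[-1][1])
    s_start, s_end = int(s_blocks[0][0]) + 1, int(s_blocks[-1][1])
    if global_mode:
        # terminal gaps are alignment columns in global mode
        columns += q_blocks[0][0] + s_blocks[0][0]
        columns += (len(query) - q_blocks[-1][1]) + (len(subject) - s_blocks[-1][1])
    return matches, int(columns), q_start, q_end, s_start, s_end


def _align(query: str, subject: str, mode: str, search_space_n: int | None) -> AlignmentResult:
    if not query or not subject:
        raise ValueError("cannot align an empty sequence")
    aligner = get_aligner(mode)
    alignment = aligner.align(query, subject)[0]
    matches, columns, q_start, q_end, s_start, s_end = _column_stats(
        alignment, query, subject, global_mode=(mode == "global")
    )
    raw = float(alignment.score)
    bits = bitscore_from_raw(raw)
    n = search_space_n if search_space_n is not None else len(subject)
    return AlignmentResult(
        raw_score=raw,
        bitscore=bits,
        evalue=evalue_from_bitscore(bits, len(query), n),
        identity_fraction=matches / columns if columns else 0.0,
        aln_columns=columns,
        q_start=q_start,
        q_end=q_end,
        s_start=s_start,
        s_end=s_end,
    )


def align_local(query: str, subject: str, search_space_n: int | None = None) -> AlignmentResult:
    """Optimal local alignment of two protein sequences (BLOSUM62, 11/1 gaps)."""
    return _align(query, subject, "local", search_space_n)


def align_global(query: str, subject: str) -> AlignmentResult:
    """Optimal global alignment; identity counts terminal gaps as columns."""
    return _align(query, subject, "global", None)


def local_score(query: str, subject: str) -> float:
    """Raw local alignment score only (fast path for top-hit ranking)."""
    if not query or not subject:
        raise ValueError("cannot align an empty sequence")
    return float(get_aligner("local").score(query, subject))


def global_identity(a: str, b: str) -> float:
    """Global-alignment identity: matches / alignment columns, gaps included."""
    return align_global(a, b).identity_fraction
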