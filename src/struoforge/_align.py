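"""Global pairwise alignment primitives shared by dereplication, clustering,
and reference search.

Two fixed scoring schemes are used throughout the package:

* nucleotide: match +1 / mismatch -1 / gap open -2 / gap extend -1
* amino acid: BLOSUM62, gap open -11 / gap extend -1

Identity is matching columns over all alignment columns (gap columns
included); coverage is the number of columns where both sequences are
aligned, divided by the length of the shorter sequence.
"""

from __future__ import annotations

from functools import lru_cache
from typing import NamedTuple

from Bio.Align import PairwiseAligner, substitution_matrices


class AlignStats(NamedTuple):
    identity: float
    coverage: float
    score: float


@lru_cache(maxsize=None)
def _nt_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -1
    return aligner


@lru_cache(maxsize=None)
def _aa_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


def _stats(aligner: PairwiseAligner, a: str, b: str) -> AlignStats:
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    alignment = aligner.align(a, b)[0]
    counts = alignment.counts()
    aligned_cols = counts.identities + counts.mismatches
    total_cols = aligned_cols + counts.gaps
    identity = counts.identities / total_cols if total_cols else 0.0
    coverage = aligned_cols / min(len(a), len(b))
    return AlignStats(identity=identity, coverage=coverage, score=alignment.score)


def align_nt(a: str, b: str) -> AlignStats:
    """Global nucleotide alignment statistics."""
    return _stats(_nt_aligner(), a, b)


def align_aa(a: str, b: str) -> AlignStats:
    """Global amino-acid alignment statistics (BLOSUM62)."""
    return _stats(_aa_aligner(), a, b)
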