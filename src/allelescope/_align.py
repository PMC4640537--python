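"""Shared pairwise-alignment configuration (Biopython PairwiseAligner backend)."""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align


@dataclass(frozen=True)
class Scoring:
    """Affine-gap scoring scheme (match bonus positive, penalties negative)."""

    match: float = 1.0
    mismatch: float = -2.0
    gap_open: float = -4.0
    gap_extend: float = -1.0


#: Local alignment scoring for probe ranking.
LOCAL_SCORING = Scoring(match=1.0, mismatch=-1.0, gap_open=-2.0, gap_extend=-1.0)

#: Global alignment scoring for allele comparison.  The mismatch penalty is
#: deliberately steeper than the gap-extension cost so that a replacement
#: locus (deleted bases next to an unrelated insertion) is represented as two
#: adjacent gap runs rather than a row of mismatch columns; with a -2
#: mismatch the optimal path absorbs short deleted segments into the
#: insertion as mismatches and their lengths become unrecoverable.
GLOBAL_SCORING = Scoring(match=1.0, mismatch=-4.0, gap_open=-4.0, gap_extend=-1.0)


def make_aligner(scoring: Scoring, mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    return aligner
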