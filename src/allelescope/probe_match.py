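"""Candidate-gene ranking by local-alignment similarity to a hybridization probe.

Reproduces probe-based candidate selection: each candidate sequence is
locally aligned to the probe (both strands by default) and ranked by percent
identity over alignment columns, keeping hits above a similarity threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio.Seq import Seq

from ._align import LOCAL_SCORING, Scoring, make_aligner

__all__ = ["ProbeHit", "LocalAlignment", "local_align", "percent_identity",
           "rank_candidates"]


@dataclass(frozen=True)
class LocalAlignment:
    """Best local alignment of a probe against one candidate strand."""

    probe: str
    candidate: str
    strand: str            # strand of the candidate that matched
    score: float
    matches: int
    columns: int           # aligned pairs + gap columns inside the local span
    candidate_span: tuple[int, int]   # 1-based closed, plus-strand coordinates
    probe_span: tuple[int, int]       # 1-based closed probe interval aligned

    @property
    def identity(self) -> float:
        """Matches over alignment columns (gap columns included)."""
        return 100.0 * self.matches / self.columns if self.columns else 0.0

    @property
    def identity_over_probe(self) -> float:
        """Matches over full probe length; insensitive to end trimming."""
        return 100.0 * self.matches / len(self.probe)

    @property
    def coverage(self) -> float:
        """Fraction of the probe inside the local alignment span."""
        s, e = self.probe_span
        return (e - s + 1) / len(self.probe) if e else 0.0


@dataclass(frozen=True)
class ProbeHit:
    """One candidate ranked against the probe."""

    candidate_id: str
    percent_identity: float
    alignment_span: tuple[int, int]
    score: float
    strand: str


def _align_one_strand(probe: str, candidate: str, scoring: Scoring) -> tuple:
    aligner = make_aligner(scoring, "local")
    result = aligner.align(probe, candidate)
    aln = result[0]
    blocks_p, blocks_c = aln.aligned
    matches = 0
    columns = 0
    for (ps, pe), (cs, ce) in zip(blocks_p, blocks_c):
        for a, b in zip(probe[ps:pe], candidate[cs:ce]):
            columns += 1
            if a == b:
                matches += 1
    # gap columns between aligned blocks (within the local span)
    for i in range(1, len(blocks_p)):
        columns += int(blocks_p[i][0] - blocks_p[i - 1][1])
        columns += int(blocks_c[i][0] - blocks_c[i - 1][1])
    span = (int(blocks_c[0][0]) + 1, int(blocks_c[-1][1])) if len(blocks_c) else (0, 0)
    pspan = (int(blocks_p[0][0]) + 1, int(blocks_p[-1][1])) if len(blocks_p) else (0, 0)
    return float(result.score), matches, columns, span, pspan


def local_align(probe: str, candidate: str, scoring: Scoring = LOCAL_SCORING,
                both_strands: bool = True) -> LocalAlignment:
    """Best-scoring local alignment of probe vs candidate.

    With ``both_strands`` the reverse complement of the candidate is also
    searched and the better-scoring strand is returned (ties prefer '+').
    Minus-strand spans are reported in plus-strand coordinates.
    """
    if not probe or not candidate:
        raise ValueError("probe and candidate must be non-empty")
    probe, candidate = probe.upper(), candidate.upper()
    score_f, m_f, c_f, span_f, pspan_f = _align_one_strand(probe, candidate, scoring)
    best = LocalAlignment(probe=probe, candidate=candidate, strand="+",
                          score=score_f, matches=m_f, columns=c_f,
                          candidate_span=span_f, probe_span=pspan_f)
    if both_strands:
        rc = str(Seq(candidate).reverse_complement())
        score_r, m_r, c_r, span_r, pspan_r = _align_one_strand(probe, rc, scoring)
        if score_r > best.score:
            n = len(candidate)
            span = (n - span_r[1] + 1, n - span_r[0] + 1)
            best = LocalAlignment(probe=probe, candidate=candidate, strand="-",
                                  score=score_r, matches=m_r, columns=c_r,
                                  candidate_span=span, probe_span=pspan_r)
    return best


def percent_identity(a: str, b: str, scoring: Scoring = LOCAL_SCORING) -> float:
    """Percent identity of the best local alignment (gaps count as columns)."""
    return local_align(a, b, scoring).identity


def rank_candidates(probe: str, candidates: Sequence[tuple[str, str]] | dict,
                    min_identity: float = 75.0, min_coverage: float = 0.5,
                    scoring: Scoring = LOCAL_SCORING,
                    both_strands: bool = True) -> list[ProbeHit]:
    """Rank candidate sequences by probe identity, keeping hits >= threshold.

    ``candidates`` is (id, sequence) pairs or a mapping.  Hits are sorted by
    identity descending, ties broken by candidate id.  ``min_coverage``
    requires the local alignment to span at least that fraction of the
    probe: without it a few-bp perfect scrap in an unrelated sequence would
    count as a 100%-identity hit.
    """
    if isinstance(candidates, dict):
        candidates = list(candidates.items())
    if not candidates:
        raise ValueError("at least one candidate is required")
    hits = []
    for cand_id, seq in candidates:
        aln = local_align(probe, seq, scoring, both_strands)
        if aln.identity >= min_identity and aln.coverage >= min_coverage:
            hits.append(ProbeHit(candidate_id=cand_id,
                                 percent_identity=aln.identity,
                                 alignment_span=aln.candidate_span,
                                 score=aln.score, strand=aln.strand))
    hits.sort(key=lambda h: (-h.percent_identity, h.candidate_id))
    return hits
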