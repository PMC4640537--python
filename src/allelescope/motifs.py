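"""IUPAC-degenerate cis-element scanning.

Scans arbitrary sequence (typically a promoter insertion segment) for short
regulatory motifs written in IUPAC degenerate code.  The default set holds
the three elements relevant to the anthocyanin-pathway promoter survey:
ARR1AT (NGATT, a cytokinin response-regulator site), CACTFTPPCA1 (YACT, a
mesophyll-expression tetranucleotide) and the CAAT box.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import Seq

__all__ = ["MotifHit", "DEFAULT_MOTIFS", "iupac_to_regex", "scan",
           "load_motifs_tsv"]

DEFAULT_MOTIFS: tuple[tuple[str, str], ...] = (
    ("ARR1AT", "NGATT"),
    ("CACTFTPPCA1", "YACT"),
    ("CAAT-box", "CAAT"),
)


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence; minus-strand hits are reported at the
    plus-strand coordinate of their leftmost base."""

    motif_name: str
    pattern: str
    position: int
    strand: str
    matched: str


def iupac_to_regex(pattern: str, motif_name: str = "") -> str:
    """Expand an IUPAC degenerate pattern into a character-class regex.

    Ambiguity classes expand to their A/C/G/T realizations only, so an N in
    the scanned sequence never matches any pattern letter (including N).
    """
    parts = []
    for ch in pattern.upper():
        bases = ambiguous_dna_values.get(ch)
        if bases is None or ch not in "ACGTRYSWKMBDHVN":
            raise ValueError(
                f"invalid IUPAC letter {ch!r} in motif {motif_name or pattern!r}")
        bases = bases.replace("N", "ACGT") if ch == "N" else bases
        parts.append(bases[0] if len(bases) == 1 else f"[{bases}]")
    return "".join(parts)


def scan(seq: str, motifs: Sequence[tuple[str, str]] = DEFAULT_MOTIFS,
         strands: str = "both") -> list[MotifHit]:
    """Find every (possibly overlapping) motif occurrence, position-sorted.

    ``strands`` is '+', '-' or 'both'.  A '-' hit means the motif occurs on
    the reverse complement; its position is the plus-strand coordinate of
    the leftmost base of the occurrence footprint.
    """
    if strands not in ("+", "-", "both"):
        raise ValueError("strands must be '+', '-' or 'both'")
    seq = seq.upper()
    n = len(seq)
    hits: list[MotifHit] = []
    for name, pattern in motifs:
        rx = re.compile(f"(?=({iupac_to_regex(pattern, name)}))")
        if strands in ("+", "both"):
            for m in rx.finditer(seq):
                hits.append(MotifHit(motif_name=name, pattern=pattern,
                                     position=m.start() + 1, strand="+",
                                     matched=m.group(1)))
        if strands in ("-", "both"):
            rc = str(Seq(seq).reverse_complement())
            for m in rx.finditer(rc):
                # leftmost plus-strand base of the footprint
                pos = n - (m.start() + len(m.group(1))) + 1
                hits.append(MotifHit(motif_name=name, pattern=pattern,
                                     position=pos, strand="-",
                                     matched=m.group(1)))
    hits.sort(key=lambda h: (h.position, h.motif_name, h.strand))
    return hits


def load_motifs_tsv(path) -> list[tuple[str, str]]:
    """Load additional motifs from a TSV with columns name, pattern."""
    df = pd.read_csv(path, sep="\t", comment="#")
    motifs = [(str(r["name"]), str(r["pattern"])) for _, r in df.iterrows()]
    for name, pattern in motifs:
        iupac_to_regex(pattern, name)   # validate eagerly
    return motifs
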