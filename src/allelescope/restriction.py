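"""Restriction-site scanning, in-silico digestion and probe-fragment reporting.

Models a blunt (or offset) cutter on a linear sequence: HaeIII is GGCC with
cut offset 2 (GG^CC).  Fragment lengths always tile the input exactly, and
the fragment(s) overlapping a probe-homologous interval reproduce what a
Southern blot with that probe would detect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .genemodel import AlleleSequence

__all__ = ["Fragment", "Digest", "RflpReport", "find_sites", "digest",
           "probe_fragments", "rflp_compare"]


@dataclass(frozen=True)
class Fragment:
    """A restriction fragment as a 1-based closed residue interval."""

    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, start: int, end: int) -> bool:
        return self.start <= end and start <= self.end


@dataclass(frozen=True)
class Digest:
    """Result of digesting one linear sequence with one enzyme."""

    enzyme_name: str
    recognition: str
    cut_offset: int
    sequence_length: int
    site_positions: tuple[int, ...]
    fragments: tuple[Fragment, ...]

    def __post_init__(self) -> None:
        total = sum(f.length for f in self.fragments)
        if total != self.sequence_length:
            raise AssertionError(
                f"fragments sum to {total}, sequence is {self.sequence_length}")

    @property
    def fragment_lengths(self) -> tuple[int, ...]:
        return tuple(f.length for f in self.fragments)


def find_sites(seq: str, recognition: str) -> list[int]:
    """1-based start positions of every (possibly overlapping) occurrence.

    Plus-strand scan; recognition must be a plain A/C/G/T word.  N in the
    sequence never matches.
    """
    if not recognition:
        raise ValueError("recognition pattern must be non-empty")
    recognition = recognition.upper()
    if set(recognition) - set("ACGT"):
        raise ValueError(f"recognition pattern {recognition!r} must be A/C/G/T only")
    seq = seq.upper()
    sites = []
    start = 0
    while True:
        i = seq.find(recognition, start)
        if i < 0:
            break
        sites.append(i + 1)
        start = i + 1  # allow overlapping occurrences
    return sites


def digest(allele_or_seq: AlleleSequence | str, recognition: str = "GGCC",
           cut_offset: int = 2, enzyme_name: str = "HaeIII") -> Digest:
    """Digest a linear sequence, returning cut sites and 5'->3' fragments.

    The cut falls between ``site_start + cut_offset - 1`` and
    ``site_start + cut_offset``; offset 2 on GGCC is the blunt GG^CC cut.
    """
    seq = allele_or_seq.residues if isinstance(allele_or_seq, AlleleSequence) else allele_or_seq
    if not 0 <= cut_offset <= len(recognition):
        raise ValueError("cut_offset must lie within the recognition pattern")
    sites = find_sites(seq, recognition)
    cut_after = sorted({s + cut_offset - 1 for s in sites if 0 < s + cut_offset - 1 < len(seq)})
    bounds = [0] + cut_after + [len(seq)]
    fragments = tuple(Fragment(start=a + 1, end=b) for a, b in zip(bounds, bounds[1:]))
    return Digest(enzyme_name=enzyme_name, recognition=recognition.upper(),
                  cut_offset=cut_offset, sequence_length=len(seq),
                  site_positions=tuple(sites), fragments=fragments)


def probe_fragments(dig: Digest, probe_interval: tuple[int, int]) -> list[Fragment]:
    """Fragments overlapping the probe interval by >= 1 bp, in order.

    More than one fragment is returned when the probe spans a cut site, as on
    a blot where a probe lights up two bands.
    """
    start, end = probe_interval
    if not (1 <= start <= end <= dig.sequence_length):
        raise ValueError(
            f"probe interval ({start},{end}) outside sequence of length "
            f"{dig.sequence_length}")
    return [f for f in dig.fragments if f.overlaps(start, end)]


@dataclass(frozen=True)
class RflpReport:
    """Two-allele restriction comparison.

    ``sites_only_in_a`` / ``sites_only_in_b`` are residue positions of
    recognition sites present in exactly one allele; ``attributions`` maps
    such a site position (in the allele that HAS the site) to the signed-
    coordinate SNV that destroys it in the other allele, when one exists.
    """

    allele_a: str
    allele_b: str
    digest_a: Digest
    digest_b: Digest
    probe_lengths_a: tuple[int, ...]
    probe_lengths_b: tuple[int, ...]
    sites_only_in_a: tuple[int, ...]
    sites_only_in_b: tuple[int, ...]
    attributions: dict = field(default_factory=dict)


def rflp_compare(allele_a: AlleleSequence, allele_b: AlleleSequence,
                 recognition: str = "GGCC",
                 probe_interval_a: tuple[int, int] | None = None,
                 probe_interval_b: tuple[int, int] | None = None,
                 cut_offset: int = 2,
                 catalog=None) -> RflpReport:
    """Compare two alleles' digests and attribute site differences to SNVs.

    Probe intervals are residue intervals in each allele's own coordinates.
    If a :class:`~allelescope.variants.VariantCatalog` (called with
    ``allele_a`` as reference) is not supplied, one is computed internally to
    attribute site presence/absence to single-base changes inside the
    recognition word.
    """
    dig_a = digest(allele_a, recognition, cut_offset)
    dig_b = digest(allele_b, recognition, cut_offset)

    if catalog is None:
        from .variants import call_variants, global_align
        catalog = call_variants(global_align(allele_a, allele_b), ref_allele=allele_a)

    # Map each allele-a site through the catalog; a site is "shared" when the
    # same recognition word survives at the mapped position in allele b.
    snv_by_index = {}
    for v in catalog.variants:
        if v.vtype == "snv":
            snv_by_index[allele_a.signed_to_index(v.position)] = v

    m = len(recognition)
    only_a, only_b = [], []
    attributions = {}
    b_sites = set(dig_b.site_positions)
    matched_b = set()
    for s in dig_a.site_positions:
        mapped = _map_index(catalog, allele_a, s)
        if mapped is not None and mapped in b_sites:
            matched_b.add(mapped)
            continue
        only_a.append(s)
        hits = [snv_by_index[i] for i in range(s, s + m) if i in snv_by_index]
        if len(hits) == 1:
            attributions[s] = hits[0]
    only_b = sorted(b_sites - matched_b)

    pl_a = tuple(f.length for f in probe_fragments(dig_a, probe_interval_a)) \
        if probe_interval_a else ()
    pl_b = tuple(f.length for f in probe_fragments(dig_b, probe_interval_b)) \
        if probe_interval_b else ()
    return RflpReport(allele_a=allele_a.name, allele_b=allele_b.name,
                      digest_a=dig_a, digest_b=dig_b,
                      probe_lengths_a=pl_a, probe_lengths_b=pl_b,
                      sites_only_in_a=tuple(only_a), sites_only_in_b=tuple(only_b),
                      attributions=attributions)


def _map_index(catalog, ref_allele: AlleleSequence, index: int) -> int | None:
    """Map a 1-based reference residue index into the alt allele via the catalog.

    Returns None for positions removed by a deletion/complex indel.
    """
    offset = 0
    for v in catalog.variants:
        i = ref_allele.signed_to_index(v.position) if v.vtype != "insertion" \
            else ref_allele.signed_to_index(v.position)
        if v.vtype == "insertion":
            if i <= index:
                offset += v.alt_len
        elif v.vtype in ("deletion", "complex_indel"):
            if i + v.ref_len - 1 < index:
                offset += v.alt_len - v.ref_len
            elif i <= index:
                return None
    return index + offset
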