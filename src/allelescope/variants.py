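"""Pairwise allele comparison: global alignment, variant calling, complex-indel
merging, feature annotation and protein effects.

The caller compares exactly two assembled allele sequences.  Differences are
reported in the signed gene frame of the reference allele (negative =
upstream of the start codon).  Indels are right-shifted (3'-normalized) so
anchors are reproducible, and insertion/deletion events at one locus can be
merged into a single ``complex_indel`` record, the representation used for
replacement polymorphisms such as a 325-bp insertion displacing 14 bp.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from ._align import GLOBAL_SCORING, Scoring, make_aligner
from .genemodel import AlleleSequence, GeneModel, extract_cds, feature_at, translate

__all__ = ["Variant", "VariantCatalog", "Alignment", "global_align",
           "call_variants", "merge_complex", "annotate", "protein_effect",
           "apply_catalog", "write_catalog_tsv", "write_catalog_vcf"]


@dataclass
class Variant:
    """One difference between two alleles.

    ``position`` is the signed gene coordinate of the first affected
    reference base; for an insertion it is the base before which the segment
    is inserted.  ``ref_allele``/``alt_allele`` hold the replaced and
    substituted segments (empty string for pure insertions/deletions).
    """

    vtype: str                      # snv | insertion | deletion | complex_indel
    position: int
    ref_allele: str
    alt_allele: str
    feature: str | None = None
    protein_effect: tuple[str, int, str] | str | None = None
    # residue-space bookkeeping (reference/alt 1-based indices)
    ref_idx: int = field(default=0, repr=False, compare=False)
    alt_idx: int = field(default=0, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.vtype not in ("snv", "insertion", "deletion", "complex_indel"):
            raise ValueError(f"unknown variant type {self.vtype!r}")
        r, a = len(self.ref_allele), len(self.alt_allele)
        if self.vtype == "snv" and not (r == a == 1 and self.ref_allele != self.alt_allele):
            raise ValueError("snv must have one differing base on each side")
        if self.vtype == "insertion" and (r != 0 or a == 0):
            raise ValueError("insertion must have empty ref and non-empty alt")
        if self.vtype == "deletion" and (r == 0 or a != 0):
            raise ValueError("deletion must have non-empty ref and empty alt")
        if self.vtype == "complex_indel" and (r == 0 or a == 0):
            raise ValueError("complex_indel must have non-empty ref and alt")

    @property
    def ref_len(self) -> int:
        return len(self.ref_allele)

    @property
    def alt_len(self) -> int:
        return len(self.alt_allele)

    @property
    def net_len(self) -> int:
        return self.alt_len - self.ref_len

    @property
    def synonymous(self) -> bool | None:
        if isinstance(self.protein_effect, tuple):
            ref_aa, _, alt_aa = self.protein_effect
            return ref_aa == alt_aa
        return None


@dataclass
class VariantCatalog:
    """Position-ordered edit list converting the reference into the alt allele."""

    ref_name: str
    alt_name: str
    variants: list[Variant]
    # sequences retained so merging can reconstruct intervening bases
    ref_residues: str = field(default="", repr=False)
    alt_residues: str = field(default="", repr=False)
    ref_anchor: int = field(default=1, repr=False)

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self):
        return iter(self.variants)

    def of_type(self, vtype: str) -> list[Variant]:
        return [v for v in self.variants if v.vtype == vtype]

    def in_feature(self, prefix: str) -> list[Variant]:
        return [v for v in self.variants
                if v.feature is not None and v.feature.startswith(prefix)]

    @property
    def net_length(self) -> int:
        return sum(v.net_len for v in self.variants)


@dataclass(frozen=True)
class Alignment:
    """End-to-end alignment of two sequences as matched-block coordinates.

    ``blocks`` pairs 0-based half-open intervals of the reference and alt
    that are aligned column-for-column (matches and mismatches); the
    unaligned stretches between consecutive blocks are deletions (reference
    side) and/or insertions (alt side).
    """

    ref_seq: str
    alt_seq: str
    blocks: tuple[tuple[tuple[int, int], tuple[int, int]], ...]
    score: float
    ref_allele: AlleleSequence | None = None
    alt_allele: AlleleSequence | None = None


def global_align(ref: AlleleSequence | str, alt: AlleleSequence | str,
                 scoring: Scoring = GLOBAL_SCORING) -> Alignment:
    """End-to-end affine-gap alignment of two allele sequences."""
    ref_allele = ref if isinstance(ref, AlleleSequence) else None
    alt_allele = alt if isinstance(alt, AlleleSequence) else None
    ref_seq = ref.residues if ref_allele else str(ref).upper()
    alt_seq = alt.residues if alt_allele else str(alt).upper()
    if not ref_seq or not alt_seq:
        raise ValueError("both sequences must be non-empty")
    aligner = make_aligner(scoring, "global")
    result = aligner.align(ref_seq, alt_seq)
    aln = result[0]
    br, ba = aln.aligned
    blocks = tuple(((int(r0), int(r1)), (int(a0), int(a1)))
                   for (r0, r1), (a0, a1) in zip(br, ba))
    return Alignment(ref_seq=ref_seq, alt_seq=alt_seq, blocks=blocks,
                     score=float(result.score), ref_allele=ref_allele,
                     alt_allele=alt_allele)


def _signed(anchor: int, index: int) -> int:
    return index - anchor + 1 if index >= anchor else index - anchor


def call_variants(alignment: Alignment,
                  ref_allele: AlleleSequence | None = None) -> VariantCatalog:
    """Call SNVs and indels from an end-to-end alignment.

    Mismatch columns become SNVs; maximal unaligned stretches become one
    insertion and/or deletion record each.  Pure indels are right-shifted to
    their 3'-most equivalent placement so anchors are deterministic; an
    indel sharing its locus with a partner gap (a replacement junction) is
    left in place so the pair can be merged downstream.
    """
    ref_allele = ref_allele or alignment.ref_allele
    anchor = ref_allele.anchor if ref_allele is not None else 1
    ref, alt = alignment.ref_seq, alignment.alt_seq
    blocks = alignment.blocks
    if not blocks:
        raise ValueError("alignment has no aligned columns")
    if blocks[0][0][0] != 0 or blocks[0][1][0] != 0 \
            or blocks[-1][0][1] != len(ref) or blocks[-1][1][1] != len(alt):
        # leading/trailing unaligned stretches are still end-to-end gaps
        pass

    raw: list[Variant] = []

    def emit_gap(r0: int, r1: int, a0: int, a1: int) -> None:
        """Unaligned ref[r0:r1] vs alt[a0:a1] (0-based half-open)."""
        if r1 > r0:
            raw.append(Variant(vtype="deletion", position=0,
                               ref_allele=ref[r0:r1], alt_allele="",
                               ref_idx=r0 + 1, alt_idx=a0 + 1))
        if a1 > a0:
            raw.append(Variant(vtype="insertion", position=0,
                               ref_allele="", alt_allele=alt[a0:a1],
                               ref_idx=r0 + 1 if r1 == r0 else r0 + 1,
                               alt_idx=a0 + 1))

    # leading gap
    emit_gap(0, blocks[0][0][0], 0, blocks[0][1][0])
    for i, ((r0, r1), (a0, a1)) in enumerate(blocks):
        for off in range(r1 - r0):
            if ref[r0 + off] != alt[a0 + off]:
                raw.append(Variant(vtype="snv", position=0,
                                   ref_allele=ref[r0 + off],
                                   alt_allele=alt[a0 + off],
                                   ref_idx=r0 + off + 1, alt_idx=a0 + off + 1))
        if i + 1 < len(blocks):
            nr, na = blocks[i + 1]
            emit_gap(r1, nr[0], a1, na[0])
    # trailing gap
    emit_gap(blocks[-1][0][1], len(ref), blocks[-1][1][1], len(alt))

    raw.sort(key=lambda v: (v.ref_idx, 0 if v.vtype == "deletion" else 1))
    _normalize_right(raw, ref, alt)

    for v in raw:
        if v.vtype == "insertion":
            # anchored at the base before which the segment is inserted
            v.position = _signed(anchor, v.ref_idx)
        else:
            v.position = _signed(anchor, v.ref_idx)
    raw.sort(key=lambda v: v.ref_idx)
    return VariantCatalog(
        ref_name=ref_allele.name if ref_allele else "ref",
        alt_name=(alignment.alt_allele.name if alignment.alt_allele else "alt"),
        variants=raw, ref_residues=ref, alt_residues=alt, ref_anchor=anchor)


def _normalize_right(raw: list[Variant], ref: str, alt: str) -> None:
    """3'-shift isolated pure indels to their right-most equivalent placement."""
    for i, v in enumerate(raw):
        if v.vtype not in ("insertion", "deletion"):
            continue
        # replacement junction: a partner gap anchored at the same locus
        partnered = any(w is not v and w.vtype in ("insertion", "deletion")
                        and w.ref_idx == v.ref_idx for w in raw)
        if partnered:
            continue
        limit = min((w.ref_idx for w in raw
                     if w is not v and w.ref_idx > v.ref_idx), default=len(ref) + 1)
        if v.vtype == "insertion":
            seg, p = v.alt_allele, v.ref_idx  # inserted before ref base p
            while p < limit and p <= len(ref) and seg[0] == ref[p - 1]:
                seg = seg[1:] + seg[0]
                p += 1
            v.alt_allele, v.ref_idx = seg, p
        else:
            s, e = v.ref_idx, v.ref_idx + v.ref_len - 1
            while e + 1 < limit and e < len(ref) and ref[s - 1] == ref[e]:
                s += 1
                e += 1
            v.ref_allele, v.ref_idx = ref[s - 1:e], s


def merge_complex(catalog: VariantCatalog, window: int = 10) -> VariantCatalog:
    """Merge indel events whose reference anchors lie within ``window`` bp.

    Merged records are ``complex_indel`` variants spanning from the first to
    the last affected reference base; intervening matched bases (identical in
    both alleles) are included in both segments so that applying the merged
    catalog still reconstructs the alt allele exactly.  SNVs are never
    merged, and an SNV between two indels keeps them apart.
    """
    events = sorted(catalog.variants, key=lambda v: v.ref_idx)
    out: list[Variant] = []
    cluster: list[Variant] = []

    def ref_end(v: Variant) -> int:
        return v.ref_idx + max(v.ref_len, 1) - 1 if v.vtype != "insertion" else v.ref_idx - 1

    def flush() -> None:
        if not cluster:
            return
        if len(cluster) == 1:
            out.append(cluster[0])
        else:
            ref = catalog.ref_residues
            ordered = sorted(cluster, key=lambda v: (v.ref_idx,
                                                     0 if v.vtype == "insertion" else 1))
            first = ordered[0]
            r0 = first.ref_idx
            r1 = max(ref_end(v) for v in cluster)
            ref_seg = ref[r0 - 1:r1]
            # rebuild the alt-side segment by replaying the cluster over the
            # reference span (robust to co-optimal gap placements)
            parts = []
            cur = r0
            for v in ordered:
                if v.ref_idx > cur:
                    parts.append(ref[cur - 1:v.ref_idx - 1])
                    cur = v.ref_idx
                if v.vtype == "insertion":
                    parts.append(v.alt_allele)
                else:
                    cur = v.ref_idx + v.ref_len
            if cur <= r1:
                parts.append(ref[cur - 1:r1])
            alt_seg = "".join(parts)
            a0 = first.alt_idx
            if not ref_seg or not alt_seg:
                # degenerate (e.g. two abutting insertions): keep as pure indel
                vtype = "insertion" if not ref_seg else "deletion"
                merged = Variant(vtype=vtype, position=first.position,
                                 ref_allele=ref_seg, alt_allele=alt_seg,
                                 ref_idx=r0, alt_idx=a0)
            else:
                merged = Variant(vtype="complex_indel", position=first.position,
                                 ref_allele=ref_seg, alt_allele=alt_seg,
                                 ref_idx=r0, alt_idx=a0)
            merged.feature = first.feature
            out.append(merged)
        cluster.clear()

    snv_anchors = [v.ref_idx for v in events if v.vtype == "snv"]
    for v in events:
        if v.vtype == "snv":
            out.append(v)
            continue
        if cluster:
            prev = cluster[-1]
            gap_ok = v.ref_idx - prev.ref_idx <= window
            snv_between = any(prev.ref_idx <= s <= v.ref_idx for s in snv_anchors)
            if gap_ok and not snv_between:
                cluster.append(v)
                continue
            flush()
        cluster.append(v)
    flush()
    out.sort(key=lambda v: v.ref_idx)
    return VariantCatalog(ref_name=catalog.ref_name, alt_name=catalog.alt_name,
                          variants=out, ref_residues=catalog.ref_residues,
                          alt_residues=catalog.alt_residues,
                          ref_anchor=catalog.ref_anchor)


def annotate(catalog: VariantCatalog, model: GeneModel) -> VariantCatalog:
    """Label each variant with the feature of its anchoring position."""
    for v in catalog.variants:
        v.feature = feature_at(model, v.position)
    return catalog


def _cds_offsets(model: GeneModel) -> list[tuple[int, int, int]]:
    """(exon_start, exon_end, cds_offset_before_exon) per exon."""
    out = []
    acc = 0
    for s, e in model.exons:
        out.append((s, e, acc))
        acc += e - s + 1
    return out


def protein_effect(catalog: VariantCatalog, ref_allele: AlleleSequence,
                   alt_allele: AlleleSequence, model: GeneModel) -> VariantCatalog:
    """Compute amino-acid effects for exonic SNVs (and flag frameshifts).

    Exonic indels are flagged ``"frameshift"`` when their net length is not a
    multiple of 3 (``"inframe_indel"`` otherwise) without amino-acid
    coordinates.  Exonic SNVs get ``(ref_aa, aa_position, alt_aa)`` with
    1-based positions from the initiator Met; synonymous changes show equal
    ref and alt amino acids.
    """
    if any(v.feature is None for v in catalog.variants):
        annotate(catalog, model)
    ref_cds = extract_cds(ref_allele, model)
    exon_offsets = _cds_offsets(model)

    alt_cds = list(ref_cds)
    exonic_snvs = []
    for v in catalog.variants:
        if not (v.feature or "").startswith("exon"):
            continue
        if v.vtype == "snv":
            for s, e, off in exon_offsets:
                if s <= v.position <= e:
                    cds_pos = off + (v.position - s + 1)
                    exonic_snvs.append((v, cds_pos))
                    alt_cds[cds_pos - 1] = v.alt_allele
                    break
        else:
            v.protein_effect = ("frameshift" if v.net_len % 3 else "inframe_indel")
    alt_cds = "".join(alt_cds)
    ref_prot = translate(ref_cds, ref_allele.name).residues
    alt_prot = translate(alt_cds, alt_allele.name).residues
    for v, cds_pos in exonic_snvs:
        aa_pos = (cds_pos + 2) // 3
        ref_aa = ref_prot[aa_pos - 1] if aa_pos <= len(ref_prot) else "*"
        alt_aa = alt_prot[aa_pos - 1] if aa_pos <= len(alt_prot) else "*"
        v.protein_effect = (ref_aa, aa_pos, alt_aa)
    return catalog


def apply_catalog(catalog: VariantCatalog,
                  ref: AlleleSequence | str) -> str:
    """Apply all variants to the reference, reconstructing the alt sequence."""
    seq = ref.residues if isinstance(ref, AlleleSequence) else str(ref).upper()
    # at a shared junction the deletion must be applied before the insertion
    order = sorted(catalog.variants,
                   key=lambda x: (x.ref_idx, 0 if x.vtype == "insertion" else 1),
                   reverse=True)
    for v in order:
        i = v.ref_idx
        if v.vtype == "insertion":
            seq = seq[:i - 1] + v.alt_allele + seq[i - 1:]
        else:
            if seq[i - 1:i - 1 + v.ref_len] != v.ref_allele:
                raise ValueError(
                    f"reference mismatch applying {v.vtype} at residue {i}")
            seq = seq[:i - 1] + v.alt_allele + seq[i - 1 + v.ref_len:]
    return seq


def write_catalog_tsv(catalog: VariantCatalog, path) -> None:
    import pandas as pd

    rows = []
    for v in catalog.variants:
        eff = v.protein_effect
        if isinstance(eff, tuple):
            eff = f"{eff[0]}{eff[1]}{eff[2]}"
        rows.append({"ref": catalog.ref_name, "alt": catalog.alt_name,
                     "type": v.vtype, "position": v.position,
                     "ref_len": v.ref_len, "alt_len": v.alt_len,
                     "net_len": v.net_len,
                     "ref_seg": v.ref_allele, "alt_seg": v.alt_allele,
                     "feature": v.feature or "", "protein_effect": eff or ""})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_catalog_vcf(catalog: VariantCatalog, path) -> None:
    """Minimal VCF 4.2 output (left-anchored indels, residue-index POS)."""
    ref = catalog.ref_residues
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={catalog.ref_name},length={len(ref)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in sorted(catalog.variants, key=lambda x: x.ref_idx):
            if v.vtype == "snv":
                pos, r, a = v.ref_idx, v.ref_allele, v.alt_allele
            else:
                pos = v.ref_idx - 1
                left = ref[pos - 1] if pos >= 1 else "N"
                r = left + v.ref_allele
                a = left + v.alt_allele
            info = f"TYPE={v.vtype}" + (f";FEATURE={v.feature.replace(' ', '_')}"
                                        if v.feature else "")
            fh.write(f"{catalog.ref_name}\t{pos}\t.\t{r}\t{a}\t.\tPASS\t{info}\n")
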