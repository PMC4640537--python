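"""Gene-structure data model, signed coordinate frame, sequence I/O and translation.

Coordinates follow the convention used for promoter/gene variant reporting:
position 1 is the first base of the start codon, positions increase 3'-ward
through exons and introns, and upstream (promoter) positions are negative,
with -1 immediately 5' of the ATG.  There is no position 0.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_NUCLEOTIDES = set("ACGTN")

__all__ = [
    "GeneModel",
    "AlleleSequence",
    "ProteinSeq",
    "read_alleles",
    "read_anchor_table",
    "write_fasta",
    "feature_at",
    "extract_cds",
    "translate",
    "fetch_genbank",
]


@dataclass(frozen=True)
class GeneModel:
    """Exon/intron/upstream structure of a gene in the signed start-codon frame.

    ``exons`` are 1-based closed intervals in gene coordinates; the first exon
    must start at position 1 (the A of the ATG).  ``upstream_length`` is the
    number of bases included 5' of the start codon (reported as -1..-upstream).
    """

    gene_id: str
    upstream_length: int
    exons: tuple[tuple[int, int], ...]
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.upstream_length < 0:
            raise ValueError("upstream_length must be >= 0")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        exons = tuple((int(s), int(e)) for s, e in self.exons)
        object.__setattr__(self, "exons", exons)
        if not exons:
            raise ValueError("gene model needs at least one exon")
        if exons[0][0] != 1:
            raise ValueError("first exon must start at gene coordinate 1")
        prev_end = 0
        for s, e in exons:
            if s > e:
                raise ValueError(f"exon interval ({s},{e}) is inverted")
            if s <= prev_end:
                raise ValueError("exons must be non-overlapping and increasing")
            prev_end = e

    @property
    def gene_end(self) -> int:
        return self.exons[-1][1]

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            out.append((e1 + 1, s2 - 1))
        return tuple(out)

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    @classmethod
    def from_tsv(cls, path: str | os.PathLike, gene_id: str = "gene",
                 upstream_length: int = 0) -> "GeneModel":
        """Read a two-column TSV (start, end) of exon intervals."""
        df = pd.read_csv(path, sep="\t", comment="#", header=None,
                         names=["start", "end"])
        return cls(gene_id=gene_id, upstream_length=upstream_length,
                   exons=tuple(zip(df["start"].astype(int), df["end"].astype(int))))

    @classmethod
    def from_gff3(cls, path: str | os.PathLike, upstream_length: int = 0) -> "GeneModel":
        """Read exon features from a GFF3 file (1-based closed intervals)."""
        import gffutils

        db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                                keep_order=True)
        exons = []
        gene_id = "gene"
        strand = "+"
        for feat in db.all_features(order_by="start"):
            if feat.featuretype == "gene":
                gene_id = feat.id
            elif feat.featuretype == "exon":
                exons.append((feat.start, feat.end))
                strand = feat.strand if feat.strand in "+-" else "+"
        if not exons:
            raise ValueError(f"no exon features found in {path}")
        return cls(gene_id=gene_id, upstream_length=upstream_length,
                   exons=tuple(sorted(exons)), strand=strand)

    def to_gff3(self, path: str | os.PathLike, seqid: str | None = None) -> None:
        seqid = seqid or self.gene_id
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            fh.write(f"# upstream_length={self.upstream_length}\n")
            fh.write("\t".join([seqid, "allelescope", "gene", "1",
                                str(self.gene_end), ".", self.strand, ".",
                                f"ID={self.gene_id}"]) + "\n")
            for k, (s, e) in enumerate(self.exons, 1):
                fh.write("\t".join([seqid, "allelescope", "exon", str(s), str(e),
                                    ".", self.strand, ".",
                                    f"ID={self.gene_id}.exon{k};Parent={self.gene_id}"])
                         + "\n")


@dataclass
class AlleleSequence:
    """A named genomic sequence (upstream + gene body) with its coordinate anchor.

    ``anchor`` is the 1-based residue index of the first base of the start
    codon; gene coordinate ``p`` maps to residue index ``anchor + p - 1`` for
    p >= 1 and ``anchor + p`` for p <= -1.
    """

    name: str
    residues: str
    anchor: int
    genotype_label: str = "unknown"

    def __post_init__(self) -> None:
        self.residues = self.residues.upper().replace("U", "T")
        bad = [(i + 1, c) for i, c in enumerate(self.residues)
               if c not in VALID_NUCLEOTIDES]
        if bad:
            pos, c = bad[0]
            raise ValueError(
                f"allele {self.name!r}: non-IUPAC character {c!r} at position {pos} "
                "(only A/C/G/T/N are accepted)")
        if not 1 <= self.anchor <= len(self.residues):
            raise ValueError(f"allele {self.name!r}: anchor {self.anchor} outside sequence")
        if self.genotype_label not in ("W3", "w3", "unknown"):
            raise ValueError(f"genotype_label must be W3/w3/unknown, got {self.genotype_label!r}")

    def __len__(self) -> int:
        return len(self.residues)

    def signed_to_index(self, position: int) -> int:
        """Signed gene coordinate -> 1-based residue index."""
        if position == 0:
            raise ValueError("there is no gene coordinate 0")
        idx = self.anchor + position - 1 if position > 0 else self.anchor + position
        if not 1 <= idx <= len(self.residues):
            raise ValueError(f"gene coordinate {position} outside allele {self.name!r}")
        return idx

    def index_to_signed(self, index: int) -> int:
        """1-based residue index -> signed gene coordinate."""
        if not 1 <= index <= len(self.residues):
            raise ValueError(f"residue index {index} outside allele {self.name!r}")
        p = index - self.anchor + 1 if index >= self.anchor else index - self.anchor
        return p

    def slice_signed(self, start: int, end: int) -> str:
        """Sequence between signed coordinates start..end inclusive."""
        i, j = self.signed_to_index(start), self.signed_to_index(end)
        return self.residues[i - 1:j]


@dataclass(frozen=True)
class ProteinSeq:
    """Amino-acid sequence produced by translating a CDS."""

    residues: str
    source_allele: str = ""

    def __len__(self) -> int:
        return len(self.residues)


def read_anchor_table(path: str | os.PathLike) -> dict[str, int]:
    """Read a TSV of (record_id, anchor) pairs."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["record_id", "anchor"])
    return dict(zip(df["record_id"].astype(str), df["anchor"].astype(int)))


def read_alleles(fasta_path: str | os.PathLike,
                 anchor_table: Mapping[str, int] | str | os.PathLike,
                 labels: Mapping[str, str] | None = None) -> list[AlleleSequence]:
    """Load allele sequences from FASTA, anchoring each at its start codon.

    ``anchor_table`` maps record id -> anchor residue index (or is a TSV path).
    Residues are uppercased and U is mapped to T; any character outside
    A/C/G/T/N is a hard error naming the position.
    """
    if not isinstance(anchor_table, Mapping):
        anchor_table = read_anchor_table(anchor_table)
    labels = labels or {}
    alleles = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id not in anchor_table:
            raise KeyError(f"record {rec.id!r} has no anchor entry")
        alleles.append(AlleleSequence(
            name=rec.id, residues=str(rec.seq), anchor=int(anchor_table[rec.id]),
            genotype_label=labels.get(rec.id, "unknown")))
    if not alleles:
        raise ValueError(f"no FASTA records found in {fasta_path}")
    return alleles


def write_fasta(path: str | os.PathLike, records: Iterable[tuple[str, str]]) -> None:
    """Write (name, sequence) pairs as FASTA wrapped at 60 columns."""
    seqrecs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    with open(path, "w") as fh:
        SeqIO.write(seqrecs, fh, "fasta")


def feature_at(model: GeneModel, position: int) -> str:
    """Label a signed gene coordinate as 'upstream', 'exon k' or 'intron k'."""
    if position == 0:
        raise ValueError("there is no gene coordinate 0")
    if position < 0:
        if position < -model.upstream_length:
            raise ValueError(f"position {position} is 5' of the modeled upstream region")
        return "upstream"
    if position > model.gene_end:
        raise ValueError(f"position {position} is 3' of the gene end {model.gene_end}")
    for k, (s, e) in enumerate(model.exons, 1):
        if s <= position <= e:
            return f"exon {k}"
        if position < s:
            return f"intron {k - 1}"
    raise AssertionError("unreachable: position inside gene but unlabeled")


def extract_cds(allele: AlleleSequence, model: GeneModel) -> str:
    """Concatenate exonic sub-sequences into the coding sequence."""
    parts = []
    for s, e in model.exons:
        parts.append(allele.slice_signed(s, e))
    cds = "".join(parts)
    if len(cds) % 3 != 0:
        raise ValueError(
            f"CDS length {len(cds)} of {allele.name!r} is not a multiple of 3")
    return cds


def translate(cds: str, source_allele: str = "") -> ProteinSeq:
    """Translate a CDS under the standard genetic code, stopping at the first stop.

    Returns the protein excluding the stop codon.  A stop before the final
    codon is accepted (the caller sees a truncated product); a CDS whose
    length is not a multiple of 3 is an error.
    """
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} is not a multiple of 3")
    aa = str(Seq(cds).translate())
    stop = aa.find("*")
    if stop >= 0:
        aa = aa[:stop]
    return ProteinSeq(residues=aa, source_allele=source_allele)


def fetch_genbank(accession: str, email: str, out_path: str | os.PathLike) -> str:
    """Optional helper: download a GenBank nucleotide record as FASTA.

    Off by default everywhere; nothing in the package or its tests calls this.
    Requires network access and an NCBI contact e-mail.
    """
    from Bio import Entrez

    Entrez.email = email
    with Entrez.efetch(db="nucleotide", id=accession, rettype="fasta",
                       retmode="text") as handle:
        data = handle.read()
    with open(out_path, "w") as fh:
        fh.write(data)
    return str(out_path)
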