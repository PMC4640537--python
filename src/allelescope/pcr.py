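"""In-silico PCR: primer-binding prediction, amplicon sizing, indel-marker
genotyping and genotype-phenotype concordance.

An indel marker discriminates alleles by product size: primers flanking a
replacement indel amplify a short product from the reference allele and a
product longer by the indel's net length from the derived allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from Bio.Seq import Seq

from .genemodel import AlleleSequence

__all__ = ["PrimerPair", "BindingSite", "Amplicon", "AmpliconResult",
           "GenotypeCall", "ThresholdRule", "ReferenceRule", "find_binding",
           "predict_amplicon", "genotype_panel", "concordance",
           "ConcordanceReport", "read_primers_tsv"]

#: phenotype class implied by each marker call under the w4 background
CALL_TO_PHENOTYPE = {"W3-type": "purple throat", "w3-type": "near-white"}


@dataclass(frozen=True)
class PrimerPair:
    """A forward/reverse primer pair, both written 5'->3'."""

    name: str
    forward: str
    reverse: str

    def __post_init__(self) -> None:
        for which, p in (("forward", self.forward), ("reverse", self.reverse)):
            if len(p) < 10:
                raise ValueError(f"{which} primer of {self.name!r} is shorter than 10 nt")
            if set(p.upper()) - set("ACGT"):
                raise ValueError(f"{which} primer of {self.name!r} is not plain A/C/G/T")
        object.__setattr__(self, "forward", self.forward.upper())
        object.__setattr__(self, "reverse", self.reverse.upper())


@dataclass(frozen=True)
class BindingSite:
    """A primer match on the template: 1-based closed interval and strand."""

    start: int
    end: int
    strand: str        # '+' primer anneals to minus strand, extends 3'-ward
    mismatches: int


@dataclass(frozen=True)
class Amplicon:
    allele_name: str
    start: int
    end: int
    sequence: str

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class AmpliconResult:
    status: str                    # ok | no-amplification | ambiguous
    amplicon: Amplicon | None = None
    warnings: tuple[str, ...] = ()


@dataclass(frozen=True)
class GenotypeCall:
    accession: str
    amplicon_length: int | None
    call: str                      # W3-type | w3-type | no-amplification | ambiguous


def _hamming_sites(seq: str, word: str, max_mismatch: int,
                   require_3prime_exact: int, three_prime_right: bool) -> list[tuple[int, int]]:
    """(1-based start, mismatches) of sliding-window matches.

    ``three_prime_right`` marks whether the primer's 3' end is the right end
    of the word on the plus strand.  N never matches.
    """
    n, m = len(seq), len(word)
    out = []
    for i in range(n - m + 1):
        window = seq[i:i + m]
        mism = 0
        ok = True
        for j, (a, b) in enumerate(zip(window, word)):
            if a == b and a != "N":
                continue
            mism += 1
            dist_from_3p = (m - 1 - j) if three_prime_right else j
            if dist_from_3p < require_3prime_exact or mism > max_mismatch:
                ok = False
                break
        if ok:
            out.append((i + 1, mism))
    return out


def find_binding(seq: AlleleSequence | str, primer: str, max_mismatch: int = 0,
                 require_3prime_exact: int = 3) -> list[BindingSite]:
    """Find primer binding sites in both orientations.

    A '+' site is a match of the primer itself (extension rightward); a '-'
    site is a match of its reverse complement (extension leftward).  The 3'
    terminal ``require_3prime_exact`` bases must match exactly.
    """
    if not primer:
        raise ValueError("primer must be non-empty")
    s = seq.residues if isinstance(seq, AlleleSequence) else str(seq).upper()
    primer = primer.upper()
    sites = []
    for start, mism in _hamming_sites(s, primer, max_mismatch,
                                      require_3prime_exact, True):
        sites.append(BindingSite(start=start, end=start + len(primer) - 1,
                                 strand="+", mismatches=mism))
    rc = str(Seq(primer).reverse_complement())
    for start, mism in _hamming_sites(s, rc, max_mismatch,
                                      require_3prime_exact, False):
        sites.append(BindingSite(start=start, end=start + len(primer) - 1,
                                 strand="-", mismatches=mism))
    sites.sort(key=lambda b: (b.start, b.strand))
    return sites


def predict_amplicon(allele: AlleleSequence | str, pair: PrimerPair,
                     max_len: int = 5000, max_mismatch: int = 0,
                     require_3prime_exact: int = 3) -> AmpliconResult:
    """Predict the PCR product of a primer pair on one template.

    The product spans from a '+' site of the forward primer to a '-' site of
    the reverse primer, inclusive of both primer footprints.  The shortest
    valid product <= ``max_len`` is reported; several co-minimal products at
    different loci make the result ambiguous, and extra longer site pairs
    are noted as warnings.
    """
    name = allele.name if isinstance(allele, AlleleSequence) else "seq"
    s = allele.residues if isinstance(allele, AlleleSequence) else str(allele).upper()
    fwd = find_binding(s, pair.forward, max_mismatch, require_3prime_exact)
    rev = find_binding(s, pair.reverse, max_mismatch, require_3prime_exact)
    products = []
    # canonical orientation: forward anneals '+', reverse anneals '-'
    for f in (b for b in fwd if b.strand == "+"):
        for r in (b for b in rev if b.strand == "-"):
            if r.start > f.end and r.end - f.start + 1 <= max_len:
                products.append((f.start, r.end))
    # flipped orientation (template supplied reverse-complemented)
    for r in (b for b in rev if b.strand == "+"):
        for f in (b for b in fwd if b.strand == "-"):
            if f.start > r.end and f.end - r.start + 1 <= max_len:
                products.append((r.start, f.end))
    if not products:
        return AmpliconResult(status="no-amplification")
    best_len = min(e - s0 + 1 for s0, e in products)
    minimal = [(s0, e) for s0, e in products if e - s0 + 1 == best_len]
    warnings = ()
    if len(minimal) > 1:
        return AmpliconResult(status="ambiguous",
                              warnings=(f"{len(minimal)} co-minimal products",))
    if len(products) > 1:
        warnings = (f"{len(products)} candidate products; shortest reported",)
    start, end = minimal[0]
    amp = Amplicon(allele_name=name, start=start, end=end,
                   sequence=s[start - 1:end])
    return AmpliconResult(status="ok", amplicon=amp, warnings=warnings)


@dataclass(frozen=True)
class ThresholdRule:
    """Size rule: shorter than threshold -> W3-type, longer -> w3-type."""

    threshold: int = 350

    def classify(self, length: int) -> str:
        if length == self.threshold:
            return "ambiguous"
        return "W3-type" if length < self.threshold else "w3-type"


@dataclass(frozen=True)
class ReferenceRule:
    """Size rule: within tolerance of either expected product size."""

    w3_length: int = 200
    w3_derived_length: int = 511
    tolerance: int = 50

    def classify(self, length: int) -> str:
        near_ref = abs(length - self.w3_length) <= self.tolerance
        near_alt = abs(length - self.w3_derived_length) <= self.tolerance
        if near_ref == near_alt:
            return "ambiguous"
        return "W3-type" if near_ref else "w3-type"


def genotype_panel(alleles: Sequence[AlleleSequence], pair: PrimerPair,
                   rule=ThresholdRule(), max_len: int = 5000) -> list[GenotypeCall]:
    """Classify each panel member by its predicted amplicon size."""
    calls = []
    for allele in alleles:
        res = predict_amplicon(allele, pair, max_len=max_len)
        if res.status != "ok":
            calls.append(GenotypeCall(accession=allele.name, amplicon_length=None,
                                      call=res.status))
        else:
            length = res.amplicon.length
            calls.append(GenotypeCall(accession=allele.name,
                                      amplicon_length=length,
                                      call=rule.classify(length)))
    return calls


@dataclass(frozen=True)
class ConcordanceReport:
    """Marker-call vs phenotype cross-tabulation and conflict list."""

    crosstab_db: pd.DataFrame
    crosstab_observed: pd.DataFrame
    conflicts_db: tuple[str, ...]        # call disagrees with database phenotype
    conflicts_observed: tuple[str, ...]  # call disagrees with observed phenotype
    missing: tuple[str, ...]             # accessions absent from one input
    excluded: tuple[str, ...]            # phenotypes outside the marker mapping

    @property
    def n_conflicts_db(self) -> int:
        return len(self.conflicts_db)


def concordance(calls: Sequence[GenotypeCall],
                phenotype_table: pd.DataFrame) -> ConcordanceReport:
    """Cross-tabulate genotype calls against phenotype annotations.

    ``phenotype_table`` needs columns accession, db_phenotype,
    observed_phenotype.  Under the w4 background, purple-throat corresponds
    to the W3-type call and near-white to the w3-type call; accessions with
    phenotypes outside that mapping (or missing from either input) are
    excluded from the counts and reported.
    """
    pheno = phenotype_table.set_index("accession")
    call_by_acc = {c.accession: c for c in calls}
    missing = tuple(sorted((set(pheno.index) ^ set(call_by_acc))))
    shared = [a for a in pheno.index if a in call_by_acc]
    valid_phenos = set(CALL_TO_PHENOTYPE.values())
    excluded = tuple(a for a in shared
                     if pheno.loc[a, "db_phenotype"] not in valid_phenos
                     and pheno.loc[a, "observed_phenotype"] not in valid_phenos)
    kept = [a for a in shared if a not in excluded]

    rows = []
    for a in kept:
        call = call_by_acc[a].call
        implied = CALL_TO_PHENOTYPE.get(call)
        rows.append({"accession": a, "call": call,
                     "db_phenotype": pheno.loc[a, "db_phenotype"],
                     "observed_phenotype": pheno.loc[a, "observed_phenotype"],
                     "implied": implied})
    df = pd.DataFrame(rows)
    if df.empty:
        empty = pd.DataFrame()
        return ConcordanceReport(empty, empty, (), (), missing, excluded)
    conflicts_db = tuple(df.loc[(df["implied"].notna())
                                & (df["implied"] != df["db_phenotype"]),
                                "accession"])
    conflicts_obs = tuple(df.loc[(df["implied"].notna())
                                 & (df["implied"] != df["observed_phenotype"]),
                                 "accession"])
    ct_db = pd.crosstab(df["call"], df["db_phenotype"])
    ct_obs = pd.crosstab(df["call"], df["observed_phenotype"])
    return ConcordanceReport(crosstab_db=ct_db, crosstab_observed=ct_obs,
                             conflicts_db=conflicts_db,
                             conflicts_observed=conflicts_obs,
                             missing=missing, excluded=excluded)


def read_primers_tsv(path) -> list[PrimerPair]:
    """Read primer pairs from a TSV with columns name, forward, reverse."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return [PrimerPair(name=str(r["name"]), forward=r["forward"],
                       reverse=r["reverse"]) for _, r in df.iterrows()]
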