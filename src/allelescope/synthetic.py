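"""Synthetic allele-pair generator with fully known ground truth.

Builds a W3-like reference allele (1.5-kb promoter + ~4-kb gene body, six
exons) and derives a w3-like allele from a packaged polymorphism profile
that mirrors the published allele differences:

* introns: four single-base substitutions (one, C2029T, destroying the
  GGCC restriction site in intron 3), one 12-bp deletion and two insertions;
* exon 6: G3941C, substituting Ala for Gly at protein residue 338;
* promoter: four single-base substitutions, a 32-bp deletion, and a complex
  indel at position -230 replacing 14 bp with a 325-bp segment (net +311 bp)
  that carries ARR1AT (NGATT), CACTFTPPCA1 (YACT) and CAAT-box elements.

Planted landmarks are guaranteed by construction (and re-verified for every
seed): exactly five GGCC sites so the probe-covering fragment is 1,097 bp in
the reference and 1,594 bp in the derived allele, and unique primer
footprints flanking the -230 indel giving 200-bp vs 511-bp marker products.

Two deliberate sequence-design choices make variant recovery exact for any
seed: the 14 replaced promoter bases are a G homopolymer while the 325-bp
insert contains a single G (inside its NGATT element, >14 bp from either
end), so no partial alignment of the deleted segment against the insert can
be score-beneficial and the aligner must represent the locus as two clean
adjacent gap runs; and each pure indel is anchored so its 3'-most
(normalized) placement is the planted one.
"""

from __future__ import annotations

import os
import random
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import yaml

from .genemodel import AlleleSequence, GeneModel, extract_cds, translate, write_fasta
from .motifs import DEFAULT_MOTIFS, scan
from .pcr import PrimerPair, predict_amplicon
from .restriction import digest, find_sites, probe_fragments

__all__ = ["ProfileEdit", "PolymorphismProfile", "SyntheticAllelePair",
           "default_gene_model", "generate_reference", "packaged_w3_profile",
           "apply_profile", "make_allele_pair", "make_panel",
           "make_probe_candidates", "simulate_to_dir",
           "PANEL_PURPLE_THROAT", "PANEL_NEAR_WHITE", "INDEL_PRIMERS"]

# ---------------------------------------------------------------- constants

UPSTREAM_LENGTH = 1500
EXONS = ((1, 180), (501, 650), (1101, 1320), (2601, 2730),
         (3101, 3220), (3729, 3966))

#: gene-coordinate starts of the five planted GGCC words (all intronic);
#: the third, at 2027, spans 2027-2030 so that C2029T destroys it.
GGCC_SITES_GENE = (400, 930, 2027, 2524, 3600)

#: probe-homologous interval inside exon 3, between planted sites 2 and 3;
#: the covering HaeIII fragment is 1,097 bp in the reference.
PROBE_GENE = (1150, 1250)

#: indel-marker primer pair (published soybean DFR1 promoter marker)
INDEL_PRIMERS = PrimerPair(name="DFR1_indel",
                           forward="CCCCTTAAAAACTGCTCCCATT",
                           reverse="GGAGACCAAAGAATTACTAGTGAGTGA")

FWD_FOOT_GENE = (-330, -309)      # forward primer footprint
REV_FOOT_GENE = (-157, -131)      # reverse-complement(reverse primer) footprint
JUNCTION_GENE = (-230, -217)      # 14-bp G homopolymer replaced by the insert

_STOPS = {"TAA", "TAG", "TGA"}

#: accession names used for the 4 + 7 genotyping panel
PANEL_PURPLE_THROAT = ("PI 315701", "PI 417579", "PI 547524", "PI 547750")
PANEL_NEAR_WHITE = ("PI 81763", "PI 81765", "PI 81767", "PI 437570",
                    "PI 437918", "PI 547751", "PI 550733")


def _build_insert() -> str:
    """Fixed 325-bp promoter insert: A/C/T alphabet with a single G.

    The lone G sits inside the planted ARR1AT (NGATT) occurrence, more than
    14 bp from either end; CAAT-box and YACT occurrences are also planted.
    """
    rng = random.Random("allelescope-insert-325")
    s = [rng.choice("ACT") for _ in range(325)]
    s[50:54] = "CAAT"
    s[100:105] = "AGATT"      # NGATT with its N realized as A; the only G
    s[200:204] = "CACT"       # YACT with Y realized as C
    return "".join(s)


INSERT_325 = _build_insert()

#: fixed substitution map for the non-anchored profile SNVs (never creates G,
#: so no substitution can create a GGCC word or a primer match)
_SNV_MAP = {"A": "C", "C": "A", "G": "A", "T": "A"}


def default_gene_model() -> GeneModel:
    """Six-exon gene model placing 2,029 in intron 3 and 3,941 in exon 6."""
    return GeneModel(gene_id="DFR1_synthetic", upstream_length=UPSTREAM_LENGTH,
                     exons=EXONS)


# ------------------------------------------------------------------ profile

@dataclass(frozen=True)
class ProfileEdit:
    """One edit converting the reference into the derived allele.

    ``position`` is a signed gene coordinate: the first replaced base for
    SNV/deletion/complex edits, the base *before which* the segment is
    inserted for insertions.
    """

    position: int
    vtype: str
    ref_segment: str
    alt_segment: str

    def __post_init__(self) -> None:
        r, a = len(self.ref_segment), len(self.alt_segment)
        checks = {"snv": r == a == 1 and self.ref_segment != self.alt_segment,
                  "insertion": r == 0 and a > 0,
                  "deletion": r > 0 and a == 0,
                  "complex_indel": r > 0 and a > 0}
        if self.vtype not in checks:
            raise ValueError(f"unknown edit type {self.vtype!r}")
        if not checks[self.vtype]:
            raise ValueError(f"segment lengths inconsistent with {self.vtype}")

    @property
    def net_len(self) -> int:
        return len(self.alt_segment) - len(self.ref_segment)


@dataclass(frozen=True)
class PolymorphismProfile:
    """Position-sorted, non-overlapping edit list (reference frame)."""

    name: str
    edits: tuple[ProfileEdit, ...]
    description: str = ""

    def __post_init__(self) -> None:
        prev = None
        for e in self.edits:
            if prev is not None and e.position <= prev:
                raise ValueError("profile edits must be strictly position-sorted")
            prev = e.position

    @property
    def net_length(self) -> int:
        return sum(e.net_len for e in self.edits)

    @property
    def upstream_net_length(self) -> int:
        return sum(e.net_len for e in self.edits if e.position < 0)

    def map_ref_index(self, allele: AlleleSequence, index: int) -> int | None:
        """Map a reference residue index into derived-allele coordinates."""
        offset = 0
        for e in self.edits:
            i = allele.signed_to_index(e.position)
            if e.vtype == "insertion":
                if i <= index:
                    offset += len(e.alt_segment)
            else:
                end = i + len(e.ref_segment) - 1
                if end < index:
                    offset += e.net_len
                elif i <= index:
                    return None
        return index + offset

    def to_dict(self) -> dict:
        return {"name": self.name, "description": self.description,
                "edits": [{"position": e.position, "type": e.vtype,
                           "ref": e.ref_segment, "alt": e.alt_segment}
                          for e in self.edits]}

    @classmethod
    def from_dict(cls, d: dict) -> "PolymorphismProfile":
        edits = tuple(ProfileEdit(position=int(e["position"]), vtype=e["type"],
                                  ref_segment=e["ref"], alt_segment=e["alt"])
                      for e in d["edits"])
        return cls(name=d["name"], edits=edits,
                   description=d.get("description", ""))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PolymorphismProfile":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# -------------------------------------------------------------- generation

def _gene_to_idx(p: int) -> int:
    """Signed gene coordinate -> 1-based residue index (anchor = 1501)."""
    if p == 0:
        raise ValueError("no position 0")
    return UPSTREAM_LENGTH + p if p > 0 else UPSTREAM_LENGTH + 1 + p


def _stamp(seq: list[str], idx: int, word: str) -> None:
    seq[idx - 1:idx - 1 + len(word)] = list(word)


def _cds_index_of(gene_pos: int) -> int | None:
    """Gene coordinate -> 1-based CDS position, or None if not exonic."""
    acc = 0
    for s, e in EXONS:
        if s <= gene_pos <= e:
            return acc + gene_pos - s + 1
        acc += e - s + 1
    return None


def _gene_of_cds(cds_pos: int) -> int:
    """1-based CDS position -> gene coordinate."""
    acc = 0
    for s, e in EXONS:
        n = e - s + 1
        if cds_pos <= acc + n:
            return s + (cds_pos - acc - 1)
        acc += n
    raise ValueError(f"CDS position {cds_pos} beyond CDS length {acc}")


def _protected_intervals() -> list[tuple[int, int]]:
    iv = []
    for g in GGCC_SITES_GENE:
        iv.append((_gene_to_idx(g), _gene_to_idx(g) + 3))
    iv.append((_gene_to_idx(FWD_FOOT_GENE[0]), _gene_to_idx(FWD_FOOT_GENE[1])))
    iv.append((_gene_to_idx(REV_FOOT_GENE[0]), _gene_to_idx(REV_FOOT_GENE[1])))
    # junction homopolymer plus one non-G flank base on each side
    iv.append((_gene_to_idx(JUNCTION_GENE[0]) - 1, _gene_to_idx(JUNCTION_GENE[1]) + 1))
    iv.append((_gene_to_idx(1), _gene_to_idx(3)))        # start codon
    iv.append((_gene_to_idx(3940), _gene_to_idx(3942)))  # Gly-338 codon
    iv.append((_gene_to_idx(3964), _gene_to_idx(3966)))  # stop codon
    return iv


def _forbidden_words() -> list[str]:
    from Bio.Seq import Seq

    fwd, rev = INDEL_PRIMERS.forward, INDEL_PRIMERS.reverse
    return ["GGCC", "GATT", "CACT", "TACT", "CAAT",
            fwd, str(Seq(fwd).reverse_complement()),
            rev, str(Seq(rev).reverse_complement())]


def generate_reference(seed: int = 1, *, name: str = "W3_synthetic",
                       rng: random.Random | None = None) -> AlleleSequence:
    """Generate one reference (W3-like) allele honoring every constraint.

    Pseudo-random background with planted landmarks, then an iterative
    repair pass that resamples single bases until no accidental restriction
    site, primer match or scanned motif word remains outside the planted
    feature intervals.  Reproducible for a fixed seed.
    """
    rng = rng or random.Random(f"allelescope-ref:{seed}")
    total = UPSTREAM_LENGTH + EXONS[-1][1]
    seq = [rng.choice("ACGT") for _ in range(total)]

    # CDS: ATG + 344 random non-stop codons + TAA, written back into exons
    codons = ["ATG"]
    while len(codons) < 345:
        c = "".join(rng.choice("ACGT") for _ in range(3))
        if c not in _STOPS:
            codons.append(c)
    codons[337] = "GGA"          # Gly at protein residue 338; G3941 = middle base
    codons.append("TAA")
    cds = "".join(codons)
    pos = 0
    for s, e in EXONS:
        _stamp(seq, _gene_to_idx(s), cds[pos:pos + (e - s + 1)])
        pos += e - s + 1

    for g in GGCC_SITES_GENE:
        _stamp(seq, _gene_to_idx(g), "GGCC")
    _stamp(seq, _gene_to_idx(FWD_FOOT_GENE[0]), INDEL_PRIMERS.forward)
    from Bio.Seq import Seq as _Seq
    _stamp(seq, _gene_to_idx(REV_FOOT_GENE[0]),
           str(_Seq(INDEL_PRIMERS.reverse).reverse_complement()))
    # junction: 14 G's with non-G flanking bases
    j0 = _gene_to_idx(JUNCTION_GENE[0])
    _stamp(seq, j0, "G" * 14)
    # Flank bases must differ from the insert's terminal bases (besides being
    # non-G): otherwise the aligner has a co-optimal path pairing an insert
    # end with a flank base, which slides the insertion gap off the junction.
    seq[j0 - 2] = rng.choice([b for b in "ACT" if b != INSERT_325[-1]])
    seq[j0 + 13] = rng.choice([b for b in "ACT" if b != INSERT_325[0]])

    _repair(seq, rng)
    return AlleleSequence(name=name, residues="".join(seq),
                          anchor=UPSTREAM_LENGTH + 1, genotype_label="W3")


def _repair(seq: list[str], rng: random.Random, max_mutations: int = 10000) -> None:
    """Mutate single bases until no forbidden word survives outside planted
    features (occurrences fully inside protected intervals are the planted
    ones and are exempt)."""
    protected = _protected_intervals()

    def is_protected(idx: int) -> bool:
        return any(a <= idx <= b for a, b in protected)

    words = _forbidden_words()
    mutations = 0
    for _ in range(500):
        text = "".join(seq)
        dirty = []
        for w in words:
            start = 0
            while True:
                i = text.find(w, start)
                if i < 0:
                    break
                occ = (i + 1, i + len(w))
                if not all(is_protected(p) for p in range(occ[0], occ[1] + 1)):
                    dirty.append((occ[0], w))
                start = i + 1
        if not dirty:
            return
        for occ_start, w in dirty:
            candidates = [p for p in range(occ_start, occ_start + len(w))
                          if not is_protected(p)]
            if not candidates:
                continue
            p = rng.choice(candidates)
            gene_pos = p - UPSTREAM_LENGTH if p > UPSTREAM_LENGTH else p - UPSTREAM_LENGTH - 1
            cds_pos = _cds_index_of(gene_pos) if gene_pos > 0 else None
            choices = [b for b in "ACGT" if b != seq[p - 1]]
            rng.shuffle(choices)
            for b in choices:
                if b == w[p - occ_start]:
                    continue
                if cds_pos is not None:
                    # rebuild the affected codon via CDS coordinates: codons
                    # can span exon boundaries, so residue-space arithmetic
                    # would read intronic bases
                    ci = (cds_pos - 1) // 3
                    codon = ""
                    for cp in range(ci * 3 + 1, ci * 3 + 4):
                        idx = _gene_to_idx(_gene_of_cds(cp))
                        codon += b if idx == p else seq[idx - 1]
                    if codon in _STOPS:
                        continue
                seq[p - 1] = b
                mutations += 1
                break
            if mutations > max_mutations:
                raise RuntimeError("constraint repair did not converge")
    raise RuntimeError("constraint repair did not converge")


def packaged_w3_profile(reference: AlleleSequence) -> PolymorphismProfile:
    """The packaged W3 -> w3 polymorphism profile, anchored on ``reference``.

    Fixed edits: C2029T (destroys the intron-3 GGCC site), G3941C (Gly338Ala
    in exon 6), the -230 complex indel (14-bp deletion + 325-bp insertion,
    net +311), a 32-bp promoter deletion, a 12-bp intron-5 deletion, 5-bp
    and 8-bp intron insertions, and three further intronic plus four
    promoter single-base substitutions.  SNV alternate bases come from a
    fixed non-G substitution map except where the published change fixes
    them.  Insertion segments take a first base different from the residue
    they precede, so their 3'-normalized placement is the planted one.
    """
    def base(p: int) -> str:
        return reference.residues[reference.signed_to_index(p) - 1]

    def seg(p_start: int, length: int) -> str:
        i = reference.signed_to_index(p_start)
        return reference.residues[i - 1:i - 1 + length]

    def snv(p: int, alt: str | None = None) -> ProfileEdit:
        ref = base(p)
        return ProfileEdit(position=p, vtype="snv", ref_segment=ref,
                           alt_segment=alt or _SNV_MAP[ref])

    def anchored_insert(p: int, tail: str) -> ProfileEdit:
        nxt = base(p)
        first = "C" if nxt != "C" else "A"
        return ProfileEdit(position=p, vtype="insertion", ref_segment="",
                           alt_segment=first + tail)

    edits = (
        snv(-1200),
        ProfileEdit(position=-1000, vtype="deletion",
                    ref_segment=seg(-1000, 32), alt_segment=""),
        snv(-900),
        snv(-700),
        snv(-500),
        ProfileEdit(position=-230, vtype="complex_indel",
                    ref_segment=seg(-230, 14), alt_segment=INSERT_325),
        anchored_insert(351, "CTAA"),          # 5-bp intron-1 insertion
        snv(700),
        snv(1500),
        snv(2029, "T"),                        # destroys the intron-3 GGCC site
        anchored_insert(2901, "CTTACAA"),      # 8-bp intron-4 insertion
        snv(3050),
        ProfileEdit(position=3300, vtype="deletion",
                    ref_segment=seg(3300, 12), alt_segment=""),
        snv(3941, "C"),                        # Gly338Ala
    )
    return PolymorphismProfile(
        name="w3",
        edits=edits,
        description=("w3-like derived allele: 4 promoter SNVs, 32-bp promoter "
                     "deletion, complex indel at -230 (325-bp ins / 14-bp del, "
                     "net +311), 4 intronic SNVs incl. C2029T, 5-bp and 8-bp "
                     "intron insertions, 12-bp intron-5 deletion, G3941C."))


def apply_profile(reference: AlleleSequence, profile: PolymorphismProfile,
                  name: str = "w3_synthetic") -> AlleleSequence:
    """Apply a profile 3'->5' so earlier coordinates stay valid.

    The anchor moves by the profile's net upstream length change.  A
    ref-segment mismatch is a hard error naming the edit.
    """
    seq = reference.residues
    for e in sorted(profile.edits, key=lambda x: x.position, reverse=True):
        i = reference.signed_to_index(e.position)
        if e.vtype == "insertion":
            seq = seq[:i - 1] + e.alt_segment + seq[i - 1:]
        else:
            found = seq[i - 1:i - 1 + len(e.ref_segment)]
            if found != e.ref_segment:
                raise ValueError(
                    f"profile edit {e.vtype}@{e.position}: reference has "
                    f"{found!r}, profile expects {e.ref_segment!r}")
            seq = seq[:i - 1] + e.alt_segment + seq[i - 1 + len(e.ref_segment):]
    anchor = reference.anchor + profile.upstream_net_length
    return AlleleSequence(name=name, residues=seq, anchor=anchor,
                          genotype_label="w3")


# ------------------------------------------------------------ allele pairs

@dataclass(frozen=True)
class SyntheticAllelePair:
    """A verified reference/derived pair with every planted landmark."""

    reference: AlleleSequence
    derived: AlleleSequence
    profile: PolymorphismProfile
    model: GeneModel
    primer_pair: PrimerPair
    probe_interval_ref: tuple[int, int]       # residue coords in reference
    probe_interval_derived: tuple[int, int]   # residue coords in derived
    site_positions_ref: tuple[int, ...]       # planted GGCC residue starts
    insert_segment: str


def make_allele_pair(seed: int = 1, max_attempts: int = 50) -> SyntheticAllelePair:
    """Generate and fully validate a reference/derived pair for any seed.

    Each attempt regenerates the background; an attempt is rejected unless
    every planted landmark checks out in both alleles (site counts, probe
    fragment lengths 1,097/1,594, unique primer sites with 200/511-bp
    products, motif presence in the insert, single Gly338Ala protein
    difference, and anchoring of every pure indel).
    """
    model = default_gene_model()
    last_err: Exception | None = None
    for attempt in range(max_attempts):
        rng = random.Random(f"allelescope-ref:{seed}:{attempt}")
        try:
            ref = generate_reference(seed, rng=rng)
            profile = packaged_w3_profile(ref)
            derived = apply_profile(ref, profile)
            pair = _validated_pair(ref, derived, profile, model)
        except (ValueError, RuntimeError) as err:
            last_err = err
            continue
        if pair is not None:
            return pair
    raise RuntimeError(
        f"could not build a valid allele pair in {max_attempts} attempts "
        f"(last error: {last_err})")


def _validated_pair(ref: AlleleSequence, derived: AlleleSequence,
                    profile: PolymorphismProfile,
                    model: GeneModel) -> SyntheticAllelePair | None:
    probe_ref = (ref.signed_to_index(PROBE_GENE[0]),
                 ref.signed_to_index(PROBE_GENE[1]))
    p0 = profile.map_ref_index(ref, probe_ref[0])
    p1 = profile.map_ref_index(ref, probe_ref[1])
    if p0 is None or p1 is None:
        return None
    planted_sites = tuple(ref.signed_to_index(g) for g in GGCC_SITES_GENE)

    dig_ref = digest(ref)
    dig_der = digest(derived)
    if dig_ref.site_positions != planted_sites or len(dig_der.site_positions) != 4:
        return None
    if tuple(f.length for f in probe_fragments(dig_ref, probe_ref)) != (1097,):
        return None
    if tuple(f.length for f in probe_fragments(dig_der, (p0, p1))) != (1594,):
        return None

    amp_ref = predict_amplicon(ref, INDEL_PRIMERS)
    amp_der = predict_amplicon(derived, INDEL_PRIMERS)
    if amp_ref.status != "ok" or amp_ref.amplicon.length != 200:
        return None
    if amp_der.status != "ok" or amp_der.amplicon.length != 511:
        return None

    found = {h.motif_name for h in scan(INSERT_325, DEFAULT_MOTIFS)}
    if {name for name, _ in DEFAULT_MOTIFS} - found:
        return None

    # pure indels must be blocked from 3'-shifting off their planted anchors
    for e in profile.edits:
        i = ref.signed_to_index(e.position)
        if e.vtype == "deletion":
            end = i + len(e.ref_segment) - 1
            if end < len(ref.residues) and ref.residues[i - 1] == ref.residues[end]:
                return None
        elif e.vtype == "insertion":
            if e.alt_segment[0] == ref.residues[i - 1]:
                return None

    ref_prot = translate(extract_cds(ref, model), ref.name).residues
    der_prot = translate(extract_cds_shifted(derived, model, profile),
                         derived.name).residues
    if len(ref_prot) != len(der_prot) or len(ref_prot) != 345:
        return None
    diffs = [k for k, (a, b) in enumerate(zip(ref_prot, der_prot), 1) if a != b]
    if diffs != [338] or ref_prot[337] != "G" or der_prot[337] != "A":
        return None

    return SyntheticAllelePair(
        reference=ref, derived=derived, profile=profile, model=model,
        primer_pair=INDEL_PRIMERS, probe_interval_ref=probe_ref,
        probe_interval_derived=(p0, p1), site_positions_ref=planted_sites,
        insert_segment=INSERT_325)


def extract_cds_shifted(derived: AlleleSequence, model: GeneModel,
                        profile: PolymorphismProfile) -> str:
    """CDS of the derived allele, with exon boundaries shifted by the net
    length of profile indels lying 5' of each exon (intronic/upstream only)."""
    parts = []
    for s, e in model.exons:
        shift = _genic_shift(profile, s)
        parts.append(derived.slice_signed(s + shift, e + shift))
    return "".join(parts)


def _genic_shift(profile: PolymorphismProfile, gene_pos: int) -> int:
    """Net coordinate shift at a gene position from genic indels 5' of it.

    Upstream indels move the anchor, not genic coordinates, so only edits
    with 0 < position < gene_pos contribute.
    """
    return sum(e.net_len for e in profile.edits
               if 0 < e.position < gene_pos and e.vtype != "snv")


# -------------------------------------------------------------- panels etc.

def make_panel(pair: SyntheticAllelePair,
               purple_throat: Sequence[str] = PANEL_PURPLE_THROAT,
               near_white: Sequence[str] = PANEL_NEAR_WHITE) -> list[AlleleSequence]:
    """A genotyping panel: reference copies for purple-throat accessions,
    derived copies for near-white ones."""
    panel = []
    for name in purple_throat:
        panel.append(AlleleSequence(name=name, residues=pair.reference.residues,
                                    anchor=pair.reference.anchor,
                                    genotype_label="W3"))
    for name in near_white:
        panel.append(AlleleSequence(name=name, residues=pair.derived.residues,
                                    anchor=pair.derived.anchor,
                                    genotype_label="w3"))
    return panel


def make_probe_candidates(probe: str, identities: Sequence[float] = (100, 92, 85, 80, 76),
                          seed: int = 1, background_length: int = 2000,
                          ) -> list[tuple[str, str, float]]:
    """Plant degraded probe copies in random backgrounds.

    Returns (candidate_id, sequence, target_identity) triples; the planted
    copy of a candidate at target identity t carries round(L * (1 - t/100))
    substitutions at distinct positions.
    """
    rng = random.Random(f"allelescope-candidates:{seed}")
    out = []
    for k, target in enumerate(identities):
        n_mut = round(len(probe) * (1 - target / 100.0))
        copy = list(probe)
        for p in rng.sample(range(len(probe)), n_mut):
            copy[p] = rng.choice([b for b in "ACGT" if b != copy[p]])
        background = [rng.choice("ACGT") for _ in range(background_length)]
        at = rng.randrange(0, background_length - len(probe))
        background[at:at + len(probe)] = copy
        out.append((f"candidate_{k + 1:02d}_id{target:g}", "".join(background),
                    float(target)))
    return out


def simulate_to_dir(outdir, seed: int = 1) -> SyntheticAllelePair:
    """Emit reference.fa, derived.fa, gene.gff3, primers.tsv, probe.bed,
    anchors.tsv, insert.fa and truth.tsv for a fresh allele pair."""
    import pandas as pd

    os.makedirs(outdir, exist_ok=True)
    pair = make_allele_pair(seed)
    write_fasta(os.path.join(outdir, "reference.fa"),
                [(pair.reference.name, pair.reference.residues)])
    write_fasta(os.path.join(outdir, "derived.fa"),
                [(pair.derived.name, pair.derived.residues)])
    write_fasta(os.path.join(outdir, "insert.fa"),
                [("insert_325", pair.insert_segment)])
    pair.model.to_gff3(os.path.join(outdir, "gene.gff3"),
                       seqid=pair.reference.name)
    with open(os.path.join(outdir, "anchors.tsv"), "w") as fh:
        fh.write(f"{pair.reference.name}\t{pair.reference.anchor}\n")
        fh.write(f"{pair.derived.name}\t{pair.derived.anchor}\n")
    with open(os.path.join(outdir, "primers.tsv"), "w") as fh:
        fh.write("name\tforward\treverse\n")
        fh.write(f"{pair.primer_pair.name}\t{pair.primer_pair.forward}\t"
                 f"{pair.primer_pair.reverse}\n")
    with open(os.path.join(outdir, "probe.bed"), "w") as fh:
        s, e = pair.probe_interval_ref
        fh.write(f"{pair.reference.name}\t{s - 1}\t{e}\tprobe\n")
    rows = [{"position": e.position, "type": e.vtype,
             "ref_len": len(e.ref_segment), "alt_len": len(e.alt_segment),
             "net_len": e.net_len} for e in pair.profile.edits]
    pd.DataFrame(rows).to_csv(os.path.join(outdir, "truth.tsv"),
                              sep="\t", index=False)
    pair.profile.to_yaml(os.path.join(outdir, "profile.yaml"))
    return pair
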