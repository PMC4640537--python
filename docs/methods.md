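# Methods

## Coordinate frame and gene model

All positions are reported in a signed frame anchored at the translation
start: position 1 is the first base of the ATG, genic positions increase
3′-ward through exons and introns, upstream (promoter) positions are
negative with −1 immediately 5′ of the ATG, and there is no position 0.
This is the frame in which promoter variants ("−230") and genic variants
("2,029", "3,941") are conventionally reported, and it lets one catalog
span both regions.

The synthetic gene model has six exons over a 3,966-bp gene body —
(1–180), (501–650), (1101–1320), (2601–2730), (3101–3220), (3729–3966) —
with a 1,500-bp modeled promoter.  The exon boundaries are a design choice
constrained by three requirements: position 2,029 must fall in intron 3,
position 3,941 in the last exon (exon 6), and the CDS (1,038 nt, 345
residues plus stop) must place 3,941 at the middle base of codon 338 so
the planted `GGA→GCA` substitution reads Gly338Ala.  True exon boundaries
of the natural gene are not modeled; only the feature assignment of the
anchored positions matters for the analyses.

## Pairwise alignment and variant calling

Global alignment uses affine-gap scoring **match +1 / mismatch −4 / gap
open −4 / gap extend −1** (a gap of length L costs `open + (L−1)·extend`),
via Biopython's `PairwiseAligner`.  The mismatch penalty is deliberately
steeper than one gap extension: at a replacement locus (a deletion abutting
an unrelated insertion), a milder mismatch (−2) makes it cheaper for the
optimal path to absorb the deleted bases as mismatch columns inside the
insertion, after which the separate insertion/deletion lengths are
unrecoverable.  With −4, representing k unrelated deleted bases as
mismatches costs `−4k` against `−(k+3)+2` for extending both gap runs, so
the clean two-gap representation wins whenever fewer than ~40 % of the
paired bases would match by chance.  Isolated SNV and indel calling is
unaffected (a lone substitution still scores better as a mismatch, −4,
than as two gap opens, −8).

Variant calling converts the alignment's matched blocks into records:
mismatch columns become SNVs; each maximal unaligned stretch becomes one
insertion and/or deletion.  Pure indels are then **right-shifted**
(3′-normalized) to their right-most equivalent placement, bounded by the
next event, so anchors are deterministic across co-optimal alignments; an
indel sharing its locus with a partner gap (a replacement junction) is
left in place so the pair can merge.

`merge_complex(window=10)` merges indel events whose reference anchors lie
within the window into one `complex_indel`.  The merged record spans from
the first to the last affected reference base; when merged events are
separated by intervening matched bases those bases are included in both
segments, so that applying the merged catalog always reconstructs the
other allele exactly (the round-trip invariant).  SNVs are never merged,
and an SNV between two indels keeps them apart.  The 10-bp default treats
events at one junction (0 bp apart, as in the packaged profile) as one
polymorphism while leaving scattered indels separate.  The merged alt-side
segment is rebuilt by replaying the cluster over the reference span rather
than by alt-coordinate arithmetic, which keeps it correct under co-optimal
gap placements.

Protein effects are computed by translating both CDSs (exon boundaries of
the derived allele shifted by the net length of 5′ genic indels).  Exonic
SNVs get `(ref_aa, position, alt_aa)` with 1-based positions from the
initiator Met; synonymous changes show equal amino acids; exonic indels
are flagged `frameshift` (net length not divisible by 3) or
`inframe_indel` without amino-acid coordinates.

## Probe ranking

Candidate ranking uses local alignment (match +1 / mismatch −1 / gap open
−2 / gap extend −1, both strands).  Percent identity is matches over
alignment columns, gap columns included; because a local alignment of an
unrelated sequence can be a few-bp perfect scrap at "100 % identity",
ranking additionally requires the alignment to span at least half the
probe (`min_coverage = 0.5`).  A second identity denominator — matches
over full probe length — is exposed (`identity_over_probe`) and is the
monotone quantity under progressive corruption of a planted copy; column
identity is not monotone, since corrupting a terminal base lets the local
alignment trim it and lose a column rather than a match.

## Restriction digestion and RFLP logic

Digestion is linear (no circular templates), on the supplied strand, with
every possibly-overlapping occurrence of the recognition word cutting at
`site_start + cut_offset − 1 | + cut_offset`; HaeIII is the blunt default
`GGCC:2`.  Fragments always tile the sequence (asserted at construction).
`N` never matches.  The probe-fragment report returns every fragment
overlapping the probe interval by ≥1 bp — more than one when the probe
spans a cut, reproducing a two-band blot.  The two-allele comparison maps
each reference site through the variant catalog and attributes a site
present in exactly one allele to an SNV inside the recognition word when a
unique one exists.

## In-silico PCR and genotyping

A primer binds where it (or its reverse complement) matches with at most
`max_mismatch` mismatches and an exactly matching 3′-terminal run
(default 3 nt); the default is exact matching, reflecting marker primers
designed to perfect-match both alleles.  Products are enumerated in both
template orientations (forward-on-plus with reverse-on-minus, and the
flipped arrangement), measured inclusive of both primer footprints, capped
at 5 kb; the shortest product is reported, several co-minimal products
make the call ambiguous.  The default size rule calls products shorter
than 350 bp reference-type and longer ones derived-type — the midpoint
between the two marker products (200 bp and 511 bp) — with exactly 350 bp
ambiguous; a reference-size ± tolerance rule (200±50 / 511±50) is provided
as an alternative.  Concordance cross-tabulates calls against a phenotype
table under the fixed mapping reference-type ↔ purple throat,
derived-type ↔ near-white; accessions with phenotypes outside the mapping
or missing from either input are excluded and reported.

## Motif scanning

IUPAC patterns expand to character-class regexes over A/C/G/T only, so
`N` in the *sequence* matches nothing.  Overlapping occurrences are all
reported (presence, not counts, is the tested contract); minus-strand hits
are positioned at the plus-strand coordinate of their leftmost base.  The
default set is the three promoter elements named above; more can be loaded
from TSV.

## The synthetic generator

The generator emulates the study's sequence structure, not its base
composition: a uniform-random A/C/G/T background (reproducible per seed)
with planted landmarks — exactly five GGCC sites (all intronic, with the
third spanning 2027–2030 so C2029T destroys it), a probe interval inside
exon 3 placed so its covering fragment is exactly 1,097 bp and fuses to
exactly 1,594 bp when the intron-3 site is lost, primer footprints
flanking −230 giving a 200-bp reference product and a 511-bp derived one,
a CDS with no internal stops, and the Gly codon at residue 338.  An
iterative repair pass resamples single bases until no accidental
restriction site, primer match (either orientation) or scanned motif word
(plus strand) survives outside the planted feature intervals; repairs
inside exons are constrained not to create in-frame stops.  Planted
features themselves are exempt — the reverse primer's footprint inherently
contains `YACT` matches.

Two sequence-design choices make variant recovery *exact for every seed*
rather than merely likely.  First, the 14 replaced promoter bases are a
**G homopolymer** while the 325-bp insert is G-free except the single G of
its planted `NGATT` element (placed >14 bp from either end), and the
junction's flanking bases differ both from G and from the insert's
terminal bases.  Under the scoring above this provably removes every
score-beneficial or co-optimal partial pairing of the deleted segment (or
its flanks) with the insert, so the optimal alignment must represent the
locus as two clean adjacent gap runs of exactly 14 and 325 columns.
Second, every pure indel is anchored: a deletion's first base differs from
the base after its last, and an insertion's first base differs from the
base it precedes, so the 3′-normalized placement is the planted one.
Construction re-verifies all of this per seed (plus digest counts,
fragment lengths, amplicon lengths, motif presence, and the
single-Gly338Ala protein difference) and resamples on the rare failure.

What the generator does **not** emulate: natural base composition and
repeat structure, linkage to other loci, sequencing error, population
variation beyond the single packaged profile, and the true exon boundaries
and intergenic context of the natural gene.  Passing tests therefore
demonstrate the correctness of the pipeline's logic and arithmetic on
structurally faithful input, not performance on raw natural sequence.

Unprinted details of the natural polymorphism set are fixed here by
documented choice: the two intron insertions use placeholder lengths 5 bp
and 8 bp (tests assert their count, not these lengths); the four promoter
substitutions and the 32-bp deletion are placed 5′ of the marker amplicon
(their true position relative to the −230 indel is not recorded), which
also keeps the amplicon difference exactly +311 bp; intronic substitutions
number four including C2029T ("several" in the source description); SNV
alternate bases outside the two fixed substitutions come from a fixed
non-G map so no substitution can create a restriction site or primer
match.

## Determinism and numerics

Every random draw flows from an explicit integer seed (string-salted
`random.Random`; no global state).  Re-running any stage with the same
inputs produces byte-identical outputs.  Alignment scores are small exact
floats; no tolerance-sensitive numerics are involved.  Degenerate inputs
are rejected eagerly with named errors: empty patterns/sequences, position
0, out-of-range intervals, non-IUPAC residues (position-named), missing
anchors (record-named), profile/reference mismatches (edit-named).

## Problem sizes

The packaged alleles are 5,466 bp (reference) and 5,746 bp (derived); a
full global alignment of the pair takes well under a second, and the whole
pipeline (generation, validation, all stages) a few seconds.  Property
suites use 10²–10³ randomized cases per invariant with brute-force oracles
(quadratic DP alignment, sliding-window scans, IUPAC enumeration) on
sequences up to a few hundred bp.

## Known limitations

* Exactly two assembled alleles per comparison; no multi-sample calling,
  no read-level data.
* Minus-strand gene models are not supported (sequences are supplied
  gene-forward).
* Identity percentages for distantly related candidates depend on the
  scoring scheme and denominator; the ranking contract is ordering above a
  threshold, not reproduction of any particular published percentage.
* The merge rule is anchored-distance-based; two biologically unrelated
  indels closer than the window would merge.
* Thermodynamics (Tm, dimers, mispriming beyond the Hamming/3′ rule) are
  outside the PCR model.
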