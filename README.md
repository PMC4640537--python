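# allelescope

Telling two alleles of a flower-color gene apart, entirely in silico.

In soybean, near-white vs purple-throat flowers (under the *w4* background)
track the *W3* locus, whose candidate gene encodes dihydroflavonol
4-reductase (DFR), an anthocyanin-pathway enzyme.  The dominant and
recessive alleles differ by a characteristic polymorphism set: intronic
single-base substitutions (one of which, C2029T, destroys a HaeIII GGCC
restriction site in intron 3), a 12-bp intron deletion, two small intron
insertions, an exon-6 substitution (G3941C, Gly338Ala), and — in the 1.5-kb
promoter — four substitutions, a 32-bp deletion, and a complex indel at
position −230 that replaces 14 bp with a 325-bp insertion (net +311 bp)
carrying putative cis-elements (ARR1AT `NGATT`, CACTFTPPCA1 `YACT`, CAAT
box).  The promoter indel doubles as a codominant PCR marker: primers
flanking it amplify ~200 bp from the dominant allele and ~500 bp from the
recessive one.

`allelescope` implements every computational step of that
characterization as a reusable, tested library with a CLI, plus a synthetic
allele-pair generator so the whole pipeline runs with known ground truth
and no downloads:

* **genemodel** — signed start-codon coordinate frame (position 1 = first
  base of the ATG, upstream positions negative, no position 0), exon/intron
  gene models (GFF3 or TSV), FASTA I/O, CDS extraction, translation.
* **restriction** — generic pattern/cut-offset digestion (HaeIII = `GGCC:2`),
  fragment tiling, probe-covering fragment report, two-allele RFLP
  comparison with site-loss attribution to SNVs.
* **probe_match** — local-alignment ranking of candidate sequences against
  a hybridization probe (both strands, identity and coverage thresholds).
* **variants** — global affine-gap alignment, SNV/indel calling with 3′
  (right-shift) normalization, merging of co-located insertion/deletion
  events into complex-indel records, feature annotation, protein effects,
  TSV and minimal-VCF output.
* **pcr** — in-silico PCR (primer binding with 3′-exactness rule, amplicon
  sizing), size-rule genotyping, genotype–phenotype concordance.
* **motifs** — IUPAC-degenerate cis-element scanning, both strands,
  overlapping hits reported.
* **synthetic** — the generator: plants five GGCC sites, a probe interval
  inside exon 3, primer footprints flanking −230, and derives the
  polymorphic allele from a packaged, editable polymorphism profile.

## Worked example

```python
from allelescope import (make_allele_pair, global_align, call_variants,
                         merge_complex, annotate, protein_effect,
                         rflp_compare, predict_amplicon)

pair = make_allele_pair(seed=1)            # verified W3-like / w3-like pair

catalog = merge_complex(call_variants(
    global_align(pair.reference, pair.derived),
    ref_allele=pair.reference), window=10)
annotate(catalog, pair.model)
protein_effect(catalog, pair.reference, pair.derived, pair.model)

for v in catalog:
    print(v.vtype, v.position, v.net_len, v.feature, v.protein_effect)
```

prints (among 14 records)

```
complex_indel -230 311 upstream None
deletion -1000 -32 upstream None
deletion 3300 -12 intron 5 None
snv 2029 0 intron 3 None
snv 3941 0 exon 6 ('G', 338, 'A')
```

— the −230 record is the merged complex indel (325-bp insertion, 14-bp
deletion, net +311 bp), position 2029 is the site-destroying C→T in
intron 3, and the exon-6 substitution changes Gly338 to Ala.  The RFLP and
marker stages reproduce the diagnostic observables:

```python
rep = rflp_compare(pair.reference, pair.derived,
                   probe_interval_a=pair.probe_interval_ref,
                   probe_interval_b=pair.probe_interval_derived)
print(rep.probe_lengths_a, rep.probe_lengths_b)   # (1097,) (1594,)
print(predict_amplicon(pair.reference, pair.primer_pair).amplicon.length)  # 200
print(predict_amplicon(pair.derived,  pair.primer_pair).amplicon.length)   # 511
```

The numbered drivers under `analysis/` run each stage as a narrative
(`python analysis/01_simulate.py` … `06_motifs.py`), writing tables under
`results/`.  The same workflow is available as a CLI:

```bash
allelescope simulate --seed 1 --outdir sim/
allelescope run-all  --seed 1 --outdir run/
```

## Scope

Wet-lab stages of the original characterization (expression assays,
actual PCR/electrophoresis, multi-species protein alignment) are out of
scope; sequence retrieval from public archives is supported only through an
optional, documented helper that nothing in the package calls by default.
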