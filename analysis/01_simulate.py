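#!/usr/bin/env python
"""Generate the synthetic W3/w3 allele pair and write it with its ground truth.

Emits reference.fa, derived.fa, gene.gff3, primers.tsv, probe.bed,
anchors.tsv, insert.fa, profile.yaml and truth.tsv under results/sim/.
"""

from allelescope import simulate_to_dir

pair = simulate_to_dir("results/sim", seed=1)

print(f"reference allele : {pair.reference.name}, "
      f"{len(pair.reference.residues)} bp (1.5-kb promoter + gene body)")
print(f"derived allele   : {pair.derived.name}, "
      f"{len(pair.derived.residues)} bp "
      f"(net {pair.profile.net_length:+d} bp from {len(pair.profile.edits)} edits)")
print(f"planted GGCC sites (reference residues): {pair.site_positions_ref}")
print(f"probe interval (reference residues)    : {pair.probe_interval_ref}")
print("outputs in results/sim/")
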