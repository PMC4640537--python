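# Soybean accessions with database vs field-observed flower phenotypes.
# Under the w4 background, purple throat marks the W3 allele and near-white
# marks w3; Harosoy (purple, W4 background) and Williams 82 (white, w1) fall
# outside that mapping.  Three accessions are annotated purple throat in the
# germplasm database but were observed near-white in the field.
accession	db_phenotype	observed_phenotype
PI 547524 (L70-4422)	purple throat	purple throat
PI 315701	purple throat	purple throat
PI 417579	purple throat	purple throat
PI 547524	purple throat	purple throat
PI 547750	purple throat	purple throat
PI 547498 (L68-1774)	near-white	near-white
PI 81763	near-white	near-white
PI 81765	near-white	near-white
PI 81767	near-white	near-white
PI 437570	purple throat	near-white
PI 437918	purple throat	near-white
PI 547751	near-white	near-white
PI 550733	purple throat	near-white
PI 548573 (Harosoy)	purple	purple
PI 518671 (Williams 82)	white	white
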