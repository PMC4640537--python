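# Indel-marker primer pair flanking the -230 promoter indel of DFR1
name	forward	reverse
DFR1_indel	CCCCTTAAAAACTGCTCCCATT	GGAGACCAAAGAATTACTAGTGAGTGA
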