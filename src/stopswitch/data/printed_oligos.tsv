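name	sequence	role	reference_sequence	orientation
install_spacer	GAAGCAGCACGACTTCTTCA	CBE install guide spacer (BE4max-SpCas9-NG), target C at protospacer position 5	wt	sense
sgRNA1	CGTGCTACTTCATGTGGTCG	ABE8e correction guide, target A at protospacer position 7	q81x	antisense
sgRNA2	GTCGTGCTACTTCATGTGGT	ABE8e correction guide, target A at protospacer position 9	q81x	antisense
sgRNA3	TCGTGCTACTTCATGTGGTC	ABE8e correction guide, target A at protospacer position 8	q81x	antisense
sa_spacer	AGTCGTGCTACTTCATGTGGT	SaABE8e correction guide spacer (21-mer)	q81x	antisense
ddpcr_fwd_primer	ATCTTCTTCAAGGACGACGGCAAC	ddPCR EGFP forward primer	wt	sense
ddpcr_rev_primer	AGCTCGATGCGGTTCACCAG	ddPCR EGFP reverse primer	wt	antisense
ddpcr_probe	TCGCCCTCGAACTTCACCTCGGCGC	ddPCR EGFP HEX probe	wt	antisense
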