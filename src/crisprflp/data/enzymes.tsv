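# Default restriction-enzyme catalog for RFLP-compatible guide design.
# Motifs and top-strand cut offsets follow the REBASE convention:
# cut_offset is measured in bases from the motif start and may exceed the
# motif length for enzymes that cut outside their recognition site.
name	motif	cut_offset	notes
BslI	CCNNNNNNNGG	7	CCNNNNN^NNGG; large degenerate site, PAM at 3' end
XcmI	CCANNNNNNNNNTGG	8	CCANNNNN^NNNNTGG; 15-nt site, PAM at 3' end
BstXI	CCANNNNNNTGG	8	CCANNNNN^NTGG; PAM at 3' end
MwoI	GCNNNNNNNGC	7	GCNNNNN^NNGC
BsrI	ACTGG	6	ACTGG(1/-1); cuts outside its site
BstNI	CCWGG	2	CC^WGG
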