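# RNA-binding-protein motif families, matched in precedence order (top first).
# pattern is a regex over the RNA alphabet ACGU applied to the pentamer.
# Users may extend or reorder this table; it is data, not code.
family	pattern
RBFOX	GCAUG|UGCAU
hnRNP F/H	GGGG
PTB	UCUC|CUCU
hnRNP L	CACA|ACAC
CELF	UGUU|GUGU
MBNL	[CU]GC[CU]
ESRP	UGG|GGU|GUGG
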