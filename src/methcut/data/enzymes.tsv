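name	recognition	cut_offset_top
AciI	CCGC	1
AclI	AACGTT	2
AgeI	ACCGGT	1
BsrFI	RCCGGY	1
BstBI	TTCGAA	2
MseI	TTAA	1
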