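# SYNTHETIC stand-in morpheme set (editable).
# CpG-rich hexamers standing in for the published MLL1/MLL2 CXXC-domain
# morpheme subset, which this package does not redistribute.  Replace this
# file with the published word list to reproduce a published scan; the
# pipeline's correctness does not depend on the membership of this set.
# Format: one word per line, optional "id<TAB>word"; '#' comments.
M1	CGCGCG
M2	GCGGCG
M3	CGGCGC
M4	CGCCGC
M5	GCCGCC
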