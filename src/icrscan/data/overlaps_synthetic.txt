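# SYNTHETIC stand-in ZFBS-morph overlap set (editable).
# Generated by icrscan.motifs.generate_overlap_motifs from the ZFP57
# binding-site hexamer TGCCGC and the synthetic morpheme set shipped in
# morphemes_synthetic.txt (min_overlap=1).  It is NOT the published
# composite-element list, which this package does not redistribute; replace
# this file with that list to reproduce a published scan.  Every word
# carries >= 2 CpG dinucleotides, the defining property of the class.
# Format: one word per line, optional "id<TAB>word"; '#' comments.
OV1	TGCCGCCGC
OV2	TGCCGCCGCC
OV3	TGCCGCGCCGC
OV4	TGCCGCGCG
OV5	TGCCGCGCGCG
OV6	TGCCGCGGCG
OV7	TGCCGCGGCGC
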