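# alias	canonical
# Editable gene-name synonym map applied (case-insensitively) before
# presence/absence matching in gene_content_matrix.
rnl	rrnL
LSU rRNA	rrnL
23S rRNA	rrnL
rns	rrnS
SSU rRNA	rrnS
16S rRNA	rrnS
rrn5	rrn5
5S rRNA	rrn5
nad4l	nad4L
ymf39	atp4
orf25	atp4
tata	tatA
mttB	tatC
ymf16	tatC
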