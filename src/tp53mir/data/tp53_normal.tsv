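source	source_kind	target	target_kind	sign	context
TP53	TF	miR-107	miRNA	activation	normal
TP53	TF	miR-215	miRNA	activation	normal
TP53	TF	miR-34b/c	miRNA	activation	normal
TP53	TF	miR-125b	miRNA	repression	normal
TP53	TF	miR-155	miRNA	repression	normal
miR-155	miRNA	AGTR1	gene	repression	validated target
miR-155	miRNA	MEIS1	gene	repression	validated target
miR-155	miRNA	LDOC1	gene	repression	validated target
miR-125b	miRNA	BAK1	gene	repression	validated target
miR-215	miRNA	DTL	gene	repression	validated target
miR-215	miRNA	TYMS	gene	repression	validated target
miR-107	miRNA	CDK6	gene	repression	validated target
miR-34b/c	miRNA	MET	gene	repression	validated target
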