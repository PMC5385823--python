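gene	parametric_p	t	cv_support	geomean_class1	geomean_class2	fold_change
MEIS1	3.4e-06	-6	100	925.27	6910.09	0.13
ERBB2	5.4e-06	-5.811	100	16675.06	44388.62	0.38
ERBB3	0.0007684	-3.85	69	9828.1	26238.49	0.37
MATR3	0.0008098	-3.829	46	24373.69	34259.58	0.71
DTL	0.0007551	3.857	69	2800.48	694.82	4.03
EIF2C2	4.48e-05	4.97	100	4086.13	1342.36	3.04
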