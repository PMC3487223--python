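relation_type	seed	n_entities	p_printed
expression_target	INS	16	1.37E-06
expression_target	STAT3	8	6.46E-04
expression_target	PGR	5	1.02E-03
expression_target	SP1	15	1.21E-03
expression_target	NR3C1	7	1.43E-03
expression_target	JUN	8	1.48E-03
expression_target	AKT1	8	2.10E-03
expression_target	CEBPA	8	3.63E-03
expression_target	SMAD	5	3.92E-03
expression_target	IGF1	8	4.86E-03
expression_target	SMAD3	5	5.56E-03
expression_target	HGF	6	5.59E-03
expression_target	SRC	5	6.62E-03
expression_target	Cytokine	13	6.86E-03
expression_target	HIF1A	6	7.38E-03
expression_target	PI3K	8	8.94E-03
expression_target	NF-kB	11	8.97E-03
expression_target	TP53	9	9.81E-03
expression_target	Jun/Fos	9	1.12E-02
expression_target	STAT	5	1.55E-02
expression_target	CTNNB1	5	1.67E-02
expression_target	PKC	8	1.69E-02
expression_target	IL-6	8	1.71E-02
expression_target	Endotoxin	5	2.32E-02
expression_target	IL-1β	8	2.35E-02
expression_target	IFNG	10	2.96E-02
expression_target	TNF	11	3.75E-02
expression_target	EP300	5	4.67E-02
expression_target	TGFB1	10	4.86E-02
expression_target	LEP	5	4.91E-02
binding_partner	Vitamin D	4	2.81E-05
binding_partner	GAPDH	4	7.44E-04
binding_partner	HDL	4	1.36E-03
binding_partner	APP	4	1.92E-03
binding_partner	Myosin	4	3.63E-03
binding_partner	Tubulin	6	5.21E-03
binding_partner	ATP	4	4.82E-02
protein_modification_target	Trypsin	6	4.39E-03
protein_modification_target	GST	4	8.28E-03
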