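# Ionizable-group pKa values (EMBOSS iep defaults).
# group	pka	sign   (+1 protonated form positive, -1 deprotonated form negative)
Nterm	8.6	+1
Cterm	3.6	-1
C	8.5	-1
D	3.9	-1
E	4.1	-1
H	6.5	+1
K	10.8	+1
R	12.5	+1
Y	10.1	-1
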