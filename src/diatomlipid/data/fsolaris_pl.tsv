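class	sn1	sn2	sn3	abundance
PC	20:5	20:5		1.0
PC	20:5	20:4		0.35
PC	20:5	18:4		0.4
PC	20:5	18:3		0.45
PC	20:5	18:2		0.5
PC	20:5	18:1		0.3
PC	20:5	16:1		0.9
PC	20:5	16:0		0.6
PC	16:0	16:1		0.8
PC	16:0	16:0		0.55
PC	14:0	16:1		0.25
PG	16:0	16:1		0.7
PG	20:5	16:0		0.5
PI	16:0	16:1		0.6
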