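class	sn1	sn2	sn3	abundance
MGDG	20:5	16:3		1.0
MGDG	20:5	16:2		0.6
MGDG	20:5	16:1		0.5
MGDG	20:5	16:0		0.4
MGDG	16:3	16:3		0.7
MGDG	16:0	16:3		0.45
MGDG	16:1	16:1		0.3
MGDG	14:0	16:1		0.2
DGDG	20:5	16:3		0.8
DGDG	20:5	16:1		0.5
DGDG	16:0	16:3		0.4
DGDG	16:1	16:1		0.3
DGDG	14:0	16:1		0.2
SQDG	16:0	16:1		0.9
SQDG	16:1	16:1		0.5
SQDG	14:0	16:1		0.3
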