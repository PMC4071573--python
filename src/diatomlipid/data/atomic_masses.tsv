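symbol	monoisotopic_mass_da
C	12.0
H	1.0078250319
N	14.0030740
O	15.9949146
P	30.9737615
S	31.9720707
Na	22.9897693
e-	0.00054858
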