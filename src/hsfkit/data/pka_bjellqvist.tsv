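# Bjellqvist pKa set used for net-charge / isoelectric-point calculation.
# kind: nterm/cterm are terminal groups; pos/neg are ionizable side chains.
group	kind	pka
nterm	positive	7.50
cterm	negative	3.55
K	positive	10.00
R	positive	12.00
H	positive	5.98
D	negative	4.05
E	negative	4.45
C	negative	9.00
Y	negative	10.00
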