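# Expected-by-chance amino-acid frequencies: codon multiplicity / 61 sense
# codons (standard genetic code), the classical random-expectation reference
# for composition comparisons. Editable: supply your own table with the same
# columns to use a different null.
residue	expected
A	0.0656
C	0.0328
D	0.0328
E	0.0328
F	0.0328
G	0.0656
H	0.0328
I	0.0492
K	0.0328
L	0.0984
M	0.0164
N	0.0328
P	0.0656
Q	0.0328
R	0.0984
S	0.0984
T	0.0656
V	0.0656
W	0.0164
Y	0.0328
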