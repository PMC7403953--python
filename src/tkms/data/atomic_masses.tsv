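# Monoisotopic atomic masses (Da), most abundant isotope, neutral atom.
# element<TAB>mass
C	12.000000000
H	1.007825032
N	14.003074005
O	15.994914620
P	30.973761998
S	31.972071174
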