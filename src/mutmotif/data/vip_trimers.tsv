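# Vertical ionization potentials (eV) of guanine-centered double-stranded
# DGN trimers (D = A/G/T on the 5' side, any base on the 3' side), plus the
# free (unalkylated) guanine reference and its experimental band maximum.
trimer	vip_ev
GGG	5.39
GGA	5.50
GGT	5.54
GGC	5.63
AGG	5.57
TGG	5.59
TGA	5.64
AGA	5.66
AGT	5.81
TGT	5.90
AGC	5.95
TGC	5.97
G	8.02
G_exp	8.26
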