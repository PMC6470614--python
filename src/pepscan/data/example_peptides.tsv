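# Example tripeptide activity table. Sequences span several C-terminal
# classes including the four catch-all (XXX) members LVQ, LVE, IWH, GPM;
# all IC50 values are synthetic placeholders (< 20 uM), not measurements.
sequence	ic50_uM	source
IPP	5.0	synthetic fixture value
AKL	14.0	synthetic fixture value
GAY	12.0	synthetic fixture value
VFK	18.0	synthetic fixture value
LRV	19.0	synthetic fixture value
FQG	15.0	synthetic fixture value
LVQ	2.2	synthetic fixture value
LVE	3.9	synthetic fixture value
IWH	1.9	synthetic fixture value
GPM	9.8	synthetic fixture value
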