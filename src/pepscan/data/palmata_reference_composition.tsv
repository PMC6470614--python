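# Literature proximate amino-acid composition of Palmaria palmata (published
# values, % of total AA and % of protein). Asp/Asn and Glu/Gln are combined
# because acid hydrolysis deamidates the amides; Trp is destroyed and absent.
aa	total_aa	protein
A	7.5	6.7
R	6.2	5.1
D+N	9.3	18.5
C	1.3	0
E+Q	13	9.9
G	7.2	13.3
H	2.1	0.5
I	5.3	3.7
L	7.8	7.1
K	8.2	3.3
M	1.9	2.7
F	5.2	5.1
P	4.4
S	4.6	6.3
T	4.5	3.6
Y	4.5	3.4
V	7.3	6.9
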