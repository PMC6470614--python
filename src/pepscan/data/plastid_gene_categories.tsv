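gene	subcategory	category
dnaB	Maintenance	Genetic System
rne	Maintenance	Genetic System
rpoA	RNA polymerase	Genetic System
rpoB	RNA polymerase	Genetic System
rpoC1	RNA polymerase	Genetic System
rpoC2	RNA polymerase	Genetic System
rpoZ	RNA polymerase	Genetic System
ntcA	Transcription factors	Genetic System
ompR	Transcription factors	Genetic System
rbcR	Transcription factors	Genetic System
ycf29	Transcription factors	Genetic System
infB	Translation	Genetic System
infC	Translation	Genetic System
tsf	Translation	Genetic System
tufA	Translation	Genetic System
rpl1	Large subunit	Ribosomal Proteins
rpl2	Large subunit	Ribosomal Proteins
rpl3	Large subunit	Ribosomal Proteins
rpl4	Large subunit	Ribosomal Proteins
rpl5	Large subunit	Ribosomal Proteins
rpl6	Large subunit	Ribosomal Proteins
rpl9	Large subunit	Ribosomal Proteins
rpl11	Large subunit	Ribosomal Proteins
rpl12	Large subunit	Ribosomal Proteins
rpl13	Large subunit	Ribosomal Proteins
rpl14	Large subunit	Ribosomal Proteins
rpl16	Large subunit	Ribosomal Proteins
rpl18	Large subunit	Ribosomal Proteins
rpl19	Large subunit	Ribosomal Proteins
rpl20	Large subunit	Ribosomal Proteins
rpl21	Large subunit	Ribosomal Proteins
rpl22	Large subunit	Ribosomal Proteins
rpl23	Large subunit	Ribosomal Proteins
rpl24	Large subunit	Ribosomal Proteins
rpl27	Large subunit	Ribosomal Proteins
rpl28	Large subunit	Ribosomal Proteins
rpl29	Large subunit	Ribosomal Proteins
rpl31	Large subunit	Ribosomal Proteins
rpl32	Large subunit	Ribosomal Proteins
rpl33	Large subunit	Ribosomal Proteins
rpl34	Large subunit	Ribosomal Proteins
rpl35	Large subunit	Ribosomal Proteins
rpl36	Large subunit	Ribosomal Proteins
rps1	Small subunit	Ribosomal Proteins
rps2	Small subunit	Ribosomal Proteins
rps3	Small subunit	Ribosomal Proteins
rps4	Small subunit	Ribosomal Proteins
rps5	Small subunit	Ribosomal Proteins
rps6	Small subunit	Ribosomal Proteins
rps7	Small subunit	Ribosomal Proteins
rps8	Small subunit	Ribosomal Proteins
rps9	Small subunit	Ribosomal Proteins
rps10	Small subunit	Ribosomal Proteins
rps11	Small subunit	Ribosomal Proteins
rps12	Small subunit	Ribosomal Proteins
rps13	Small subunit	Ribosomal Proteins
rps14	Small subunit	Ribosomal Proteins
rps16	Small subunit	Ribosomal Proteins
rps17	Small subunit	Ribosomal Proteins
rps18	Small subunit	Ribosomal Proteins
rps19	Small subunit	Ribosomal Proteins
rps20	Small subunit	Ribosomal Proteins
tilS	tRNA processing	Ribosomal Proteins
clpC	Protein quality control	Ribosomal Proteins
dnaK	Protein quality control	Ribosomal Proteins
ftsH	Protein quality control	Ribosomal Proteins
groEL	Protein quality control	Ribosomal Proteins
apcA	Phycobilisomes	Photosystems
apcB	Phycobilisomes	Photosystems
apcD	Phycobilisomes	Photosystems
apcE	Phycobilisomes	Photosystems
apcF	Phycobilisomes	Photosystems
rpcA	Phycobilisomes	Photosystems
rpcB	Phycobilisomes	Photosystems
cpcG	Phycobilisomes	Photosystems
cpcS	Phycobilisomes	Photosystems
rpeA	Phycobilisomes	Photosystems
rpeB	Phycobilisomes	Photosystems
nblA	Phycobilisomes	Photosystems
psaA	Photosystem I	Photosystems
psaB	Photosystem I	Photosystems
psaC	Photosystem I	Photosystems
psaD	Photosystem I	Photosystems
psaE	Photosystem I	Photosystems
psaF	Photosystem I	Photosystems
psaI	Photosystem I	Photosystems
psaJ	Photosystem I	Photosystems
psaK	Photosystem I	Photosystems
psaL	Photosystem I	Photosystems
psaM	Photosystem I	Photosystems
ycf3	Photosystem I	Photosystems
ycf4	Photosystem I	Photosystems
psbA	Photosystem II	Photosystems
psbB	Photosystem II	Photosystems
psbC	Photosystem II	Photosystems
psbD	Photosystem II	Photosystems
psbE	Photosystem II	Photosystems
psbF	Photosystem II	Photosystems
psbH	Photosystem II	Photosystems
psbI	Photosystem II	Photosystems
psbJ	Photosystem II	Photosystems
psbK	Photosystem II	Photosystems
psbL	Photosystem II	Photosystems
psbN	Photosystem II	Photosystems
psbT	Photosystem II	Photosystems
psbV	Photosystem II	Photosystems
psbW	Photosystem II	Photosystems
psbX	Photosystem II	Photosystems
psbY	Photosystem II	Photosystems
psbZ	Photosystem II	Photosystems
psb30	Photosystem II	Photosystems
ccs1	Cytochrome complex	Photosystems
ccsA	Cytochrome complex	Photosystems
petA	Cytochrome complex	Photosystems
petB	Cytochrome complex	Photosystems
petD	Cytochrome complex	Photosystems
petF	Cytochrome complex	Photosystems
petG	Cytochrome complex	Photosystems
petJ	Cytochrome complex	Photosystems
petL	Cytochrome complex	Photosystems
petM	Cytochrome complex	Photosystems
petN	Cytochrome complex	Photosystems
acsF	Redox system	Photosystems
bas1	Redox system	Photosystems
dsbD	Redox system	Photosystems
ftrB	Redox system	Photosystems
grx	Redox system	Photosystems
pbsA	Redox system	Photosystems
trxA	Redox system	Photosystems
atpA	ATP synthase	ATP Synthesis
atpB	ATP synthase	ATP Synthesis
atpD	ATP synthase	ATP Synthesis
atpE	ATP synthase	ATP Synthesis
atpF	ATP synthase	ATP Synthesis
atpG	ATP synthase	ATP Synthesis
atpH	ATP synthase	ATP Synthesis
atpI	ATP synthase	ATP Synthesis
cfxQ	Carbohydrates	Metabolism
pdhA	Carbohydrates	Metabolism
pdhB	Carbohydrates	Metabolism
pgmA	Carbohydrates	Metabolism
rbcL	Carbohydrates	Metabolism
rbcS	Carbohydrates	Metabolism
accA	Lipids	Metabolism
accB	Lipids	Metabolism
accD	Lipids	Metabolism
acpP	Lipids	Metabolism
fabH	Lipids	Metabolism
carA	Nucleotides	Metabolism
upp	Nucleotides	Metabolism
argB	Amino acids	Metabolism
gltB	Amino acids	Metabolism
ilvB	Amino acids	Metabolism
ilvH	Amino acids	Metabolism
hisS	Amino acids	Metabolism
syfB	Amino acids	Metabolism
trpA	Amino acids	Metabolism
trpG	Amino acids	Metabolism
chlB	Cofactors	Metabolism
chlI	Cofactors	Metabolism
chlL	Cofactors	Metabolism
chlN	Cofactors	Metabolism
moeB	Cofactors	Metabolism
preA	Cofactors	Metabolism
thiG	Cofactors	Metabolism
thiS	Cofactors	Metabolism
dfr	Secondary metabolites	Metabolism
cemA	Transport	Transport
secA	Transport	Transport
secG	Transport	Transport
secY	Transport	Transport
sufB	Transport	Transport
sufC	Transport	Transport
tatC	Transport	Transport
ycf38	Transport	Transport
ycf63	Transport	Transport
ycf19	Conserved ORFs	Unknown
ycf20	Conserved ORFs	Unknown
ycf21	Conserved ORFs	Unknown
ycf22	Conserved ORFs	Unknown
ycf23	Conserved ORFs	Unknown
ycf33	Conserved ORFs	Unknown
ycf34	Conserved ORFs	Unknown
ycf35	Conserved ORFs	Unknown
ycf36	Conserved ORFs	Unknown
ycf37	Conserved ORFs	Unknown
ycf39	Conserved ORFs	Unknown
ycf41	Conserved ORFs	Unknown
ycf45	Conserved ORFs	Unknown
ycf46	Conserved ORFs	Unknown
ycf52	Conserved ORFs	Unknown
ycf53	Conserved ORFs	Unknown
ycf54	Conserved ORFs	Unknown
ycf55	Conserved ORFs	Unknown
ycf56	Conserved ORFs	Unknown
ycf60	Conserved ORFs	Unknown
ycf65	Conserved ORFs	Unknown
ycf80	Conserved ORFs	Unknown
ycf92	Conserved ORFs	Unknown
orf55	Unique ORFs	Unknown
orf88	Unique ORFs	Unknown
orf169	Unique ORFs	Unknown
orf402	Unique ORFs	Unknown
orf441	Unique ORFs	Unknown
orf768	Unique ORFs	Unknown
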