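# NCBI genetic code 9 (echinoderm/flatworm mitochondrial)
# name: echinoderm_mt
# columns: codon<TAB>amino acid one-letter or * for stop<TAB>start flag (M for initiation codon)
TTT	F	-
TTC	F	-
TTA	L	-
TTG	L	-
TCT	S	-
TCC	S	-
TCA	S	-
TCG	S	-
TAT	Y	-
TAC	Y	-
TAA	*	-
TAG	*	-
TGT	C	-
TGC	C	-
TGA	W	-
TGG	W	-
CTT	L	-
CTC	L	-
CTA	L	-
CTG	L	-
CCT	P	-
CCC	P	-
CCA	P	-
CCG	P	-
CAT	H	-
CAC	H	-
CAA	Q	-
CAG	Q	-
CGT	R	-
CGC	R	-
CGA	R	-
CGG	R	-
ATT	I	-
ATC	I	-
ATA	I	-
ATG	M	M
ACT	T	-
ACC	T	-
ACA	T	-
ACG	T	-
AAT	N	-
AAC	N	-
AAA	N	-
AAG	K	-
AGT	S	-
AGC	S	-
AGA	S	-
AGG	S	-
GTT	V	-
GTC	V	-
GTA	V	-
GTG	V	M
GCT	A	-
GCC	A	-
GCA	A	-
GCG	A	-
GAT	D	-
GAC	D	-
GAA	E	-
GAG	E	-
GGT	G	-
GGC	G	-
GGA	G	-
GGG	G	-
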