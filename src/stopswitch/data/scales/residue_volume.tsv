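# Zamyatnin (1972) amino acid residue volumes (cubic Angstrom), Prog Biophys Mol Biol 24:107-123
# columns: aa<TAB>volume_A3
A	88.6
C	108.5
D	111.1
E	138.4
F	189.9
G	60.1
H	153.2
I	166.7
K	168.6
L	166.7
M	162.9
N	114.1
P	112.7
Q	143.8
R	173.4
S	89.0
T	116.1
V	140.0
W	227.8
Y	193.6
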