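# Codon usage, Saccharomyces cerevisiae, per-thousand frequencies.
# Source: standard codon-usage compilation for S. cerevisiae coding sequences
# (GenBank-derived tabulation); values rounded to 0.1 per thousand.
# Columns: codon, amino acid (one letter), frequency per 1000 codons.
codon	aa	freq_per_thousand
TTT	F	26.1
TTC	F	18.4
TTA	L	26.2
TTG	L	27.2
CTT	L	12.3
CTC	L	5.4
CTA	L	13.4
CTG	L	10.5
ATT	I	30.1
ATC	I	17.2
ATA	I	17.8
ATG	M	20.9
GTT	V	22.1
GTC	V	11.8
GTA	V	11.8
GTG	V	10.8
TCT	S	23.5
TCC	S	14.2
TCA	S	18.7
TCG	S	8.6
AGT	S	14.2
AGC	S	9.8
CCT	P	13.5
CCC	P	6.8
CCA	P	18.3
CCG	P	5.3
ACT	T	20.3
ACC	T	12.7
ACA	T	17.8
ACG	T	8.0
GCT	A	21.2
GCC	A	12.6
GCA	A	16.2
GCG	A	6.2
TAT	Y	18.8
TAC	Y	14.8
CAT	H	13.6
CAC	H	7.8
CAA	Q	27.3
CAG	Q	12.1
AAT	N	35.7
AAC	N	24.8
AAA	K	41.9
AAG	K	30.8
GAT	D	37.6
GAC	D	20.2
GAA	E	45.6
GAG	E	19.2
TGT	C	8.1
TGC	C	4.8
TGG	W	10.4
CGT	R	6.4
CGC	R	2.6
CGA	R	3.0
CGG	R	1.7
AGA	R	21.3
AGG	R	9.2
GGT	G	23.9
GGC	G	9.8
GGA	G	10.9
GGG	G	6.0
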