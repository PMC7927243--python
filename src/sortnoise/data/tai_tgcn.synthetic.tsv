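# Synthetic tRNA gene-copy-number table (constructed, not measured data).
# Schema: codon<TAB>tgcn<TAB>s ; one row per (codon, isoacceptor) pairing,
# s = selective constraint on codon-anticodon coupling in [0,1].
codon	tgcn	s
AAA	2	0.0
AAC	3	0.68
AAG	3	0.68
AAG	2	0.41
AAT	2	0.28
AAT	3	0.0
ACA	3	0.68
ACA	5	0.68
ACC	6	0.68
ACC	1	0.68
ACG	5	0.41
ACG	4	0.89
ACT	6	0.68
ACT	4	0.89
AGA	4	0.0
AGA	1	0.68
AGC	0	0.89
AGG	6	0.41
AGG	5	0.0
AGT	2	0.0
AGT	2	0.28
ATA	4	0.28
ATC	5	0.0
ATG	4	0.28
ATG	1	0.0
ATT	4	0.41
ATT	6	0.0
CAA	4	0.68
CAC	5	0.41
CAC	3	0.68
CAG	1	0.0
CAT	5	0.28
CAT	1	0.68
CCA	1	0.41
CCA	5	0.68
CCC	5	0.28
CCG	4	0.28
CCG	1	0.28
CCT	1	0.0
CGA	5	0.89
CGC	2	0.89
CGC	2	0.89
CGG	2	0.41
CGG	2	0.41
CGT	1	0.68
CGT	4	0.0
CTA	4	0.68
CTA	6	0.41
CTC	3	0.28
CTG	6	0.41
CTG	4	0.41
CTT	1	0.68
CTT	1	0.89
GAA	2	0.28
GAC	0	0.89
GAC	0	0.68
GAG	2	0.68
GAT	6	0.0
GCA	2	0.28
GCC	5	0.28
GCG	1	0.0
GCG	4	0.0
GCT	5	0.41
GCT	4	0.28
GGA	3	0.0
GGA	5	0.28
GGC	4	0.28
GGG	5	0.68
GGG	1	0.0
GGT	2	0.89
GTA	1	0.28
GTA	2	0.0
GTC	4	0.28
GTC	3	0.28
GTG	2	0.89
GTG	3	0.41
GTT	4	0.89
TAC	5	0.89
TAC	6	0.0
TAT	4	0.41
TAT	4	0.89
TCA	2	0.68
TCA	1	0.68
TCC	6	0.89
TCG	1	0.41
TCG	2	0.68
TCT	4	0.41
TGC	0	0.68
TGC	0	0.41
TGG	5	0.68
TGT	2	0.89
TTA	5	0.68
TTC	5	0.0
TTG	6	0.28
TTT	3	0.28
TTT	3	0.68
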