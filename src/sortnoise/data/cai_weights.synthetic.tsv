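# Synthetic CAI relative-adaptiveness weights (constructed, not measured data).
# Schema: codon<TAB>w ; per amino-acid family max(w)=1, all w in (0,1].
codon	w
AAA	0.3782
AAC	0.2367
AAG	1.0000
AAT	1.0000
ACA	0.7393
ACC	0.7192
ACG	0.3335
ACT	1.0000
AGA	0.1475
AGC	0.2321
AGG	0.6688
AGT	0.7479
ATA	0.7527
ATC	0.0552
ATG	1.0000
ATT	1.0000
CAA	1.0000
CAC	0.0519
CAG	0.4405
CAT	1.0000
CCA	0.1216
CCC	1.0000
CCG	0.0907
CCT	0.4434
CGA	0.7215
CGC	0.4368
CGG	1.0000
CGT	0.5311
CTA	0.1920
CTC	0.7986
CTG	0.2039
CTT	1.0000
GAA	1.0000
GAC	0.4418
GAG	0.8293
GAT	1.0000
GCA	1.0000
GCC	0.1840
GCG	0.5077
GCT	0.1828
GGA	0.2319
GGC	0.5925
GGG	1.0000
GGT	0.2431
GTA	0.4692
GTC	1.0000
GTG	0.2882
GTT	0.3953
TAC	1.0000
TAT	0.1676
TCA	0.3956
TCC	0.2858
TCG	1.0000
TCT	0.8034
TGC	1.0000
TGG	1.0000
TGT	0.2233
TTA	0.4229
TTC	1.0000
TTG	0.5483
TTT	0.1931
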