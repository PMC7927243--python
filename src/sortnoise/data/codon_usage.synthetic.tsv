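# Synthetic abundance-weighted codon usage U_i (constructed, not measured data).
# Schema: codon<TAB>usage ; usage > 0, arbitrary units.
codon	usage
AAA	2114.1
AAC	1318.7
AAG	2292.6
AAT	5705.4
ACA	3947.9
ACC	3292.9
ACG	1195.9
ACT	1990.0
AGA	6749.4
AGC	10803.8
AGG	2108.8
AGT	5084.9
ATA	4221.7
ATC	13506.4
ATG	4781.9
ATT	5353.4
CAA	4490.5
CAC	2691.1
CAG	2048.3
CAT	3813.9
CCA	759.4
CCC	3921.4
CCG	4285.8
CCT	1453.8
CGA	2863.7
CGC	7215.4
CGG	1875.0
CGT	2029.8
CTA	10043.6
CTC	522.0
CTG	2936.8
CTT	3722.1
GAA	2002.4
GAC	1808.7
GAG	1509.3
GAT	3601.3
GCA	1587.2
GCC	2587.7
GCG	1218.3
GCT	596.3
GGA	5093.7
GGC	5316.6
GGG	3478.6
GGT	4573.2
GTA	2525.1
GTC	7429.9
GTG	10182.6
GTT	5243.8
TAC	16436.7
TAT	4884.4
TCA	1884.5
TCC	3010.7
TCG	3062.3
TCT	3886.0
TGC	2760.8
TGG	2276.9
TGT	1919.6
TTA	2239.5
TTC	11197.1
TTG	696.3
TTT	3358.3
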