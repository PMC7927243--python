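"""Score codon sequences with CAI, TAI, nTE and GC content.

Builds small weight tables from first principles, scores a two-codon toy by
hand-checkable arithmetic, then scores an 8-codon variable region with the
bundled (synthetic, illustrative) tables.
"""

from sortnoise import codon_metrics as cm

# TAI weights from a tiny tRNA supply table: AAA is read by a 4-copy tRNA
# with perfect coupling (s=0), AAG by the same pool with wobble penalty 0.5
src = cm.TaiSourceTable({"AAA": [(4.0, 0.0)], "AAG": [(4.0, 0.5)]})
tai_w = cm.build_tai_weights(src)
print("TAI weights:", tai_w)  # {'AAA': 1.0, 'AAG': 0.5}
print("TAI of AAA+AAG:", cm.compute_tai("AAAAAG", tai_w))  # sqrt(1*0.5) ~ 0.707
# the score is the geometric mean of per-codon weights, so a sequence mixing
# a perfectly adapted and a half-adapted codon lands at ~0.71

# nTE divides tRNA supply by abundance-weighted demand, then renormalizes
nte_w = cm.build_nte_weights_from_usage({"AAA": 10.0, "AAG": 5.0}, tai_w)
print("nTE weights:", nte_w)  # AAG is rarely demanded -> relative supply 1.0

# full bundled tables (synthetic stand-ins; substitute your organism's)
tables = cm.load_synthetic_tables()
region = "GCAAGCAAAGGCGAGGAACTCTTC"  # 8 codons, 24 bases
print("variable region scores:", cm.score_sequence(region, tables))
print("GC content:", cm.gc_content(region))
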