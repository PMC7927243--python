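"""Choose a sorting-bin design by measuring CV² discretization error.

Simulates ten Gamma-distributed strains, applies virtual bins with varying
counts and spacings, and prints the error sweep: the percent deviation of the
binned CV² from the raw CV². Few bins destroy the variability estimate
(a single bin gives 100% error); ~20 bins keep it within a few percent.
"""

import numpy as np

from sortnoise.binning_validation import BinningScheme, cv2_error, sweep_report

rng = np.random.default_rng(7)
strains = {}
for i, mean in enumerate(np.geomspace(1e2, 1e4, 10)):
    shape = rng.uniform(1, 10)
    strains[f"strain{i}"] = rng.gamma(shape, mean / shape, size=20_000)

report = sweep_report(strains, n_bins_list=[1, 5, 10, 20, 40], spacings=["log"])
medians = report.groupby("n_bins")["percent_error"].median()
print("median CV2 percent error by bin count (log spacing):")
print(medians.round(2).to_string())

at20 = report[report["n_bins"] == 20]["percent_error"]
print(f"\nat 20 log bins: {int((at20 < 5).sum())}/10 strains below 5% error")
# the error shrinks monotonically with bin count; 20 log-spaced bins hold the
# CV2 distortion of every typical unimodal strain to a few percent
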