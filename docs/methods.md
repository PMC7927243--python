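# Methods

## Distribution reconstruction from binned counts

Single-cell fluorescence per variant is modelled as Gamma(α, β) (shape,
scale), the standard two-parameter model for protein abundance
distributions. The sorter provides only interval data: cells per
fluorescence bin, with log-spaced gate edges. We therefore fit by maximum
likelihood on the interval-censored (binned multinomial) model: bin b with
linear-scale edges [l_b, u_b) contributes weight n_b · log[F(u_b) − F(l_b)],
where F is the Gamma CDF and n_b the estimated cell count. The bottom gate
is extended to 0 and the top to +∞, because the sorter's outer gates capture
the distribution tails. This is preferred over moment-matching on bin
midpoints, which biases the variance for wide log bins; moment estimates at
the geometric midpoints √(l·u) serve only to seed the optimizer
(Nelder–Mead on (log α, log β), so positivity is structural). Derived
statistics are exact identities of the fit: mean = αβ, variance = αβ²,
CV² = 1/α.

Where only gate edges are known (the sorter case) the representative bin
fluorescence is the geometric midpoint, the natural centre of a log-spaced
bin. In the virtual-binning module the raw values are available, so the
representative value is the within-bin mean, which preserves the sample mean
exactly.

## Normalization and QC

Reads in a bin are scaled to cells: a variant's cell count in bin b is its
read fraction of that bin times the number of cells sorted into the bin, so
per-bin cell totals are conserved by construction. Variants occupying fewer
than 2 bins or with fewer than 20 estimated cells (CPS) are removed — with
one bin the two-parameter fit is unidentifiable, and below ~20 cells the
CV² estimate is dominated by sampling noise. Across replicate sorts, the
percent error of a statistic is the sample standard deviation (ddof = 1)
over the mean, ×100; variants are excluded when the mean's error exceeds
30% or the CV²'s exceeds 40%. The exclusion combines the two thresholds as
"either exceeds" by default (a `require_both` switch gives the laxer
reading); the underlying report of these cut-offs is ambiguous between the
two, and we follow the stricter, more conservative gate.

## Codon metrics

All three indices are geometric means of per-codon weights, computed in log
space so whole-gene scans cannot underflow. CAI uses externally supplied
relative-adaptiveness weights (max 1 per amino-acid family). TAI builds
absolute adaptiveness W_i = Σ_j (1 − s_ij)·tGCN_ij over the isoacceptors
recognizing codon i, normalizes by W_max, and assigns codons with W_i = 0
the geometric mean of the nonzero weights (computed before substitution).
nTE divides the TAI weight (supply) by relative codon usage cu_i = U_i/U_max
with U_i = Σ_j a_j·c_ij (demand, transcript-abundance-weighted), then
renormalizes to max 1. A codon with zero genomic usage but positive supply
weight makes nTE undefined; we raise rather than impute. Stop codons are
rejected: they carry no adaptation weight and cannot occur in a synonymous
coding library. ΔΔG is plain mean-centring of user-supplied folding free
energies; computing the free energies themselves is out of scope.

The bundled weight tables are **constructed synthetic stand-ins** satisfying
all structural invariants (documented schema in `src/sortnoise/data/`); no
test or reported quantity depends on their values — correctness tests use
randomized tables against independent brute-force oracles.

## Synthetic data generator

The generator emulates the reference experimental design: an 8-codon
synonymous library (sequences drawn without replacement from the exact
synonymous space of a fixed peptide), per-variant Gamma fluorescence, and a
sort of 2.16 million cells into 20 log-spaced bins spanning the pooled
library's 0.1–99.9 percentile range, followed by ~195,000 reads per bin
(3.9 M total) with a 9-base bin index, fixed flanks and per-base
substitution errors. Pre-sort abundances are lognormal
(`abundance_sigma`, default 1.5) to reproduce the broadly varying
cells-per-sequence distribution that motivates the CPS filter. Defaults not
fixed by the reference design: Gamma shapes uniform on [1, 10] (CV² 0.1–1,
the plausible range for moderately expressed reporters) and means
log-uniform over [10², 10⁴] fluorescence units (the sorter's usable dynamic
range). Tests and the acceptance studies run scaled-down instances of the
same generator (20–100 variants, 5×10⁴–10⁵ cells, 10³–5×10³ reads/bin),
with sizes stated in each test; the parameter-recovery study narrows the
mean range to ~5-fold and raises the abundance skew to σ = 2.5, mirroring
the reported five-fold mean range of analyzable variants and the heavy
censoring (most sequences below 20 cells) of the real library.

What the generator does **not** model: sorter droplet physics, doublets and
sort impurity, PCR amplification bias (read sampling is uniform
multinomial), optical measurement noise, and basal cell autofluorescence.
Passing tests therefore demonstrate correctness of the reconstruction under
the Gamma model and realistic sampling noise, not robustness to instrument
artifacts. A lognormal fluorescence mode provides a model-mismatch stress
test; `exact_depth` sequences every sorted cell once, giving exactly
proportional read counts for round-trip tests.

## Virtual-binning validation

Discretizing a continuous sample into bins and replacing values by bin means
always shrinks CV² (within-bin variance is discarded), so binned CV² ≤ raw
CV² and the error vanishes as bins multiply. With 20 log-spaced bins,
simulated unimodal strains (Gamma, shapes 1–10, 2×10⁴ cells) keep the CV²
error below 5%. One caveat found in simulation: the log-over-linear
advantage at fixed bin count holds for samples bounded away from zero
(lognormal, or any signal with a basal offset — the flow-cytometry case),
but for Gamma samples whose observed minimum approaches zero, min–max
log-spaced bins spend most of their resolution on nearly empty low decades
and linear spacing can win. The property test asserts the log advantage in
the flow-like regime; CV² here uses the population (n) denominator
(configurable).

## Numerical choices and edge cases

- Bin probabilities are floored at 1e−300 in the likelihood; non-finite
  proposals score +∞, so the optimizer cannot escape the feasible region.
- Fits are flagged `converged`; non-converged variants are excluded
  downstream with a reason code, as are variants whose loosened-filter cell
  vectors occupy a single bin (unidentifiable).
- The rightmost virtual-bin edge is inclusive; values at the lower edge land
  in bin 0.
- Barcode matching is exact by default; an optional ≤1-mismatch rescue
  assigns a read only when exactly one bin barcode is within distance 1
  (simulated bin indexes keep pairwise Hamming distance ≥ 3).
- Demultiplexing discards carry reasons (unmatched index, missing flank /
  indel, ambiguous base); an error in the variable region itself is not
  detectable per-read and surfaces instead as a phantom low-CPS variant,
  which the CPS filter removes — one practical function of that filter.
- All stochastic steps take a mandatory seed; replicate simulations derive
  per-replicate streams from (seed, replicate index) so they share one
  library but are otherwise independent; outputs are byte-reproducible.

## Known limitations

- The Gamma fit assumes a unimodal expression distribution; bimodal variants
  (e.g. bistable promoters) will fit poorly and are only caught indirectly
  by the replicate gate.
- CPS is an estimate (reads → cells), not a direct cell count; at very low
  read depth the filter's effective stringency shifts.
- The regression stage reports simple OLS slope/R²/p per metric without
  multiple-testing correction, matching standard practice for these
  metric-association summaries.
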