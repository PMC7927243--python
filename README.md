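# sortnoise

Sort-seq reconstruction of single-cell gene-expression variability, for
groups measuring how synonymous codon choice shapes protein expression
**noise** in massively parallel reporter libraries.

In a Sort-seq experiment a pooled library of fluorescent-reporter variants
(e.g. a GFP with its first eight codons synonymously randomized) is sorted by
FACS into ~20 fluorescence bins on a logarithmic scale; each bin is barcoded
and sequenced, so a variant's read distribution across bins encodes its
single-cell expression distribution. `sortnoise` turns those reads back into
distribution statistics and relates them to codon-usage metrics.

## The model

Per variant, single-cell fluorescence x is modelled as Gamma-distributed,

    P(x) = x^(α−1) e^(−x/β) / (β^α Γ(α)),

and the fit to the binned cell counts is by **interval-censored maximum
likelihood**: the probability of a cell landing in bin b with linear-scale
edges [l_b, u_b) is F(u_b; α, β) − F(l_b; α, β), weighted by the estimated
cell count in the bin. Reported statistics follow from the fitted shape α and
scale β:

    mean = αβ,   variance = αβ²,   CV² = variance/mean² = 1/α.

Around this sit the standard Sort-seq processing steps: demultiplexing by a
9-base bin index, read-to-cell normalization (reads in a bin are scaled to
the number of cells the sorter deposited there), minimum-sampling filters
(≥ 2 occupied bins, ≥ 20 cells per sequence), and a reproducibility gate on
replicate percent errors (≤ 30% on mean, ≤ 40% on CV²).

Sequences are scored with the field's codon-adaptation indices — CAI
(geometric mean of relative-adaptiveness weights), TAI (weights from tRNA
gene copy numbers with wobble-coupling penalties) and nTE (tRNA supply over
transcript-abundance-weighted demand) — plus GC content and mean-centred
mRNA folding free energies (ΔΔG), and a `binning_validation` module
quantifies the CV² discretization error of any virtual-bin design. A
ground-truthed simulator (`synthetic_data`) makes every stage testable
without experimental data.

## Worked example

```python
from sortnoise.pipeline import RunConfig, run_all
from sortnoise.synthetic_data import SimulationConfig

sim = SimulationConfig(seed=11, n_variants=20, total_cells=50_000,
                       reads_per_bin=2000, error_rate=0.0, abundance_sigma=0.5)
cfg = RunConfig(outdir="run", seed=11, simulate=sim, n_sim_replicates=1)
run_all(cfg)
```

or, stage by stage, `examples/03_simulate_and_fit.py` prints:

```
assigned 40000/40000 reads; discards: {}
20 variants pass the sampling filters (0 removed)

   variant  true mean   fit mean  true CV2   fit CV2
  GCTAGCAA      252.1      253.3     0.352     0.337
  GCGTCAAA      477.1      475.8     0.321     0.340
  GCCTCTAA      128.6      124.1     0.572     0.565
```

Each row is one library variant: the Gamma fit recovers the true mean to a
few percent, and the recovered CV² (= 1/α, the noise) tracks the true value
with precision limited by how many cells the variant contributed to the
sort. The other scripts in `examples/` cover codon scoring, bin-design
validation and the full two-replicate pipeline with its QC funnel; a thin
CLI (`sortnoise simulate|count|fit|filter|score|associate|run-all|binsweep`)
wraps the same functions.

Bundled codon-weight tables are **synthetic stand-ins** (see
`src/sortnoise/data/README.md`); substitute measured organism tables for
real analyses.

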