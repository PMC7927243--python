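# Bundled codon-weight resources (synthetic)

All three tables here are **constructed, synthetic stand-ins** — they satisfy
the structural invariants of real codon-adaptation resources (per-family CAI
maximum of 1, non-negative integer tGCN, wobble constraints `s` in [0, 1],
strictly positive codon usage) so the pipeline runs end-to-end out of the box,
but they are not measured data for any organism. For real analyses substitute
organism-specific tables with the same schema via
`sortnoise.codon_metrics.read_cai_weights` / `read_tai_source` /
`read_codon_usage`.

Schemas (tab-separated, `#` comments, one header row):

| file | columns | meaning |
|------|---------|---------|
| `cai_weights.synthetic.tsv` | `codon`, `w` | relative adaptiveness, max 1 per amino-acid family |
| `tai_tgcn.synthetic.tsv` | `codon`, `tgcn`, `s` | one row per (codon, isoacceptor); gene copy number and coupling constraint |
| `codon_usage.synthetic.tsv` | `codon`, `usage` | transcript-abundance-weighted codon usage `U_i` |
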