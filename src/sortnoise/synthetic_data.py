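"""Ground-truthed Sort-seq simulator: library -> FACS sort -> barcoded reads.

Every downstream stage is testable against known truth:

* **Library**: synonymous-codon variants of a fixed 8-residue peptide, each
  with its own Gamma-distributed single-cell fluorescence (shape ``alpha``,
  scale ``beta``) and a lognormally skewed pre-sort abundance, emulating the
  broad cells-per-sequence spread seen when growth rates differ across
  variants.
* **Sort**: cells are multinomially deposited into log-spaced fluorescence
  bins with probabilities given by each variant's Gamma CDF across the bin
  gates (outer gates capture the tails).
* **Sequencing**: per-bin amplicon reads (9-base bin index + fixed flanks +
  24-base variable region) drawn in proportion to the bin's cell composition,
  with optional per-base substitution errors.

Fluorescence is Gamma by construction, matching the reconstruction model so
baseline tests have zero model mismatch; a lognormal mode provides a
mismatch stress test.
"""

from __future__ import annotations

import itertools
import math
from collections.abc import Sequence
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from scipy import stats

from sortnoise.sortseq_core import (
    BARCODE_LENGTH,
    BinManifest,
    ReadLayout,
)

__all__ = [
    "SimulationConfig",
    "TrueVariant",
    "synonymous_codons",
    "library_space_size",
    "make_library",
    "simulate_sort",
    "simulate_reads",
    "simulate_dataset",
]

_TABLE = CodonTable.unambiguous_dna_by_id[1]

_BACK_TABLE: dict[str, tuple[str, ...]] = {}
for _codon, _aa in _TABLE.forward_table.items():
    _BACK_TABLE.setdefault(_aa, tuple())
_BACK_TABLE = {
    aa: tuple(sorted(c for c, a in _TABLE.forward_table.items() if a == aa))
    for aa in _BACK_TABLE
}


def synonymous_codons(amino_acid: str) -> tuple[str, ...]:
    """All sense codons encoding one amino acid (single-letter code)."""
    try:
        return _BACK_TABLE[amino_acid.upper()]
    except KeyError:
        raise ValueError(f"unknown amino acid {amino_acid!r}") from None


def library_space_size(peptide: str) -> int:
    """Number of distinct synonymous coding sequences for a peptide."""
    size = 1
    for aa in peptide:
        size *= len(synonymous_codons(aa))
    return size


@dataclass(frozen=True)
class TrueVariant:
    """One library member with its ground-truth expression distribution."""

    sequence: str  # 24-base variable region (8 codons)
    alpha: float
    beta: float
    abundance: float  # pre-sort relative abundance; sums to 1 over the library

    @property
    def mean(self) -> float:
        return self.alpha * self.beta

    @property
    def cv2(self) -> float:
        return 1.0 / self.alpha


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for a simulated Sort-seq experiment.

    Defaults mirror the experimental design being emulated: an 8-codon
    synonymous library, 2.16 million cells sorted into 20 log-spaced bins,
    and sequencing depth of 195,000 reads per bin (3.9 million reads over 20
    bins). ``abundance_sigma`` is the lognormal spread of pre-sort variant
    abundances; ``alpha_range`` spans low- to high-noise variants and
    ``mean_range`` spans roughly two decades of fluorescence. ``seed`` is
    mandatory — every stochastic step derives from it.
    """

    seed: int
    n_variants: int = 100
    peptide: str = "ASKGEELF"  # 8 residues downstream of the start codon
    abundance_sigma: float = 1.5
    alpha_range: tuple[float, float] = (1.0, 10.0)
    mean_range: tuple[float, float] = (1e2, 1e4)
    total_cells: int = 2_160_000
    n_bins: int = 20
    spacing: str = "log"
    reads_per_bin: int = 195_000
    error_rate: float = 0.001
    fluorescence_model: str = "gamma"  # or "lognormal" (mismatch stress test)
    exact_depth: bool = False  # sequence every sorted cell exactly once

    def __post_init__(self) -> None:
        if self.n_variants < 1 or self.total_cells < 1 or self.n_bins < 2:
            raise ValueError("n_variants, total_cells and n_bins must be positive")
        if self.reads_per_bin < 0 or not 0 <= self.error_rate < 1:
            raise ValueError("invalid reads_per_bin or error_rate")
        if self.fluorescence_model not in ("gamma", "lognormal"):
            raise ValueError(f"unknown fluorescence model {self.fluorescence_model!r}")
        if len(self.peptide) != 8:
            raise ValueError("the variable region is 8 codons; peptide must be 8 residues")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def make_library(cfg: SimulationConfig, rng: np.random.Generator | None = None) -> list[TrueVariant]:
    """Sample distinct synonymous variants with ground-truth Gamma parameters.

    Enumerates the synonymous space when it is small, otherwise samples
    without replacement; errors if ``n_variants`` exceeds the space, reporting
    the maximum. Gamma shapes are uniform over ``alpha_range``; means are
    log-uniform over ``mean_range`` with ``beta = mean / alpha``; abundances
    are lognormal with spread ``abundance_sigma``, normalized to sum to 1.
    """
    rng = rng or cfg.rng()
    space = library_space_size(cfg.peptide)
    if cfg.n_variants > space:
        raise ValueError(
            f"requested {cfg.n_variants} variants but peptide {cfg.peptide!r} "
            f"has only {space} synonymous coding sequences"
        )
    choices_per_pos = [synonymous_codons(aa) for aa in cfg.peptide]
    if space <= 100_000:
        all_seqs = ["".join(c) for c in itertools.product(*choices_per_pos)]
        picks = rng.choice(space, size=cfg.n_variants, replace=False)
        sequences = [all_seqs[i] for i in picks]
    else:
        seen: set[str] = set()
        while len(seen) < cfg.n_variants:
            seq = "".join(codons[rng.integers(len(codons))] for codons in choices_per_pos)
            seen.add(seq)
        sequences = sorted(seen)

    alphas = rng.uniform(*cfg.alpha_range, size=cfg.n_variants)
    log_lo, log_hi = math.log(cfg.mean_range[0]), math.log(cfg.mean_range[1])
    means = np.exp(rng.uniform(log_lo, log_hi, size=cfg.n_variants))
    raw_abund = rng.lognormal(mean=0.0, sigma=cfg.abundance_sigma, size=cfg.n_variants)
    abund = raw_abund / raw_abund.sum()
    return [
        TrueVariant(sequence=s, alpha=float(a), beta=float(m / a), abundance=float(p))
        for s, a, m, p in zip(sequences, alphas, means, abund)
    ]


def _pooled_edges(lib: Sequence[TrueVariant], cfg: SimulationConfig,
                  rng: np.random.Generator) -> np.ndarray:
    """Log-spaced gate edges spanning the 0.1-99.9 percentile of the pooled library."""
    n_probe = 100_000
    counts = rng.multinomial(n_probe, [v.abundance for v in lib])
    draws = np.concatenate([
        stats.gamma.rvs(v.alpha, scale=v.beta, size=c, random_state=rng)
        for v, c in zip(lib, counts) if c > 0
    ])
    lo, hi = np.percentile(draws, [0.1, 99.9])
    lo = max(lo, 1e-9)
    return np.geomspace(lo, hi, cfg.n_bins + 1)


def _bin_probabilities(v: TrueVariant, edges: np.ndarray, model: str) -> np.ndarray:
    """Per-bin sorting probabilities; outer gates absorb the tails."""
    inner = edges[1:-1]
    if model == "gamma":
        cdf = stats.gamma.cdf(inner, v.alpha, scale=v.beta)
    else:  # lognormal with matched mean and CV²
        sigma2 = math.log1p(v.cv2)
        mu = math.log(v.mean) - sigma2 / 2
        cdf = stats.lognorm.cdf(inner, math.sqrt(sigma2), scale=math.exp(mu))
    return np.diff(np.concatenate(([0.0], cdf, [1.0])))


def simulate_sort(
    lib: Sequence[TrueVariant],
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[BinManifest, pd.DataFrame]:
    """Sort the library: multinomial cell deposition into log-spaced bins.

    Returns the resulting bin manifest (``cells_sorted`` = column sums over
    variants) and a ground-truth table with one row per variant: sequence,
    true alpha/beta/abundance and its true cells-per-bin vector in columns
    ``bin00..``. Total cells are conserved exactly.
    """
    rng = rng or cfg.rng()
    edges = _pooled_edges(lib, cfg, rng)
    cells_per_variant = rng.multinomial(cfg.total_cells, [v.abundance for v in lib])
    rows = []
    matrix = np.zeros((len(lib), cfg.n_bins), dtype=np.int64)
    for i, (v, n_cells) in enumerate(zip(lib, cells_per_variant)):
        probs = _bin_probabilities(v, edges, cfg.fluorescence_model)
        matrix[i] = rng.multinomial(n_cells, probs)
        rows.append(
            {"variant": v.sequence, "alpha": v.alpha, "beta": v.beta,
             "abundance": v.abundance, "true_mean": v.mean, "true_cv2": v.cv2}
        )
    truth = pd.DataFrame(rows)
    for b in range(cfg.n_bins):
        truth[f"bin{b:02d}"] = matrix[:, b]
    barcodes = _bin_barcodes(cfg.n_bins, rng)
    manifest = BinManifest(
        lower=edges[:-1],
        upper=edges[1:],
        barcodes=barcodes,
        cells_sorted=matrix.sum(axis=0).astype(float),
        spacing="log",
    )
    return manifest, truth


def _bin_barcodes(n_bins: int, rng: np.random.Generator) -> tuple[str, ...]:
    """Distinct 9-base bin indexes, minimum pairwise Hamming distance 3."""
    bases = np.array(list("ACGT"))
    codes: list[str] = []
    while len(codes) < n_bins:
        cand = "".join(bases[rng.integers(4, size=BARCODE_LENGTH)])
        if all(sum(a != b for a, b in zip(cand, c)) >= 3 for c in codes):
            codes.append(cand)
    return tuple(codes)


def _truth_cell_matrix(truth: pd.DataFrame) -> np.ndarray:
    bin_cols = [c for c in truth.columns if c.startswith("bin")]
    return truth[bin_cols].to_numpy(dtype=np.int64)


def simulate_reads(
    truth: pd.DataFrame,
    manifest: BinManifest,
    cfg: SimulationConfig,
    path: str | Path,
    rng: np.random.Generator | None = None,
    layout: ReadLayout | None = None,
) -> pd.DataFrame:
    """Write barcoded FASTQ reads for every bin and return the read-count truth.

    Each bin receives ``reads_per_bin`` reads allocated multinomially across
    variants in proportion to their cell counts in that bin (empty bins yield
    no reads); with ``cfg.exact_depth`` every sorted cell is instead
    sequenced exactly once, making read counts exactly proportional to cell
    counts. Reads are ``index(9) + upstream flank + variable(24) +
    downstream flank`` with per-base substitution errors at ``error_rate``.
    The returned table holds the error-free read allocation per variant and
    bin, against which demultiplexing can be reconciled exactly when
    ``error_rate = 0``.
    """
    rng = rng or cfg.rng()
    layout = layout or ReadLayout()
    cells = _truth_cell_matrix(truth)
    variants = truth["variant"].tolist()
    n_bins = manifest.n_bins
    read_counts = np.zeros_like(cells)
    header = (
        f"# layout: index({layout.index_length}) + {layout.upstream} + "
        f"variable({layout.variable_length}) + {layout.downstream}\n"
    )
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("")  # FASTQ proper has no header; layout goes in a sidecar
        read_no = 0
        for b in range(n_bins):
            col = cells[:, b].astype(float)
            total = col.sum()
            if total == 0 or (cfg.reads_per_bin == 0 and not cfg.exact_depth):
                continue
            if cfg.exact_depth:
                alloc = cells[:, b].copy()
            else:
                alloc = rng.multinomial(cfg.reads_per_bin, col / total)
            read_counts[:, b] = alloc
            barcode = manifest.barcodes[b]
            for vi, n_reads in enumerate(alloc):
                if n_reads == 0:
                    continue
                template = barcode + layout.upstream + variants[vi] + layout.downstream
                for seq in _mutate_reads(template, n_reads, cfg.error_rate, rng):
                    read_no += 1
                    fh.write(f"@sim_{read_no} bin={b}\n{seq}\n+\n{'I' * len(seq)}\n")
    path.with_suffix(path.suffix + ".layout.txt").write_text(header)
    out = truth[["variant"]].copy()
    for b in range(n_bins):
        out[f"bin{b:02d}"] = read_counts[:, b]
    return out


def _mutate_reads(template: str, n: int, rate: float,
                  rng: np.random.Generator) -> list[str]:
    if rate == 0:
        return [template] * n
    arr = np.frombuffer(template.encode(), dtype=np.uint8)
    reads = np.tile(arr, (n, 1))
    hits = rng.random(reads.shape) < rate
    if hits.any():
        # substitute with a uniformly random *different* base
        bases = np.frombuffer(b"ACGT", dtype=np.uint8)
        idx = np.nonzero(hits)
        current = reads[idx]
        offsets = rng.integers(1, 4, size=current.shape)
        base_pos = np.searchsorted(bases, current)
        reads[idx] = bases[(base_pos + offsets) % 4]
    return ["".join(chr(c) for c in row) for row in reads]


def simulate_replicates(
    cfg: SimulationConfig, n_replicates: int, outdir: str | Path
) -> list[dict[str, Path]]:
    """Simulate replicate sorts of ONE shared library.

    The library (sequences, true Gamma parameters, abundances) is drawn once
    from ``cfg.seed``; each replicate then re-sorts and re-sequences it with
    an independent stream derived from (seed, replicate index), emulating
    independent experiments on the same pool. Returns per-replicate artifact
    paths as in ``simulate_dataset``.
    """
    outdir = Path(outdir)
    lib = make_library(cfg, cfg.rng())
    results = []
    for i in range(n_replicates):
        rep_rng = np.random.default_rng([cfg.seed, i])
        repdir = outdir / f"rep{i}"
        repdir.mkdir(parents=True, exist_ok=True)
        manifest, truth = simulate_sort(lib, cfg, rep_rng)
        fastq = repdir / "reads.fastq"
        simulate_reads(truth, manifest, cfg, fastq, rep_rng)
        manifest_path = repdir / "manifest.tsv"
        manifest.to_tsv(manifest_path)
        truth_path = repdir / "truth.tsv"
        truth.to_csv(truth_path, sep="\t", index=False)
        results.append({"fastq": fastq, "manifest": manifest_path, "truth": truth_path})
    return results


def simulate_dataset(cfg: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """One-call simulation: library, sort, reads; writes all artifacts to disk.

    Emits ``reads.fastq``, ``manifest.tsv`` and ``truth.tsv`` (per-variant
    ground truth with true parameters and cells per bin) and returns their
    paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = cfg.rng()
    lib = make_library(cfg, rng)
    manifest, truth = simulate_sort(lib, cfg, rng)
    fastq = outdir / "reads.fastq"
    simulate_reads(truth, manifest, cfg, fastq, rng)
    manifest_path = outdir / "manifest.tsv"
    manifest.to_tsv(manifest_path)
    truth_path = outdir / "truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    return {"fastq": fastq, "manifest": manifest_path, "truth": truth_path}
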