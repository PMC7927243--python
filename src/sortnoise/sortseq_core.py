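"""Core Sort-seq reconstruction: reads -> bin counts -> cell counts -> Gamma fits.

The experimental design: a pooled library of fluorescent-reporter variants is
sorted by FACS into fluorescence bins (log-spaced gates), each bin is
amplified with a bin-specific 9-base index and sequenced, and every variant's
read distribution across bins encodes its single-cell expression
distribution. This module reconstructs that distribution per variant:

1. demultiplex reads into bins by index and extract the variable region;
2. normalize read counts to estimated cell counts using the number of cells
   the sorter deposited in each bin;
3. apply minimum-sampling filters (occupied bins, cells per sequence);
4. fit a Gamma distribution to each variant's binned cell counts by
   interval-censored maximum likelihood, yielding shape ``alpha`` and scale
   ``beta`` and hence mean = alpha*beta, variance = alpha*beta**2 and
   CV² = 1/alpha;
5. gate on reproducibility across replicate sorts and regress the
   distribution statistics on sequence metrics.
"""

from __future__ import annotations

import gzip
import math
from collections import Counter
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio.SeqIO.QualityIO import FastqGeneralIterator
from scipy import optimize, special, stats

__all__ = [
    "BinManifest",
    "ReadLayout",
    "DemuxResult",
    "GammaFit",
    "RegressionSummary",
    "demultiplex_and_count",
    "counts_to_cells",
    "filter_variants",
    "fit_gamma",
    "percent_error",
    "replicate_gate",
    "associate_metrics",
]

BARCODE_LENGTH = 9
VARIABLE_REGION_LENGTH = 24


@dataclass(frozen=True)
class BinManifest:
    """The sorting design: ordered fluorescence gates, bin barcodes, cells sorted.

    ``lower``/``upper`` are the gate boundaries in fluorescence units (linear
    scale, strictly increasing and contiguous), ``barcodes`` the 9-base bin
    indexes, ``cells_sorted`` the number of cells the sorter deposited per
    bin. ``spacing`` records whether the gates are log- or linearly spaced;
    for log spacing the upper/lower ratio must be constant across bins.
    """

    lower: np.ndarray
    upper: np.ndarray
    barcodes: tuple[str, ...]
    cells_sorted: np.ndarray
    spacing: str = "log"

    def __post_init__(self) -> None:
        lower = np.asarray(self.lower, dtype=float)
        upper = np.asarray(self.upper, dtype=float)
        cells = np.asarray(self.cells_sorted, dtype=float)
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)
        object.__setattr__(self, "cells_sorted", cells)
        n = len(lower)
        if not (len(upper) == len(self.barcodes) == len(cells) == n) or n < 1:
            raise ValueError("manifest columns have inconsistent lengths")
        if np.any(upper <= lower):
            raise ValueError("each bin's upper bound must exceed its lower bound")
        if n > 1 and not np.allclose(upper[:-1], lower[1:], rtol=1e-9):
            raise ValueError("bins must be contiguous (upper[i] == lower[i+1])")
        if np.any(cells < 0):
            raise ValueError("cells_sorted must be non-negative")
        for bc in self.barcodes:
            if len(bc) != BARCODE_LENGTH or any(b not in "ACGT" for b in bc):
                raise ValueError(f"bin barcode {bc!r} is not {BARCODE_LENGTH} ACGT bases")
        if len(set(self.barcodes)) != n:
            raise ValueError("bin barcodes must be pairwise distinct")
        if self.spacing not in ("log", "linear"):
            raise ValueError(f"unknown spacing {self.spacing!r}")
        if self.spacing == "log":
            if np.any(lower <= 0):
                raise ValueError("log-spaced bins require positive bounds")
            ratios = upper / lower
            if not np.allclose(ratios, ratios[0], rtol=1e-6):
                raise ValueError("log spacing requires a constant upper/lower ratio")

    @property
    def n_bins(self) -> int:
        return len(self.lower)

    def barcode_index(self) -> dict[str, int]:
        return {bc: i for i, bc in enumerate(self.barcodes)}

    def representative_fluorescence(self) -> np.ndarray:
        """Per-bin representative fluorescence on the linear scale.

        The sorter reports only gate edges, so the representative value is the
        geometric midpoint sqrt(lower*upper) — the natural centre of a
        log-spaced bin, already in linear fluorescence units.
        """
        return np.sqrt(self.lower * self.upper)

    # -- I/O ---------------------------------------------------------------

    @classmethod
    def from_frame(cls, df: pd.DataFrame, spacing: str = "log") -> "BinManifest":
        df = df.sort_values("index").reset_index(drop=True)
        return cls(
            lower=df["lower"].to_numpy(float),
            upper=df["upper"].to_numpy(float),
            barcodes=tuple(df["barcode"].astype(str)),
            cells_sorted=df["cells_sorted"].to_numpy(float),
            spacing=spacing,
        )

    @classmethod
    def from_tsv(cls, path: str | Path, spacing: str = "log") -> "BinManifest":
        return cls.from_frame(pd.read_csv(path, sep="\t", comment="#"), spacing=spacing)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "BinManifest":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls.from_frame(pd.DataFrame(doc["bins"]), spacing=doc.get("spacing", "log"))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index": np.arange(self.n_bins),
                "lower": self.lower,
                "upper": self.upper,
                "barcode": list(self.barcodes),
                "cells_sorted": self.cells_sorted,
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class ReadLayout:
    """Amplicon layout: 9-base bin index, fixed flanks, 24-base variable region.

    Reads are ``index + upstream_flank + variable_region + downstream_flank``;
    the bin index sits in the forward primer at the start of the read and the
    flanks are the constant reporter sequence delimiting the mutated codons.
    """

    upstream: str = "ATGCGTAAAGGC"
    downstream: str = "GGTGAAGAACTG"
    index_length: int = BARCODE_LENGTH
    variable_length: int = VARIABLE_REGION_LENGTH

    def extract(self, read: str) -> tuple[str | None, str | None, str | None]:
        """Return (barcode, variable_region, discard_reason) for one read."""
        read = read.upper()
        if len(read) < self.index_length:
            return None, None, "read_too_short"
        barcode = read[: self.index_length]
        rest = read[self.index_length :]
        start = rest.find(self.upstream)
        if start < 0:
            return barcode, None, "upstream_flank_not_found"
        vr_start = start + len(self.upstream)
        vr_end = vr_start + self.variable_length
        if len(rest) < vr_end + len(self.downstream):
            return barcode, None, "read_too_short"
        if rest[vr_end : vr_end + len(self.downstream)] != self.downstream:
            return barcode, None, "indel_in_variable_region"
        variable = rest[vr_start:vr_end]
        if any(b not in "ACGT" for b in variable):
            return barcode, None, "ambiguous_base"
        return barcode, variable, None


@dataclass
class DemuxResult:
    """Demultiplexed read counts plus the discard ledger."""

    counts: dict[str, np.ndarray]
    discards: Counter
    n_reads: int
    n_assigned: int

    def to_frame(self, manifest: BinManifest) -> pd.DataFrame:
        df = pd.DataFrame.from_dict(self.counts, orient="index").astype(int)
        df.columns = [f"bin{i:02d}" for i in range(manifest.n_bins)]
        df.index.name = "variant"
        return df.sort_index()


def _open_maybe_gzip(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _iter_read_sequences(reads) -> Iterable[str]:
    if isinstance(reads, (str, Path)):
        with _open_maybe_gzip(reads) as fh:
            for _title, seq, _qual in FastqGeneralIterator(fh):
                yield seq
    else:
        for item in reads:
            yield str(getattr(item, "seq", item))


def demultiplex_and_count(
    reads,
    manifest: BinManifest,
    layout: ReadLayout | None = None,
    *,
    max_barcode_mismatches: int = 0,
) -> DemuxResult:
    """Assign each read to a bin by its 9-base index and count variable regions.

    ``reads`` may be a FASTQ path (plain or gzip), an iterable of SeqRecords,
    or an iterable of raw sequence strings. Every read is either assigned to
    exactly one bin or discarded with a reason (unmatched barcode, missing
    flank / indel, ambiguous base); the discard ledger tallies the reasons.
    Barcode matching is exact by default; ``max_barcode_mismatches=1`` enables
    nearest-barcode rescue when it is unambiguous.
    """
    layout = layout or ReadLayout()
    lookup = manifest.barcode_index()
    counts: dict[str, np.ndarray] = {}
    discards: Counter = Counter()
    n_reads = n_assigned = 0
    for seq in _iter_read_sequences(reads):
        n_reads += 1
        barcode, variable, reason = layout.extract(seq)
        if barcode is not None:
            bin_idx = lookup.get(barcode)
            if bin_idx is None and max_barcode_mismatches > 0:
                bin_idx = _rescue_barcode(barcode, manifest.barcodes, lookup,
                                          max_barcode_mismatches)
            if bin_idx is None:
                discards["unmatched_barcode"] += 1
                continue
        else:
            discards[reason] += 1
            continue
        if reason is not None:
            discards[reason] += 1
            continue
        row = counts.get(variable)
        if row is None:
            row = counts[variable] = np.zeros(manifest.n_bins, dtype=np.int64)
        row[bin_idx] += 1
        n_assigned += 1
    return DemuxResult(counts=counts, discards=discards, n_reads=n_reads, n_assigned=n_assigned)


def _rescue_barcode(barcode, barcodes, lookup, max_mm) -> int | None:
    hits = [
        lookup[bc]
        for bc in barcodes
        if sum(a != b for a, b in zip(barcode, bc)) <= max_mm
    ]
    return hits[0] if len(hits) == 1 else None


def counts_to_cells(
    counts: Mapping[str, np.ndarray], manifest: BinManifest
) -> dict[str, np.ndarray]:
    """Convert per-bin read counts into estimated cell counts.

    Within each bin, a variant's reads are normalized by the bin's total reads
    and multiplied by the number of cells the sorter deposited there, so per
    bin the estimated cells over all variants sum exactly to ``cells_sorted``.
    """
    if not counts:
        return {}
    matrix = np.vstack([np.asarray(v, dtype=float) for v in counts.values()])
    bin_totals = matrix.sum(axis=0)
    occupied = bin_totals > 0
    if np.any(occupied & (manifest.cells_sorted == 0)):
        bad = np.nonzero(occupied & (manifest.cells_sorted == 0))[0]
        raise ValueError(f"bins {bad.tolist()} contain reads but zero cells_sorted")
    scale = np.zeros_like(bin_totals)
    scale[occupied] = manifest.cells_sorted[occupied] / bin_totals[occupied]
    cells = matrix * scale
    return {variant: cells[i] for i, variant in enumerate(counts)}


def filter_variants(
    cells: Mapping[str, np.ndarray],
    *,
    min_bins: int = 2,
    min_cps: float = 20.0,
) -> tuple[dict[str, np.ndarray], dict[str, list[str]]]:
    """Apply the minimum-sampling filters.

    A variant is kept iff it occupies at least ``min_bins`` bins AND its total
    estimated cell count (CPS, cells per sequence) is at least ``min_cps``.
    Removed variants carry reason codes; both filters are checked so a variant
    can fail for more than one reason.
    """
    kept: dict[str, np.ndarray] = {}
    removed: dict[str, list[str]] = {}
    for variant, row in cells.items():
        row = np.asarray(row, dtype=float)
        reasons = []
        if int(np.count_nonzero(row > 0)) < min_bins:
            reasons.append("too_few_bins")
        if row.sum() < min_cps:
            reasons.append("low_cps")
        if reasons:
            removed[variant] = reasons
        else:
            kept[variant] = row
    return kept, removed


@dataclass(frozen=True)
class GammaFit:
    """A fitted Gamma distribution and its derived statistics.

    mean = alpha*beta, variance = alpha*beta**2 and cv2 = 1/alpha hold exactly
    by construction; ``nll`` is the negative log-likelihood of the binned fit.
    """

    alpha: float
    beta: float
    nll: float
    converged: bool

    @property
    def mean(self) -> float:
        return self.alpha * self.beta

    @property
    def variance(self) -> float:
        return self.alpha * self.beta**2

    @property
    def cv2(self) -> float:
        return 1.0 / self.alpha


def _binned_nll(log_params: np.ndarray, edges_lo, edges_hi, weights) -> float:
    with np.errstate(over="ignore", invalid="ignore"):
        alpha, beta = np.exp(log_params)
        if not (np.isfinite(alpha) and np.isfinite(beta)):
            return 1e300
        p = special.gammainc(alpha, edges_hi / beta) - special.gammainc(alpha, edges_lo / beta)
    p = np.clip(p, 1e-300, None)
    return -float(np.dot(weights, np.log(p)))


def fit_gamma(cells_per_bin: np.ndarray, manifest: BinManifest) -> GammaFit:
    """Fit a Gamma distribution to one variant's binned cell counts.

    Maximum likelihood on the interval-censored (binned multinomial) model:
    the probability mass of each bin is the Gamma CDF difference across the
    bin's linear-scale fluorescence edges, weighted by the estimated cell
    count in the bin. The bottom bin is extended to 0 and the top bin to
    +infinity, since the sorter's outer gates capture the distribution tails.
    Moment estimates at the geometric bin midpoints seed the optimizer.
    """
    weights = np.asarray(cells_per_bin, dtype=float)
    if weights.shape != (manifest.n_bins,):
        raise ValueError("cells_per_bin length must equal the number of bins")
    if np.count_nonzero(weights > 0) < 2:
        raise ValueError("need cells in at least 2 bins to fit a distribution")

    mids = manifest.representative_fluorescence()
    total = weights.sum()
    m1 = float(np.dot(weights, mids)) / total
    var = float(np.dot(weights, (mids - m1) ** 2)) / total
    var = max(var, 1e-12 * m1**2)
    alpha0 = max(m1**2 / var, 1e-3)
    beta0 = var / m1

    edges_lo = manifest.lower.copy()
    edges_hi = manifest.upper.copy()
    edges_lo[0] = 0.0
    edges_hi[-1] = np.inf

    result = optimize.minimize(
        _binned_nll,
        x0=np.log([alpha0, beta0]),
        args=(edges_lo, edges_hi, weights),
        method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000},
    )
    alpha, beta = np.exp(result.x)
    converged = bool(result.success and np.isfinite(result.fun))
    return GammaFit(alpha=float(alpha), beta=float(beta), nll=float(result.fun),
                    converged=converged)


# ---------------------------------------------------------------------------
# replicate agreement
# ---------------------------------------------------------------------------

def percent_error(values: Sequence[float]) -> float:
    """Percent error across replicates: sample std (ddof=1) over mean, x100."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("percent error needs at least two replicates")
    mean = arr.mean()
    if mean == 0:
        raise ValueError("percent error undefined for zero mean")
    return float(arr.std(ddof=1) / abs(mean) * 100.0)


def replicate_gate(
    fits: Mapping[str, Sequence[GammaFit]],
    *,
    max_err_mean: float = 30.0,
    max_err_cv2: float = 40.0,
    require_both: bool = False,
) -> tuple[dict[str, dict[str, float]], dict[str, str]]:
    """Gate variants on reproducibility of mean and CV² across replicate sorts.

    Returns (kept, removed). ``kept[variant]`` carries the replicate-averaged
    statistics and their percent errors. By default a variant is excluded when
    EITHER percent error exceeds its threshold (kept iff err_mean <=
    max_err_mean and err_cv2 <= max_err_cv2, both strict "above" exclusions);
    ``require_both=True`` switches to excluding only when both thresholds are
    exceeded. Variants present in fewer than two replicates are excluded.
    """
    kept: dict[str, dict[str, float]] = {}
    removed: dict[str, str] = {}
    for variant, reps in fits.items():
        reps = [f for f in reps if f.converged]
        if len(reps) < 2:
            removed[variant] = "too_few_replicates"
            continue
        means = [f.mean for f in reps]
        cv2s = [f.cv2 for f in reps]
        err_mean = percent_error(means)
        err_cv2 = percent_error(cv2s)
        mean_fail = err_mean > max_err_mean
        cv2_fail = err_cv2 > max_err_cv2
        excluded = (mean_fail and cv2_fail) if require_both else (mean_fail or cv2_fail)
        if excluded:
            removed[variant] = "replicate_error"
        else:
            kept[variant] = {
                "mean": float(np.mean(means)),
                "variance": float(np.mean([f.variance for f in reps])),
                "cv2": float(np.mean(cv2s)),
                "percent_error_mean": err_mean,
                "percent_error_cv2": err_cv2,
                "n_replicates": len(reps),
            }
    return kept, removed


# ---------------------------------------------------------------------------
# metric association
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegressionSummary:
    slope: float
    intercept: float
    r2: float
    pvalue: float
    n: int


def associate_metrics(
    table: pd.DataFrame, metric: str, response: str
) -> RegressionSummary:
    """Ordinary least squares of a distribution statistic on a sequence metric.

    Reports the slope, R² and the two-sided p-value for the slope, matching
    how metric-vs-noise correlations are conventionally summarized.
    """
    sub = table[[metric, response]].dropna()
    if len(sub) < 3:
        raise ValueError("need at least 3 records for a regression")
    res = stats.linregress(sub[metric].to_numpy(float), sub[response].to_numpy(float))
    return RegressionSummary(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        pvalue=float(res.pvalue),
        n=len(sub),
    )
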