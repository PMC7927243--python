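"""Codon-usage metrics for synonymous-codon libraries and whole coding sequences.

Implements the three standard geometric-mean adaptation scores:

* **CAI** (Codon Adaptation Index): geometric mean of per-codon relative
  adaptiveness weights ``w_k`` derived from highly expressed genes.
* **TAI** (tRNA Adaptation Index): geometric mean of per-codon weights built
  from tRNA gene copy numbers (tGCN) discounted by codon-anticodon coupling
  constraints ``s_ij``.
* **nTE** (Normalized Translation Efficiency): tRNA supply (the TAI weight)
  divided by demand (transcript-abundance-weighted codon usage ``cu_i``),
  renormalized to a maximum of one, then geometric-mean aggregated.

Also provides GC content and mean-centred mRNA folding free energies (ddG).
All geometric means are computed in log space so whole-gene scans of long
CDSs cannot underflow.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable

__all__ = [
    "STOP_CODONS",
    "SENSE_CODONS",
    "parse_codons",
    "compute_cai",
    "compute_tai",
    "compute_nte",
    "gc_content",
    "compute_ddg",
    "TaiSourceTable",
    "NteSourceTable",
    "build_tai_weights",
    "build_nte_weights",
    "build_nte_weights_from_usage",
    "read_cai_weights",
    "read_tai_source",
    "read_codon_usage",
    "load_synthetic_tables",
    "score_sequence",
    "score_fasta",
]

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_STANDARD_TABLE.stop_codons)
SENSE_CODONS = tuple(sorted(_STANDARD_TABLE.forward_table))  # 61 codons


def parse_codons(sequence: str | Sequence[str], *, allow_stop: bool = False) -> list[str]:
    """Normalize a nucleotide sequence (or codon list) into uppercase DNA codons.

    Case is folded and RNA ``U`` is mapped to ``T``. Raises ``ValueError`` for
    sequences whose length is not a multiple of three, for non-ACGT bases, for
    empty input, and — unless ``allow_stop`` — for stop codons, which carry no
    adaptation weight.
    """
    if isinstance(sequence, str):
        seq = sequence.strip().upper().replace("U", "T")
        if len(seq) == 0 or len(seq) % 3 != 0:
            raise ValueError(
                f"sequence length {len(seq)} is not a positive multiple of 3"
            )
        codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    else:
        codons = [str(c).strip().upper().replace("U", "T") for c in sequence]
        if not codons:
            raise ValueError("empty codon sequence")
    for codon in codons:
        if len(codon) != 3 or any(b not in "ACGT" for b in codon):
            raise ValueError(f"invalid codon {codon!r}")
        if codon in STOP_CODONS and not allow_stop:
            raise ValueError(f"stop codon {codon} has no adaptation weight")
    return codons


def _geometric_mean_score(codons: list[str], weights: Mapping[str, float], label: str) -> float:
    log_sum = 0.0
    for codon in codons:
        try:
            w = weights[codon]
        except KeyError:
            raise KeyError(f"no {label} weight for codon {codon}") from None
        if not (w > 0):
            raise ValueError(f"{label} weight for codon {codon} must be positive, got {w}")
        log_sum += math.log(w)
    return math.exp(log_sum / len(codons))


def compute_cai(sequence: str | Sequence[str], weights: Mapping[str, float]) -> float:
    """CAI of a sequence: geometric mean of per-codon relative-adaptiveness weights."""
    return _geometric_mean_score(parse_codons(sequence), weights, "CAI")


def compute_tai(sequence: str | Sequence[str], weights: Mapping[str, float]) -> float:
    """TAI of a sequence: geometric mean of per-codon tRNA-adaptiveness weights."""
    return _geometric_mean_score(parse_codons(sequence), weights, "TAI")


def compute_nte(sequence: str | Sequence[str], weights: Mapping[str, float]) -> float:
    """nTE of a sequence: geometric mean of per-codon normalized-efficiency weights."""
    return _geometric_mean_score(parse_codons(sequence), weights, "nTE")


def gc_content(sequence: str | Sequence[str]) -> float:
    """Fraction of G or C bases over the full codon sequence."""
    codons = parse_codons(sequence, allow_stop=True)
    joined = "".join(codons)
    return (joined.count("G") + joined.count("C")) / len(joined)


def compute_ddg(dg: Mapping[str, float]) -> dict[str, float]:
    """Mean-centre per-variant mRNA folding free energies (kcal/mol).

    ddG of a variant is its folding free energy minus the mean over all
    supplied variants, so the output sums to zero.
    """
    if not dg:
        raise ValueError("need at least one variant with a folding free energy")
    values = np.asarray(list(dg.values()), dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite folding free energy supplied")
    center = values.mean()
    return {variant: float(value - center) for variant, value in dg.items()}


# ---------------------------------------------------------------------------
# weight-table construction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TaiSourceTable:
    """tRNA supply table: one row per (codon, isoacceptor) pairing.

    ``entries`` maps a codon to its list of ``(tGCN, s)`` pairs, where tGCN is
    the gene copy number of the recognizing tRNA and ``s`` in [0, 1] is the
    selective constraint on the efficiency of that codon-anticodon coupling.
    """

    entries: Mapping[str, Sequence[tuple[float, float]]]

    def __post_init__(self) -> None:
        for codon, pairs in self.entries.items():
            if codon in STOP_CODONS:
                raise ValueError(f"stop codon {codon} in tRNA supply table")
            for tgcn, s in pairs:
                if tgcn < 0:
                    raise ValueError(f"negative tGCN for {codon}")
                if not 0.0 <= s <= 1.0:
                    raise ValueError(f"s outside [0, 1] for {codon}: {s}")


def build_tai_weights(src: TaiSourceTable) -> dict[str, float]:
    """Turn tGCN/s pairings into per-codon TAI weights.

    The absolute adaptiveness is ``W_i = sum_j (1 - s_ij) * tGCN_ij``; weights
    are ``W_i / W_max`` where ``W_i`` is nonzero, and codons with ``W_i = 0``
    receive the geometric mean of the nonzero weights.
    """
    absolute = {
        codon: sum((1.0 - s) * tgcn for tgcn, s in pairs)
        for codon, pairs in src.entries.items()
    }
    w_max = max(absolute.values(), default=0.0)
    if w_max <= 0:
        raise ValueError("all absolute adaptiveness values are zero; weights undefined")
    nonzero = [w / w_max for w in absolute.values() if w > 0]
    w_mean = math.exp(sum(math.log(w) for w in nonzero) / len(nonzero))
    return {
        codon: (w / w_max if w > 0 else w_mean) for codon, w in absolute.items()
    }


@dataclass(frozen=True)
class NteSourceTable:
    """Codon demand source: transcript abundances and per-gene codon counts.

    ``abundance`` maps gene -> transcript abundance (arbitrary units, >= 0);
    ``codon_counts`` maps gene -> {codon: count}. Codon usage demand is
    ``U_i = sum_j a_j * c_ij`` over all genes j.
    """

    abundance: Mapping[str, float]
    codon_counts: Mapping[str, Mapping[str, int]]

    def __post_init__(self) -> None:
        for gene, a in self.abundance.items():
            if a < 0:
                raise ValueError(f"negative transcript abundance for gene {gene}")
        for gene in self.codon_counts:
            if gene not in self.abundance:
                raise ValueError(f"gene {gene} has codon counts but no abundance")

    def usage(self) -> dict[str, float]:
        """Abundance-weighted codon usage U_i aggregated over genes."""
        usage: dict[str, float] = {}
        for gene, counts in self.codon_counts.items():
            a = self.abundance[gene]
            for codon, c in counts.items():
                if c < 0:
                    raise ValueError(f"negative codon count for {codon} in {gene}")
                usage[codon] = usage.get(codon, 0.0) + a * c
        return usage


def build_nte_weights_from_usage(
    usage: Mapping[str, float], tai_weights: Mapping[str, float]
) -> dict[str, float]:
    """Per-codon nTE weights from aggregated codon usage and TAI weights.

    Normalizes usage to ``cu_i = U_i / U_max``, forms supply/demand ratios
    ``nTE'_i = w_i / cu_i`` and rescales so the maximum weight is one. A codon
    with zero usage but nonzero supply weight is an error: the ratio is
    undefined and we refuse to impute it.
    """
    u_max = max(usage.values(), default=0.0)
    if u_max <= 0:
        raise ValueError("total codon usage is zero; cu_i undefined")
    prime: dict[str, float] = {}
    for codon, w in tai_weights.items():
        u = usage.get(codon, 0.0)
        if u <= 0:
            raise ValueError(
                f"codon {codon} has supply weight {w} but zero genomic usage; "
                "nTE'_i = w_i/cu_i is undefined"
            )
        prime[codon] = w / (u / u_max)
    prime_max = max(prime.values())
    return {codon: p / prime_max for codon, p in prime.items()}


def build_nte_weights(src: NteSourceTable, tai_weights: Mapping[str, float]) -> dict[str, float]:
    """Per-codon nTE weights from a gene-level demand table (see ``NteSourceTable``)."""
    return build_nte_weights_from_usage(src.usage(), tai_weights)


# ---------------------------------------------------------------------------
# file I/O: tab-separated weight tables with header rows
# ---------------------------------------------------------------------------

def _normalize_codon_column(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["codon"] = df["codon"].str.upper().str.replace("U", "T")
    return df


def read_cai_weights(path: str | Path) -> dict[str, float]:
    """Read a CAI weight table: TSV with columns ``codon`` and ``w``."""
    df = _normalize_codon_column(pd.read_csv(path, sep="\t", comment="#"))
    weights = dict(zip(df["codon"], df["w"].astype(float)))
    for codon, w in weights.items():
        if not 0 < w <= 1:
            raise ValueError(f"CAI weight for {codon} outside (0, 1]: {w}")
    return weights


def read_tai_source(path: str | Path) -> TaiSourceTable:
    """Read a tRNA supply table: TSV with columns ``codon``, ``tgcn``, ``s``.

    Multiple rows per codon encode multiple recognizing isoacceptors.
    """
    df = _normalize_codon_column(pd.read_csv(path, sep="\t", comment="#"))
    entries: dict[str, list[tuple[float, float]]] = {}
    for row in df.itertuples(index=False):
        entries.setdefault(row.codon, []).append((float(row.tgcn), float(row.s)))
    return TaiSourceTable(entries)


def read_codon_usage(path: str | Path) -> dict[str, float]:
    """Read aggregated codon usage: TSV with columns ``codon``, ``usage``."""
    df = _normalize_codon_column(pd.read_csv(path, sep="\t", comment="#"))
    return dict(zip(df["codon"], df["usage"].astype(float)))


@dataclass(frozen=True)
class CodonWeightTable:
    """Resolved per-codon weights for all three scores, with a provenance label."""

    cai: Mapping[str, float]
    tai: Mapping[str, float]
    nte: Mapping[str, float]
    provenance: str = "user"


def load_synthetic_tables() -> CodonWeightTable:
    """Load the bundled synthetic weight tables.

    These are constructed illustrative tables (see ``data/README.md`` in the
    package): they satisfy every structural invariant of real CAI / tGCN /
    codon-usage resources so the pipeline runs end-to-end, but they are not
    measured E. coli data. Substitute organism-specific tables via the
    ``read_*`` functions for real analyses.
    """
    root = resources.files("sortnoise") / "data"
    with resources.as_file(root / "cai_weights.synthetic.tsv") as p:
        cai = read_cai_weights(p)
    with resources.as_file(root / "tai_tgcn.synthetic.tsv") as p:
        tai = build_tai_weights(read_tai_source(p))
    with resources.as_file(root / "codon_usage.synthetic.tsv") as p:
        nte = build_nte_weights_from_usage(read_codon_usage(p), tai)
    return CodonWeightTable(cai=cai, tai=tai, nte=nte, provenance="synthetic-bundled")


# ---------------------------------------------------------------------------
# scoring convenience
# ---------------------------------------------------------------------------

def score_sequence(sequence: str | Sequence[str], tables: CodonWeightTable) -> dict[str, float]:
    """Score one codon sequence with all three indices plus GC content."""
    codons = parse_codons(sequence)
    return {
        "cai": _geometric_mean_score(codons, tables.cai, "CAI"),
        "tai": _geometric_mean_score(codons, tables.tai, "TAI"),
        "nte": _geometric_mean_score(codons, tables.nte, "nTE"),
        "gc": gc_content(codons),
    }


def score_fasta(path: str | Path, tables: CodonWeightTable) -> pd.DataFrame:
    """Genome-scan mode: score every CDS in a FASTA file over all its codons.

    A single trailing stop codon is stripped; records that do not parse as a
    run of sense codons are reported with NaN scores and a reason.
    """
    rows = []
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper().replace("U", "T")
        if len(seq) >= 3 and seq[-3:] in STOP_CODONS:
            seq = seq[:-3]
        try:
            scores = score_sequence(seq, tables)
            rows.append({"id": record.id, **scores, "n_codons": len(seq) // 3, "note": ""})
        except (ValueError, KeyError) as exc:
            rows.append(
                {"id": record.id, "cai": np.nan, "tai": np.nan, "nte": np.nan,
                 "gc": np.nan, "n_codons": len(seq) // 3, "note": str(exc)}
            )
    return pd.DataFrame(rows)
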