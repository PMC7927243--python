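"""End-to-end orchestration: simulate -> count -> fit -> filter -> score -> associate.

Stages hand off through plain files so each one is independently testable and
a run is restartable; the QC story is a funnel (detected variants -> sampling
filters -> replicate gate -> analyzed variants) and every boundary count is
recorded in the QC summary. A run manifest (seed, thresholds, versions)
suffices to reproduce the run.
"""

from __future__ import annotations

import json
import logging
import math
from collections.abc import Sequence
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from sortnoise import __version__, codon_metrics
from sortnoise.sortseq_core import (
    BinManifest,
    GammaFit,
    ReadLayout,
    associate_metrics,
    counts_to_cells,
    demultiplex_and_count,
    filter_variants,
    fit_gamma,
    replicate_gate,
)
from sortnoise.synthetic_data import SimulationConfig, simulate_replicates

__all__ = ["RunConfig", "run_replicate", "run_all"]

logger = logging.getLogger("sortnoise")

METRIC_COLUMNS = ("cai", "tai", "nte", "gc")
RESPONSE_COLUMNS = ("mean", "variance", "cv2")


@dataclass
class RunConfig:
    """All knobs for a full run; defaults are the reference study conditions.

    ``replicates`` is a list of (fastq, manifest) path pairs. When it is
    empty, ``simulate`` must hold a simulation config: one shared library is
    generated and sorted/sequenced ``n_sim_replicates`` times. Thresholds: variants must occupy >= 2 bins
    and have >= 20 estimated cells (CPS), and replicate percent errors must
    not exceed 30% on the mean or 40% on CV².
    """

    outdir: Path
    seed: int = 0
    replicates: list[tuple[Path, Path]] = field(default_factory=list)
    simulate: SimulationConfig | None = None
    n_sim_replicates: int = 2
    min_bins: int = 2
    min_cps: float = 20.0
    max_err_mean: float = 30.0
    max_err_cv2: float = 40.0
    require_both: bool = False
    ddg_path: Path | None = None
    weight_tables: codon_metrics.CodonWeightTable | None = None

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if not self.replicates and self.simulate is None:
            raise ValueError("config needs either replicate inputs or simulation configs")


def run_replicate(
    fastq: Path,
    manifest_path: Path,
    *,
    min_bins: int = 2,
    min_cps: float = 20.0,
    layout: ReadLayout | None = None,
) -> dict:
    """Run one replicate through demux, normalization, filters and Gamma fits."""
    manifest = BinManifest.from_tsv(manifest_path)
    demux = demultiplex_and_count(fastq, manifest, layout)
    cells = counts_to_cells(demux.counts, manifest)
    kept, removed = filter_variants(cells, min_bins=min_bins, min_cps=min_cps)
    fits: dict[str, GammaFit] = {}
    failed_fits = []
    for variant, row in kept.items():
        try:
            fit = fit_gamma(row, manifest)
        except ValueError:  # e.g. single occupied bin when min_bins is loosened
            failed_fits.append(variant)
            continue
        if fit.converged:
            fits[variant] = fit
        else:
            failed_fits.append(variant)
    logger.info(
        "replicate %s: %d reads, %d assigned, %d variants detected, %d pass filters, %d fits",
        fastq, demux.n_reads, demux.n_assigned, len(cells), len(kept), len(fits),
    )
    return {
        "manifest": manifest,
        "demux": demux,
        "cells": cells,
        "kept": kept,
        "removed": removed,
        "fits": fits,
        "failed_fits": failed_fits,
    }


def _score_variants(variants: Sequence[str],
                    tables: codon_metrics.CodonWeightTable,
                    ddg: dict[str, float] | None) -> pd.DataFrame:
    rows = []
    for v in variants:
        try:
            scores = codon_metrics.score_sequence(v, tables)
        except (ValueError, KeyError) as exc:
            scores = {m: np.nan for m in METRIC_COLUMNS}
            scores["score_note"] = str(exc)
        rows.append({"variant": v, **scores})
    df = pd.DataFrame(rows, columns=["variant", *METRIC_COLUMNS] if not rows else None)
    if ddg is not None:
        df["ddg"] = df["variant"].map(ddg)
    return df


def run_all(cfg: RunConfig) -> dict:
    """Execute the full pipeline and write the report bundle to ``cfg.outdir``.

    Produces ``variant_table.tsv`` (statistics, QC flags, metric scores),
    ``qc_summary.json`` (the filter funnel with per-reason counts),
    ``discards.tsv``, ``regressions.tsv`` and ``run_manifest.json``. Returns
    the in-memory results keyed by artifact name.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    replicates = list(cfg.replicates)
    if cfg.simulate is not None:
        for paths in simulate_replicates(cfg.simulate, cfg.n_sim_replicates, outdir / "sim"):
            replicates.append((paths["fastq"], paths["manifest"]))

    rep_results = [
        run_replicate(fq, mf, min_bins=cfg.min_bins, min_cps=cfg.min_cps)
        for fq, mf in replicates
    ]

    detected = sorted(set().union(*(r["cells"].keys() for r in rep_results)))
    removed_reasons: dict[str, str] = {}

    if len(rep_results) > 1:
        common = set(rep_results[0]["fits"])
        for r in rep_results[1:]:
            common &= set(r["fits"])
        fits_by_variant = {v: [r["fits"][v] for r in rep_results] for v in sorted(common)}
        gated, gate_removed = replicate_gate(
            fits_by_variant,
            max_err_mean=cfg.max_err_mean,
            max_err_cv2=cfg.max_err_cv2,
            require_both=cfg.require_both,
        )
        stats_df = pd.DataFrame.from_dict(gated, orient="index")
        removed_reasons.update(gate_removed)
    else:
        only = rep_results[0]
        stats_df = pd.DataFrame.from_dict(
            {
                v: {"mean": f.mean, "variance": f.variance, "cv2": f.cv2,
                    "alpha": f.alpha, "beta": f.beta}
                for v, f in only["fits"].items()
            },
            orient="index",
        )

    for r in rep_results:
        for v, reasons in r["removed"].items():
            removed_reasons.setdefault(v, "+".join(reasons))
        for v in r["failed_fits"]:
            removed_reasons.setdefault(v, "fit_not_converged")
    passing = set(stats_df.index)  # variant ids; index not yet reset here
    for v in detected:  # e.g. detected in one replicate, absent from another
        if v not in passing:
            removed_reasons.setdefault(v, "not_in_all_replicates")

    if stats_df.empty:
        stats_df = pd.DataFrame(columns=["variant", *RESPONSE_COLUMNS])
    else:
        stats_df.index.name = "variant"
        stats_df = stats_df.reset_index()

    tables = cfg.weight_tables or codon_metrics.load_synthetic_tables()
    ddg = None
    if cfg.ddg_path is not None:
        dg_df = pd.read_csv(cfg.ddg_path, sep="\t", comment="#")
        ddg = codon_metrics.compute_ddg(dict(zip(dg_df["variant"], dg_df["dg"])))
    scores = _score_variants(stats_df["variant"].tolist(), tables, ddg)
    variant_table = stats_df.merge(scores, on="variant", how="left")
    variant_table["qc_pass"] = True
    if removed_reasons:
        removed_df = pd.DataFrame(
            {"variant": list(removed_reasons), "qc_reason": list(removed_reasons.values())}
        )
    else:
        removed_df = pd.DataFrame(columns=["variant", "qc_reason"])

    regressions = []
    metric_cols = [m for m in (*METRIC_COLUMNS, "ddg") if m in variant_table.columns]
    for metric in metric_cols:
        for response in RESPONSE_COLUMNS:
            try:
                s = associate_metrics(variant_table, metric, response)
            except ValueError:
                continue
            regressions.append(
                {"metric": metric, "response": response, "slope": s.slope,
                 "r2": s.r2, "pvalue": s.pvalue, "n": s.n}
            )
    regressions_df = pd.DataFrame(regressions)

    qc_summary = {
        "n_replicates": len(rep_results),
        "variants_detected": len(detected),
        "variants_passing": int(len(variant_table)),
        "variants_removed": len(removed_reasons),
        "removed_by_reason": _reason_counts(removed_reasons),
        "discards_per_replicate": [dict(r["demux"].discards) for r in rep_results],
        "reads_per_replicate": [r["demux"].n_reads for r in rep_results],
    }

    float_fmt = "%.10g"
    variant_table.to_csv(outdir / "variant_table.tsv", sep="\t", index=False,
                         float_format=float_fmt)
    removed_df.to_csv(outdir / "removed_variants.tsv", sep="\t", index=False)
    regressions_df.to_csv(outdir / "regressions.tsv", sep="\t", index=False,
                          float_format=float_fmt)
    with open(outdir / "qc_summary.json", "w") as fh:
        json.dump(qc_summary, fh, indent=2, sort_keys=True)
    run_manifest = {
        "sortnoise_version": __version__,
        "seed": cfg.seed,
        "thresholds": {
            "min_bins": cfg.min_bins,
            "min_cps": cfg.min_cps,
            "max_err_mean": cfg.max_err_mean,
            "max_err_cv2": cfg.max_err_cv2,
            "require_both": cfg.require_both,
        },
        "replicates": [[str(a), str(b)] for a, b in replicates],
        "weight_tables": tables.provenance,
    }
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(run_manifest, fh, indent=2, sort_keys=True)

    return {
        "variant_table": variant_table,
        "removed": removed_df,
        "regressions": regressions_df,
        "qc_summary": qc_summary,
        "replicates": rep_results,
    }


def _reason_counts(reasons: dict[str, str]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for reason in reasons.values():
        counts[reason] = counts.get(reason, 0) + 1
    return dict(sorted(counts.items()))
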