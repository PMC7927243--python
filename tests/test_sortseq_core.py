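"""Demultiplexing, normalization, filtering, Gamma fitting and association."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sortnoise.sortseq_core import (
    BinManifest,
    GammaFit,
    ReadLayout,
    associate_metrics,
    counts_to_cells,
    demultiplex_and_count,
    filter_variants,
    fit_gamma,
    percent_error,
    replicate_gate,
)
from tests.conftest import deterministic_barcodes, make_manifest

LAYOUT = ReadLayout()
VR_A = "GCAAGCAAAGGCGAGGAACTCTTC"
VR_B = "GCTTCTAAAGGTGAAGAGCTGTTT"


def make_read(barcode: str, variable: str) -> str:
    return barcode + LAYOUT.upstream + variable + LAYOUT.downstream


class TestBinManifest:
    def test_duplicate_barcodes_rejected(self):
        edges = np.geomspace(1, 100, 3)
        with pytest.raises(ValueError, match="distinct"):
            BinManifest(edges[:-1], edges[1:], ("ACGTACGTA", "ACGTACGTA"),
                        np.array([10.0, 10.0]))

    def test_non_contiguous_bins_rejected(self):
        with pytest.raises(ValueError, match="contiguous"):
            BinManifest(np.array([1.0, 20.0]), np.array([10.0, 200.0]),
                        deterministic_barcodes(2), np.array([10.0, 10.0]))

    def test_log_spacing_requires_constant_ratio(self):
        with pytest.raises(ValueError, match="ratio"):
            BinManifest(np.array([1.0, 10.0]), np.array([10.0, 30.0]),
                        deterministic_barcodes(2), np.array([10.0, 10.0]), spacing="log")

    def test_tsv_round_trip(self, tmp_path, manifest20):
        path = tmp_path / "manifest.tsv"
        manifest20.to_tsv(path)
        loaded = BinManifest.from_tsv(path)
        np.testing.assert_allclose(loaded.lower, manifest20.lower)
        assert loaded.barcodes == manifest20.barcodes


class TestDemultiplex:
    def test_perfect_reads_counted_per_bin(self):
        manifest = make_manifest(2, lo=1, hi=100)
        bcA, bcB = manifest.barcodes
        reads = [make_read(bcA, VR_A), make_read(bcA, VR_B),
                 make_read(bcB, VR_A), make_read(bcB, VR_B)]
        result = demultiplex_and_count(reads, manifest, LAYOUT)
        assert result.n_assigned == 4 and not result.discards
        np.testing.assert_array_equal(result.counts[VR_A], [1, 1])
        np.testing.assert_array_equal(result.counts[VR_B], [1, 1])

    def test_unknown_barcode_discarded_and_logged(self):
        manifest = make_manifest(2, lo=1, hi=100)
        result = demultiplex_and_count(
            [make_read("TTTTTTTTT", VR_A)], manifest, LAYOUT)
        assert result.counts == {} and result.discards["unmatched_barcode"] == 1

    def test_indel_in_variable_region_discarded(self):
        manifest = make_manifest(2, lo=1, hi=100)
        broken = manifest.barcodes[0] + LAYOUT.upstream + VR_A + "A" + LAYOUT.downstream
        result = demultiplex_and_count([broken], manifest, LAYOUT)
        assert result.discards["indel_in_variable_region"] == 1

    def test_ambiguous_base_discarded(self):
        manifest = make_manifest(2, lo=1, hi=100)
        read = make_read(manifest.barcodes[0], VR_A[:-1] + "N")
        result = demultiplex_and_count([read], manifest, LAYOUT)
        assert result.discards["ambiguous_base"] == 1

    def test_one_mismatch_rescue(self):
        manifest = make_manifest(2, lo=1, hi=100)
        bc = manifest.barcodes[0]
        mutated = ("T" if bc[0] != "T" else "G") + bc[1:]
        read = make_read(mutated, VR_A)
        strict = demultiplex_and_count([read], manifest, LAYOUT)
        assert strict.discards["unmatched_barcode"] == 1
        relaxed = demultiplex_and_count([read], manifest, LAYOUT,
                                        max_barcode_mismatches=1)
        assert relaxed.counts[VR_A][0] == 1


class TestCountsToCells:
    def test_direct_substitution(self):
        manifest = make_manifest(2, lo=1, hi=100, cells_sorted=[1000, 500])
        counts = {"v1": np.array([10, 0]), "v2": np.array([90, 0])}
        cells = counts_to_cells(counts, manifest)
        assert cells["v1"][0] == pytest.approx(100.0)
        assert cells["v2"][0] == pytest.approx(900.0)

    def test_empty_bin_gives_zero_cells(self):
        manifest = make_manifest(2, lo=1, hi=100)
        cells = counts_to_cells({"v1": np.array([5, 0])}, manifest)
        assert cells["v1"][1] == 0.0

    def test_conservation_against_per_entry_oracle(self, rng):
        n_bins, n_var = 8, 30
        manifest = make_manifest(n_bins, cells_sorted=rng.integers(100, 5000, n_bins))
        counts = {f"v{i}": rng.integers(0, 50, n_bins) for i in range(n_var)}
        cells = counts_to_cells(counts, manifest)
        matrix = np.vstack(list(cells.values()))
        totals = np.vstack(list(counts.values())).sum(axis=0)
        occupied = totals > 0
        np.testing.assert_allclose(
            matrix.sum(axis=0)[occupied], manifest.cells_sorted[occupied], rtol=1e-12
        )
        for i, v in enumerate(counts):  # per-entry oracle loop
            for b in range(n_bins):
                if totals[b] > 0:
                    expected = counts[v][b] / totals[b] * manifest.cells_sorted[b]
                    assert cells[v][b] == pytest.approx(expected, rel=1e-12)

    def test_reads_in_bin_with_zero_cells_sorted_errors(self):
        manifest = make_manifest(2, lo=1, hi=100, cells_sorted=[0, 100])
        with pytest.raises(ValueError, match="zero cells_sorted"):
            counts_to_cells({"v1": np.array([5, 5])}, manifest)


class TestFilterVariants:
    def test_single_bin_removed_for_bins_reason(self):
        kept, removed = filter_variants({"v": np.array([100.0, 0.0, 0.0])})
        assert not kept and removed["v"] == ["too_few_bins"]

    def test_cps_19_removed(self):
        kept, removed = filter_variants({"v": np.array([10.0, 5.0, 4.0])})
        assert removed["v"] == ["low_cps"]

    def test_cps_20_in_2_bins_kept(self):
        kept, removed = filter_variants({"v": np.array([10.0, 10.0, 0.0])})
        assert "v" in kept and not removed

    def test_filters_idempotent_and_order_independent(self, rng):
        cells = {f"v{i}": rng.uniform(0, 20, 5) * rng.integers(0, 2, 5)
                 for i in range(50)}
        kept_joint, _ = filter_variants(cells)
        bins_first, _ = filter_variants(cells, min_cps=0)
        both, _ = filter_variants(bins_first, min_bins=0)
        cps_first, _ = filter_variants(cells, min_bins=0)
        both_rev, _ = filter_variants(cps_first, min_cps=0)
        assert set(kept_joint) == set(both) == set(both_rev)
        again, _ = filter_variants(kept_joint)
        assert set(again) == set(kept_joint)


class TestGammaFit:
    def test_derived_statistics_closed_form(self):
        fit = GammaFit(alpha=4.0, beta=2.0, nll=0.0, converged=True)
        assert fit.mean == 8.0 and fit.variance == 16.0 and fit.cv2 == 0.25

    def test_parameter_recovery_from_binned_cells(self, rng):
        alpha, scale = 3.0, 50.0
        values = rng.gamma(alpha, scale, size=50_000)
        manifest = make_manifest(20, lo=values.min() * 0.99, hi=values.max() * 1.01)
        edges = np.append(manifest.lower, manifest.upper[-1])
        counts, _ = np.histogram(values, bins=edges)
        fit = fit_gamma(counts.astype(float), manifest)
        assert fit.converged
        assert fit.alpha == pytest.approx(alpha, rel=0.05)
        assert fit.mean == pytest.approx(alpha * scale, rel=0.02)

    def test_single_occupied_bin_rejected(self, manifest20):
        cells = np.zeros(20)
        cells[7] = 500.0
        with pytest.raises(ValueError, match="at least 2 bins"):
            fit_gamma(cells, manifest20)


class TestReplicateGate:
    @staticmethod
    def fits(means, alphas):
        return [GammaFit(alpha=a, beta=m / a, nll=0.0, converged=True)
                for m, a in zip(means, alphas)]

    def test_identical_replicates_kept_with_zero_error(self):
        fits = {"v": self.fits([100, 100, 100], [4, 4, 4])}
        kept, removed = replicate_gate(fits)
        assert kept["v"]["percent_error_mean"] == 0.0 and not removed

    def test_percent_error_std_over_mean(self):
        # oracle: std([100,100,200], ddof=1)=57.735, mean=133.33 -> 43.30%
        assert percent_error([100, 100, 200]) == pytest.approx(43.301, rel=1e-4)

    def test_discordant_means_removed(self):
        fits = {"v": self.fits([100, 100, 200], [4, 4, 4])}
        kept, removed = replicate_gate(fits)
        assert removed["v"] == "replicate_error"

    def test_boundary_errors_kept(self):
        # two replicates: err = sqrt(2)*(x-1)/(x+1)*100; solve for 29% and 39%
        x_mean = (1 + 0.29 / np.sqrt(2)) / (1 - 0.29 / np.sqrt(2))
        x_cv2 = (1 + 0.39 / np.sqrt(2)) / (1 - 0.39 / np.sqrt(2))
        means = [100.0, 100.0 * x_mean]
        alphas = [4.0, 4.0 / x_cv2]  # cv2 = 1/alpha
        assert percent_error(means) == pytest.approx(29.0, rel=1e-9)
        assert percent_error([1 / a for a in alphas]) == pytest.approx(39.0, rel=1e-9)
        kept, removed = replicate_gate({"v": self.fits(means, alphas)})
        assert "v" in kept and not removed

    def test_single_replicate_excluded(self):
        kept, removed = replicate_gate({"v": self.fits([100], [4])})
        assert removed["v"] == "too_few_replicates"

    def test_require_both_mode_keeps_one_sided_outliers(self):
        fits = {"v": self.fits([100, 100, 200], [4, 4, 4])}  # mean err only
        kept, _ = replicate_gate(fits, require_both=True)
        assert "v" in kept


class TestAssociateMetrics:
    def test_collinear_points_r2_one(self):
        df = pd.DataFrame({"tai": [0.1, 0.2, 0.3, 0.4], "mean": [10, 20, 30, 40.0]})
        s = associate_metrics(df, "tai", "mean")
        assert s.r2 == pytest.approx(1.0, abs=1e-12) and s.slope == pytest.approx(100.0)

    def test_five_point_normal_equations_oracle(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0])
        # closed-form normal equations, computed independently
        sxx = ((x - x.mean()) ** 2).sum()
        sxy = ((x - x.mean()) * (y - y.mean())).sum()
        slope = sxy / sxx
        r2 = sxy**2 / (sxx * ((y - y.mean()) ** 2).sum())
        s = associate_metrics(pd.DataFrame({"m": x, "mean": y}), "m", "mean")
        assert s.slope == pytest.approx(slope, rel=1e-12)
        assert s.r2 == pytest.approx(r2, rel=1e-12)

    def test_permuted_metric_shows_no_association(self, rng):
        metric = rng.uniform(0, 1, 200)
        response = 5 * metric + rng.normal(0, 0.1, 200)
        permuted = rng.permutation(metric)
        s = associate_metrics(pd.DataFrame({"m": permuted, "mean": response}), "m", "mean")
        assert s.r2 < 0.05 and s.pvalue > 0.001

    def test_too_few_records_errors(self):
        with pytest.raises(ValueError, match="at least 3"):
            associate_metrics(pd.DataFrame({"m": [1, 2], "mean": [1, 2]}), "m", "mean")
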