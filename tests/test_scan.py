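"""SNP back-solving, weight updates, window binning and region reporting."""

import numpy as np
import pandas as pd
import pytest
import scipy.linalg as la

from sswgwas import genomic as gen
from sswgwas import scan
from sswgwas import ssgblup as ss
from sswgwas import synthetic as syn


class TestWeights:
    @pytest.mark.parametrize(
        "u, p, expected",
        [(0.5, 0.5, 0.125), (0.0, 0.3, 0.0), (1.0, 0.1, 0.18)],
    )
    def test_update_weight_values(self, u, p, expected):
        d = scan.update_weights(np.array([u]), np.array([p]))
        assert d[0] == pytest.approx(expected)

    def test_update_rejects_boundary_frequency(self):
        with pytest.raises(ValueError):
            scan.update_weights(np.array([1.0]), np.array([0.0]))

    @pytest.mark.parametrize(
        "d_new, n, expected",
        [((1.0, 3.0), 2, (0.5, 1.5)), ((2.0, 2.0), 2, (1.0, 1.0))],
    )
    def test_normalize_conserves_trace(self, d_new, n, expected):
        out = scan.normalize_weights(np.array(d_new), float(n))
        assert out == pytest.approx(np.array(expected))
        assert out.sum() == pytest.approx(n)

    def test_normalize_rejects_all_zero(self):
        with pytest.raises(ValueError):
            scan.normalize_weights(np.zeros(3), 3.0)


class TestBacksolve:
    def test_zero_gebv_gives_zero_effects(self, rng):
        Z = rng.standard_normal((5, 8))
        u = scan.backsolve_snp_effects(np.zeros(5), Z, np.ones(8), np.eye(5), 2.0)
        assert np.allclose(u, 0.0)

    def test_consistency_with_unblended_G(self, rng):
        """Z u reproduces the GEBVs exactly when G is built from the same Z, D."""
        n, m = 12, 40
        dos = rng.integers(0, 3, size=(n, m)).astype(float)
        p = np.full(m, 0.4)  # external frequencies keep G full rank
        markers = pd.DataFrame({"snp": [f"s{j}" for j in range(m)],
                                "chrom": [1] * m, "pos": np.arange(m) * 10_000 + 1})
        g = gen.GenotypeMatrix(ids=np.array([f"a{i}" for i in range(n)], dtype=object),
                               dosages=dos, markers=markers)
        G = gen.build_G(g, freqs=p)
        Z = dos - 2 * p
        g_hat = rng.standard_normal(n)
        u = scan.backsolve_snp_effects(g_hat, Z, np.ones(m), G.values, G.lam)
        assert np.abs(Z @ u - g_hat).max() < 1e-8


class TestAssignWindows:
    def test_basic_binning(self):
        markers = pd.DataFrame({"snp": ["a", "b", "c"], "chrom": [1, 1, 1],
                                "pos": [100_000, 500_000, 900_000]})
        out = scan.assign_windows(markers)
        assert list(out["window_start"]) == [0, 0, 800_000]

    def test_boundary_snp_goes_to_second_window(self):
        markers = pd.DataFrame({"snp": ["a"], "chrom": [1], "pos": [800_000]})
        assert scan.assign_windows(markers)["window_start"].iloc[0] == 800_000

    def test_short_chromosome_bin_count(self):
        markers = pd.DataFrame({"snp": [f"s{i}" for i in range(20)], "chrom": [1] * 20,
                                "pos": np.linspace(1, 1_999_999, 20).astype(int)})
        out = scan.assign_windows(markers)
        assert out["window_start"].nunique() <= 3


class TestWindowVariance:
    def test_single_window_covers_everything(self, rng):
        Z = rng.standard_normal((30, 10))
        u = rng.standard_normal(10)
        markers = pd.DataFrame({"snp": [f"s{j}" for j in range(10)],
                                "chrom": [1] * 10, "pos": np.arange(10) * 1000 + 1})
        res = scan.window_variance(Z, u, markers)
        assert len(res) == 1
        assert res["gvar_percent"].iloc[0] == pytest.approx(100.0)

    def test_zero_effects_zero_share(self, rng):
        Z = rng.standard_normal((30, 20))
        u = np.zeros(20)
        u[:10] = rng.standard_normal(10)
        markers = pd.DataFrame({"snp": [f"s{j}" for j in range(20)], "chrom": [1] * 20,
                                "pos": np.concatenate([np.arange(10) * 1000 + 1,
                                                       np.arange(10) * 1000 + 900_000])})
        res = scan.window_variance(Z, u, markers)
        assert res["gvar_percent"].iloc[1] == pytest.approx(0.0)

    def test_snp_empty_bins_absent(self):
        markers = pd.DataFrame({"snp": ["a", "b"], "chrom": [1, 1],
                                "pos": [100_000, 5_000_000]})
        Z = np.random.default_rng(0).standard_normal((10, 2))
        res = scan.window_variance(Z, np.ones(2), markers)
        assert len(res) == 2  # intermediate empty bins never reported


class TestReportRegions:
    def _windows(self, shares):
        return pd.DataFrame({
            "chrom": [1] * len(shares),
            "start": np.arange(len(shares)) * 800_000,
            "end": (np.arange(len(shares)) + 1) * 800_000,
            "n_snps": [5] * len(shares),
            "gvar_percent": shares,
        })

    def test_genome_average_windows_not_significant(self):
        """Windows at the expected genome-wide average share stay below 1%."""
        avg = scan.expected_average_share(2115)
        report = scan.report_regions(self._windows([avg] * 10))
        assert report.significant.empty

    def test_threshold_arithmetic(self):
        report = scan.report_regions(self._windows([2.5, 1.2, 0.9]))
        assert len(report.significant) == 2
        assert report.total_significant_gvar == pytest.approx(3.7)

    def test_flank_extension(self):
        w = pd.DataFrame({"chrom": [4], "start": [4_380_000], "end": [5_980_000],
                          "n_snps": [43], "gvar_percent": [3.07]})
        report = scan.report_regions(w, top_k=1)
        assert report.top_regions["region_start"].iloc[0] == 3_980_000
        assert report.top_regions["region_end"].iloc[0] == 6_380_000

    def test_sorting_and_tiebreak(self):
        w = self._windows([1.5, 2.5, 1.5])
        w.loc[2, "chrom"] = 2
        report = scan.report_regions(w)
        assert report.significant["gvar_percent"].iloc[0] == 2.5
        assert report.significant["chrom"].iloc[1] == 1  # lower chromosome wins the tie


@pytest.fixture(scope="module")
def scan_inputs():
    cfg = syn.SimConfig(
        n_founders=300, n_generations=3, litter_size=3, n_chromosomes=2,
        chrom_length_bp=24_000_000, n_snps_per_chrom=500, h2_target=0.4,
        qtl_windows=(syn.QtlWindow(1, 8_000_000, 8_800_000, 0.2),),
        genotyped_fraction=0.5, seed=23,
    )
    ped, geno, pheno, truth, masked = syn.simulate_dataset(cfg)
    qcg, _ = gen.qc_filter(masked)
    return ped, qcg, pheno, truth


class TestRunWssgwas:

    def test_trace_conserved_every_iteration(self, scan_inputs):
        ped, qcg, pheno, _ = scan_inputs
        res = scan.run_wssgwas(ped, qcg, pheno)
        m = qcg.n_snps
        for h in res.history:
            assert h["weights"].sum() == pytest.approx(m, rel=1e-12)

    def test_single_iteration_keeps_unit_weights_in_G(self, scan_inputs):
        """One iteration is plain unweighted single-step GWAS (D = I in G)."""
        ped, qcg, pheno, _ = scan_inputs
        res = scan.run_wssgwas(ped, qcg, pheno, n_iterations=1)
        assert len(res.history) == 1

    def test_deterministic_end_to_end(self, scan_inputs):
        ped, qcg, pheno, _ = scan_inputs
        r1 = scan.run_wssgwas(ped, qcg, pheno, vc=None)
        r2 = scan.run_wssgwas(ped, qcg, pheno, vc=None)
        assert np.array_equal(r1.snp_effects["weight"], r2.snp_effects["weight"])

    def test_strong_planted_window_found(self, scan_inputs):
        """A 20%-variance window lands among the top hits and clears 1%."""
        ped, qcg, pheno, truth = scan_inputs
        res = scan.run_wssgwas(ped, qcg, pheno)
        top3 = res.windows.sort_values("gvar_percent", ascending=False).head(3)
        planted = top3[(top3["chrom"] == 1) & (top3["start"] == 8_000_000)]
        assert len(planted) == 1
        assert planted["gvar_percent"].iloc[0] > scan.GVAR_THRESHOLD_PERCENT

    def test_plot_writes_file(self, scan_inputs, tmp_path):
        ped, qcg, pheno, _ = scan_inputs
        res = scan.run_wssgwas(ped, qcg, pheno, n_iterations=1)
        out = tmp_path / "windows.png"
        scan.plot_windows(res.windows, out)
        assert out.exists() and out.stat().st_size > 0


class TestAverageShare:
    def test_value_and_threshold_ratio(self):
        avg = scan.expected_average_share(2115)
        assert avg == pytest.approx(0.0473, abs=5e-5)
        assert scan.GVAR_THRESHOLD_PERCENT / avg >= 20.0

    def test_rejects_nonpositive_count(self):
        with pytest.raises(ValueError):
            scan.expected_average_share(0)
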