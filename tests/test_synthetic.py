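"""Properties of the synthetic population generator."""

import numpy as np
import pandas as pd
import pytest

from sswgwas import synthetic as syn
from sswgwas.pedigree import Pedigree


def _cfg(**over) -> syn.SimConfig:
    base = dict(
        n_founders=40,
        n_generations=3,
        litter_size=2,
        n_chromosomes=2,
        chrom_length_bp=20_000_000,
        n_snps_per_chrom=200,
        genotyped_fraction=0.5,
        seed=1,
    )
    base.update(over)
    return syn.SimConfig(**base)


class TestSimulatePedigree:
    def test_founders_only(self):
        ped = syn.simulate_pedigree(_cfg(n_founders=10, n_generations=1))
        assert ped.n == 10
        assert np.all(ped.sire == -1) and np.all(ped.dam == -1)

    def test_parent_sexes_and_ordering(self):
        ped = syn.simulate_pedigree(_cfg(n_founders=20, n_generations=3, litter_size=4))
        sexes = np.asarray(ped.meta["sex"])
        for i in range(ped.n):
            s, d = ped.sire[i], ped.dam[i]
            if s >= 0:
                assert s < i and sexes[s] == "male"
            if d >= 0:
                assert d < i and sexes[d] == "female"

    def test_deterministic_under_seed(self):
        a = syn.simulate_pedigree(_cfg(seed=5)).to_frame()
        b = syn.simulate_pedigree(_cfg(seed=5)).to_frame()
        pd.testing.assert_frame_equal(a, b)

    def test_rejects_zero_counts(self):
        with pytest.raises(ValueError):
            syn.simulate_pedigree(_cfg(n_founders=0))
        with pytest.raises(ValueError):
            syn.simulate_pedigree(_cfg(litter_size=0))


class TestSimulateGenotypes:
    def test_mendelian_consistency(self, small_dataset):
        ped, geno = small_dataset["ped"], small_dataset["geno"]
        d = geno.dosages
        for i in range(ped.n):
            s, m = ped.sire[i], ped.dam[i]
            if s < 0:
                continue
            # offspring dosage bounded by what parents can transmit
            low = (d[s] == 2).astype(int) + (d[m] == 2).astype(int)
            high = 2 - (d[s] == 0).astype(int) - (d[m] == 0).astype(int)
            assert np.all(d[i] >= low) and np.all(d[i] <= high)

    def test_no_recombination_transmits_intact_chromosomes(self):
        cfg = _cfg(recomb_rate_per_bp=0.0, n_founders=10, n_generations=2, litter_size=2)
        ped = syn.simulate_pedigree(cfg)
        hap, _ = syn.gene_drop_haplotypes(ped, cfg)
        per_chrom = cfg.n_snps_per_chrom
        for i in range(ped.n):
            for k, parent in enumerate((ped.sire[i], ped.dam[i])):
                if parent < 0:
                    continue
                for c in range(cfg.n_chromosomes):
                    sl = slice(c * per_chrom, (c + 1) * per_chrom)
                    gamete = hap[i, k, sl]
                    assert np.array_equal(gamete, hap[parent, 0, sl]) or np.array_equal(
                        gamete, hap[parent, 1, sl]
                    )

    def test_mean_maf_matches_founder_distribution(self):
        """Mean observed MAF ~ E[min(p, 1-p)] = 0.3 for p ~ U(0.1, 0.9)."""
        cfg = _cfg(n_founders=120, n_generations=1, n_snps_per_chrom=1000, seed=3)
        ped = syn.simulate_pedigree(cfg)
        geno = syn.simulate_genotypes(ped, cfg)
        freq = geno.dosages.mean(axis=0) / 2
        poly = (freq > 0) & (freq < 1)
        maf = np.minimum(freq, 1 - freq)[poly]
        assert abs(maf.mean() - 0.3) < 0.05

    def test_ld_decays_with_distance(self, small_dataset):
        geno = small_dataset["geno"]
        Z = geno.dosages - geno.dosages.mean(0)
        sd = Z.std(0)
        poly = sd > 0
        pos = geno.markers["pos"].to_numpy()
        ch = geno.markers["chrom"].to_numpy()
        rng = np.random.default_rng(0)
        def mean_r2(dmin, dmax, n=200):
            vals = []
            tries = 0
            while len(vals) < n and tries < 50 * n:
                tries += 1
                i = int(rng.integers(geno.n_snps))
                if not poly[i]:
                    continue
                close = np.where(
                    (ch == ch[i]) & poly & (np.abs(pos - pos[i]) >= dmin)
                    & (np.abs(pos - pos[i]) <= dmax) & (np.arange(geno.n_snps) != i)
                )[0]
                if close.size == 0:
                    continue
                j = int(rng.choice(close))
                r = np.corrcoef(Z[:, i], Z[:, j])[0, 1]
                vals.append(r * r)
            return float(np.mean(vals))
        assert mean_r2(0, 100_000) > mean_r2(5_000_000, 20_000_000)

    def test_deterministic_under_seed(self):
        cfg = _cfg(seed=9)
        ped = syn.simulate_pedigree(cfg)
        g1 = syn.simulate_genotypes(ped, cfg)
        g2 = syn.simulate_genotypes(ped, cfg)
        assert np.array_equal(g1.dosages, g2.dosages)


class TestSimulatePhenotypes:
    def test_noise_free_limit_phenotype_equals_breeding_value(self):
        cfg = _cfg(h2_target=1.0, fixed_effect_sd=0.0)
        ped = syn.simulate_pedigree(cfg)
        geno = syn.simulate_genotypes(ped, cfg)
        pheno, truth = syn.simulate_phenotypes(ped, geno, cfg)
        assert np.allclose(pheno["phenotype"].to_numpy(), truth.breeding_values)
        assert truth.realized_h2 == pytest.approx(1.0)

    def test_phenotype_regression_on_breeding_value_near_one(self):
        """Slope of y on true a is ~1 under the additive model."""
        cfg = _cfg(n_founders=300, n_generations=3, litter_size=3,
                   h2_target=0.33, fixed_effect_sd=0.0, seed=2)
        ped = syn.simulate_pedigree(cfg)
        geno = syn.simulate_genotypes(ped, cfg)
        pheno, truth = syn.simulate_phenotypes(ped, geno, cfg)
        a = truth.breeding_values
        y = pheno["phenotype"].to_numpy()
        slope = np.cov(y, a)[0, 1] / np.var(a)
        assert slope == pytest.approx(1.0, abs=0.15)

    def test_realized_h2_tracks_target_across_replicates(self):
        vals = [
            syn.simulate_dataset(_cfg(seed=s, h2_target=0.33))[3].realized_h2
            for s in range(20)
        ]
        assert abs(np.mean(vals) - 0.33) < 0.03

    def test_planted_window_fraction_recovered_in_truth(self):
        """var(window genetic value)/var(a) stays near the 3% target."""
        shares = []
        for s in range(20):
            cfg = _cfg(
                n_founders=120, n_generations=3, litter_size=3,
                qtl_windows=(syn.QtlWindow(1, 8_000_000, 8_800_000, 0.03),), seed=s,
            )
            ped, geno, pheno, truth, _ = syn.simulate_dataset(cfg)
            qtl_idx = [
                geno.markers[geno.markers.snp == s_].index[0]
                for s_ in truth.qtl_effects.snp
            ]
            Zc = geno.dosages[:, qtl_idx] - geno.dosages[:, qtl_idx].mean(0)
            qval = Zc @ truth.qtl_effects.effect.to_numpy()
            shares.append(qval.var() / truth.breeding_values.var())
        assert 0.02 <= np.mean(shares) <= 0.04

    def test_empty_qtl_window_rejected(self):
        cfg = _cfg(qtl_windows=(syn.QtlWindow(1, 19_999_990, 20_000_000, 0.03),))
        ped = syn.simulate_pedigree(cfg)
        geno = syn.simulate_genotypes(ped, cfg)
        with pytest.raises(ValueError, match="no SNPs"):
            syn.simulate_phenotypes(ped, geno, cfg)


class TestMaskGenotypes:
    def test_full_fraction_is_identity(self, small_dataset):
        geno = small_dataset["geno"]
        out = syn.mask_genotypes(geno, 1.0)
        assert np.array_equal(out.dosages, geno.dosages)

    def test_half_fraction_counts(self, small_dataset):
        geno = small_dataset["geno"]
        out = syn.mask_genotypes(geno, 0.5)
        assert out.n_animals == round(0.5 * geno.n_animals)

    def test_youngest_generation_preferred(self, small_dataset):
        ped, geno = small_dataset["ped"], small_dataset["geno"]
        out = syn.mask_genotypes(geno, 0.3, ped=ped)
        gen_of = dict(zip(ped.ids, ped.meta["generation"]))
        kept = [gen_of[a] for a in out.ids]
        dropped = [gen_of[a] for a in geno.ids if a not in set(out.ids)]
        assert min(kept) >= max(0, max(dropped) - 1)

    def test_deterministic_under_seed(self, small_dataset):
        geno = small_dataset["geno"]
        a = syn.mask_genotypes(geno, 0.4, seed=3)
        b = syn.mask_genotypes(geno, 0.4, seed=3)
        assert np.array_equal(a.ids, b.ids)

    def test_rejects_zero_fraction(self, small_dataset):
        with pytest.raises(ValueError):
            syn.mask_genotypes(small_dataset["geno"], 0.0)


class TestConfigValidation:
    def test_variance_fractions_must_sum_below_one(self):
        with pytest.raises(ValueError, match="sum"):
            _cfg(
                qtl_windows=(
                    syn.QtlWindow(1, 0, 800_000, 0.6),
                    syn.QtlWindow(2, 0, 800_000, 0.5),
                )
            ).validate()

    def test_window_outside_chromosome_rejected(self):
        with pytest.raises(ValueError):
            _cfg(qtl_windows=(syn.QtlWindow(3, 0, 800_000, 0.1),)).validate()

    def test_h2_bounds(self):
        with pytest.raises(ValueError):
            _cfg(h2_target=0.0).validate()
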