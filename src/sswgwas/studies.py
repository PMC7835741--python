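"""Reproducible validation studies: algebraic identities, oracle
equivalences, parameter recovery and null calibration.

Each function builds its own inputs with the synthetic generator, runs the
pipeline, and returns plain dictionaries of measurements.  Problem sizes
are scaled-down study conditions chosen once: recovery uses a pedigree of
2000 animals (1000 genotyped) and 5000 SNPs at the array density of a
porcine 50K chip (~21 SNPs/Mb); the null study uses 1000 animals (500
genotyped) and 4000 SNPs.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg as la

from . import genomic as gen
from . import pedigree as pdg
from . import scan
from . import ssgblup as ss
from . import synthetic as syn

#: number of SNP-containing 0.8 Mb windows on the porcine 50K array after QC
#: (printed summary of the reference analysis; used as an input)
REFERENCE_WINDOW_COUNT = 2115


def window_share_arithmetic(n_windows: int = REFERENCE_WINDOW_COUNT) -> dict:
    """Average window share of genetic variance and its ratio to the 1% cut."""
    avg = scan.expected_average_share(n_windows)
    return {
        "n_windows": n_windows,
        "average_share_percent": avg,
        "threshold_percent": scan.GVAR_THRESHOLD_PERCENT,
        "threshold_over_average": scan.GVAR_THRESHOLD_PERCENT / avg,
    }


def _recovery_config(seed: int, qtl: bool = True) -> syn.SimConfig:
    windows = (syn.QtlWindow(3, 30_400_000, 31_200_000, 0.03),) if qtl else ()
    return syn.SimConfig(
        n_founders=500, n_generations=3, litter_size=3,
        n_chromosomes=4, chrom_length_bp=60_000_000, n_snps_per_chrom=1250,
        h2_target=0.33, qtl_windows=windows, genotyped_fraction=0.5, seed=seed,
    )


def identity_checks(seed: int = 1) -> dict:
    """Exact algebraic identities of the single-step machinery.

    * H^-1 equals A^-1 when G is replaced by A22;
    * Henderson-rules A^-1 agrees with the dense tabular inverse;
    * Z u reproduces the GEBVs for an unblended full-rank G;
    * the weight trace equals the SNP count after normalization.
    """
    cfg = syn.SimConfig(
        n_founders=80, n_generations=4, litter_size=3, n_chromosomes=2,
        chrom_length_bp=20_000_000, n_snps_per_chrom=300, h2_target=0.4,
        genotyped_fraction=0.4, seed=seed,
    )
    ped, geno, pheno, truth, masked = syn.simulate_dataset(cfg)
    A = pdg.build_A(ped)
    A_inv = pdg.build_A_inverse(ped)
    henderson_err = float(np.abs(A_inv.toarray() - la.inv(A)).max())

    gp = ped.positions(masked.ids)
    A22, A22_inv = pdg.subset_A22(A, gp)
    H_inv = ss.build_H_inverse(A_inv, gp, la.inv(A22), A22_inv)
    h_identity_err = float(np.abs(H_inv - A_inv.toarray()).max())

    # unblended G needs external frequencies and more haplotype diversity
    cfg2 = syn.SimConfig(
        n_founders=120, n_generations=1, litter_size=2, n_chromosomes=2,
        chrom_length_bp=20_000_000, n_snps_per_chrom=300,
        n_ancestral_haplotypes=150, genotyped_fraction=1.0, seed=seed + 100,
    )
    ped2 = syn.simulate_pedigree(cfg2)
    geno2 = syn.simulate_genotypes(ped2, cfg2)
    qcg, _ = gen.qc_filter(geno2)
    keep = geno2.markers["snp"].isin(set(qcg.markers["snp"])).to_numpy()
    pf = geno2.founder_freq[keep]
    G = gen.build_G(qcg, freqs=pf)
    Z = qcg.dosages - 2 * pf
    rng = np.random.default_rng(seed)
    g_hat = rng.standard_normal(G.n)
    u = scan.backsolve_snp_effects(g_hat, Z, np.ones(qcg.n_snps), G.values, G.lam)
    backsolve_err = float(np.abs(Z @ u - g_hat).max())

    d = scan.normalize_weights(scan.update_weights(u, gen.allele_frequencies(qcg)),
                               float(qcg.n_snps))
    trace_err = float(abs(d.sum() - qcg.n_snps))
    return {
        "n_pedigree": ped.n,
        "henderson_vs_dense_max_abs_err": henderson_err,
        "h_inverse_identity_max_abs_err": h_identity_err,
        "backsolve_consistency_max_abs_err": backsolve_err,
        "weight_trace_abs_err": trace_err,
    }


def oracle_checks(seed: int = 1) -> dict:
    """Cross-route equivalences on small simulations.

    * ssGBLUP with an empty genotyped set reproduces pedigree-BLUP EBVs
      computed by an independent dense GLS route;
    * the GEBV back-solve with every animal genotyped equals direct ridge
      SNP-BLUP;
    * AI-REML and the MME-based EM-REML land on the same optimum.
    """
    cfg = syn.SimConfig(
        n_founders=50, n_generations=3, litter_size=3, n_chromosomes=1,
        chrom_length_bp=10_000_000, n_snps_per_chrom=80, h2_target=0.4,
        genotyped_fraction=1.0, seed=seed,
    )
    ped, geno, pheno, truth, _ = syn.simulate_dataset(cfg)
    model = ss.build_model(pheno, ped)
    A = pdg.build_A(ped)
    A_inv = pdg.build_A_inverse(ped)
    vc = ss.VarianceComponents(0.4, 0.6, 0.4, 0.0, True, 0)
    sol = ss.solve_mme(model, A_inv, vc)
    V = vc.sigma_a2 * A[np.ix_(model.animal_index, model.animal_index)] \
        + vc.sigma_e2 * np.eye(len(model.y))
    Vi = la.inv(V)
    X, y = model.X, model.y
    b = la.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    a = vc.sigma_a2 * A[:, model.animal_index] @ Vi @ (y - X @ b)
    blup_err = float(np.abs(sol.a_hat - a).max())

    # all-genotyped back-solve vs direct SNP-BLUP
    cfg2 = syn.SimConfig(
        n_founders=100, n_generations=1, litter_size=2, n_chromosomes=2,
        chrom_length_bp=20_000_000, n_snps_per_chrom=200,
        n_ancestral_haplotypes=150, h2_target=0.4, genotyped_fraction=1.0,
        seed=seed + 1,
    )
    ped2, geno2, pheno2, _, _ = syn.simulate_dataset(cfg2)
    qcg, _ = gen.qc_filter(geno2)
    keep = geno2.markers["snp"].isin(set(qcg.markers["snp"])).to_numpy()
    pf = geno2.founder_freq[keep]
    Z = qcg.dosages - 2 * pf
    G = gen.build_G(qcg, freqs=pf)
    model2 = ss.build_model(pheno2, ped2)
    A2 = pdg.build_A(ped2)
    A2_inv = pdg.build_A_inverse(ped2)
    gp2 = ped2.positions(qcg.ids)
    A22, A22_inv = pdg.subset_A22(A2, gp2)
    H_inv = ss.build_H_inverse(A2_inv, gp2, G.inverse(), A22_inv)
    sol2 = ss.solve_mme(model2, H_inv, vc)
    u = scan.backsolve_snp_effects(sol2.a_hat[gp2], Z, np.ones(qcg.n_snps),
                                   G.values, G.lam)
    X2, y2 = model2.X, model2.y
    m = qcg.n_snps
    ridge = G.lam * vc.sigma_e2 / vc.sigma_a2
    C = np.block([[X2.T @ X2, X2.T @ Z], [Z.T @ X2, Z.T @ Z + ridge * np.eye(m)]])
    direct = la.solve(C, np.concatenate([X2.T @ y2, Z.T @ y2]))[X2.shape[1]:]
    snp_blup_err = float(np.abs(u - direct).max())

    # AI-REML vs EM-REML on a 200-record pedigree
    cfg3 = syn.SimConfig(
        n_founders=50, n_generations=3, litter_size=3, n_chromosomes=1,
        chrom_length_bp=10_000_000, n_snps_per_chrom=60, h2_target=0.4,
        genotyped_fraction=1.0, seed=seed + 2,
    )
    ped3, _, pheno3, _, _ = syn.simulate_dataset(cfg3)
    model3 = ss.build_model(pheno3, ped3)
    A3_inv = pdg.build_A_inverse(ped3)
    ai = ss.aireml(model3, K_inv=A3_inv)
    em = ss.em_reml(model3, A3_inv, tol=1e-12, max_iter=50000)
    scale = float(np.var(model3.y))
    reml_gap = max(abs(ai.sigma_a2 - em.sigma_a2), abs(ai.sigma_e2 - em.sigma_e2)) / scale
    return {
        "n_records_reml": len(model3.y),
        "ssgblup_vs_pedigree_blup_max_abs_err": blup_err,
        "backsolve_vs_snp_blup_max_abs_err": snp_blup_err,
        "aireml_vs_emreml_rel_gap": float(reml_gap),
    }


def recovery_study(n_reps: int = 20, seed: int = 1) -> dict:
    """Heritability and planted-QTL recovery across replicate populations.

    Each replicate simulates 2000 pedigreed animals (1000 genotyped, 5000
    SNPs, h2 = 0.33) with one 0.8 Mb QTL window carrying 3% of additive
    variance, runs QC plus the three-iteration weighted scan, and records
    the ssGBLUP heritability estimate, the planted window's estimated
    variance share and its rank among all windows.
    """
    h2s, shares, ranks = [], [], []
    for rep in range(n_reps):
        cfg = _recovery_config(seed * 1000 + rep)
        ped, geno, pheno, truth, masked = syn.simulate_dataset(cfg)
        qcg, _ = gen.qc_filter(masked)
        result = scan.run_wssgwas(ped, qcg, pheno)
        w = result.windows
        planted = w[(w["chrom"] == 3) & (w["start"] == 30_400_000)]
        share = float(planted["gvar_percent"].iloc[0]) if len(planted) else 0.0
        h2s.append(result.vc.h2)
        shares.append(share)
        ranks.append(int((w["gvar_percent"] > share).sum()) + 1)
    return {
        "n_reps": n_reps,
        "n_pedigree": 2000,
        "h2_estimates": h2s,
        "h2_mean": float(np.mean(h2s)),
        "h2_abs_bias": float(abs(np.mean(h2s) - 0.33)),
        "planted_shares": shares,
        "planted_share_mean": float(np.mean(shares)),
        "planted_rank1_fraction": float(np.mean([r == 1 for r in ranks])),
    }


def null_study(n_reps: int = 20, seed: int = 1) -> dict:
    """False-positive calibration with a purely polygenic trait.

    No QTL are planted; the fraction of 0.8 Mb windows whose estimated
    share exceeds the 1% threshold measures how often the weighted scan
    manufactures spurious candidate regions.
    """
    fractions = []
    for rep in range(n_reps):
        cfg = syn.SimConfig(
            n_founders=250, n_generations=3, litter_size=3,
            n_chromosomes=4, chrom_length_bp=60_000_000, n_snps_per_chrom=1000,
            h2_target=0.33, genotyped_fraction=0.5, seed=seed * 1000 + rep,
        )
        ped, geno, pheno, truth, masked = syn.simulate_dataset(cfg)
        qcg, _ = gen.qc_filter(masked)
        result = scan.run_wssgwas(ped, qcg, pheno)
        fractions.append(
            float((result.windows["gvar_percent"] > scan.GVAR_THRESHOLD_PERCENT).mean())
        )
    return {
        "n_reps": n_reps,
        "fractions_above_threshold": fractions,
        "mean_fraction_above_threshold": float(np.mean(fractions)),
    }
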