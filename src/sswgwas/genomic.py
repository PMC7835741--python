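"""Genotype QC and the (weighted) genomic relationship matrix.

QC mirrors a standard array-data pipeline: animals with call rate < 90% go
first, then SNPs with call rate < 90%, Hardy-Weinberg chi-square p < 1e-6,
minor allele frequency < 0.01, and non-autosomal or unmapped positions.
Thresholds are strict inequalities (an animal missing exactly 10% of SNPs
is retained).  Remaining missing dosages are imputed with the column mean
2p, which is neutral under centering.

G follows VanRaden: G = Z D Z' / sum_i 2 p_i (1 - p_i) with Z the
column-centered dosage matrix and D a diagonal matrix of per-SNP weights
(identity for the unweighted first pass).  "Minor" allele frequency in the
scaling is read as the observed frequency of the dosage-counted allele;
2p(1-p) is symmetric in p <-> 1-p so the scaling constant is unaffected.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

MAP_COLUMNS = ("snp", "chrom", "pos")


@dataclass
class GenotypeMatrix:
    """Animals x SNPs allele dosages {0,1,2} with a physical marker map.

    ``dosages`` is float with NaN marking missing calls.  ``founder_freq``
    optionally carries the allele frequencies the genotypes were simulated
    from (used where an external-frequency G is wanted).
    """

    ids: np.ndarray
    dosages: np.ndarray
    markers: pd.DataFrame
    founder_freq: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.ids), len(self.markers)):
            raise ValueError("dosage matrix shape does not match ids x markers")

    @property
    def n_animals(self) -> int:
        return len(self.ids)

    @property
    def n_snps(self) -> int:
        return len(self.markers)

    def subset_animals(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        return GenotypeMatrix(
            ids=self.ids[keep],
            dosages=self.dosages[keep],
            markers=self.markers.reset_index(drop=True),
            founder_freq=self.founder_freq,
        )

    def subset_snps(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        ff = self.founder_freq[keep] if self.founder_freq is not None else None
        return GenotypeMatrix(
            ids=self.ids,
            dosages=self.dosages[:, keep],
            markers=self.markers.iloc[keep].reset_index(drop=True),
            founder_freq=ff,
        )


@dataclass(frozen=True)
class QcThresholds:
    """PLINK-style exclusion thresholds; strict inequalities throughout."""

    mind: float = 0.10  # max fraction of missing SNPs per animal (call rate >= 90%)
    geno: float = 0.10  # max fraction of missing animals per SNP
    hwe: float = 1e-6
    maf: float = 0.01
    autosome_max: int | None = None  # keep chrom in 1..autosome_max; None = any numeric


@dataclass
class QcReport:
    n_animals_in: int = 0
    n_snps_in: int = 0
    animals_removed_call_rate: int = 0
    snps_removed_call_rate: int = 0
    snps_removed_hwe: int = 0
    snps_removed_maf: int = 0
    snps_removed_nonautosomal: int = 0
    n_animals_out: int = 0
    n_snps_out: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"criterion": list(vars(self)), "count": list(vars(self).values())}
        )


def hwe_pvalues(dosages: np.ndarray) -> np.ndarray:
    """Hardy-Weinberg chi-square test (1 df, no continuity correction) per SNP."""
    d = dosages
    n0 = np.nansum(d == 0, axis=0).astype(float)
    n1 = np.nansum(d == 1, axis=0).astype(float)
    n2 = np.nansum(d == 2, axis=0).astype(float)
    n = n0 + n1 + n2
    with np.errstate(divide="ignore", invalid="ignore"):
        p = (2 * n2 + n1) / (2 * n)
        q = 1 - p
        e0, e1, e2 = n * q**2, 2 * n * p * q, n * p**2
        chi2 = np.zeros(d.shape[1])
        for obs, exp in ((n0, e0), (n1, e1), (n2, e2)):
            term = np.where(exp > 0, (obs - exp) ** 2 / np.where(exp > 0, exp, 1.0), 0.0)
            chi2 += term
    return stats.chi2.sf(chi2, df=1)


def _numeric_chrom(chrom: pd.Series) -> np.ndarray:
    """Chromosome labels as integers; non-numeric (X, Y, MT, ...) become -1."""
    out = pd.to_numeric(chrom, errors="coerce")
    return np.where(np.isfinite(out), out, -1).astype(np.int64)


def qc_filter(
    geno: GenotypeMatrix, thresholds: QcThresholds | None = None
) -> tuple[GenotypeMatrix, QcReport]:
    """Apply animal call-rate then SNP filters; impute survivors' missing calls.

    Filters are applied in the order: animal call rate, SNP call rate, HWE,
    MAF, non-autosomal/unmapped.  Raises if nothing survives.  Idempotent:
    running the output through the same thresholds removes nothing further.
    """
    th = thresholds or QcThresholds()
    if geno.n_animals == 0 or geno.n_snps == 0:
        raise ValueError("empty genotype matrix")
    report = QcReport(n_animals_in=geno.n_animals, n_snps_in=geno.n_snps)

    missing = np.isnan(geno.dosages)
    animal_miss = missing.mean(axis=1)
    keep_animals = animal_miss <= th.mind  # call rate < 90% excluded, ==90% kept
    report.animals_removed_call_rate = int((~keep_animals).sum())
    if not keep_animals.any():
        raise ValueError("all animals removed by call-rate filter")
    geno = geno.subset_animals(np.where(keep_animals)[0])

    d = geno.dosages
    keep = np.ones(geno.n_snps, dtype=bool)

    snp_miss = np.isnan(d).mean(axis=0)
    fail = keep & (snp_miss > th.geno)
    report.snps_removed_call_rate = int(fail.sum())
    keep &= ~fail

    pvals = hwe_pvalues(d)
    fail = keep & (pvals < th.hwe)
    report.snps_removed_hwe = int(fail.sum())
    keep &= ~fail

    freq = np.nanmean(d, axis=0) / 2.0
    maf = np.minimum(freq, 1 - freq)
    fail = keep & (maf < th.maf)
    report.snps_removed_maf = int(fail.sum())
    keep &= ~fail

    chrom = _numeric_chrom(geno.markers["chrom"])
    pos = np.asarray(geno.markers["pos"], dtype=np.int64)
    autosomal = (chrom >= 1) & (pos > 0)
    if th.autosome_max is not None:
        autosomal &= chrom <= th.autosome_max
    fail = keep & ~autosomal
    report.snps_removed_nonautosomal = int(fail.sum())
    keep &= ~fail

    if not keep.any():
        raise ValueError("all SNPs removed by QC")
    geno = geno.subset_snps(np.where(keep)[0])

    # mean-impute what is left: neutral under 2p centering
    d = geno.dosages
    if np.isnan(d).any():
        col_mean = np.nanmean(d, axis=0)
        nan_r, nan_c = np.where(np.isnan(d))
        d[nan_r, nan_c] = col_mean[nan_c]

    report.n_animals_out = geno.n_animals
    report.n_snps_out = geno.n_snps
    return geno, report


def allele_frequencies(geno: GenotypeMatrix) -> np.ndarray:
    """Observed frequency of the dosage-counted allele, per SNP."""
    return np.nanmean(geno.dosages, axis=0) / 2.0


def centered_dosages(geno: GenotypeMatrix, freqs: np.ndarray | None = None) -> np.ndarray:
    """Z = dosage - 2p, columnwise."""
    p = allele_frequencies(geno) if freqs is None else np.asarray(freqs, dtype=float)
    return geno.dosages - 2.0 * p


@dataclass
class GenomicMatrix:
    """G over genotyped animals plus the ingredients it was built from."""

    values: np.ndarray
    freqs: np.ndarray
    lam: float  # sum_i 2 p_i (1 - p_i)
    weights: np.ndarray
    blend_alpha: float = 0.0

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def inverse(self) -> np.ndarray:
        inv = np.linalg.inv(self.values)
        return 0.5 * (inv + inv.T)


def build_G(
    geno: GenotypeMatrix,
    weights: np.ndarray | None = None,
    freqs: np.ndarray | None = None,
) -> GenomicMatrix:
    """VanRaden genomic relationship matrix G = Z D Z' / sum 2p(1-p)."""
    p = allele_frequencies(geno) if freqs is None else np.asarray(freqs, dtype=float)
    m = geno.n_snps
    w = np.ones(m) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != (m,):
        raise ValueError("weights length must equal SNP count")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    lam = float(np.sum(2.0 * p * (1.0 - p)))
    if lam <= 0:
        raise ValueError("scaling constant sum 2p(1-p) is zero (monomorphic panel?)")
    Z = geno.dosages - 2.0 * p
    G = (Z * w) @ Z.T / lam
    return GenomicMatrix(values=0.5 * (G + G.T), freqs=p, lam=lam, weights=w)


def blend_and_tune_G(G: GenomicMatrix, A22: np.ndarray, alpha: float = 0.05) -> GenomicMatrix:
    """G* = (1 - alpha) G + alpha A22; alpha > 0 restores invertibility.

    With observed allele frequencies the raw G is singular by construction
    (centered columns sum to zero), so every inverse-using consumer goes
    through a blended G.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    A22 = np.asarray(A22, dtype=float)
    if A22.shape != G.values.shape:
        raise ValueError("A22 dimensions do not match G")
    return replace(G, values=(1.0 - alpha) * G.values + alpha * A22, blend_alpha=alpha)
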