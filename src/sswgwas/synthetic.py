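"""Synthetic Duroc-like populations for exercising the single-step pipeline.

Gene-dropping simulator with discrete generations.  Founder haplotypes are
mosaics of a small pool of ancestral haplotypes (Li & Stephens style):
marker frequencies in the pool are Uniform(0.1, 0.9) and each founder
haplotype copies from a randomly switching ancestor along the chromosome,
which gives the population the window-scale linkage disequilibrium a
0.8 Mb window scan presumes (a small ancestor pool mimics the small
effective size of a closed nucleus herd).  Offspring receive parental
gametes with crossovers as a Poisson process at a uniform 1 cM/Mb rate,
no interference.

Breeding values decompose into planted QTL-window effects (each scaled to
a target share of the additive variance) plus a polygenic remainder.  By
default the remainder is itself marker-based -- many small effects on a
random half of the SNPs -- so the genomic relationship matrix is the true
covariance of the genetic background and variance-component estimates are
well calibrated; a pedigree-recursion remainder (parental average +
Mendelian sampling, genetically untracked by the markers) is available as
``polygenic_mode='pedigree'``.  Residual variance is scaled to hit the
target heritability; fixed effects (birth year by generation, sex, farm)
are overlaid on top.  Because genotypes are simulated for every pedigree
animal before masking, ungenotyped ancestors carry information exactly
the way single-step methods assume.

Default sizes emulate a three-generation nucleus-herd pedigree of ~5100
animals with ~36k SNPs on 18 autosomes and about half the animals
genotyped (youngest first).  All randomness flows from a single seed via
named SeedSequence streams per stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genomic import GenotypeMatrix
from .pedigree import Pedigree, mendelian_variances

_STAGES = ("pedigree", "founders", "gametes", "phenotypes", "mask")


@dataclass(frozen=True)
class QtlWindow:
    chrom: int
    start_bp: int
    end_bp: int
    variance_fraction: float


@dataclass(frozen=True)
class SimConfig:
    """Population and genome layout for one simulated dataset."""

    n_founders: int = 600
    n_generations: int = 4  # founder generation included
    litter_size: int = 5
    n_chromosomes: int = 18
    chrom_length_bp: int = 100_000_000
    n_snps_per_chrom: int = 2000
    recomb_rate_per_bp: float = 1e-8  # Morgans per base = 1 cM/Mb
    qtl_windows: tuple[QtlWindow, ...] = ()
    h2_target: float = 0.33
    n_farms: int = 2
    fixed_effect_sd: float = 0.5  # SD of simulated level effects; 0 disables them
    founder_freq_range: tuple[float, float] = (0.1, 0.9)
    n_ancestral_haplotypes: int = 4  # founder LD: small pool = strong, herd-like LD
    ancestral_segment_bp: float = 500_000.0  # mean ancestor-copying segment length
    polygenic_mode: str = "markers"  # 'markers' or 'pedigree'
    polygenic_snp_fraction: float = 1.0  # share of non-QTL SNPs with background effects
    qtl_snps_per_window: int = 5
    genotyped_fraction: float = 0.53
    seed: int = 0

    def validate(self) -> None:
        counts = dict(
            n_founders=self.n_founders,
            n_generations=self.n_generations,
            litter_size=self.litter_size,
            n_chromosomes=self.n_chromosomes,
            chrom_length_bp=self.chrom_length_bp,
            n_snps_per_chrom=self.n_snps_per_chrom,
            n_farms=self.n_farms,
        )
        for name, value in counts.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive (got {value})")
        if not 0.0 < self.h2_target <= 1.0:
            raise ValueError("h2_target must be in (0, 1]")
        if not 0.0 < self.genotyped_fraction <= 1.0:
            raise ValueError("genotyped_fraction must be in (0, 1]")
        if self.polygenic_mode not in ("markers", "pedigree"):
            raise ValueError("polygenic_mode must be 'markers' or 'pedigree'")
        if not 0.0 < self.polygenic_snp_fraction <= 1.0:
            raise ValueError("polygenic_snp_fraction must be in (0, 1]")
        if self.n_ancestral_haplotypes < 2 or self.qtl_snps_per_window < 1:
            raise ValueError("need >=2 ancestral haplotypes and >=1 causal SNP per window")
        total = sum(q.variance_fraction for q in self.qtl_windows)
        if total >= 1.0:
            raise ValueError("QTL variance fractions must sum to < 1")
        for q in self.qtl_windows:
            if not (1 <= q.chrom <= self.n_chromosomes):
                raise ValueError(f"QTL window on unsimulated chromosome {q.chrom}")
            if not (0 <= q.start_bp < q.end_bp <= self.chrom_length_bp):
                raise ValueError("QTL window outside simulated chromosome")

    def rng(self, stage: str) -> np.random.Generator:
        if stage not in _STAGES:
            raise KeyError(f"unknown rng stage {stage!r}")
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(_STAGES.index(stage),))
        )


@dataclass
class TrueValues:
    """Simulation ground truth for parameter-recovery tests."""

    breeding_values: np.ndarray
    qtl_effects: pd.DataFrame  # snp, chrom, pos, effect, window
    realized_h2: float
    sigma_a2_realized: float
    sigma_e2: float
    window_fractions: dict[tuple[int, int, int], float] = field(default_factory=dict)


def simulate_pedigree(config: SimConfig) -> Pedigree:
    """Discrete-generation pedigree: founders plus litter-structured matings.

    Each post-founder generation draws n_founders/2 sire-dam pairs from the
    previous generation (boars reused freely, dams without replacement when
    possible) and produces ``litter_size`` offspring per mating.  Sexes are
    assigned alternately within litters; birth year tracks generation and
    farms are drawn at random.
    """
    config.validate()
    rng = config.rng("pedigree")
    ids: list[str] = []
    sire: list[int] = []
    dam: list[int] = []
    sex: list[str] = []
    generation: list[int] = []
    farm: list[int] = []

    def add(s: int, d: int, g: int, sx: str) -> None:
        ids.append(f"G{g}_{len(ids) + 1}")
        sire.append(s)
        dam.append(d)
        sex.append(sx)
        generation.append(g)
        farm.append(int(rng.integers(1, config.n_farms + 1)))

    for i in range(config.n_founders):
        add(-1, -1, 0, "male" if i % 2 == 0 else "female")

    prev = np.arange(config.n_founders)
    for g in range(1, config.n_generations):
        males = [i for i in prev if sex[i] == "male"]
        females = [i for i in prev if sex[i] == "female"]
        if not males or not females:
            raise ValueError("a generation lacks one sex; enlarge n_founders")
        n_matings = max(1, config.n_founders // 2)
        sires = rng.choice(males, size=n_matings, replace=True)
        dams = rng.choice(females, size=n_matings, replace=n_matings > len(females))
        start = len(ids)
        for s, d in zip(sires, dams):
            for k in range(config.litter_size):
                add(int(s), int(d), g, "male" if k % 2 == 0 else "female")
        prev = np.arange(start, len(ids))

    meta = pd.DataFrame(
        {
            "sex": sex,
            "birth_year": [2015 + g for g in generation],
            "farm": farm,
            "generation": generation,
        }
    )
    return Pedigree(
        ids=np.asarray(ids, dtype=object),
        sire=np.asarray(sire, dtype=np.int64),
        dam=np.asarray(dam, dtype=np.int64),
        meta=meta,
    )


def marker_map(config: SimConfig) -> pd.DataFrame:
    """Evenly spaced 1-based SNP positions on each autosome."""
    spacing = config.chrom_length_bp // config.n_snps_per_chrom
    rows = []
    for c in range(1, config.n_chromosomes + 1):
        for j in range(config.n_snps_per_chrom):
            rows.append((f"chr{c}_snp{j + 1}", c, spacing * j + spacing // 2 + 1))
    return pd.DataFrame(rows, columns=["snp", "chrom", "pos"])


def _recombined_gamete(
    hap0: np.ndarray,
    hap1: np.ndarray,
    positions: np.ndarray,
    length_bp: int,
    rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    n_x = rng.poisson(length_bp * rate)
    start = int(rng.integers(2))
    if n_x == 0:
        return hap0.copy() if start == 0 else hap1.copy()
    xpos = np.sort(rng.uniform(0, length_bp, size=n_x))
    segment = (start + np.searchsorted(xpos, positions)) % 2
    return np.where(segment == 0, hap0, hap1)


def _founder_haplotype(
    ancestral: np.ndarray,
    positions: np.ndarray,
    length_bp: int,
    segment_bp: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One founder haplotype as a switching mosaic of the ancestral pool."""
    K = ancestral.shape[0]
    n_switch = rng.poisson(length_bp / segment_bp)
    if n_switch == 0:
        return ancestral[rng.integers(K)].copy()
    cuts = np.sort(rng.uniform(0, length_bp, size=n_switch))
    ancestors = rng.integers(K, size=n_switch + 1)
    segment = np.searchsorted(cuts, positions)
    return ancestral[ancestors[segment], np.arange(len(positions))]


def gene_drop_haplotypes(ped: Pedigree, config: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Drop founder haplotypes through the pedigree; returns (haplotypes, freqs).

    ``haplotypes`` has shape (n_animals, 2, n_snps) with 0/1 alleles; the
    first gamete of each non-founder comes from the sire, the second from
    the dam.
    """
    config.validate()
    markers = marker_map(config)
    m = len(markers)
    founders_rng = config.rng("founders")
    gamete_rng = config.rng("gametes")
    freqs = founders_rng.uniform(*config.founder_freq_range, size=m)
    positions = markers["pos"].to_numpy()
    chrom_slices = [
        slice(c * config.n_snps_per_chrom, (c + 1) * config.n_snps_per_chrom)
        for c in range(config.n_chromosomes)
    ]
    K = config.n_ancestral_haplotypes
    ancestral = (founders_rng.random((K, m)) < freqs).astype(np.uint8)
    hap = np.empty((ped.n, 2, m), dtype=np.uint8)
    for i in range(ped.n):
        s, d = ped.sire[i], ped.dam[i]
        if s < 0 and d < 0:
            for k in range(2):
                for sl in chrom_slices:
                    hap[i, k, sl] = _founder_haplotype(
                        ancestral[:, sl],
                        positions[sl],
                        config.chrom_length_bp,
                        config.ancestral_segment_bp,
                        founders_rng,
                    )
            continue
        if s < 0 or d < 0:
            raise ValueError(f"animal {ped.ids[i]!r} has exactly one known parent")
        for k, parent in enumerate((s, d)):
            for sl in chrom_slices:
                hap[i, k, sl] = _recombined_gamete(
                    hap[parent, 0, sl],
                    hap[parent, 1, sl],
                    positions[sl],
                    config.chrom_length_bp,
                    config.recomb_rate_per_bp,
                    gamete_rng,
                )
    return hap, freqs


def simulate_genotypes(ped: Pedigree, config: SimConfig) -> GenotypeMatrix:
    """Dosage matrix {0,1,2} from gene-dropped haplotypes with a marker map."""
    hap, freqs = gene_drop_haplotypes(ped, config)
    dosages = hap.sum(axis=1).astype(float)
    return GenotypeMatrix(
        ids=ped.ids.copy(), dosages=dosages, markers=marker_map(config), founder_freq=freqs
    )


def _polygenic_values(ped: Pedigree, sigma2: float, rng: np.random.Generator) -> np.ndarray:
    """Pedigree-correlated deviates via parental average + Mendelian sampling."""
    d = mendelian_variances(ped)
    u = np.zeros(ped.n)
    z = rng.standard_normal(ped.n)
    for i in range(ped.n):
        s, m = ped.sire[i], ped.dam[i]
        mean = 0.0
        if s >= 0:
            mean += 0.5 * u[s]
        if m >= 0:
            mean += 0.5 * u[m]
        u[i] = mean + np.sqrt(d[i] * sigma2) * z[i]
    return u


def simulate_phenotypes(
    ped: Pedigree, geno: GenotypeMatrix, config: SimConfig
) -> tuple[pd.DataFrame, TrueValues]:
    """Phenotypes = fixed effects + breeding value + residual noise.

    Each QTL window's causal SNPs (``qtl_snps_per_window``, drawn within the
    window) are scaled so the window contributes its target fraction of the
    additive variance; the polygenic remainder supplies the rest (marker-
    based small effects by default, pedigree recursion on request); residual
    variance is set so realized h2 matches ``h2_target``.
    """
    config.validate()
    rng = config.rng("phenotypes")
    n = ped.n
    sigma_a2 = 1.0  # additive variance in arbitrary trait units
    qtl_rows = []
    window_fractions: dict[tuple[int, int, int], float] = {}
    qtl_value = np.zeros(n)
    chrom = geno.markers["chrom"].to_numpy()
    pos = geno.markers["pos"].to_numpy()
    qtl_snps: list[int] = []
    for win in config.qtl_windows:
        in_win = np.where((chrom == win.chrom) & (pos >= win.start_bp) & (pos < win.end_bp))[0]
        if in_win.size == 0:
            raise ValueError(
                f"QTL window {win.chrom}:{win.start_bp}-{win.end_bp} contains no SNPs"
            )
        # a QTL must segregate: prefer common SNPs, accept any polymorphic one
        win_freq = geno.dosages[:, in_win].mean(axis=0) / 2.0
        win_maf = np.minimum(win_freq, 1.0 - win_freq)
        usable = in_win[win_maf >= 0.05]
        if usable.size == 0:
            usable = in_win[win_maf > 0.0]
        if usable.size == 0:
            raise ValueError("QTL window is monomorphic in this population")
        causal = rng.choice(
            usable, size=min(config.qtl_snps_per_window, usable.size), replace=False
        )
        raw = rng.standard_normal(causal.size)
        Zc = geno.dosages[:, causal] - geno.dosages[:, causal].mean(axis=0)
        value = Zc @ raw
        var = value.var()
        if var <= 0:
            raise ValueError("QTL window is monomorphic in this population")
        scale = np.sqrt(win.variance_fraction * sigma_a2 / var)
        qtl_value += value * scale
        key = (win.chrom, win.start_bp, win.end_bp)
        window_fractions[key] = win.variance_fraction
        qtl_snps.extend(int(j) for j in causal)
        for j, eff in zip(causal, raw * scale):
            qtl_rows.append(
                (geno.markers["snp"].iloc[j], int(chrom[j]), int(pos[j]), float(eff), key)
            )
    poly_frac = 1.0 - sum(window_fractions.values())
    if config.polygenic_mode == "pedigree":
        poly = _polygenic_values(ped, poly_frac * sigma_a2, rng)
    else:
        candidates = np.setdiff1d(np.arange(geno.n_snps), np.asarray(qtl_snps, dtype=int))
        n_bg = max(1, int(round(config.polygenic_snp_fraction * candidates.size)))
        bg = rng.choice(candidates, size=n_bg, replace=False)
        bg_value = np.zeros(n)
        # chunked to keep the centered background matrix small
        effects = rng.standard_normal(n_bg)
        for start in range(0, n_bg, 2000):
            sel = bg[start : start + 2000]
            Zbg = geno.dosages[:, sel] - geno.dosages[:, sel].mean(axis=0)
            bg_value += Zbg @ effects[start : start + 2000]
        var_bg = bg_value.var()
        if var_bg <= 0:
            raise ValueError("polygenic background is monomorphic in this population")
        poly = bg_value * np.sqrt(poly_frac * sigma_a2 / var_bg) if poly_frac > 0 else np.zeros(n)
    a = qtl_value + poly
    var_a = float(a.var())
    if config.h2_target >= 1.0:
        sigma_e2 = 0.0
        e = np.zeros(n)
    else:
        sigma_e2 = var_a * (1.0 - config.h2_target) / config.h2_target
        e = rng.normal(0.0, np.sqrt(sigma_e2), size=n)
    var_e = float(e.var()) if sigma_e2 > 0 else 0.0
    realized_h2 = var_a / (var_a + var_e) if (var_a + var_e) > 0 else float("nan")

    meta = ped.meta
    fixed = np.zeros(n)
    if config.fixed_effect_sd > 0:
        for col in ("birth_year", "sex", "farm"):
            levels = pd.unique(meta[col])
            effects = dict(zip(levels, rng.normal(0.0, config.fixed_effect_sd, len(levels))))
            fixed += np.asarray([effects[v] for v in meta[col]])
    pheno = pd.DataFrame(
        {
            "id": ped.ids,
            "phenotype": fixed + a + e,
            "sex": meta["sex"].to_numpy(),
            "birth_year": meta["birth_year"].to_numpy(),
            "farm": meta["farm"].to_numpy(),
        }
    )
    truth = TrueValues(
        breeding_values=a,
        qtl_effects=pd.DataFrame(
            qtl_rows, columns=["snp", "chrom", "pos", "effect", "window"]
        ),
        realized_h2=realized_h2,
        sigma_a2_realized=var_a,
        sigma_e2=sigma_e2,
        window_fractions=window_fractions,
    )
    return pheno, truth


def mask_genotypes(
    geno: GenotypeMatrix,
    fraction: float,
    ped: Pedigree | None = None,
    seed: int | None = None,
) -> GenotypeMatrix:
    """Retain genotypes for a fraction of animals, youngest generation first.

    Mirrors selective genotyping in nucleus herds: candidates from the most
    recent generations are genotyped, older ancestors contribute through the
    pedigree only.  Ties within a generation are broken at random when a
    seed is given, else by table order.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    n = geno.n_animals
    n_keep = int(round(fraction * n))
    if fraction < 1.0 and n_keep == n:
        n_keep = n - 1
    n_keep = max(1, n_keep)
    if n_keep == n:
        return geno.subset_animals(np.arange(n))
    if ped is not None and "generation" in ped.meta.columns:
        gen = np.asarray(ped.meta["generation"])[ped.positions(geno.ids)]
    else:
        gen = np.zeros(n)
    tie = (
        np.random.default_rng(seed).random(n) if seed is not None else np.arange(n) / n
    )
    order = np.lexsort((tie, -gen))  # youngest first
    keep = np.sort(order[:n_keep])
    return geno.subset_animals(keep)


def simulate_dataset(config: SimConfig):
    """One call for the full bundle: pedigree, genotypes, phenotypes, truth, masked genotypes."""
    ped = simulate_pedigree(config)
    geno = simulate_genotypes(ped, config)
    pheno, truth = simulate_phenotypes(ped, geno, config)
    masked = mask_genotypes(geno, config.genotyped_fraction, ped=ped, seed=config.seed)
    return ped, geno, pheno, truth, masked
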