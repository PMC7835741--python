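"""Weighted single-step GWAS: SNP back-solving, reweighting, window scans.

The iterative procedure (three rounds by default):

1. start with unit SNP weights D = I;
2. build the weighted G = Z D Z' / lambda, lambda = sum 2p(1-p);
3. solve the single-step MME for GEBVs of all animals;
4. back-solve SNP effects u = D Z' G^-1 g_hat / lambda from the genotyped
   animals' GEBVs (the scaling makes Z u reproduce g_hat exactly whenever
   G is the unblended matrix built from the same Z and D);
5. update weights d_i = u_i^2 * 2 p_i (1 - p_i);
6. rescale the weights so their sum stays equal to the SNP count (total
   genetic variance held constant), and iterate.

Genetic variance is then partitioned into consecutive non-overlapping
0.8 Mb windows: each window's share is var(Z_w u_w) over genotyped animals
divided by the variance of the total genomic breeding value (or by the
REML additive variance, on request), times 100.  Windows above 1% of the
genetic variance are candidate QTL regions; the top three per trait are
reported with 0.4 Mb flanks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import genomic, pedigree, ssgblup
from .genomic import GenotypeMatrix
from .pedigree import Pedigree

WINDOW_BP = 800_000
FLANK_BP = 400_000
GVAR_THRESHOLD_PERCENT = 1.0


def expected_average_share(n_windows: int) -> float:
    """Percent of genetic variance an average window carries: 100 / #windows."""
    if n_windows <= 0:
        raise ValueError("window count must be positive")
    return 100.0 / n_windows


def backsolve_snp_effects(
    g_hat: np.ndarray,
    Z: np.ndarray,
    weights: np.ndarray,
    G: np.ndarray,
    lam: float,
) -> np.ndarray:
    """SNP effects from genotyped animals' GEBVs: u = D Z' G^-1 g_hat / lambda."""
    g_hat = np.asarray(g_hat, dtype=float)
    if G.shape[0] != g_hat.size:
        raise ValueError("g_hat must cover exactly the genotyped animals")
    try:
        Ginv_g = np.linalg.solve(G, g_hat)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular G in back-solve; blend with A22 (alpha > 0) or use "
            "external allele frequencies"
        ) from exc
    return np.asarray(weights, dtype=float) * (Z.T @ Ginv_g) / lam


def update_weights(u_hat: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """Per-SNP variance weights d_i = u_i^2 * 2 p_i (1 - p_i)."""
    u = np.asarray(u_hat, dtype=float)
    p = np.asarray(freqs, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("allele frequencies must lie strictly in (0, 1)")
    return u**2 * 2.0 * p * (1.0 - p)


def normalize_weights(d_new: np.ndarray, trace_target: float) -> np.ndarray:
    """Rescale weights so their sum equals ``trace_target`` (the SNP count)."""
    d = np.asarray(d_new, dtype=float)
    total = d.sum()
    if total <= 0:
        raise ValueError("cannot normalize all-zero SNP weights")
    return d * (trace_target / total)


def assign_windows(markers: pd.DataFrame, window_bp: int = WINDOW_BP) -> pd.DataFrame:
    """Bin SNPs into consecutive half-open [k*w, (k+1)*w) windows per chromosome.

    Returns a copy of the marker table with ``window_start``/``window_end``
    columns; positions are 1-based so a SNP exactly at the window size falls
    in the second bin.
    """
    out = markers.copy()
    pos = np.asarray(out["pos"], dtype=np.int64)
    if np.any(pos < 0):
        raise ValueError("negative marker position")
    bin_idx = pos // window_bp
    out["window_start"] = bin_idx * window_bp
    out["window_end"] = (bin_idx + 1) * window_bp
    return out


def window_variance(
    Z: np.ndarray,
    u_hat: np.ndarray,
    markers: pd.DataFrame,
    sigma_a2: float | None = None,
    window_bp: int = WINDOW_BP,
) -> pd.DataFrame:
    """Percent of additive genetic variance per 0.8 Mb window.

    Each window's genetic values are a_w = Z_w u_w across genotyped animals.
    The denominator is the (population) variance of the total genomic
    breeding value Z u unless ``sigma_a2`` overrides it with the REML
    additive variance.  SNP-empty bins never appear.
    """
    binned = assign_windows(markers, window_bp)
    total = Z @ np.asarray(u_hat, dtype=float)
    denom = float(np.var(total)) if sigma_a2 is None else float(sigma_a2)
    if denom <= 0:
        raise ValueError("zero denominator: no genomic variance to partition")
    rows = []
    for (chrom, start, end), grp in binned.groupby(
        ["chrom", "window_start", "window_end"], sort=True
    ):
        cols = grp.index.to_numpy()
        a_w = Z[:, cols] @ np.asarray(u_hat, dtype=float)[cols]
        rows.append(
            {
                "chrom": chrom,
                "start": int(start),
                "end": int(end),
                "n_snps": len(cols),
                "gvar_percent": float(np.var(a_w)) / denom * 100.0,
            }
        )
    return (
        pd.DataFrame(rows)
        .sort_values(["chrom", "start"], kind="mergesort")
        .reset_index(drop=True)
    )


@dataclass
class RegionReport:
    significant: pd.DataFrame
    top_regions: pd.DataFrame
    total_significant_gvar: float
    threshold: float


def report_regions(
    windows: pd.DataFrame,
    threshold: float = GVAR_THRESHOLD_PERCENT,
    top_k: int = 3,
    flank_bp: int = FLANK_BP,
    chrom_lengths: dict | None = None,
) -> RegionReport:
    """Windows strictly above the threshold plus flank-extended top regions.

    Sorting is by descending variance share; ties break toward the lower
    chromosome, then the lower start.  Flanks are clipped at zero and, when
    chromosome lengths are known, at the chromosome end.
    """
    if windows.empty:
        raise ValueError("no windows to report")
    ordered = windows.sort_values(
        ["gvar_percent", "chrom", "start"],
        ascending=[False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    significant = ordered[ordered["gvar_percent"] > threshold].reset_index(drop=True)
    top = ordered.head(top_k).copy()
    region_start = np.maximum(top["start"].to_numpy() - flank_bp, 0)
    region_end = top["end"].to_numpy() + flank_bp
    if chrom_lengths:
        limits = np.asarray([chrom_lengths.get(c, np.iinfo(np.int64).max) for c in top["chrom"]])
        region_end = np.minimum(region_end, limits)
    top["region_start"] = region_start
    top["region_end"] = region_end
    return RegionReport(
        significant=significant,
        top_regions=top.reset_index(drop=True),
        total_significant_gvar=float(significant["gvar_percent"].sum()),
        threshold=threshold,
    )


@dataclass
class WssgwasResult:
    snp_effects: pd.DataFrame  # snp, chrom, pos, u_hat, weight (final iteration)
    windows: pd.DataFrame
    vc: ssgblup.VarianceComponents
    solution: ssgblup.MmeSolution
    genotyped_ids: np.ndarray
    history: list[dict] = field(default_factory=list)


def run_wssgwas(
    ped: Pedigree,
    geno: GenotypeMatrix,
    pheno: pd.DataFrame,
    response: str = "phenotype",
    fixed_factors: tuple[str, ...] = ("sex", "birth_year", "farm"),
    vc: ssgblup.VarianceComponents | None = None,
    n_iterations: int = 3,
    blend_alpha: float = 0.05,
    freqs: np.ndarray | None = None,
    window_bp: int = WINDOW_BP,
    denominator_sigma_a2: bool = False,
) -> WssgwasResult:
    """The full iterative weighted single-step scan.

    Variance components are estimated once from the unweighted (D = I)
    single-step model and held fixed while the weight loop re-estimates
    GEBVs and SNP effects; pass ``vc`` to skip the REML step.  The returned
    window table uses the final iteration's effects.
    """
    if n_iterations < 1:
        raise ValueError("need at least one iteration")
    geno_pos = ped.positions(geno.ids)
    A_inv = pedigree.build_A_inverse(ped)
    A = pedigree.build_A(ped)
    A22, A22_inv = pedigree.subset_A22(A, geno_pos)
    p = genomic.allele_frequencies(geno) if freqs is None else np.asarray(freqs, dtype=float)
    Z = geno.dosages - 2.0 * p
    model = ssgblup.build_model(pheno, ped, response=response, fixed_factors=fixed_factors)

    m = geno.n_snps
    d = np.ones(m)
    history: list[dict] = []
    u = np.zeros(m)
    solution = None
    for t in range(1, n_iterations + 1):
        G = genomic.build_G(geno, weights=d, freqs=p)
        G_use = genomic.blend_and_tune_G(G, A22, blend_alpha) if blend_alpha > 0 else G
        H_inv = ssgblup.build_H_inverse(A_inv, geno_pos, G_use.inverse(), A22_inv)
        if vc is None:
            vc = ssgblup.aireml(model, K_inv=H_inv)
        solution = ssgblup.solve_mme(model, H_inv, vc)
        g_hat = solution.a_hat[geno_pos]
        u = backsolve_snp_effects(g_hat, Z, d, G_use.values, G.lam)
        d = normalize_weights(update_weights(u, p), float(m))
        history.append(
            {
                "iteration": t,
                "u_hat": u.copy(),
                "weights": d.copy(),
                "gebv_var": float(np.var(g_hat)),
            }
        )
    windows = window_variance(
        Z,
        u,
        geno.markers,
        sigma_a2=vc.sigma_a2 if denominator_sigma_a2 else None,
        window_bp=window_bp,
    )
    snp_effects = geno.markers.copy()
    snp_effects["u_hat"] = u
    snp_effects["weight"] = history[-1]["weights"]
    snp_effects["iteration"] = n_iterations
    return WssgwasResult(
        snp_effects=snp_effects,
        windows=windows,
        vc=vc,
        solution=solution,
        genotyped_ids=geno.ids.copy(),
        history=history,
    )


def plot_windows(windows: pd.DataFrame, path, threshold: float = GVAR_THRESHOLD_PERCENT) -> None:
    """Manhattan-style plot of window variance shares along the genome."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 3.2))
    offset = 0
    ticks, labels = [], []
    for i, (chrom, grp) in enumerate(windows.groupby("chrom", sort=True)):
        x = offset + (grp["start"] + grp["end"]) / 2
        ax.scatter(x, grp["gvar_percent"], s=8, color="C0" if i % 2 == 0 else "C2")
        ticks.append(offset + (grp["end"].max()) / 2)
        labels.append(str(chrom))
        offset += grp["end"].max()
    ax.axhline(threshold, color="red", lw=0.8, ls="--")
    ax.set_xticks(ticks, labels)
    ax.set_xlabel("chromosome")
    ax.set_ylabel("gVar (%)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
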