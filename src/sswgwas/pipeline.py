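"""End-to-end orchestration: read inputs, run stages, write outputs.

Stage order is fixed: (optional) trait adjustment -> genotype QC -> variance
components under both the pedigree-only and the single-step relationship
structure -> weighted single-step scan.  Every stage logs paper-style
audit counts (animals used, SNPs surviving QC, windows formed) into a run
manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import genomic, plink, scan, ssgblup, synthetic
from .pedigree import Pedigree

log = logging.getLogger("sswgwas")

TRAITS = ("AGE", "ADG", "BF", "LMP", "phenotype")


@dataclass
class RunConfig:
    pedigree_csv: str
    phenotype_csv: str
    plink_prefix: str
    out_dir: str
    trait: str = "phenotype"
    fixed_factors: tuple[str, ...] = ("sex", "birth_year", "farm")
    qc: genomic.QcThresholds = field(default_factory=genomic.QcThresholds)
    n_iterations: int = 3
    window_bp: int = scan.WINDOW_BP
    threshold: float = scan.GVAR_THRESHOLD_PERCENT
    flank_bp: int = scan.FLANK_BP
    blend_alpha: float = 0.05
    seed: int = 0
    make_plot: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        qc = genomic.QcThresholds(**raw.pop("qc", {}))
        fixed = tuple(raw.pop("fixed_factors", ("sex", "birth_year", "farm")))
        return cls(qc=qc, fixed_factors=fixed, **raw)

    def validate(self) -> None:
        if self.trait not in TRAITS:
            raise ValueError(f"unrecognized trait {self.trait!r}; expected one of {TRAITS}")
        for path in (self.pedigree_csv, self.phenotype_csv):
            if not Path(path).exists():
                raise FileNotFoundError(path)
        if not Path(self.plink_prefix).with_suffix(".ped").exists():
            raise FileNotFoundError(f"{self.plink_prefix}.ped")


@dataclass
class RunManifest:
    version: str
    config: dict
    counts: dict = field(default_factory=dict)
    stages: list = field(default_factory=list)

    def record(self, stage: str, **counts) -> None:
        self.stages.append(stage)
        self.counts.update({f"{stage}.{k}": v for k, v in counts.items()})
        log.info("stage %s: %s", stage, counts)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def read_inputs(config: RunConfig) -> tuple[Pedigree, pd.DataFrame, genomic.GenotypeMatrix]:
    """Load and cross-validate pedigree, phenotypes and genotypes."""
    config.validate()
    ped = Pedigree.from_frame(pd.read_csv(config.pedigree_csv))
    pheno = pd.read_csv(config.phenotype_csv)
    pheno["id"] = pheno["id"].astype(str)
    if pheno["id"].duplicated().any():
        raise ValueError("duplicate animal ids in phenotype file")
    known = set(ped.ids)
    missing = [a for a in pheno["id"] if a not in known]
    if missing:
        raise ValueError(f"phenotyped animals absent from pedigree: {missing[:5]}")
    geno = plink.read_ped_map(config.plink_prefix)
    absent = [a for a in geno.ids if a not in known]
    if absent:
        raise ValueError(f"genotyped animals absent from pedigree: {absent[:5]}")
    return ped, pheno, geno


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute QC -> variance components (BLUP and ssGBLUP) -> wssGWAS scan."""
    from . import __version__

    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(version=__version__, config=_config_dict(config))

    ped, pheno, geno = read_inputs(config)
    manifest.record(
        "read", animals=ped.n, phenotyped=len(pheno), genotyped=geno.n_animals,
        snps=geno.n_snps,
    )
    if config.trait not in pheno.columns:
        needed = {"LMP": "lmd"}.get(config.trait, config.trait)
        raise ValueError(
            f"trait {config.trait!r} requires a {needed!r} column in the phenotype file"
        )

    geno_qc, report = genomic.qc_filter(geno, config.qc)
    report.to_frame().to_csv(out / "qc_report.tsv", sep="\t", index=False)
    manifest.record(
        "qc", animals=report.n_animals_out, snps=report.n_snps_out,
        snps_removed=report.n_snps_in - report.n_snps_out,
    )

    model = ssgblup.build_model(
        pheno, ped, response=config.trait, fixed_factors=config.fixed_factors
    )
    from .pedigree import build_A_inverse

    A_inv = build_A_inverse(ped)
    vc_blup = ssgblup.aireml(model, K_inv=A_inv)
    manifest.record("varcomp_blup", h2=round(vc_blup.h2, 4), converged=vc_blup.converged)

    result = scan.run_wssgwas(
        ped,
        geno_qc,
        pheno,
        response=config.trait,
        fixed_factors=config.fixed_factors,
        n_iterations=config.n_iterations,
        blend_alpha=config.blend_alpha,
        window_bp=config.window_bp,
    )
    vc_ss = result.vc
    manifest.record("varcomp_ssgblup", h2=round(vc_ss.h2, 4), converged=vc_ss.converged)
    manifest.record("scan", windows=len(result.windows))

    vc_rows = []
    for label, vc in (("BLUP", vc_blup), ("ssGBLUP", vc_ss)):
        vc_rows.append(
            {
                "trait": config.trait,
                "model": label,
                "sigma_a2": vc.sigma_a2,
                "sigma_e2": vc.sigma_e2,
                "sigma_p2": vc.sigma_p2,
                "h2": vc.h2,
                "se_h2": vc.se_h2,
            }
        )
    pd.DataFrame(vc_rows).to_csv(out / "variance_components.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"id": ped.ids, "gebv": result.solution.a_hat}
    ).to_csv(out / "gebv.tsv", sep="\t", index=False)
    result.snp_effects.to_csv(out / "snp_effects.tsv", sep="\t", index=False)
    result.windows.to_csv(out / "windows.tsv", sep="\t", index=False)
    regions = scan.report_regions(
        result.windows, threshold=config.threshold, flank_bp=config.flank_bp
    )
    regions.significant.to_csv(out / "significant_windows.tsv", sep="\t", index=False)
    regions.top_regions.to_csv(out / "top_regions.tsv", sep="\t", index=False)
    if config.make_plot:
        scan.plot_windows(result.windows, out / "windows.png", threshold=config.threshold)
    manifest.record(
        "report",
        significant=len(regions.significant),
        total_gvar=round(regions.total_significant_gvar, 4),
    )
    manifest.write(out / "manifest.yaml")
    return manifest


def write_simulation(config: synthetic.SimConfig, out_dir) -> dict:
    """Simulate a dataset and write CSV/PED/MAP/truth files for the pipeline."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ped, geno, pheno, truth, masked = synthetic.simulate_dataset(config)
    ped.to_frame().to_csv(out / "pedigree.csv", index=False)
    pheno.to_csv(out / "phenotypes.csv", index=False)
    sex = dict(zip(ped.ids, ped.meta["sex"]))
    plink.write_ped_map(masked, out / "genotypes", sex=sex)
    truth_df = pd.DataFrame(
        {"id": ped.ids, "breeding_value": truth.breeding_values}
    )
    truth_df.to_csv(out / "truth.tsv", sep="\t", index=False)
    with open(out / "truth_summary.json", "w") as fh:
        json.dump(
            {
                "realized_h2": truth.realized_h2,
                "sigma_a2_realized": truth.sigma_a2_realized,
                "sigma_e2": truth.sigma_e2,
                "founder_freq_mean": float(np.mean(geno.founder_freq)),
            },
            fh,
            indent=2,
        )
    return {
        "animals": ped.n,
        "genotyped": masked.n_animals,
        "snps": geno.n_snps,
        "out_dir": str(out),
    }


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    d["fixed_factors"] = list(config.fixed_factors)
    return d
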