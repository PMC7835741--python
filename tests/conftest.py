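import numpy as np
import pandas as pd
import pytest

from sswgwas import synthetic as syn
from sswgwas.pedigree import Pedigree


@pytest.fixture()
def trio_pedigree() -> Pedigree:
    frame = pd.DataFrame(
        {"id": ["s", "d", "o"], "sire": ["0", "0", "s"], "dam": ["0", "0", "d"]}
    )
    return Pedigree.from_frame(frame)


@pytest.fixture()
def fullsib_mating_pedigree() -> Pedigree:
    """Founders s,d; full sibs x,y; w = x mated to y (F_w = 0.25)."""
    frame = pd.DataFrame(
        {
            "id": ["s", "d", "x", "y", "w"],
            "sire": ["0", "0", "s", "s", "x"],
            "dam": ["0", "0", "d", "d", "y"],
        }
    )
    return Pedigree.from_frame(frame)


@pytest.fixture(scope="session")
def small_dataset():
    """A small but non-trivial simulated population shared across tests."""
    config = syn.SimConfig(
        n_founders=80,
        n_generations=3,
        litter_size=3,
        n_chromosomes=2,
        chrom_length_bp=20_000_000,
        n_snps_per_chrom=250,
        h2_target=0.4,
        qtl_windows=(syn.QtlWindow(1, 8_000_000, 8_800_000, 0.1),),
        genotyped_fraction=0.5,
        seed=7,
    )
    ped, geno, pheno, truth, masked = syn.simulate_dataset(config)
    return {
        "config": config,
        "ped": ped,
        "geno": geno,
        "pheno": pheno,
        "truth": truth,
        "masked": masked,
    }


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20210119)
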