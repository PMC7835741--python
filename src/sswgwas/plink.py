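"""Text PLINK PED/MAP reading and writing for biallelic A/B-coded SNPs.

Dosage is the count of the 'A' allele (so 'A A' = 2, 'A B' = 1, 'B B' = 0,
'0 0' = missing).  Only the text formats are supported; binary BED files
are out of scope.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .genomic import GenotypeMatrix

_ALLELES = {2: ("A", "A"), 1: ("A", "B"), 0: ("B", "B")}


def write_ped_map(geno: GenotypeMatrix, prefix, sex: dict | None = None) -> None:
    """Write ``prefix.ped`` and ``prefix.map``; missing dosages become '0 0'."""
    prefix = Path(prefix)
    with open(prefix.with_suffix(".map"), "w") as fh:
        for row in geno.markers.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.snp}\t0\t{row.pos}\n")
    sex = sex or {}
    code = {"male": 1, "female": 2}
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i, animal in enumerate(geno.ids):
            sx = code.get(sex.get(animal, ""), 0)
            fields = [str(animal), str(animal), "0", "0", str(sx), "-9"]
            for d in geno.dosages[i]:
                if np.isnan(d):
                    fields.extend(("0", "0"))
                else:
                    fields.extend(_ALLELES[int(round(d))])
            fh.write(" ".join(fields) + "\n")


def read_ped_map(prefix) -> GenotypeMatrix:
    """Read ``prefix.ped`` + ``prefix.map`` into a dosage matrix.

    Raises with a line number on malformed rows and on duplicate animal ids.
    """
    prefix = Path(prefix)
    markers = pd.read_csv(
        prefix.with_suffix(".map"),
        sep=r"\s+",
        header=None,
        names=["chrom", "snp", "cm", "pos"],
        dtype={"chrom": str, "snp": str, "pos": np.int64},
    )[["snp", "chrom", "pos"]]
    m = len(markers)
    ids: list[str] = []
    rows: list[np.ndarray] = []
    with open(prefix.with_suffix(".ped")) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 6 + 2 * m:
                raise ValueError(
                    f"{prefix.with_suffix('.ped')}:{lineno}: expected {6 + 2 * m} "
                    f"columns, found {len(fields)}"
                )
            ids.append(fields[1])
            alleles = fields[6:]
            dose = np.empty(m)
            for j in range(m):
                a1, a2 = alleles[2 * j], alleles[2 * j + 1]
                if a1 == "0" or a2 == "0":
                    dose[j] = np.nan
                else:
                    dose[j] = (a1 == "A") + (a2 == "A")
            rows.append(dose)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate animal ids in PED file")
    numeric_chrom = pd.to_numeric(markers["chrom"], errors="coerce")
    if numeric_chrom.notna().all():
        markers["chrom"] = numeric_chrom.astype(np.int64)
    return GenotypeMatrix(
        ids=np.asarray(ids, dtype=object),
        dosages=np.vstack(rows) if rows else np.empty((0, m)),
        markers=markers,
    )
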