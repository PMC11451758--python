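"""File formats: minimal GT-only VCF 4.2, dosage TSV, phenotype TSV,
and tab-separated result tables with self-describing header comments.

The VCF dialect carries hard genotype calls only (FORMAT=GT); positions are
1-based. Reading goes through cyvcf2; multiallelic records are skipped with
a logged reason, missing calls become -1 in the dosage matrix.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .containers import MISSING, DataError, GenotypeMatrix

__all__ = [
    "write_vcf",
    "read_vcf",
    "write_dosage_tsv",
    "read_dosage_tsv",
    "read_genotypes",
    "write_phenotypes",
    "read_phenotypes",
    "write_table",
]

_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(genotypes: GenotypeMatrix, path) -> None:
    """Write a minimal VCF 4.2 with only the GT field."""
    path = Path(path)
    chroms = list(dict.fromkeys(genotypes.variants["chrom"].astype(str)))
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=vqtlscan\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.individual_ids)
            + "\n"
        )
        for j, row in genotypes.variants.iterrows():
            gts = "\t".join(_GT[int(d)] for d in genotypes.dosages[:, j])
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{row['id']}\t{row['ref']}\t"
                f"{row['alt']}\t.\t.\t.\tGT\t{gts}\n"
            )


def read_vcf(path) -> tuple[GenotypeMatrix, dict[str, str]]:
    """Read a GT-only VCF; returns the matrix and a skipped-variant reason map."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
    remap = np.array([0, 1, MISSING, 2], dtype=np.int8)
    columns = []
    meta = []
    skipped: dict[str, str] = {}
    for i, v in enumerate(vcf):
        vid = v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}"
        if len(v.ALT) != 1:
            skipped[vid] = "multiallelic"
            continue
        gt = np.asarray(v.gt_types)
        if gt.max() > 3 or gt.min() < 0:
            raise DataError(f"malformed genotype record at line for {vid}")
        columns.append(remap[gt])
        meta.append(
            {"id": vid, "chrom": str(v.CHROM), "pos": int(v.POS),
             "ref": v.REF, "alt": v.ALT[0]}
        )
    if not columns:
        raise DataError(f"no usable biallelic variants in {path}")
    dosages = np.column_stack(columns)
    return GenotypeMatrix(dosages, pd.DataFrame(meta), samples), skipped


def write_dosage_tsv(genotypes: GenotypeMatrix, path) -> None:
    """Dosage matrix TSV: rows = individuals, columns = variants."""
    frame = pd.DataFrame(
        genotypes.dosages.astype(float),
        columns=genotypes.variant_ids,
        index=pd.Index(genotypes.individual_ids, name="individual_id"),
    )
    frame[frame == MISSING] = np.nan
    frame.to_csv(path, sep="\t", na_rep="NA")


def read_dosage_tsv(path) -> GenotypeMatrix:
    """Read a dosage TSV; variant metadata is minimal (ids only)."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if frame.index.name != "individual_id":
        raise DataError("dosage TSV must have an 'individual_id' index column")
    values = frame.to_numpy(dtype=float)
    bad = np.isfinite(values) & ~np.isin(values, (0.0, 1.0, 2.0))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise DataError(
            f"non-hard-call dosage {values[i, j]!r} at row {frame.index[i]!r}, "
            f"column {frame.columns[j]!r}"
        )
    dosages = np.where(np.isfinite(values), values, MISSING).astype(np.int8)
    variants = pd.DataFrame(
        {
            "id": list(frame.columns),
            "chrom": ".",
            "pos": np.arange(1, frame.shape[1] + 1),
            "ref": "N",
            "alt": "N",
        }
    )
    return GenotypeMatrix(dosages, variants, [str(i) for i in frame.index])


def read_genotypes(path, fmt: str = "vcf") -> tuple[GenotypeMatrix, dict[str, str]]:
    """Dispatch on format: ``vcf`` or ``dosage_tsv``."""
    if fmt == "vcf":
        return read_vcf(path)
    if fmt == "dosage_tsv":
        return read_dosage_tsv(path), {}
    raise ValueError(f"unknown genotype format {fmt!r}")


def write_phenotypes(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def write_table(frame: pd.DataFrame, path, stage: str, config: dict | None = None) -> None:
    """Write a result table with self-describing header comments."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# stage: {stage}\n")
        if config is not None:
            fh.write(f"# config_hash: {config_hash(config)}\n")
        frame.to_csv(fh, sep="\t", index=False, na_rep="NA")
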