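"""Readers and writers for the pipeline's plain-text interchange formats.

Genotypes travel as a TSV of ids x markers with 0/1/2/NA codes (primary
format) or as a GT-only biallelic VCF (read via cyvcf2; a minimal writer is
provided for interoperability). Pedigrees, ring tables, designs, trait
tables and labeled relationship matrices are CSV/TSV; simulation truth
(seed, QTL effects, true breeding values) is JSON.
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .phenotypes import validate_ring_table
from .relationships import GenotypeMatrix, Pedigree, RelationshipMatrix

__all__ = [
    "read_genotypes", "write_genotypes_tsv", "write_vcf",
    "read_pedigree", "write_pedigree",
    "read_rings", "write_rings",
    "read_design", "write_design",
    "read_relationship_matrix", "write_relationship_matrix",
    "write_truth", "file_checksum",
]


def read_genotypes(path, fmt: str | None = None) -> GenotypeMatrix:
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if path.suffix in (".vcf", ".gz") else "tsv"
    if fmt == "tsv":
        return _read_genotypes_tsv(path)
    if fmt == "vcf":
        return _read_genotypes_vcf(path)
    raise ValueError(f"unknown genotype format {fmt!r}")


def _read_genotypes_tsv(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    if df.empty:
        raise ValueError(f"{path}: empty genotype table")
    codes = df.to_numpy(dtype=float)
    bad = ~(np.isnan(codes) | np.isin(codes, (0.0, 1.0, 2.0)))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"{path}: invalid code {codes[r, c]!r} at line {r + 2}, marker {df.columns[c]}"
        )
    return GenotypeMatrix(df.index.to_numpy(object), df.columns.to_numpy(object), codes)


def _read_genotypes_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    ids = np.array(vcf.samples, dtype=object)
    markers, rows = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(
                f"non-biallelic record {var.CHROM}:{var.POS} (ALT={','.join(var.ALT)})"
            )
        markers.append(var.ID or f"{var.CHROM}:{var.POS}")
        gt = var.gt_types.astype(float)  # 0=hom-ref, 1=het, 2=hom-alt, 3=unknown
        gt[gt == 3] = np.nan
        rows.append(gt)
    if not rows:
        raise ValueError(f"{path}: VCF contains no variant records")
    return GenotypeMatrix(ids, np.array(markers, dtype=object), np.array(rows).T)


def write_genotypes_tsv(genotypes: GenotypeMatrix, path) -> None:
    genotypes.to_frame().to_csv(path, sep="\t", na_rep="NA", float_format="%g")


def write_vcf(genotypes: GenotypeMatrix, path, chrom: str = "1") -> None:
    """Minimal GT-only VCF: one pseudo-position per marker."""
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(map(str, genotypes.ids)) + "\n")
        for j, marker in enumerate(genotypes.markers):
            cells = [
                gt_map.get(c, "./.") if not np.isnan(c) else "./."
                for c in genotypes.codes[:, j]
            ]
            fh.write(f"{chrom}\t{j + 1}\t{marker}\tA\tG\t.\tPASS\t.\tGT\t"
                     + "\t".join(cells) + "\n")


def read_pedigree(path) -> Pedigree:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.empty:
        raise ValueError(f"{path}: empty pedigree file")
    need = {"id", "dam", "sire"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: pedigree needs columns {sorted(need)}")
    if "generation" in df:
        df["generation"] = pd.to_numeric(df["generation"])
    return Pedigree(df)


def write_pedigree(pedigree: Pedigree, path) -> None:
    cols = [c for c in ("id", "dam", "sire", "generation", "group", "true_sire")
            if c in pedigree.frame.columns]
    pedigree.frame[cols].to_csv(path, index=False)


def read_rings(path, value_col: str = "value") -> pd.DataFrame:
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: empty ring table")
    validate_ring_table(df, value_col=value_col)
    return df


def write_rings(rings: pd.DataFrame, path) -> None:
    rings.to_csv(path, index=False)


def read_design(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: empty design table")
    if not {"id", "trial", "block"} <= set(df.columns):
        raise ValueError(f"{path}: design needs id, trial, block columns")
    return df


def write_design(design: pd.DataFrame, path) -> None:
    design.to_csv(path, index=False)


def read_relationship_matrix(path, kind: str = "unknown") -> RelationshipMatrix:
    # round_trip parsing keeps the shortest-repr floats written below bit-exact
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    return RelationshipMatrix(df.index.to_numpy(object), df.to_numpy(float), kind)


def write_relationship_matrix(K: RelationshipMatrix, path) -> None:
    K.to_frame().to_csv(path, sep="\t")


def write_truth(sim, path) -> None:
    """Simulation ground truth as JSON (seed/config, QTL effects, TBVs,
    hidden sires)."""
    payload = {
        "config": sim.config.to_dict(),
        "qtl_effects": {m: float(v) for m, v in sim.qtl_effects.items() if v != 0.0},
        "true_breeding_values": {i: float(v) for i, v in sim.true_breeding_values.items()},
        "true_sires": dict(sim.true_sires),
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def file_checksum(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
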