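"""Reading and writing genotype panels and result tables.

Genotypes travel either as minimal unphased VCF (GT only, "0/1" style,
missing "./.") or as a plain SNPs x samples TSV; the marker map is a
4-column TSV (snp_id, chrom, pos_bp, pos_kb).  VCF reading goes through
cyvcf2.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix, MarkerMap
from .errors import StructuralError

__all__ = [
    "write_vcf",
    "read_vcf",
    "write_genotype_tsv",
    "read_genotype_tsv",
    "write_marker_map",
    "read_marker_map",
]

_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(g: GenotypeMatrix, marker_map: MarkerMap, path) -> None:
    """Write one population as an uncompressed VCF 4.2 with GT only."""
    info = marker_map.lookup(g.snps)
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=ldphase\n##population={g.population}\n")
        for chrom in pd.unique(info["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.samples)
            + "\n"
        )
        for col, row in enumerate(info.itertuples(index=False)):
            gts = "\t".join(_GT_STRINGS[int(c)] for c in g.codes[:, col])
            fh.write(f"{row.chrom}\t{row.pos}\t{row.snp_id}\tA\tC\t.\t.\t.\tGT\t{gts}\n")


def read_vcf(path, population: str | None = None) -> tuple[GenotypeMatrix, MarkerMap]:
    """Read a biallelic VCF into a genotype matrix plus its marker map."""
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)  # gt_types: 0/1/2 = dosage, 3 = missing
    samples = list(vcf.samples)
    snp_ids, chroms, positions, rows = [], [], [], []
    for i, variant in enumerate(vcf):
        snp_ids.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
        chroms.append(str(variant.CHROM))
        positions.append(int(variant.POS))
        codes = variant.gt_types.astype(np.int8)
        codes[codes == 3] = MISSING
        rows.append(codes)
    vcf.close()
    if not rows:
        raise StructuralError(f"no variants in {path}")
    marker_map = MarkerMap(
        pd.DataFrame({"snp_id": snp_ids, "chrom": chroms, "pos": positions})
    )
    g = GenotypeMatrix(
        population=population or Path(path).stem,
        samples=samples,
        snps=np.asarray(snp_ids),
        codes=np.stack(rows, axis=1),
    )
    return g, marker_map


def write_genotype_tsv(g: GenotypeMatrix, path) -> None:
    """SNPs x samples TSV; missing genotypes are empty cells."""
    g.to_frame().to_csv(path, sep="\t")


def read_genotype_tsv(path, population: str | None = None) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col="snp_id")
    codes = df.to_numpy(dtype=float).T
    codes = np.where(np.isnan(codes), MISSING, codes).astype(np.int8)
    return GenotypeMatrix(
        population=population or Path(path).stem,
        samples=[str(c) for c in df.columns],
        snps=df.index.to_numpy(),
        codes=codes,
    )


def write_marker_map(marker_map: MarkerMap, path) -> None:
    out = marker_map.frame.rename(columns={"pos": "pos_bp"}).copy()
    out["pos_kb"] = out["pos_bp"] / 1000.0
    out.to_csv(path, sep="\t", index=False)


def read_marker_map(path) -> MarkerMap:
    df = pd.read_csv(path, sep="\t")
    if "pos_bp" in df.columns:
        df = df.rename(columns={"pos_bp": "pos"})
    df["chrom"] = df["chrom"].astype(str)
    return MarkerMap(df[["snp_id", "chrom", "pos"]])
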