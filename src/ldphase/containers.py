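"""Core in-memory containers: genotype matrices and marker maps.

Genotypes are coded as copies of the panel-wide ALT allele: 0 (hom REF),
1 (het), 2 (hom ALT), with ``-1`` for missing.  The coding is shared by
every population analysed together — signed-LD comparisons across
populations are only meaningful under a common allele orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import StructuralError

MISSING: int = -1


@dataclass
class MarkerMap:
    """SNP id, chromosome and base-pair position for a genotyping panel.

    Positions in kb are derived as ``pos / 1000``.  SNP ids must be unique;
    unmapped SNPs are simply absent from the map.
    """

    frame: pd.DataFrame  # columns: snp_id, chrom, pos

    def __post_init__(self) -> None:
        required = {"snp_id", "chrom", "pos"}
        missing = required - set(self.frame.columns)
        if missing:
            raise StructuralError(f"marker map lacks columns: {sorted(missing)}")
        if self.frame["snp_id"].duplicated().any():
            raise StructuralError("marker map contains duplicate snp_id values")
        if (self.frame["pos"] < 0).any():
            raise StructuralError("marker map contains negative positions")
        self.frame = self.frame.reset_index(drop=True)

    @property
    def snp_ids(self) -> np.ndarray:
        return self.frame["snp_id"].to_numpy()

    @property
    def pos_kb(self) -> np.ndarray:
        return self.frame["pos"].to_numpy(dtype=float) / 1000.0

    def __len__(self) -> int:
        return len(self.frame)

    def subset(self, snp_ids) -> "MarkerMap":
        keep = self.frame["snp_id"].isin(set(snp_ids))
        return MarkerMap(self.frame.loc[keep].reset_index(drop=True))

    def lookup(self, snp_ids) -> pd.DataFrame:
        """Rows for the given SNPs, in the given order; raises if any is unmapped."""
        indexed = self.frame.set_index("snp_id")
        try:
            return indexed.loc[list(snp_ids)].reset_index()
        except KeyError as exc:  # pragma: no cover - message detail only
            raise StructuralError(f"snp ids absent from the marker map: {exc}") from exc

    def same_as(self, other: "MarkerMap") -> bool:
        a, b = self.frame, other.frame
        return (
            len(a) == len(b)
            and (a["snp_id"].to_numpy() == b["snp_id"].to_numpy()).all()
            and (a["chrom"].to_numpy() == b["chrom"].to_numpy()).all()
            and (a["pos"].to_numpy() == b["pos"].to_numpy()).all()
        )


@dataclass
class GenotypeMatrix:
    """Samples x SNPs genotype codes for one population.

    ``codes`` is an int8 array with entries in {0, 1, 2, MISSING}.
    """

    population: str
    samples: list[str]
    snps: np.ndarray
    codes: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.snps = np.asarray(self.snps)
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.shape != (len(self.samples), len(self.snps)):
            raise StructuralError(
                f"genotype matrix shape {self.codes.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snps)} snps"
            )
        bad = ~np.isin(self.codes, (0, 1, 2, MISSING))
        if bad.any():
            raise StructuralError("genotype codes outside {0, 1, 2, missing}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def subset_snps(self, snp_ids) -> "GenotypeMatrix":
        """Restrict to the given SNPs, preserving this matrix's column order."""
        keep = np.isin(self.snps, np.asarray(list(snp_ids)))
        return GenotypeMatrix(
            population=self.population,
            samples=list(self.samples),
            snps=self.snps[keep],
            codes=self.codes[:, keep],
        )

    def to_frame(self) -> pd.DataFrame:
        """SNPs x samples table (one row per SNP), missing as pandas NA."""
        df = pd.DataFrame(
            self.codes.T, index=pd.Index(self.snps, name="snp_id"), columns=self.samples
        ).astype("Int8")
        return df.mask(df == MISSING)
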