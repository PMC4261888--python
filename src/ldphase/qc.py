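"""Marker quality control and cross-population marker intersection.

Filters mirror routine SNP-chip QC: drop unmapped and X-linked markers,
then drop markers with call rate < 0.90, MAF < 0.05 or an exact
Hardy-Weinberg p-value < 1e-4.  Thresholds are strict (<): a marker at
call rate exactly 0.90 or MAF exactly 0.05 is retained.

For analyses that span several populations, only markers that pass QC in
every population of the group are kept (the intersection rule).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix, MarkerMap
from .errors import QCError

__all__ = [
    "QCReport",
    "hwe_exact_p",
    "filter_positional",
    "filter_quality",
    "intersect_markers",
    "run_qc",
]


@dataclass
class QCReport:
    """Per-population removal counts, attributed to the first failing filter
    in the order: unmapped/excluded chromosome, call rate, MAF, HWE."""

    population: str
    n_input: int
    removed_unmapped_or_excluded: int
    removed_call_rate: int
    removed_maf: int
    removed_hwe: int
    n_retained: int

    def __post_init__(self) -> None:
        total = (
            self.removed_unmapped_or_excluded
            + self.removed_call_rate
            + self.removed_maf
            + self.removed_hwe
            + self.n_retained
        )
        if total != self.n_input:
            raise QCError("QC report counts do not add up to the input SNP count")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def hwe_exact_p(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided exact Hardy-Weinberg test p-value.

    Enumerates every heterozygote count compatible with the observed allele
    counts, accumulating the probabilities of all configurations no more
    likely than the observed one (no mid-p correction).  Probabilities are
    built by the standard ratio recurrence, which is exact up to floating
    point for the sample sizes a genotyping panel sees.
    """
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        return 1.0
    n_rare = 2 * n_hom_alt + n_het
    if n_rare > n:  # orient to the rarer allele
        n_rare = 2 * n - n_rare
    # heterozygote counts share the parity of the rare-allele count
    het_min = n_rare % 2
    het_max = min(n_rare, 2 * n - n_rare)
    hets = np.arange(het_min, het_max + 1, 2)
    probs = np.empty(len(hets))
    probs[0] = 1.0
    for k in range(1, len(hets)):
        h = hets[k]  # P(h) / P(h-2) ratio
        rare_hom = (n_rare - h) // 2 + 1
        common_hom = (2 * n - n_rare - h) // 2 + 1
        probs[k] = probs[k - 1] * 4.0 * rare_hom * common_hom / (h * (h - 1))
    probs /= probs.sum()
    observed = probs[(hets == n_het).nonzero()[0][0]]
    return float(min(1.0, probs[probs <= observed * (1 + 1e-12)].sum()))


def filter_positional(
    g: GenotypeMatrix, marker_map: MarkerMap, excluded_chroms=("X",)
) -> GenotypeMatrix:
    """Drop SNPs with no map position and SNPs on excluded chromosomes."""
    mapped = marker_map.frame.set_index("snp_id")["chrom"]
    keep = []
    excluded = set(str(c) for c in excluded_chroms)
    for snp in g.snps:
        chrom = mapped.get(snp)
        keep.append(chrom is not None and str(chrom) not in excluded)
    return g.subset_snps(g.snps[np.asarray(keep, dtype=bool)])


def _snp_stats(g: GenotypeMatrix) -> pd.DataFrame:
    codes = g.codes
    observed = codes != MISSING
    n_obs = observed.sum(axis=0)
    n_het = (codes == 1).sum(axis=0)
    n_alt = (codes == 2).sum(axis=0)
    n_ref = (codes == 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        alt_freq = (2 * n_alt + n_het) / (2 * n_obs)
    maf = np.minimum(alt_freq, 1 - alt_freq)
    hwe = np.array(
        [
            hwe_exact_p(int(r), int(h), int(a)) if m > 0 else 1.0
            for r, h, a, m in zip(n_ref, n_het, n_alt, n_obs)
        ]
    )
    return pd.DataFrame(
        {
            "snp_id": g.snps,
            "call_rate": n_obs / g.n_samples,
            "maf": np.where(n_obs > 0, maf, 0.0),
            "hwe_p": hwe,
        }
    )


def filter_quality(
    g: GenotypeMatrix,
    call_rate_min: float = 0.90,
    maf_min: float = 0.05,
    hwe_p_min: float = 1e-4,
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply the marker-level filters; a SNP failing any criterion is removed.

    Removal counts attribute each SNP to its first failing filter (call
    rate, then MAF, then HWE); the retained set does not depend on that
    order.
    """
    if g.n_samples == 0:
        raise QCError(f"population {g.population}: zero samples")
    stats = _snp_stats(g)
    fail_cr = stats["call_rate"].to_numpy() < call_rate_min
    fail_maf = stats["maf"].to_numpy() < maf_min
    fail_hwe = stats["hwe_p"].to_numpy() < hwe_p_min
    removed = fail_cr | fail_maf | fail_hwe
    report = QCReport(
        population=g.population,
        n_input=g.n_snps,
        removed_unmapped_or_excluded=0,
        removed_call_rate=int(fail_cr.sum()),
        removed_maf=int((fail_maf & ~fail_cr).sum()),
        removed_hwe=int((fail_hwe & ~fail_cr & ~fail_maf).sum()),
        n_retained=int((~removed).sum()),
    )
    return g.subset_snps(g.snps[~removed]), report


def run_qc(
    g: GenotypeMatrix,
    marker_map: MarkerMap,
    excluded_chroms=("X",),
    call_rate_min: float = 0.90,
    maf_min: float = 0.05,
    hwe_p_min: float = 1e-4,
) -> tuple[GenotypeMatrix, QCReport]:
    """Positional filter followed by the quality filters, with one report."""
    positioned = filter_positional(g, marker_map, excluded_chroms)
    n_positional = g.n_snps - positioned.n_snps
    filtered, report = filter_quality(positioned, call_rate_min, maf_min, hwe_p_min)
    report = QCReport(
        population=report.population,
        n_input=g.n_snps,
        removed_unmapped_or_excluded=n_positional,
        removed_call_rate=report.removed_call_rate,
        removed_maf=report.removed_maf,
        removed_hwe=report.removed_hwe,
        n_retained=report.n_retained,
    )
    return filtered, report


def intersect_markers(group: list[GenotypeMatrix]) -> list[GenotypeMatrix]:
    """Restrict each population to the SNPs retained in *all* of them.

    Column order within each matrix is preserved.  An empty intersection is
    an error, never a silent empty result.
    """
    if len(group) < 2:
        raise QCError("marker intersection needs at least 2 populations")
    common: set = set(group[0].snps)
    for g in group[1:]:
        common &= set(g.snps)
    if not common:
        raise QCError(
            "no SNP passed QC in all populations: "
            + ", ".join(g.population for g in group)
        )
    return [g.subset_snps(common) for g in group]
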