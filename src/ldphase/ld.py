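"""Pairwise linkage disequilibrium from unphased genotypes.

For each SNP pair the 3x3 joint genotype table (samples non-missing at both
loci) yields:

* maximum-likelihood haplotype frequencies via EM over the double-
  heterozygote phase ambiguity;
* r^2 = (p_22 - p_2. p_.2)^2 / (p_2.(1-p_2.) p_.2(1-p_.2)), the squared
  correlation of gene frequencies;
* the composite disequilibrium D computed from genotype-class proportions
  with double heterozygotes excluded and the remainder rescaled by
  tau = 2 - 2 * P(double het);
* signed r = sign(D) * sqrt(r^2), which is comparable across populations
  that share an allele orientation: it is positive when the
  more-frequent-than-expected haplotype couples the same alleles.

Genotype codes count copies of the panel ALT allele, so haplotype-notation
allele "2" is ALT and genotype class 22 is the ALT homozygote.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix, MarkerMap
from .errors import ConvergenceError, UndefinedLDError, UndefinedSignError

__all__ = [
    "TwoLocusGenotypeCounts",
    "HaploFreqs",
    "em_haplofreqs",
    "r_squared",
    "composite_d",
    "signed_r",
    "pair_ld_table",
]


@dataclass
class TwoLocusGenotypeCounts:
    """Joint genotype counts n[gA][gB], gA/gB = ALT dosage 0/1/2."""

    table: np.ndarray  # (3, 3) int

    def __post_init__(self) -> None:
        self.table = np.asarray(self.table, dtype=np.int64)
        if self.table.shape != (3, 3) or (self.table < 0).any():
            raise ValueError("counts must be a nonnegative 3x3 table")

    @classmethod
    def from_codes(cls, a: np.ndarray, b: np.ndarray) -> "TwoLocusGenotypeCounts":
        ok = (a != MISSING) & (b != MISSING)
        table = np.zeros((3, 3), dtype=np.int64)
        np.add.at(table, (a[ok], b[ok]), 1)
        return cls(table)

    @property
    def n_total(self) -> int:
        return int(self.table.sum())


@dataclass
class HaploFreqs:
    """ML haplotype frequencies p_ab (a = allele at locus A, 1=REF, 2=ALT)."""

    p11: float
    p12: float
    p21: float
    p22: float
    loglik: float
    n_iter: int
    converged: bool

    @property
    def p_i(self) -> float:
        """ALT frequency at the first locus."""
        return self.p21 + self.p22

    @property
    def p_j(self) -> float:
        """ALT frequency at the second locus."""
        return self.p12 + self.p22


def _em_tables(
    tables: np.ndarray, tol: float = 1e-8, max_iter: int = 1000
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised EM over a stack of 3x3 tables.

    Returns (freqs, n_iter, converged) where freqs has shape (k, 4) ordered
    p11, p12, p21, p22.  Margins are preserved exactly by every EM step
    (only the phase of double heterozygotes is latent), so the returned
    frequencies always satisfy the observed allele frequencies.
    """
    t = np.asarray(tables, dtype=np.float64)
    n = t.sum(axis=(1, 2))
    if (n == 0).any():
        raise UndefinedLDError("empty genotype table")
    two_n = 2.0 * n
    qa = (2 * t[:, 2, :].sum(axis=1) + t[:, 1, :].sum(axis=1)) / two_n
    qb = (2 * t[:, :, 2].sum(axis=1) + t[:, :, 1].sum(axis=1)) / two_n
    # fixed, fully observed haplotype contributions
    c22 = 2 * t[:, 2, 2] + t[:, 2, 1] + t[:, 1, 2]
    c21 = 2 * t[:, 2, 0] + t[:, 2, 1] + t[:, 1, 0]
    c12 = 2 * t[:, 0, 2] + t[:, 0, 1] + t[:, 1, 2]
    c11 = 2 * t[:, 0, 0] + t[:, 0, 1] + t[:, 1, 0]
    dh = t[:, 1, 1].astype(np.float64)

    # linkage-equilibrium initialisation; iterate on the still-active subset
    # only (boundary solutions converge slowly and would otherwise drag the
    # whole stack through extra iterations)
    freqs = np.stack(
        [(1 - qa) * (1 - qb), (1 - qa) * qb, qa * (1 - qb), qa * qb], axis=1
    )  # columns p11, p12, p21, p22
    fixed = np.stack([c11, c12, c21, c22], axis=1)
    n_iter = np.zeros(len(t), dtype=np.int64)
    idx = np.arange(len(t))
    for it in range(1, max_iter + 1):
        p = freqs[idx]
        cis = p[:, 3] * p[:, 0]
        trans = p[:, 1] * p[:, 2]
        denom = cis + trans
        w = np.where(denom > 0, cis / np.where(denom > 0, denom, 1.0), 0.5)
        latent = np.stack([w, 1 - w, 1 - w, w], axis=1) * dh[idx, None]
        new = (fixed[idx] + latent) / two_n[idx, None]
        delta = np.max(np.abs(new - p), axis=1)
        freqs[idx] = new
        n_iter[idx] = it
        idx = idx[delta >= tol]
        if not len(idx):
            break
    converged = np.ones(len(t), dtype=bool)
    converged[idx] = False
    return freqs, n_iter, converged


def _loglik_tables(tables: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """Multinomial log-likelihood of 3x3 tables under haplotype freqs (k, 4)."""
    p11, p12, p21, p22 = freqs[:, 0], freqs[:, 1], freqs[:, 2], freqs[:, 3]
    probs = np.empty((len(freqs), 3, 3))
    probs[:, 0, 0] = p11**2
    probs[:, 0, 1] = 2 * p11 * p12
    probs[:, 0, 2] = p12**2
    probs[:, 1, 0] = 2 * p11 * p21
    probs[:, 1, 1] = 2 * (p22 * p11 + p12 * p21)
    probs[:, 1, 2] = 2 * p12 * p22
    probs[:, 2, 0] = p21**2
    probs[:, 2, 1] = 2 * p21 * p22
    probs[:, 2, 2] = p22**2
    t = np.asarray(tables, dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = t * np.log(probs)
    terms[t == 0] = 0.0  # 0 * log 0 = 0
    return terms.sum(axis=(1, 2))


def em_haplofreqs(
    counts: TwoLocusGenotypeCounts, tol: float = 1e-8, max_iter: int = 1000
) -> HaploFreqs:
    """ML haplotype frequencies for one pair of loci.

    Raises :class:`UndefinedLDError` if either locus is monomorphic among
    the counted samples and :class:`ConvergenceError` if EM does not reach
    `tol` within `max_iter` iterations.
    """
    t = counts.table[None, :, :]
    n = counts.n_total
    if n == 0:
        raise UndefinedLDError("no samples genotyped at both loci")
    qa = (2 * counts.table[2, :].sum() + counts.table[1, :].sum()) / (2 * n)
    qb = (2 * counts.table[:, 2].sum() + counts.table[:, 1].sum()) / (2 * n)
    if qa in (0.0, 1.0) or qb in (0.0, 1.0):
        raise UndefinedLDError("monomorphic locus: LD undefined")
    freqs, n_iter, converged = _em_tables(t, tol=tol, max_iter=max_iter)
    if not converged[0]:
        raise ConvergenceError(f"EM did not converge within {max_iter} iterations")
    loglik = float(_loglik_tables(t, freqs)[0])
    p11, p12, p21, p22 = (float(x) for x in freqs[0])
    return HaploFreqs(p11, p12, p21, p22, loglik, int(n_iter[0]), True)


def r_squared(h: HaploFreqs) -> float:
    """Squared correlation of gene frequencies from haplotype frequencies."""
    pi, pj = h.p_i, h.p_j
    if pi <= 0 or pi >= 1 or pj <= 0 or pj >= 1:
        raise UndefinedLDError("fixed margin: r^2 undefined")
    r2 = (h.p22 - pi * pj) ** 2 / (pi * (1 - pi) * pj * (1 - pj))
    return float(min(1.0, r2))


def composite_d(counts: TwoLocusGenotypeCounts) -> float:
    """Composite two-locus disequilibrium from genotype-class proportions.

    Double heterozygotes (phase-ambiguous) are excluded through
    tau = 2 - 2 * P(het, het); the three informative haplotype-class
    frequencies are rescaled by tau and combined as
    D = f22 - (f12 + f22)(f21 + f22).
    """
    t = counts.table
    n = counts.n_total
    if n == 0:
        raise UndefinedLDError("no samples genotyped at both loci")
    p = t / n
    tau = 2.0 - 2.0 * p[1, 1]
    if tau <= 0:
        raise UndefinedSignError("tau = 0: every sample is double-heterozygous")
    f22 = (2 * p[2, 2] + p[2, 1] + p[1, 2]) / tau
    f12 = (2 * p[0, 2] + p[0, 1] + p[1, 2]) / tau
    f21 = (2 * p[2, 0] + p[2, 1] + p[1, 0]) / tau
    return float(f22 - (f12 + f22) * (f21 + f22))


def signed_r(
    counts: TwoLocusGenotypeCounts, tol: float = 1e-8, max_iter: int = 1000
) -> tuple[float, float, float]:
    """(r2, composite D, signed r) for one pair.

    signed r = sign(D) * sqrt(r2); a D of exactly zero takes the + sign so
    the output is deterministic.
    """
    h = em_haplofreqs(counts, tol=tol, max_iter=max_iter)
    r2 = r_squared(h)
    d = composite_d(counts)
    sign = -1.0 if d < 0 else 1.0
    return r2, d, sign * float(np.sqrt(r2))


def _joint_count_tables(codes: np.ndarray) -> np.ndarray:
    """All-pairs 3x3 joint counts via indicator matrix products.

    Returns an array of shape (3, 3, m, m) where entry [a, b, i, j] is the
    number of samples with dosage a at SNP i and dosage b at SNP j.
    """
    ind = np.stack([(codes == g).astype(np.float64) for g in (0, 1, 2)])
    out = np.empty((3, 3, codes.shape[1], codes.shape[1]))
    for a in range(3):
        for b in range(3):
            out[a, b] = ind[a].T @ ind[b]
    return out


def pair_ld_table(
    g: GenotypeMatrix,
    marker_map: MarkerMap,
    max_distance_kb: float = 5000.0,
    tol: float = 1e-8,
    max_iter: int = 20000,
) -> pd.DataFrame:
    """All within-chromosome SNP pairs up to `max_distance_kb`.

    Columns: population, snp_a, snp_b, chrom, distance_kb, n, r2,
    d_composite, r_signed.  Pairs where LD is undefined (a locus
    monomorphic among the jointly genotyped samples) or where the composite
    sign is undefined are skipped; pairs at zero distance are excluded.
    EM non-convergence for a pair raises :class:`ConvergenceError` rather
    than silently passing a bad estimate through.
    """
    info = marker_map.lookup(g.snps)
    chrom = info["chrom"].to_numpy()
    pos_kb = info["pos"].to_numpy(dtype=float) / 1000.0
    m = g.n_snps
    ii, jj = np.triu_indices(m, k=1)
    same = chrom[ii] == chrom[jj]
    dist = np.abs(pos_kb[jj] - pos_kb[ii])
    keep = same & (dist > 0) & (dist <= max_distance_kb)
    ii, jj, dist = ii[keep], jj[keep], dist[keep]
    if len(ii) == 0:
        return pd.DataFrame(
            columns=[
                "population", "snp_a", "snp_b", "chrom", "distance_kb",
                "n", "r2", "d_composite", "r_signed",
            ]
        )

    counts = _joint_count_tables(g.codes)  # (3, 3, m, m)
    tables = counts[:, :, ii, jj].transpose(2, 0, 1)  # (k, 3, 3)
    n = tables.sum(axis=(1, 2))
    two_n = 2.0 * n
    with np.errstate(invalid="ignore", divide="ignore"):
        qa = (2 * tables[:, 2, :].sum(axis=1) + tables[:, 1, :].sum(axis=1)) / two_n
        qb = (2 * tables[:, :, 2].sum(axis=1) + tables[:, :, 1].sum(axis=1)) / two_n
    defined = (n > 0) & (qa > 0) & (qa < 1) & (qb > 0) & (qb < 1)
    ii, jj, dist, tables = ii[defined], jj[defined], dist[defined], tables[defined]
    qa, qb, n = qa[defined], qb[defined], n[defined]

    freqs, _, converged = _em_tables(tables, tol=tol, max_iter=max_iter)
    if not converged.all():
        raise ConvergenceError(
            f"EM failed to converge for {int((~converged).sum())} pairs"
        )
    p22 = freqs[:, 3]
    r2 = np.minimum(1.0, (p22 - qa * qb) ** 2 / (qa * (1 - qa) * qb * (1 - qb)))

    p = tables / n[:, None, None]
    tau = 2.0 - 2.0 * p[:, 1, 1]
    sign_ok = tau > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        f22 = (2 * p[:, 2, 2] + p[:, 2, 1] + p[:, 1, 2]) / tau
        f12 = (2 * p[:, 0, 2] + p[:, 0, 1] + p[:, 1, 2]) / tau
        f21 = (2 * p[:, 2, 0] + p[:, 2, 1] + p[:, 1, 0]) / tau
    d = f22 - (f12 + f22) * (f21 + f22)

    out = pd.DataFrame(
        {
            "population": g.population,
            "snp_a": g.snps[ii],
            "snp_b": g.snps[jj],
            "chrom": chrom[ii],
            "distance_kb": dist,
            "n": n.astype(np.int64),
            "r2": r2,
            "d_composite": d,
            "r_signed": np.where(d < 0, -1.0, 1.0) * np.sqrt(r2),
        }
    )
    return out[sign_ok].reset_index(drop=True)
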