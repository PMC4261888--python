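"""LD core: EM haplotype frequencies against an independent ML oracle,
the r2 formula, composite-D conventions, and the pair table."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize

import ldphase as lp
from ldphase.errors import UndefinedLDError
from ldphase.ld import _loglik_tables

from conftest import make_genotypes, make_map


def counts_from_table(table) -> lp.TwoLocusGenotypeCounts:
    return lp.TwoLocusGenotypeCounts(np.asarray(table))


def direct_ml_oracle(table: np.ndarray) -> tuple[np.ndarray, float]:
    """Independent maximum-likelihood haplotype frequencies.

    Direct numerical maximisation of the observed-data multinomial
    log-likelihood over the softmax-parametrised 3-simplex from several
    starts (no EM involved).  Returns (freqs p11,p12,p21,p22, loglik).
    """
    t = np.asarray(table, dtype=float)[None]

    def neg_loglik(z: np.ndarray) -> float:
        z = np.concatenate([[0.0], z])
        p = np.exp(z - z.max())
        p /= p.sum()
        return -_loglik_tables(t, p[None])[0]

    best, best_val = None, np.inf
    rng = np.random.default_rng(0)
    starts = [np.zeros(3)] + [rng.normal(scale=2.0, size=3) for _ in range(7)]
    for x0 in starts:
        res = optimize.minimize(neg_loglik, x0, method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
        if res.fun < best_val:
            best, best_val = res.x, res.fun
    z = np.concatenate([[0.0], best])
    p = np.exp(z - z.max())
    p /= p.sum()
    return p, -best_val


def random_table(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random polymorphic-at-both-loci 3x3 genotype count table."""
    while True:
        probs = rng.dirichlet(np.ones(9)).reshape(3, 3)
        t = rng.multinomial(n, probs.ravel()).reshape(3, 3)
        na = 2 * t[2, :].sum() + t[1, :].sum()
        nb = 2 * t[:, 2].sum() + t[:, 1].sum()
        if 0 < na < 2 * n and 0 < nb < 2 * n:
            return t


class TestEM:
    def test_no_double_heterozygotes_equals_gene_counting(self):
        # without phase ambiguity the EM fixed point is the closed-form
        # gene-count solution
        t = np.array([[10, 4, 0], [3, 0, 2], [1, 5, 8]])
        h = lp.em_haplofreqs(counts_from_table(t))
        n2 = 2 * t.sum()
        expect = {
            "p11": (2 * t[0, 0] + t[0, 1] + t[1, 0]) / n2,
            "p12": (2 * t[0, 2] + t[0, 1] + t[1, 2]) / n2,
            "p21": (2 * t[2, 0] + t[2, 1] + t[1, 0]) / n2,
            "p22": (2 * t[2, 2] + t[2, 1] + t[1, 2]) / n2,
        }
        for key, val in expect.items():
            assert getattr(h, key) == pytest.approx(val, abs=1e-9)

    def test_perfect_association(self):
        t = np.zeros((3, 3), dtype=int)
        t[0, 0] = 25
        t[2, 2] = 25
        h = lp.em_haplofreqs(counts_from_table(t))
        assert h.p11 == pytest.approx(0.5, abs=1e-9)
        assert h.p22 == pytest.approx(0.5, abs=1e-9)
        assert lp.r_squared(h) == pytest.approx(1.0, abs=1e-9)

    def test_margins_match_observed_allele_frequencies(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            t = random_table(rng, 40)
            h = lp.em_haplofreqs(counts_from_table(t))
            n2 = 2 * t.sum()
            assert h.p_i == pytest.approx((2 * t[2, :].sum() + t[1, :].sum()) / n2, abs=1e-7)
            assert h.p_j == pytest.approx((2 * t[:, 2].sum() + t[:, 1].sum()) / n2, abs=1e-7)
            assert h.p11 + h.p12 + h.p21 + h.p22 == pytest.approx(1.0, abs=1e-9)

    def test_attains_maximum_likelihood(self):
        """EM log-likelihood matches (or beats, within tolerance) direct
        numerical ML and a coarse grid over the haplotype simplex."""
        rng = np.random.default_rng(17)
        for _ in range(25):
            t = random_table(rng, 40)
            h = lp.em_haplofreqs(counts_from_table(t))
            p_ref, ll_ref = direct_ml_oracle(t)
            assert h.loglik >= ll_ref - 1e-6
            # grid: no point on a coarse simplex grid beats EM
            grid = []
            step = 0.05
            for a in np.arange(0, 1 + 1e-9, step):
                for b in np.arange(0, 1 - a + 1e-9, step):
                    for c in np.arange(0, 1 - a - b + 1e-9, step):
                        grid.append([a, b, c, 1 - a - b - c])
            grid = np.clip(np.array(grid), 0, 1)
            lls = _loglik_tables(np.repeat(t[None], len(grid), axis=0), grid)
            assert h.loglik >= np.nanmax(lls) - 1e-6

    def test_monomorphic_locus_rejected(self):
        t = np.zeros((3, 3), dtype=int)
        t[0, 0] = 10
        t[0, 2] = 10
        with pytest.raises(UndefinedLDError):
            lp.em_haplofreqs(counts_from_table(t))


class TestR2:
    def test_hand_computed_value(self):
        h = lp.HaploFreqs(p11=0.4, p12=0.1, p21=0.1, p22=0.4, loglik=0.0, n_iter=0, converged=True)
        # (0.4 - 0.25)^2 / (0.25 * 0.25) = 0.36
        assert lp.r_squared(h) == pytest.approx(0.36, abs=1e-12)

    def test_equilibrium_is_zero(self):
        h = lp.HaploFreqs(p11=0.42, p12=0.28, p21=0.18, p22=0.12, loglik=0.0, n_iter=0, converged=True)
        # p22 = 0.3 * 0.4 exactly
        assert lp.r_squared(h) == pytest.approx(0.0, abs=1e-12)

    def test_fixed_margin_rejected(self):
        h = lp.HaploFreqs(p11=0.5, p12=0.5, p21=0.0, p22=0.0, loglik=0.0, n_iter=0, converged=True)
        with pytest.raises(UndefinedLDError):
            lp.r_squared(h)


class TestCompositeD:
    def test_hand_computed_coupling(self):
        t = np.zeros((3, 3), dtype=int)
        t[2, 2] = 10
        t[0, 0] = 10
        # f22 = 0.5, f12 = f21 = 0 -> D = 0.5 - 0.25 = 0.25
        assert lp.composite_d(counts_from_table(t)) == pytest.approx(0.25, abs=1e-12)

    def test_independent_loci_d_near_zero(self):
        rng = np.random.default_rng(8)
        n = 10_000
        ga = rng.binomial(2, 0.5, size=n).astype(np.int8)
        gb = rng.binomial(2, 0.5, size=n).astype(np.int8)
        d = lp.composite_d(lp.TwoLocusGenotypeCounts.from_codes(ga, gb))
        assert abs(d) < 3.0 / np.sqrt(n)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=40, deadline=None)
    def test_one_locus_relabel_flips_sign(self, seed):
        """Composite D is antisymmetric under relabeling one locus
        (g -> 2 - g) and invariant under relabeling both."""
        rng = np.random.default_rng(seed)
        t = random_table(rng, 30)
        d = lp.composite_d(counts_from_table(t))
        d_flip_a = lp.composite_d(counts_from_table(t[::-1, :]))
        d_flip_both = lp.composite_d(counts_from_table(t[::-1, ::-1]))
        assert d_flip_a == pytest.approx(-d, abs=1e-12)
        assert d_flip_both == pytest.approx(d, abs=1e-12)


class TestSignedR:
    def test_perfect_coupling_and_repulsion(self):
        coupling = np.zeros((3, 3), dtype=int)
        coupling[0, 0] = coupling[2, 2] = 25
        r2, d, r = lp.signed_r(counts_from_table(coupling))
        assert r == pytest.approx(1.0, abs=1e-9)
        repulsion = np.zeros((3, 3), dtype=int)
        repulsion[0, 2] = repulsion[2, 0] = 25
        r2, d, r = lp.signed_r(counts_from_table(repulsion))
        assert r == pytest.approx(-1.0, abs=1e-9)

    def test_sqrt_consistency(self):
        rng = np.random.default_rng(21)
        for _ in range(30):
            t = random_table(rng, 35)
            r2, d, r = lp.signed_r(counts_from_table(t))
            assert r * r == pytest.approx(r2, abs=1e-9)
            if d != 0:
                assert np.sign(r) == np.sign(d)

    def test_sign_matches_phased_truth(self):
        """On genotypes collapsed from phased haplotypes, sign(signed r)
        recovers the sign of the phased D of those same haplotypes for
        >= 99% of pairs with |phased r| > 0.1 (phased-truth oracle: the
        simulator knows the haplotypes that built each diploid)."""
        spec = lp.LineSpec("A", "pure", n_sampled=10, ne=100, generations=50)
        pool = lp.simulate_founders(
            lp.SimConfig(
                lines=(spec,),
                seed=31,
                n_snps=80,
                n_founder_haplotypes=400,
                chrom_length_kb=2000.0,
                ancestral_generations=0,
            )
        )
        drifted = lp.drift_line(pool, spec, seed=32)
        rng = np.random.default_rng(34)
        # random union of gametes: enough independent pairings that the
        # non-gametic disequilibrium (invisible to any genotype-based
        # estimator) averages out of the sample
        h1 = drifted.haplotypes[rng.integers(drifted.n_haplotypes, size=2000)].astype(float)
        h2 = drifted.haplotypes[rng.integers(drifted.n_haplotypes, size=2000)].astype(float)
        haps = np.concatenate([h1, h2])  # the sampled phased truth
        codes = (h1 + h2).astype(np.int8)
        freq = haps.mean(axis=0)
        checked = agree = 0
        pairs = rng.choice(haps.shape[1], size=(700, 2))
        for i, j in pairs:
            if i == j or not (0.0 < freq[i] < 1.0 and 0.0 < freq[j] < 1.0):
                continue
            d_true = np.mean(haps[:, i] * haps[:, j]) - freq[i] * freq[j]
            r_true = d_true / np.sqrt(
                freq[i] * (1 - freq[i]) * freq[j] * (1 - freq[j])
            )
            if abs(r_true) <= 0.1:
                continue
            counts = lp.TwoLocusGenotypeCounts.from_codes(codes[:, i], codes[:, j])
            try:
                _, _, r_hat = lp.signed_r(counts, max_iter=20000)
            except UndefinedLDError:
                continue
            checked += 1
            agree += int(np.sign(r_hat) == np.sign(d_true))
        assert checked >= 100
        assert agree / checked >= 0.99


class TestPairTable:
    def test_within_chromosome_and_distance_cap(self):
        mm = make_map(
            ["a", "b", "c", "d"], ["1", "1", "2", "2"], [1000, 6_001_000, 1000, 2_001_000]
        )
        rng = np.random.default_rng(9)
        codes = rng.integers(0, 3, size=(60, 4)).astype(np.int8)
        g = make_genotypes(codes, snp_ids=["a", "b", "c", "d"])
        table = lp.pair_ld_table(g, mm, max_distance_kb=5000)
        got = set(zip(table["snp_a"], table["snp_b"]))
        assert got == {("c", "d")}  # a-b exceeds 5000 kb; cross-chrom excluded

    def test_r2_matches_scalar_api(self, scenario):
        genotypes, marker_map, _ = scenario
        g = genotypes["SL2"]
        table = lp.pair_ld_table(g, marker_map, max_distance_kb=500).head(50)
        snp_index = {s: k for k, s in enumerate(g.snps)}
        for row in table.itertuples():
            counts = lp.TwoLocusGenotypeCounts.from_codes(
                g.codes[:, snp_index[row.snp_a]], g.codes[:, snp_index[row.snp_b]]
            )
            r2, d, r = lp.signed_r(counts, max_iter=20000)
            assert row.r2 == pytest.approx(r2, abs=1e-6)
            assert row.d_composite == pytest.approx(d, abs=1e-9)
            assert row.r_signed == pytest.approx(r, abs=1e-6)
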