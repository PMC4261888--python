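# Methods

## Scope

`ldphase` quantifies linkage disequilibrium (LD) and its transferability
across related populations genotyped on one shared biallelic SNP panel —
the situation of a pig breeding program with several pure lines, an F1
cross of two dam lines and terminal crosses of the F1 with a sire line.
Three questions drive the design: how fast does r² decay with distance in
each population, do populations differ *formally* in that decay, and does
the sign of LD (the phase) persist between populations at the panel's
marker spacing.

## Pairwise LD from unphased genotypes

For two biallelic loci the data are the 3×3 joint genotype table over
samples non-missing at both loci. Genotypes count copies of the panel-wide
ALT allele, so the coding is identical in every population; signed
quantities are only comparable across populations under such a shared
orientation (see *Design choices*).

**Haplotype frequencies.** Only the double heterozygote is
phase-ambiguous. Maximum-likelihood haplotype frequencies p₁₁, p₁₂, p₂₁,
p₂₂ come from EM over that ambiguity: the E-step splits the double-het
count between the cis (2/2 with 1/1) and trans configurations in
proportion to p₂₂p₁₁ : p₁₂p₂₁; the M-step is gene counting. Every EM step
preserves the observed allele frequencies, so the margins of the solution
equal the sample allele frequencies exactly and the ML problem is
effectively one-dimensional — a property the test suite exploits for an
exhaustive-grid oracle.

**r².** The squared correlation of gene frequencies,

    r² = (p₂₂ − p_A p_B)² / (p_A(1−p_A) p_B(1−p_B)),

with p_A, p_B the ALT frequencies at the two loci. Undefined (and the pair
skipped) when either locus is monomorphic among the jointly genotyped
samples.

**Composite D and signed r.** Phase persistence needs a *sign*. The
composite disequilibrium excludes double heterozygotes and rescales the
three informative two-locus classes by τ = 2 − 2·P(het,het):

    f₂₂ = (2 P(22,22) + P(22,12) + P(12,22)) / τ
    f₁₂ = (2 P(11,22) + P(11,12) + P(12,22)) / τ
    f₂₁ = (2 P(22,11) + P(22,12) + P(12,11)) / τ
    D   = f₂₂ − (f₁₂ + f₂₂)(f₂₁ + f₂₂)

(genotype class 22 = hom ALT, 12 = het, 11 = hom REF). Then
signed r = sign(D)·√r². D > 0 means the ALT–ALT haplotype is more common
than allele frequencies predict; because the orientation is shared,
"same sign in two populations" means the same haplotype is over-represented
in both. A D of exactly zero takes the + sign so output is deterministic;
τ = 0 (every sample double-heterozygous) leaves the sign undefined and the
pair is dropped with an error.

Pairs are enumerated within chromosomes only, up to 5000 kb by default
(the largest distance any analysis here uses); pairs at zero distance are
excluded because the decay model requires d > 0.

## LD decay model

Expected r² in line k at distance d (kb) follows the hyperbolic kernel

    E[r²] = 1 / (1 + 4 β_k d),

with iid Gaussian residuals — the drift-recombination equilibrium form in
which β plays the role of effective population size times recombination
rate per kb. Lines enter through dummy variables, so a *partition* of
lines into β-groups defines a family of nested nonlinear least-squares
models: one β per line (complete), one β overall (reduced), or anything
between. Groups share no parameters, so each group is fitted by its own
1-D least squares (Levenberg–Marquardt-style trust-region, β₀ = 10⁻³,
bounds [10⁻⁸, 1], analytic Jacobian); standard errors use the pooled
residual variance SSR/(N − p) and the Jacobian at the optimum, and the
per-coefficient p-value is the asymptotic t-test of β = 0.

**Equality of curves.** Nested fits are compared by

    χ² = N · ln(SSR_reduced / SSR_full),   df = p_full − p_reduced,

referred to the χ² upper tail. The pairwise procedure applies this to each
unordered pair of lines — refitting on the two lines' records only, so the
residual variance of unrelated lines never enters a pair's test — with a
Bonferroni threshold α/number_of_pairs (0.05/28 ≈ 0.0018 for eight lines).
Ordinary (unweighted) least squares is used throughout, as the iid
residual assumption implies; r² records are heteroscedastic in truth, which
the equality test absorbs into its asymptotics.

**Binned summaries.** Mean ± SD (ddof = 1) of r² in half-open distance
bins, with pair counts; empty bins report count 0 and undefined statistics.

## Persistence of phase

For two populations restricted to their common QC-passing markers, pair
tables are inner-joined on the (snp_a, snp_b) key and the Pearson
correlation of signed r is computed inside half-open 50-kb bins from 0 to
5000 kb. A pair at distance d falls in bin ⌊d/width⌋. Bins with fewer than
two pairs or zero variance are reported missing with a reason — never as
zero. Candidate bin widths (10/30/50/70/100 kb) are compared by the
coefficient of variation (sample SD / mean) of per-bin pair counts over
the full 0–5000 kb range, empty bins included: a lower CV means each
correlation rests on a similar number of pairs.

## Marker quality control

Per population: drop unmapped markers and excluded chromosomes (default
{X}); then drop markers with call rate < 0.90, MAF < 0.05, or an exact
two-sided Hardy–Weinberg p-value < 10⁻⁴. Thresholds are strict as printed
(exactly 0.90 or 0.05 is retained). The HWE test enumerates every
heterozygote count compatible with the observed allele counts and sums the
probabilities of configurations no more likely than the observed one (no
mid-p); the χ² approximation misbehaves exactly in the MAF-near-threshold
region that matters here. Removal counts attribute each marker to its
first failing filter in the order call rate → MAF → HWE; the retained set
is identical under any order. Multi-population analyses use only markers
retained in *every* member population, and an empty intersection is an
error, not an empty result.

## Synthetic study design

The simulator stands in for proprietary genotypes and defines the
conditions under which the pipeline is tested.

* **Founders.** Marker positions uniform per chromosome; per-locus allele
  frequencies from Beta(0.5, 0.5) truncated to MAF ≥ 0.05 (a U-shaped
  spectrum thinned the way chip ascertainment thins rare variants);
  haplotype alleles independent Bernoulli draws — founders carry no LD.
* **Ancestral burn-in.** A Wright–Fisher phase (default Ne = 150 for 100
  generations) builds the LD that all lines subsequently share. This step
  is essential to the study design: without it every line's LD would be
  private post-split drift, independent across lines, and persistence of
  phase between any two pure lines would be ≈ 0 at all distances.
* **Line drift.** Each pure line drifts from the burned-in pool at its own
  Ne for 60 generations (a line founded a few decades ago). Gametes
  recombine with a Poisson crossover count at 1 cM/Mb (Haldane, no
  interference). Loci may fix; QC removes them.
* **Crosses.** An F1/terminal individual receives one recombinant gamete
  from a random parent of each parental pool. Genotyping samples diploid
  individuals (haplotype rows 2i, 2i+1) with replacement — haplotypes are
  never re-paired across individuals, because the pairing *is* the
  population structure of a cross — codes ALT dosage, and masks entries
  missing independently (default rate 0.02).
* **Default scenario.** Five pure lines with Ne 125–210 chosen so the
  equilibrium 1/(1 + 4 Ne c) on a 1 cM/Mb map spans decay coefficients of
  roughly 1.2–2.2 × 10⁻³ per kb, an F1 of the two dam lines, and two
  terminal crosses; 400 SNPs on one 8-Mb chromosome; sample sizes 50–260
  per line (a one-fifth scale-down of a realistic genotyping campaign,
  floor 50). One master seed; every operation consumes a counter-derived
  child seed recorded in the manifest.

**What the generator does not emulate:** mutation after founding,
selection, migration, pedigree overlap between generations, sex
chromosomes, a nonuniform recombination map, and genome-scale marker
counts. Passing direction checks on this fixture therefore show that the
*estimators and tests* behave as the population-genetic theory predicts at
desk scale — not that any particular real population matches the default
parameter values.

## Design choices where the design was open

* **Allele orientation.** Signed r is computed against a panel-wide ALT
  orientation shared by all populations (as a common chip or VCF
  provides). A per-population orientation (e.g. each population's minor
  allele) would flip the sign of every pair involving a relabeled locus in
  that population only and corrupt cross-population correlations; the test
  suite asserts exactly this antisymmetry.
* **Composite-D formula grouping.** The τ rescaling divides the full
  three-term numerator of each haplotype-class frequency (f₂₂, f₁₂ and
  f₂₁ alike), by symmetry of the three classes.
* **Statistic orientation.** The SSR ratio is taken reduced-over-full so
  the statistic is nonnegative and the rejection region χ² ≥ χ²_α(ν) is
  meaningful.
* **EM settings.** Tolerance 10⁻⁸ on frequencies, linkage-equilibrium
  initialisation. The likelihood for two biallelic loci is unimodal in
  practice; solutions on the simplex boundary converge geometrically
  slowly, so the bulk pair-table path allows up to 20,000 iterations and
  treats non-convergence as an error, never as a silent estimate.
* **Pairwise-test data scope.** Each pairwise equality test refits on the
  two lines' records only; pooling all eight lines' residuals would change
  the degrees-of-freedom bookkeeping without a principled gain.
* **F1 composite LD.** In a true F1 the gametic and non-gametic
  disequilibria of the admixture cancel, so composite D is ≈ 0 there; the
  admixture sign law D ∝ δp_A·δp_B is tested in the F2, where
  recombination realises the mixture LD in transmitted gametes.

## Problem sizes in the test suite

The statistical acceptance checks run at sizes chosen to make their
Monte-Carlo error small relative to the asserted margins: β recovery uses
200 replicates of 100,000 records; test calibration uses 1000 null
replicates (two lines × 500 records) and 200 replicates under the extreme
published alternative; the study-design direction checks use 20 replicates
of the two Ne-contrasted pure lines and 5 full-scenario replicates for the
crossbred persistence ordering.

## Known limitations

* The composite-D sign is weakly informative for rare alleles, where most
  carriers of the coupling haplotype are double heterozygotes and thus
  excluded by τ — mitigated in practice by the MAF ≥ 0.05 filter.
* Genotype-level LD differs from haplotype-level LD by the realised
  non-gametic disequilibrium of the particular gamete pairing, a
  ~O(n^−1/2) term no unphased estimator can recover; sign agreement with
  phased truth is therefore asserted under random union of gametes.
* The decay model's Gaussian residual is an approximation; r² residuals
  are bounded and heteroscedastic. The equality test remains calibrated
  (checked by simulation) but coefficient standard errors are asymptotic.
* Single-chromosome defaults make physical and genetic distance
  proportional; multi-chromosome configurations are supported but the
  default analyses treat chromosomes jointly only through pooled records.
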