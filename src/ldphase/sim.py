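"""Forward simulation of multi-line and crossbred SNP genotype panels.

The generator emulates a commercial pig breeding design: several pure lines
that diverged from a common ancestral population by drift, an F1 cross of two
dam lines, and terminal crosses of the F1 with a sire line, all genotyped on
one shared biallelic panel.

Model
-----
* Founder haplotypes carry alleles drawn independently per locus with
  frequencies from a U-shaped Beta(0.5, 0.5) spectrum truncated to
  MAF >= 0.05, approximating the ascertainment of a commercial SNP chip.
* An optional ancestral Wright-Fisher burn-in builds up linkage
  disequilibrium that all lines subsequently share; without it every line's
  LD would be private post-split drift and phase would not persist across
  lines at any distance.
* Each pure line then drifts independently at its own effective size for a
  configured number of non-overlapping generations.  Transmitted gametes
  recombine with a crossover count that is Poisson in map length (Haldane,
  no interference) on a uniform 1 cM/Mb map.
* Crosses draw one recombinant gamete from a random parent of each pool.
* Genotyping pairs haplotypes into diploids, codes ALT-allele dosage 0/1/2,
  and masks entries to missing independently at a configured rate.

There is no mutation after founding, no selection and no pedigree overlap
between generations beyond what drift implies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix, MarkerMap
from .errors import ConfigurationError, StructuralError

__all__ = [
    "LineSpec",
    "SimConfig",
    "HaplotypePool",
    "simulate_founders",
    "drift_line",
    "cross_populations",
    "genotype_sample",
    "simulate_scenario",
    "default_scenario",
]

LINE_KINDS = ("pure", "f1", "terminal")


@dataclass(frozen=True)
class LineSpec:
    """One population in the breeding design.

    ``pure`` lines drift from the shared founder pool at effective size
    ``ne`` for ``generations`` generations.  ``f1`` and ``terminal`` lines
    are single-generation crosses of two previously declared lines.
    """

    name: str
    kind: str
    n_sampled: int
    parents: tuple[str, str] | tuple[()] = ()
    ne: int | None = None
    generations: int | None = None
    pool_size: int = 150  # diploid offspring kept for crossbred pools

    def validate(self) -> None:
        if self.kind not in LINE_KINDS:
            raise ConfigurationError(f"line {self.name}: kind must be one of {LINE_KINDS}")
        if self.n_sampled < 1:
            raise ConfigurationError(f"line {self.name}: n_sampled must be >= 1")
        if self.kind == "pure":
            if self.parents:
                raise ConfigurationError(f"line {self.name}: pure lines take no parents")
            if self.ne is None or self.ne < 2:
                raise ConfigurationError(f"line {self.name}: ne must be >= 2 for pure lines")
            if self.generations is None or self.generations < 0:
                raise ConfigurationError(f"line {self.name}: generations must be >= 0")
        else:
            if len(self.parents) != 2:
                raise ConfigurationError(
                    f"line {self.name}: kind {self.kind} requires exactly 2 parents"
                )


@dataclass(frozen=True)
class SimConfig:
    """Full scenario configuration; identical seed implies identical output."""

    lines: tuple[LineSpec, ...]
    seed: int
    n_founder_haplotypes: int = 600
    n_snps: int = 400
    n_chromosomes: int = 1
    chrom_length_kb: float = 8000.0
    missing_rate: float = 0.02
    maf_min_founder: float = 0.05
    cm_per_mb: float = 1.0
    ancestral_ne: int = 150
    ancestral_generations: int = 100

    def validate(self) -> None:
        if self.n_snps < 2:
            raise ConfigurationError("n_snps must be >= 2")
        if self.chrom_length_kb <= 0:
            raise ConfigurationError("chrom_length_kb must be > 0")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ConfigurationError("missing_rate must be in [0, 1]")
        if self.n_founder_haplotypes < 2 or self.n_founder_haplotypes % 2:
            raise ConfigurationError("n_founder_haplotypes must be an even count >= 2")
        if self.n_chromosomes < 1:
            raise ConfigurationError("n_chromosomes must be >= 1")
        if not 0.0 <= self.maf_min_founder < 0.5:
            raise ConfigurationError("maf_min_founder must be in [0, 0.5)")
        if self.ancestral_ne < 2:
            raise ConfigurationError("ancestral_ne must be >= 2")
        if self.ancestral_generations < 0:
            raise ConfigurationError("ancestral_generations must be >= 0")
        seen: set[str] = set()
        for spec in self.lines:
            spec.validate()
            for parent in spec.parents:
                if parent not in seen:
                    raise ConfigurationError(
                        f"line {spec.name}: parent {parent!r} must be declared earlier"
                    )
            if spec.name in seen:
                raise ConfigurationError(f"duplicate line name {spec.name!r}")
            seen.add(spec.name)


@dataclass
class HaplotypePool:
    """An even number of binary haplotypes over a shared marker map.

    Rows 2i and 2i+1 form diploid individual i when a pool acts as a parent
    population in a cross.
    """

    haplotypes: np.ndarray  # (n_haplotypes, n_snps) uint8 in {0, 1}
    map: MarkerMap

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        if self.haplotypes.ndim != 2 or self.haplotypes.shape[0] % 2:
            raise StructuralError("haplotype pool needs an even number of haplotype rows")
        if self.haplotypes.shape[1] != len(self.map):
            raise StructuralError("haplotype pool and marker map disagree on SNP count")
        if self.haplotypes.size and self.haplotypes.max() > 1:
            raise StructuralError("haplotype alleles must be 0/1")

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]


def _child_seed(master: int, counter: int) -> int:
    """Deterministic per-operation seed below 2**31."""
    ss = np.random.SeedSequence(entropy=master, spawn_key=(counter,))
    return int(ss.generate_state(1)[0] % (2**31))


def simulate_founders(config: SimConfig) -> HaplotypePool:
    """Draw founder haplotypes at linkage equilibrium on a fresh marker map.

    Marker positions are uniform on each chromosome (then sorted); per-locus
    allele frequencies come from Beta(0.5, 0.5) truncated to
    MAF >= ``maf_min_founder``; haplotype alleles are independent Bernoulli
    draws, so founders carry no LD (LD is built by the ancestral burn-in and
    line drift).
    """
    config.validate()
    rng = np.random.default_rng(_child_seed(config.seed, 0))

    # markers: split evenly across chromosomes, remainder to the first ones
    per_chrom = np.full(config.n_chromosomes, config.n_snps // config.n_chromosomes)
    per_chrom[: config.n_snps % config.n_chromosomes] += 1
    rows = []
    for c, m in enumerate(per_chrom, start=1):
        pos_kb = np.sort(rng.uniform(0.0, config.chrom_length_kb, size=m))
        rows.append(pd.DataFrame({"chrom": str(c), "pos": np.round(pos_kb * 1000).astype(np.int64)}))
    frame = pd.concat(rows, ignore_index=True)
    frame.insert(0, "snp_id", [f"snp{i + 1:05d}" for i in range(len(frame))])
    marker_map = MarkerMap(frame)

    m = len(frame)
    freqs = rng.beta(0.5, 0.5, size=m)
    low = np.minimum(freqs, 1 - freqs) < config.maf_min_founder
    while low.any():  # rejection sampling from the truncated spectrum
        freqs[low] = rng.beta(0.5, 0.5, size=int(low.sum()))
        low = np.minimum(freqs, 1 - freqs) < config.maf_min_founder
    haps = (rng.random((config.n_founder_haplotypes, m)) < freqs).astype(np.uint8)
    return HaplotypePool(haps, marker_map)


def _chrom_blocks(marker_map: MarkerMap) -> list[tuple[slice, np.ndarray]]:
    """Contiguous column slices per chromosome with their positions in kb."""
    chroms = marker_map.frame["chrom"].to_numpy()
    pos_kb = marker_map.pos_kb
    blocks = []
    start = 0
    for i in range(1, len(chroms) + 1):
        if i == len(chroms) or chroms[i] != chroms[start]:
            blocks.append((slice(start, i), pos_kb[start:i]))
            start = i
    return blocks


def _make_gametes(
    haps: np.ndarray,
    n_gametes: int,
    marker_map: MarkerMap,
    rng: np.random.Generator,
    cm_per_mb: float,
) -> np.ndarray:
    """Recombinant gametes from random diploid parents of `haps`.

    Crossovers per chromosome are Poisson with mean equal to the map length
    in Morgans (Haldane); crossover positions are uniform.  Zero-crossover
    chromosomes (the common case at desk-scale map lengths) are copied
    wholesale, which keeps the loop below short.
    """
    n_parents = haps.shape[0] // 2
    parents = rng.integers(n_parents, size=n_gametes)
    h1 = haps[2 * parents]
    h2 = haps[2 * parents + 1]
    out = np.empty((n_gametes, haps.shape[1]), dtype=np.uint8)
    morgans_per_kb = cm_per_mb / 1000.0 / 100.0
    for cols, pos_kb in _chrom_blocks(marker_map):
        length_m = (pos_kb[-1] - pos_kb[0]) * morgans_per_kb if len(pos_kb) > 1 else 0.0
        start = rng.integers(2, size=n_gametes).astype(np.uint8)
        n_xo = rng.poisson(length_m, size=n_gametes)
        block = np.where(start[:, None] == 0, h1[:, cols], h2[:, cols])
        for g in np.nonzero(n_xo > 0)[0]:
            xo = np.sort(rng.uniform(pos_kb[0], pos_kb[-1], size=n_xo[g]))
            source = (start[g] + np.searchsorted(xo, pos_kb, side="right")) % 2
            block[g] = np.where(source == 0, h1[g, cols], h2[g, cols])
        out[:, cols] = block
    return out


def drift_line(pool: HaplotypePool, spec: LineSpec, seed: int) -> HaplotypePool:
    """Wright-Fisher drift of a pure line from `pool` for `spec.generations`.

    Each generation, 2*ne gametes are produced by random mating with
    recombination.  ``generations == 0`` resamples haplotypes from the input
    pool without drift or recombination.  Loci may fix; downstream QC removes
    monomorphic markers.
    """
    if spec.kind != "pure":
        raise ConfigurationError(f"drift_line requires a pure line, got kind {spec.kind!r}")
    spec.validate()
    rng = np.random.default_rng(seed)
    n_haps = 2 * int(spec.ne)
    if spec.generations == 0:
        idx = rng.integers(pool.n_haplotypes, size=n_haps)
        return HaplotypePool(pool.haplotypes[idx].copy(), pool.map)
    haps = pool.haplotypes
    for _ in range(spec.generations):
        haps = _make_gametes(haps, n_haps, pool.map, rng, cm_per_mb=1.0)
    return HaplotypePool(haps, pool.map)


def cross_populations(
    a: HaplotypePool, b: HaplotypePool, n_offspring: int, seed: int
) -> HaplotypePool:
    """Single-generation cross: each offspring gets one recombinant gamete
    from a random parent in `a` and one from a random parent in `b`."""
    if not a.map.same_as(b.map):
        raise StructuralError("cannot cross pools with different marker maps")
    rng = np.random.default_rng(seed)
    gam_a = _make_gametes(a.haplotypes, n_offspring, a.map, rng, cm_per_mb=1.0)
    gam_b = _make_gametes(b.haplotypes, n_offspring, b.map, rng, cm_per_mb=1.0)
    haps = np.empty((2 * n_offspring, a.haplotypes.shape[1]), dtype=np.uint8)
    haps[0::2] = gam_a
    haps[1::2] = gam_b
    return HaplotypePool(haps, a.map)


def genotype_sample(
    pool: HaplotypePool,
    n_sampled: int,
    missing_rate: float,
    seed: int,
    population: str = "pop",
) -> GenotypeMatrix:
    """Genotype `n_sampled` diploids from the pool.

    Diploid individuals (haplotype rows 2i, 2i+1) are drawn with
    replacement — the pool's pairing carries the population structure of a
    cross, so haplotypes are never re-paired across individuals — coded as
    ALT dosage 0/1/2, and masked to missing independently at
    `missing_rate`.
    """
    if not 0.0 <= missing_rate <= 1.0:
        raise ConfigurationError("missing_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    ind = rng.integers(pool.n_haplotypes // 2, size=n_sampled)
    codes = (
        pool.haplotypes[2 * ind].astype(np.int8)
        + pool.haplotypes[2 * ind + 1].astype(np.int8)
    )
    if missing_rate > 0:
        codes[rng.random(codes.shape) < missing_rate] = MISSING
    samples = [f"{population}_{k + 1:04d}" for k in range(n_sampled)]
    return GenotypeMatrix(population, samples, pool.map.snp_ids.copy(), codes)


def simulate_scenario(
    config: SimConfig,
) -> tuple[dict[str, GenotypeMatrix], MarkerMap, list[dict]]:
    """Run the full breeding design and genotype every declared line.

    Returns the per-line genotype matrices (in declaration order), the shared
    marker map, and a seed log recording the child seed used by each
    operation (one master seed, children derived by a counter).
    """
    config.validate()
    seed_log: list[dict] = [{"operation": "simulate_founders", "seed": _child_seed(config.seed, 0)}]
    founders = simulate_founders(config)
    counter = 1

    def next_seed(op: str) -> int:
        nonlocal counter
        s = _child_seed(config.seed, counter)
        seed_log.append({"operation": op, "seed": s})
        counter += 1
        return s

    base = founders
    if config.ancestral_generations > 0:
        anc = LineSpec(
            "ancestral",
            "pure",
            n_sampled=1,
            ne=config.ancestral_ne,
            generations=config.ancestral_generations,
        )
        base = drift_line(founders, anc, next_seed("drift_line:ancestral"))

    pools: dict[str, HaplotypePool] = {}
    genotypes: dict[str, GenotypeMatrix] = {}
    for spec in config.lines:
        if spec.kind == "pure":
            pools[spec.name] = drift_line(base, spec, next_seed(f"drift_line:{spec.name}"))
        else:
            pa, pb = (pools[p] for p in spec.parents)
            pools[spec.name] = cross_populations(
                pa, pb, max(spec.pool_size, spec.n_sampled), next_seed(f"cross:{spec.name}")
            )
        genotypes[spec.name] = genotype_sample(
            pools[spec.name],
            spec.n_sampled,
            config.missing_rate,
            next_seed(f"genotype:{spec.name}"),
            population=spec.name,
        )
    return genotypes, founders.map, seed_log


def default_scenario(seed: int = 2014) -> SimConfig:
    """The default 8-population study design: five pure lines with distinct
    effective sizes, an F1 of the two dam lines, and two terminal crosses
    (F1 x sire line).

    Effective sizes are chosen so the equilibrium decay 1/(1 + 4*Ne*c) on a
    1 cM/Mb map spans coefficients of roughly 1.2e-3 to 2.2e-3 per kb across
    the pure lines, with the crossbreds decaying faster still; sample sizes
    are a one-fifth scale-down of a realistic genotyping campaign (floor 50).
    """
    lines = (
        LineSpec("SL1", "pure", n_sampled=260, ne=180, generations=60),
        LineSpec("SL2", "pure", n_sampled=128, ne=125, generations=60),
        LineSpec("SL3", "pure", n_sampled=55, ne=170, generations=60),
        LineSpec("DL1", "pure", n_sampled=125, ne=210, generations=60),
        LineSpec("DL2", "pure", n_sampled=202, ne=170, generations=60),
        LineSpec("DLF1", "f1", n_sampled=50, parents=("DL1", "DL2")),
        LineSpec("TER1", "terminal", n_sampled=57, parents=("DLF1", "SL1")),
        LineSpec("TER2", "terminal", n_sampled=66, parents=("DLF1", "SL2")),
    )
    return SimConfig(lines=lines, seed=seed)


def scenario_from_dict(raw: dict) -> SimConfig:
    """Build a SimConfig from a plain dict (parsed YAML/JSON)."""
    lines = tuple(
        LineSpec(
            name=item["name"],
            kind=item["kind"],
            n_sampled=int(item["n_sampled"]),
            parents=tuple(item.get("parents", ())),
            ne=item.get("ne"),
            generations=item.get("generations"),
            pool_size=int(item.get("pool_size", 150)),
        )
        for item in raw["lines"]
    )
    kwargs = {k: v for k, v in raw.items() if k != "lines"}
    return SimConfig(lines=lines, **kwargs)
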