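"""Forward-in-time mutation-drift simulation of a livestock population.

The base population is simulated as a constant-size diploid Wright-Fisher
population with discrete generations: all founders are homozygous for the
same allele at every SNP, and variation builds up over hundreds of
generations of random mating through symmetric per-gamete flip mutation
(each transmitted allele copy mutates to the other allele with the per-locus
rate) and recombination on a multi-chromosome Morgan map (crossovers per
chromosome Poisson with mean equal to the map length, positions uniform, no
interference).  With an effective size of 100 and a mutation rate of
2.5e-3/locus/generation the scaled mutation rate is 4*Ne*u = 1, whose
stationary allele-frequency distribution is uniform, giving the mean SNP
heterozygosity of 1/3 observed at mutation-drift balance.

Training and test sets are bred from the base population as paternal
half-sib families: each family has one sire and one distinct dam per
offspring, two phenotyped training generations and two unphenotyped test
generations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "GenomeMap",
    "Population",
    "MarkerStats",
    "simulate_base_population",
    "meiosis",
    "breed_structured_generations",
    "compute_marker_stats",
    "oriented_genotypes",
    "adjacent_ld",
    "thin_markers",
]


@dataclass
class GenomeMap:
    """Marker positions on a multi-chromosome genetic map (Morgan units).

    ``positions`` are global coordinates (chromosome index times chromosome
    length plus the within-chromosome position), strictly increasing.
    """

    n_chromosomes: int
    chromosome_length: float
    positions: np.ndarray
    chromosome: np.ndarray

    def __post_init__(self):
        if self.n_markers == 0:
            raise ValueError("a genome map needs at least one marker")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("marker positions must be strictly increasing")

    @property
    def n_markers(self) -> int:
        return len(self.positions)

    @property
    def total_length(self) -> float:
        return self.n_chromosomes * self.chromosome_length

    @classmethod
    def uniform_random(cls, n_markers: int, rng, n_chromosomes: int = 30,
                       chromosome_length: float = 1.0) -> "GenomeMap":
        """Markers placed uniformly at random over the genome, then sorted."""
        total = n_chromosomes * chromosome_length
        pos = np.sort(rng.uniform(0.0, total, n_markers))
        # ties have probability ~0; nudge if they occur so the map is strict
        while np.any(np.diff(pos) <= 0):
            pos = np.sort(pos + rng.uniform(0, 1e-12, n_markers))
        chrom = np.minimum((pos / chromosome_length).astype(np.int64),
                           n_chromosomes - 1)
        return cls(n_chromosomes, chromosome_length, pos, chrom)

    def subset(self, idx: np.ndarray) -> "GenomeMap":
        return GenomeMap(self.n_chromosomes, self.chromosome_length,
                         self.positions[idx], self.chromosome[idx])


@dataclass
class Population:
    """Phased diploid individuals with pedigree and generation labels.

    ``haplotypes`` has shape (2 * n_individuals, n_markers); rows 2i and
    2i+1 are individual i's paternal and maternal haplotypes.  ``sire`` and
    ``dam`` are row indices into the same population (-1 for founders).
    """

    haplotypes: np.ndarray
    sire: np.ndarray
    dam: np.ndarray
    generation: np.ndarray
    sex: np.ndarray  # 0 = male, 1 = female
    phenotyped: np.ndarray
    genome: GenomeMap

    @property
    def n_individuals(self) -> int:
        return self.haplotypes.shape[0] // 2

    @property
    def genotypes(self) -> np.ndarray:
        """Allele-1 dosage matrix (individual x marker), values 0/1/2."""
        return (self.haplotypes[0::2].astype(np.int16)
                + self.haplotypes[1::2].astype(np.int16))

    def individuals_in(self, generations) -> np.ndarray:
        return np.where(np.isin(self.generation, np.atleast_1d(generations)))[0]

    def validate_pedigree(self) -> None:
        """Assert acyclicity / generation monotonicity of the pedigree."""
        for name, parent in (("sire", self.sire), ("dam", self.dam)):
            has = parent >= 0
            if np.any(self.generation[parent[has]] >= self.generation[has]):
                raise ValueError(f"{name} not from an earlier generation")


@dataclass
class MarkerStats:
    """Per-marker allele/genotype frequencies in a set of individuals.

    Genotype classes are oriented so class 22 is the homozygote of the more
    frequent allele; ``frequent_allele`` records which raw allele (0 or 1)
    that is, so the orientation can be frozen and reused for other
    individuals.  ``het`` is the observed heterozygote frequency p12.
    """

    p: np.ndarray            # frequency of raw allele 1
    p11: np.ndarray
    p12: np.ndarray
    p22: np.ndarray
    maf: np.ndarray
    het: np.ndarray
    retained: np.ndarray
    frequent_allele: np.ndarray
    maf_threshold: float


@njit(cache=True)
def _assemble_gametes(hap, parent, pos, chrom_ix, cx_flat, cx_off, phases, out):
    n_gam, m = out.shape
    for g in range(n_gam):
        h0 = hap[2 * parent[g]]
        h1 = hap[2 * parent[g] + 1]
        s = cx_off[g]
        e = cx_off[g + 1]
        ptr = s
        for j in range(m):
            while ptr < e and cx_flat[ptr] <= pos[j]:
                ptr += 1
            if (phases[g, chrom_ix[j]] + (ptr - s)) & 1 == 0:
                out[g, j] = h0[j]
            else:
                out[g, j] = h1[j]


def _gametes(hap, parents, genome: GenomeMap, rng) -> np.ndarray:
    """Form one recombinant gamete per entry of ``parents`` (vectorized)."""
    n_gam = len(parents)
    m = genome.n_markers
    ncx = rng.poisson(genome.total_length, n_gam)
    cx_off = np.zeros(n_gam + 1, dtype=np.int64)
    np.cumsum(ncx, out=cx_off[1:])
    cx_flat = rng.uniform(0.0, genome.total_length, cx_off[-1])
    # sort crossover positions within each gamete's segment
    order = np.lexsort((cx_flat, np.repeat(np.arange(n_gam), ncx)))
    cx_flat = cx_flat[order]
    phases = rng.integers(0, 2, size=(n_gam, genome.n_chromosomes)).astype(np.int64)
    out = np.empty((n_gam, m), dtype=np.uint8)
    _assemble_gametes(hap, parents.astype(np.int64), genome.positions,
                      genome.chromosome, cx_flat, cx_off, phases, out)
    return out


def _mutate(gametes: np.ndarray, mutation_rate: float, rng) -> None:
    """Symmetric allele flips, applied in place per transmitted gamete."""
    if mutation_rate <= 0:
        return
    n_gam, m = gametes.shape
    n_mut = rng.binomial(n_gam * m, mutation_rate)
    rows = rng.integers(0, n_gam, n_mut)
    cols = rng.integers(0, m, n_mut)
    gametes[rows, cols] ^= 1


def meiosis(parent_haplotypes: np.ndarray, genome: GenomeMap, rng) -> np.ndarray:
    """One gamete from a pair of phased parental haplotypes.

    Crossover counts per chromosome are Poisson with mean equal to the
    chromosome length in Morgan (no interference); the gamete is the
    resulting mosaic.  Mutation is applied separately.
    """
    hap = np.ascontiguousarray(parent_haplotypes, dtype=np.uint8)
    if hap.shape != (2, genome.n_markers):
        raise ValueError("expected two phased haplotypes matching the map")
    return _gametes(hap, np.zeros(1, dtype=np.int64), genome, rng)[0]


def simulate_base_population(genome: GenomeMap, effective_size: int,
                             mutation_rate: float, n_generations: int,
                             rng) -> Population:
    """Mutation-drift simulation from homozygous founders.

    Each generation, every one of ``effective_size`` offspring draws a sire
    and a distinct dam uniformly from the previous generation (discrete
    generations, constant size, sexes assigned half and half).  Returns the
    final generation only, labelled ``n_generations``.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    N = int(effective_size)
    if N < 2:
        raise ValueError("effective size must be at least 2")
    if not 0.0 < mutation_rate < 1.0:
        raise ValueError("mutation rate must be in (0, 1)")
    if n_generations < 1:
        raise ValueError("need at least one generation")

    m = genome.n_markers
    sex = np.arange(N, dtype=np.int8) % 2  # deterministic half/half
    hap = np.zeros((2 * N, m), dtype=np.uint8)
    for _ in range(n_generations):
        males = np.where(sex == 0)[0]
        females = np.where(sex == 1)[0]
        sires = rng.choice(males, size=N)
        dams = rng.choice(females, size=N)
        parents = np.empty(2 * N, dtype=np.int64)
        parents[0::2] = sires
        parents[1::2] = dams
        new = _gametes(hap, parents, genome, rng)
        _mutate(new, mutation_rate, rng)
        hap = new
        sex = rng.permutation(sex)

    gen = np.full(N, n_generations, dtype=np.int64)
    none = np.full(N, -1, dtype=np.int64)
    return Population(hap, none.copy(), none.copy(), gen, sex.copy(),
                      np.zeros(N, dtype=bool), genome)


def breed_structured_generations(base: Population, n_families: int,
                                 n_offspring_per_family: int,
                                 n_train_generations: int,
                                 n_test_generations: int, rng,
                                 mutation_rate: float = 0.0) -> Population:
    """Append half-sib training and test generations to a base population.

    Each generation consists of ``n_families`` paternal half-sib families
    with ``n_offspring_per_family`` offspring: one sire per family (sires
    drawn without replacement from the previous generation's males) and a
    distinct dam per offspring within a family (dams drawn without
    replacement per family from the females, reusable across families).
    Training-generation individuals are flagged phenotyped.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    genome = base.genome
    hap_blocks = [base.haplotypes]
    sire_all = [base.sire]
    dam_all = [base.dam]
    gen_all = [base.generation]
    sex_all = [base.sex]
    phen_all = [base.phenotyped]

    prev_ids = np.arange(base.n_individuals)
    prev_sex = base.sex
    next_id = base.n_individuals
    gen0 = int(base.generation.max())
    n_new = n_train_generations + n_test_generations
    per_gen = n_families * n_offspring_per_family

    hap_prev = base.haplotypes
    for g in range(1, n_new + 1):
        males = prev_ids[prev_sex == 0]
        females = prev_ids[prev_sex == 1]
        if len(males) < n_families:
            raise ValueError(
                f"need {n_families} sires but only {len(males)} males available"
            )
        if len(females) < n_offspring_per_family:
            raise ValueError(
                f"need {n_offspring_per_family} distinct dams per family but "
                f"only {len(females)} females available"
            )
        sires = rng.choice(males, size=n_families, replace=False)
        sire_vec = np.repeat(sires, n_offspring_per_family)
        dam_vec = np.concatenate([
            rng.choice(females, size=n_offspring_per_family, replace=False)
            for _ in range(n_families)
        ])
        # local row indices within the previous generation block
        local = {int(i): r for r, i in enumerate(prev_ids)}
        sire_loc = np.array([local[int(i)] for i in sire_vec], dtype=np.int64)
        dam_loc = np.array([local[int(i)] for i in dam_vec], dtype=np.int64)

        pat = _gametes(hap_prev, sire_loc, genome, rng)
        mat = _gametes(hap_prev, dam_loc, genome, rng)
        _mutate(pat, mutation_rate, rng)
        _mutate(mat, mutation_rate, rng)
        hap_new = np.empty((2 * per_gen, genome.n_markers), dtype=np.uint8)
        hap_new[0::2] = pat
        hap_new[1::2] = mat

        hap_blocks.append(hap_new)
        sire_all.append(sire_vec)
        dam_all.append(dam_vec)
        gen_all.append(np.full(per_gen, gen0 + g, dtype=np.int64))
        sex_all.append(np.arange(per_gen, dtype=np.int8) % 2)
        phen_all.append(np.full(per_gen, g <= n_train_generations))

        prev_ids = np.arange(next_id, next_id + per_gen)
        prev_sex = sex_all[-1]
        next_id += per_gen
        hap_prev = hap_new

    pop = Population(
        np.concatenate(hap_blocks, axis=0),
        np.concatenate(sire_all), np.concatenate(dam_all),
        np.concatenate(gen_all), np.concatenate(sex_all),
        np.concatenate(phen_all), genome,
    )
    pop.validate_pedigree()
    return pop


def compute_marker_stats(genotypes: np.ndarray, subset=None,
                         maf_threshold: float = 0.01) -> MarkerStats:
    """Allele and genotype-class frequencies, counted in a subset.

    ``genotypes`` is an allele-1 dosage matrix; ``subset`` selects the
    individuals used for counting (default: all).  Classes are oriented to
    the more frequent allele (ties go to allele 1) and markers with
    MAF > ``maf_threshold`` are flagged retained.
    """
    g = np.asarray(genotypes)
    if subset is not None:
        g = g[subset]
    if g.shape[0] == 0:
        raise ValueError("empty individual subset")
    n = g.shape[0]
    p = g.mean(axis=0) / 2.0
    frequent = (p >= 0.5).astype(np.int8)
    maf = np.minimum(p, 1.0 - p)
    n0 = (g == 0).sum(axis=0) / n
    n1 = (g == 1).sum(axis=0) / n
    n2 = (g == 2).sum(axis=0) / n
    p22 = np.where(frequent == 1, n2, n0)
    p11 = np.where(frequent == 1, n0, n2)
    return MarkerStats(p=p, p11=p11, p12=n1, p22=p22, maf=maf, het=n1,
                       retained=maf > maf_threshold, frequent_allele=frequent,
                       maf_threshold=maf_threshold)


def oriented_genotypes(genotypes: np.ndarray, stats: MarkerStats) -> np.ndarray:
    """Frequent-allele counts (0/1/2) under a frozen orientation."""
    g = np.asarray(genotypes)
    return np.where(stats.frequent_allele == 1, g, 2 - g)


def adjacent_ld(genotypes: np.ndarray, retained: np.ndarray,
                genome: GenomeMap) -> float:
    """Mean r^2 between adjacent retained markers, within chromosomes.

    r^2 is the squared Pearson correlation of genotype dosages; pairs
    spanning a chromosome boundary are excluded.
    """
    idx = np.where(retained)[0]
    if len(idx) < 2:
        raise ValueError("need at least two retained markers")
    g = np.asarray(genotypes, dtype=np.float64)[:, idx]
    ch = genome.chromosome[idx]
    g = g - g.mean(axis=0)
    sd = g.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (g[:, :-1] * g[:, 1:]).mean(axis=0) / (sd[:-1] * sd[1:])
    ok = (ch[:-1] == ch[1:]) & np.isfinite(r)
    if not ok.any():
        raise ValueError("no adjacent retained pair shares a chromosome")
    return float(np.mean(r[ok] ** 2))


def thin_markers(n_markers: int, step: int, forced_indices=None) -> np.ndarray:
    """Every ``step``-th marker (step-1, 2*step-1, ...), plus forced indices.

    Keeps floor(n_markers / step) markers; ``step=1`` is the identity.
    """
    if step < 1:
        raise ValueError("thinning step must be >= 1")
    keep = np.arange(step - 1, n_markers, step, dtype=np.int64)
    if forced_indices is not None:
        forced = np.asarray(forced_indices, dtype=np.int64)
        if forced.size and (forced.min() < 0 or forced.max() >= n_markers):
            raise ValueError("forced marker index outside the panel")
        keep = np.union1d(keep, forced)
    return keep
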