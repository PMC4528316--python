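"""Forward-in-time simulator of an intermated biparental pool-seq design.

The generator emulates the study design the scan is built for: two fully
homozygous founder lines are crossed, the F2 is intermated for ``t``
generations of random mating (default 14), a polygenic trait with planted
QTL is assigned, the ``n_selected`` most extreme individuals per
phenotypic tail (default 46) plus a random control pool (default 92) are
pooled, and each pool is sequenced with Poisson read depth (default mean
40) and binomial allele sampling with symmetric sequencing error.

Meiosis follows the Haldane model: crossover counts are Poisson with mean
equal to the chromosome's genetic length in Morgans, crossover positions
uniform on the genetic map, no interference.  Genotypes are tracked as
parental-origin haplotypes per SNP (1 = reference-parent allele), so pool
allele frequencies are exact.

A single seed drives everything; each stochastic stage derives a child
generator deterministically from it (``numpy`` ``SeedSequence`` spawning),
so runs are exactly reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, ValidationError
from .io import PoolCountTable

logger = logging.getLogger(__name__)

__all__ = [
    "GenomeMap",
    "QtlSpec",
    "SimConfig",
    "SimTruth",
    "Pools",
    "Population",
    "simulate_population",
    "assign_phenotypes",
    "select_pools",
    "pool_and_sequence",
    "simulate_experiment",
    "simulate_null_counts",
    "draw_crossover_positions",
]


class GenomeMap:
    """Chromosome lengths plus SNP physical and genetic positions.

    Genetic positions (cM) are obtained from physical positions by a
    constant cM/Mb rate per chromosome unless given explicitly; they must
    be non-decreasing in bp.
    """

    def __init__(
        self,
        lengths_bp: dict[str, int],
        snp_pos: dict[str, np.ndarray],
        cm_per_mb: float = 0.5,
        cm_pos: dict[str, np.ndarray] | None = None,
    ):
        self.lengths_bp = {str(c): int(l) for c, l in lengths_bp.items()}
        self.chroms = list(self.lengths_bp)
        self.snp_pos = {
            str(c): np.asarray(p, dtype=np.int64) for c, p in snp_pos.items()
        }
        if set(self.snp_pos) != set(self.chroms):
            raise ConfigError("snp_pos chromosomes do not match lengths_bp")
        if cm_pos is None:
            cm_pos = {
                c: self.snp_pos[c] / 1e6 * cm_per_mb for c in self.chroms
            }
        self.cm_pos = {c: np.asarray(v, dtype=float) for c, v in cm_pos.items()}
        self.cm_per_mb = cm_per_mb
        for c in self.chroms:
            p = self.snp_pos[c]
            if p.size and ((p < 1).any() or (np.diff(p) <= 0).any()):
                raise ValidationError(f"SNP positions on {c} not strictly increasing")
            if (np.diff(self.cm_pos[c]) < 0).any():
                raise ValidationError(f"genetic positions on {c} decrease")

    @property
    def n_snps(self) -> int:
        return sum(p.size for p in self.snp_pos.values())

    @property
    def total_bp(self) -> int:
        return sum(self.lengths_bp.values())

    def genetic_length_cm(self, chrom: str) -> float:
        return self.lengths_bp[chrom] / 1e6 * self.cm_per_mb

    @classmethod
    def uniform_random(
        cls,
        n_chrom: int,
        length_bp: int,
        n_snps: int,
        cm_per_mb: float = 0.5,
        rng: np.random.Generator | None = None,
    ) -> "GenomeMap":
        """Random SNP placement: ``n_snps`` total, split evenly, uniform bp."""
        rng = rng or np.random.default_rng()
        per = [n_snps // n_chrom] * n_chrom
        for i in range(n_snps % n_chrom):
            per[i] += 1
        lengths = {f"chr{i + 1}": length_bp for i in range(n_chrom)}
        snp_pos = {}
        for i, c in enumerate(lengths):
            # rejection sampling of distinct positions (collisions are rare
            # for realistic SNP densities, so one round normally suffices)
            want = per[i]
            pos = np.unique(rng.integers(1, length_bp + 1, size=want + want // 20 + 16))
            while pos.size < want:
                extra = rng.integers(1, length_bp + 1, size=want)
                pos = np.unique(np.concatenate([pos, extra]))
            if pos.size > want:
                pos = np.sort(rng.choice(pos, size=want, replace=False))
            snp_pos[c] = pos
        return cls(lengths, snp_pos, cm_per_mb=cm_per_mb)


@dataclass(frozen=True)
class QtlSpec:
    """A planted QTL: additive effect ``a`` per reference-parent allele and
    dominance degree ``k`` (0 = additive, 1 = full dominance)."""

    chrom: str
    pos: int
    a: float
    k: float = 0.0


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of the simulated experiment."""

    pop_size: int = 10_000
    intermating_generations: int = 14
    n_selected: int = 46
    n_control: int = 92
    h2: float = 0.7
    mean_depth: float = 40.0
    seq_error: float = 0.001
    seed: int = 0

    def __post_init__(self):
        if 2 * self.n_selected > self.pop_size:
            raise ConfigError("2 * n_selected must not exceed pop_size")
        if not (0 < self.h2 <= 1):
            raise ConfigError(f"heritability must be in (0, 1], got {self.h2}")
        if self.mean_depth <= 0:
            raise ConfigError("mean_depth must be positive")
        if not (0 <= self.seq_error < 0.5):
            raise ConfigError("seq_error must be in [0, 0.5)")


@dataclass
class Pools:
    """Index sets of the selected tails and the random control pool."""

    high: np.ndarray
    low: np.ndarray
    control: np.ndarray

    def as_dict(self) -> dict[str, np.ndarray]:
        return {"high": self.high, "low": self.low, "control": self.control}


@dataclass
class SimTruth:
    """Ground truth of a simulated experiment.

    ``true_freqs``: DataFrame chrom, pos, ``{pool}_freq`` with the exact
    reference-allele frequency of each pool (no sequencing noise).
    ``selection_differentials``: mean(pool) - mean(all), in phenotypic SD.
    """

    qtls: list[QtlSpec]
    true_freqs: pd.DataFrame
    selection_differentials: dict[str, float] = field(default_factory=dict)


class Population:
    """N diploid individuals as parental-origin haplotypes per chromosome.

    ``haps[chrom]`` has shape (N, 2, S) with value 1 for the reference
    (B73-like) parental allele and 0 for the alternate parent.
    """

    def __init__(self, haps: dict[str, np.ndarray], genome: GenomeMap):
        self.haps = haps
        self.genome = genome
        sizes = {h.shape[0] for h in haps.values()}
        if len(sizes) != 1:
            raise ValidationError("inconsistent population size across chromosomes")
        self.size = sizes.pop()

    def genotypes(self, chrom: str) -> np.ndarray:
        """Reference-allele copy number (0/1/2) per individual per SNP."""
        return self.haps[chrom].sum(axis=1)


def draw_crossover_positions(
    rng: np.random.Generator, genetic_length_cm: float
) -> np.ndarray:
    """Haldane crossover positions (cM) for one meiosis: Poisson count with
    mean = length in Morgans, positions uniform, sorted."""
    k = rng.poisson(genetic_length_cm / 100.0)
    if k == 0:
        return np.empty(0)
    return np.sort(rng.uniform(0.0, genetic_length_cm, k))


def _gamete(
    hap_pair: np.ndarray,
    cm_pos: np.ndarray,
    length_cm: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One recombinant gamete from a (2, S) haplotype pair."""
    start = rng.integers(2)
    xo = draw_crossover_positions(rng, length_cm)
    if xo.size == 0:
        return hap_pair[start]
    which = (start + np.searchsorted(xo, cm_pos, side="right")) % 2
    return np.where(which == 0, hap_pair[0], hap_pair[1])


def _next_generation(
    haps: dict[str, np.ndarray],
    genome: GenomeMap,
    n_offspring: int,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Random mating with two distinct parents per offspring."""
    n_parents = next(iter(haps.values())).shape[0]
    mothers = rng.integers(n_parents, size=n_offspring)
    fathers = (mothers + 1 + rng.integers(n_parents - 1, size=n_offspring)) % n_parents
    out: dict[str, np.ndarray] = {}
    for chrom in genome.chroms:
        cm = genome.cm_pos[chrom]
        length = genome.genetic_length_cm(chrom)
        parent_haps = haps[chrom]
        child = np.empty((n_offspring, 2, cm.size), dtype=np.uint8)
        for i in range(n_offspring):
            child[i, 0] = _gamete(parent_haps[mothers[i]], cm, length, rng)
            child[i, 1] = _gamete(parent_haps[fathers[i]], cm, length, rng)
        out[chrom] = child
    return out


def simulate_population(
    genome: GenomeMap,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> Population:
    """Founders -> F1 -> F2 -> ``t`` generations of random intermating.

    The two founders are fully homozygous (all-reference and all-alternate
    haplotypes), so every F1 is identical and heterozygous everywhere; the
    F2 is produced by random F1 x F1 matings, and each subsequent
    generation by random mating with distinct parents.
    """
    if genome.n_snps == 0:
        raise ValidationError("genome map has no SNPs")
    rng = rng or np.random.default_rng(config.seed)
    # F1: one reference haplotype, one alternate haplotype per chromosome
    f1 = {
        c: np.stack(
            [np.ones((1, genome.snp_pos[c].size), dtype=np.uint8),
             np.zeros((1, genome.snp_pos[c].size), dtype=np.uint8)],
            axis=1,
        )
        for c in genome.chroms
    }
    # F2 from F1 x F1 (all F1 genetically identical)
    haps = _next_generation(
        {c: np.repeat(f1[c], 2, axis=0) for c in genome.chroms},
        genome, config.pop_size, rng,
    )
    for _ in range(config.intermating_generations):
        haps = _next_generation(haps, genome, config.pop_size, rng)
    return Population(haps, genome)


def _snap_to_snp(genome: GenomeMap, chrom: str, pos: int) -> int:
    """Index of the map SNP nearest to ``pos`` on ``chrom``."""
    snps = genome.snp_pos[str(chrom)]
    i = int(np.searchsorted(snps, pos))
    if i == 0:
        return 0
    if i >= snps.size:
        return snps.size - 1
    return i if snps[i] - pos < pos - snps[i - 1] else i - 1


def assign_phenotypes(
    population: Population,
    qtls: list[QtlSpec],
    h2: float,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Polygenic phenotypes: genetic values from the planted QTL plus
    normal environmental noise scaled to the target heritability.

    The genetic value of individual i is sum over QTL of
    a * (c - 1) + a * k * [c == 1], with c the reference-allele copy
    number at the SNP nearest the QTL position.  Noise variance is set so
    Var(g) / (Var(g) + Var(e)) = h2; with zero genetic variance and
    h2 < 1 a unit noise variance is used (warning logged).
    """
    rng = rng or np.random.default_rng()
    g = np.zeros(population.size)
    for q in qtls:
        if str(q.chrom) not in population.genome.chroms:
            raise ConfigError(f"QTL chromosome {q.chrom!r} not on the map")
        idx = _snap_to_snp(population.genome, q.chrom, q.pos)
        c = population.genotypes(str(q.chrom))[:, idx].astype(float)
        g += q.a * (c - 1.0) + q.a * q.k * (c == 1.0)
    var_g = float(np.var(g))
    if h2 >= 1.0:
        var_e = 0.0
    elif var_g == 0.0:
        logger.warning("zero genetic variance; using unit environmental variance")
        var_e = 1.0
    else:
        var_e = var_g * (1.0 - h2) / h2
    return g + rng.normal(0.0, np.sqrt(var_e), population.size)


def select_pools(
    phenotypes: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> Pools:
    """Truncation selection of the phenotypic extremes plus a random control.

    ``high`` holds the ``n_selected`` largest phenotypes, ``low`` the
    smallest; ties at the cutoffs break by individual index.  The control
    pool is a uniform draw without replacement from all individuals and
    may overlap the tails.
    """
    phenotypes = np.asarray(phenotypes, dtype=float)
    if not np.isfinite(phenotypes).all():
        raise ValidationError("phenotypes must be finite")
    n = phenotypes.size
    if 2 * config.n_selected > n:
        raise ConfigError("n_selected exceeds half the population")
    rng = rng or np.random.default_rng()
    asc = np.argsort(phenotypes, kind="stable")
    low = np.sort(asc[: config.n_selected])
    desc = np.argsort(-phenotypes, kind="stable")
    high = np.sort(desc[: config.n_selected])
    control = np.sort(rng.choice(n, size=config.n_control, replace=False))
    return Pools(high=high, low=low, control=control)


def _pool_freqs(population: Population, idx: np.ndarray) -> dict[str, np.ndarray]:
    return {
        c: population.haps[c][idx].sum(axis=(0, 1)) / (2.0 * idx.size)
        for c in population.genome.chroms
    }


def pool_and_sequence(
    population: Population,
    pools: Pools,
    genome: GenomeMap,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    qtls: list[QtlSpec] | None = None,
) -> tuple[PoolCountTable, SimTruth]:
    """Pooled sequencing: Poisson depth, binomial allele sampling.

    Per SNP and pool, the true reference-allele frequency f is the exact
    allele count in the pool over 2 x pool size; read depth is
    Poisson(mean_depth) and the reference read count is binomial with
    success probability f(1 - e) + (1 - f)e (symmetric sequencing error).
    """
    rng = rng or np.random.default_rng()
    pool_idx = pools.as_dict()
    for name, idx in pool_idx.items():
        if idx.size == 0:
            raise ConfigError(f"pool {name!r} is empty")
    e = config.seq_error
    frames = []
    truth_frames = []
    for chrom in genome.chroms:
        s = genome.snp_pos[chrom].size
        block = pd.DataFrame(
            {"chrom": chrom, "pos": genome.snp_pos[chrom]}
        )
        truth_block = block[["chrom", "pos"]].copy()
        for name, idx in pool_idx.items():
            f = population.haps[chrom][idx].sum(axis=(0, 1)) / (2.0 * idx.size)
            depth = rng.poisson(config.mean_depth, size=s)
            p_obs = f * (1.0 - e) + (1.0 - f) * e
            ref = rng.binomial(depth, p_obs)
            block[f"{name}_ref"] = ref
            block[f"{name}_tot"] = depth
            truth_block[f"{name}_freq"] = f
        frames.append(block)
        truth_frames.append(truth_block)
    counts = PoolCountTable(pd.concat(frames, ignore_index=True))
    truth = SimTruth(
        qtls=list(qtls or []),
        true_freqs=pd.concat(truth_frames, ignore_index=True),
    )
    return counts, truth


def simulate_experiment(
    genome: GenomeMap,
    qtls: list[QtlSpec],
    config: SimConfig,
) -> dict:
    """End-to-end generation of one pool-seq experiment.

    Returns a dict with ``counts`` (PoolCountTable with pools high / low /
    control), ``truth`` (SimTruth incl. selection differentials),
    ``phenotypes``, ``pools`` and ``population``.  Every stage uses a
    child generator spawned from ``config.seed``.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_pop, rng_phen, rng_sel, rng_seq = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    population = simulate_population(genome, config, rng_pop)
    phenotypes = assign_phenotypes(population, qtls, config.h2, rng_phen)
    pools = select_pools(phenotypes, config, rng_sel)
    counts, truth = pool_and_sequence(
        population, pools, genome, config, rng_seq, qtls=qtls
    )
    sd = float(np.std(phenotypes))
    mean = float(np.mean(phenotypes))
    if sd > 0:
        truth.selection_differentials = {
            name: (float(np.mean(phenotypes[idx])) - mean) / sd
            for name, idx in pools.as_dict().items()
        }
    return {
        "counts": counts,
        "truth": truth,
        "phenotypes": phenotypes,
        "pools": pools,
        "population": population,
    }


def simulate_null_counts(
    genome: GenomeMap,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[PoolCountTable, SimTruth]:
    """Null pool-seq counts: both contrast pools share the same underlying
    frequencies.

    A population is simulated without any QTL, one random pool of
    ``n_selected`` individuals defines the per-SNP frequency f, and reads
    for the high and bottom pools (and the control) are all drawn from
    that same f.  Any difference between the two pools is then pure
    read-sampling noise, so per-SNP z should be standard normal.
    """
    rng = rng or np.random.default_rng(config.seed)
    population = simulate_population(genome, config, rng)
    idx = np.sort(rng.choice(population.size, config.n_selected, replace=False))
    e = config.seq_error
    frames = []
    truth_frames = []
    for chrom in genome.chroms:
        s = genome.snp_pos[chrom].size
        f = population.haps[chrom][idx].sum(axis=(0, 1)) / (2.0 * idx.size)
        block = pd.DataFrame({"chrom": chrom, "pos": genome.snp_pos[chrom]})
        truth_block = block.copy()
        p_obs = f * (1.0 - e) + (1.0 - f) * e
        for name in ("high", "low", "control"):
            depth = rng.poisson(config.mean_depth, size=s)
            block[f"{name}_ref"] = rng.binomial(depth, p_obs)
            block[f"{name}_tot"] = depth
            truth_block[f"{name}_freq"] = f
        frames.append(block)
        truth_frames.append(truth_block)
    counts = PoolCountTable(pd.concat(frames, ignore_index=True))
    truth = SimTruth(qtls=[], true_freqs=pd.concat(truth_frames, ignore_index=True))
    return counts, truth
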