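"""Forward Wright-Fisher simulation of polygenic stabilizing selection.

Each of several independent diploid populations carries individuals
represented by a vector of biallelic markers: the first block contributes
additively and codominantly to a quantitative trait, the rest are neutral.
With ``m`` the number of trait-increasing ("beneficial") alleles an
individual carries across the selected loci, viability is the Gaussian
stabilizing-selection kernel

    w(m) = exp(-(m - mu)^2 * x^2 / (2 s)),

maximal at ``m = mu`` and symmetric around it.  Generations are discrete:
each offspring picks two parents with probability proportional to w, and
each parent transmits one recombinant gamete (the copied source haplotype
switches between adjacent loci with probability ``recomb_rate``).  There is
no mutation and no migration, so fixed loci stay fixed.

The interesting regime has ``mu`` below the number of selected alleles
needed to saturate the trait: many distinct allele subsets maximize
fitness, and each population stochastically commits to one of them, which
inflates among-population differentiation at the selected loci relative to
the neutral ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .fst import SNPPanel, panel_fst

__all__ = [
    "SimParams",
    "Population",
    "SimResult",
    "DegenerateFitnessError",
    "fitness",
    "init_population",
    "next_generation",
    "run_simulation",
    "sim_fst_summary",
    "population_to_panel",
]


class DegenerateFitnessError(RuntimeError):
    """Every parental fitness underflowed to zero."""


@dataclass(frozen=True)
class SimParams:
    """Constants of one simulation run.

    Defaults follow the stabilizing-selection toy model: 10 selected plus
    10 neutral loci, per-allele effect x=5, optimum mu=10 beneficial
    alleles, selection strength s=10, initial allele frequency 0.5, three
    independent populations.  The population size default is 1,000 (a
    drift-visible scaling of the model's N=10,000).  Generations and the
    recombination rate are free choices: 200 generations shows the
    allele-frequency splitting clearly, and unlinked markers
    (recomb_rate=0.5) are the minimal assumption when no genetic map is
    specified.
    """

    n_individuals: int = 1000
    n_loci_selected: int = 10
    n_loci_neutral: int = 10
    effect_x: float = 5.0
    optimum_mu: float = 10.0
    strength_s: float = 10.0
    init_freq: float = 0.5
    n_populations: int = 3
    n_generations: int = 200
    recomb_rate: float = 0.5
    exact_init: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n_individuals < 2:
            raise ValueError("n_individuals must be >= 2")
        if self.n_loci_selected < 0 or self.n_loci_neutral < 0 or self.n_loci_selected + self.n_loci_neutral < 1:
            raise ValueError("need at least one locus")
        if not (0 <= self.optimum_mu <= 2 * self.n_loci_selected):
            raise ValueError("optimum_mu must lie in [0, 2 * n_loci_selected]")
        if not (0.0 <= self.init_freq <= 1.0):
            raise ValueError("init_freq must lie in [0, 1]")
        if not (0.0 <= self.recomb_rate <= 0.5):
            raise ValueError("recomb_rate must lie in [0, 0.5]")
        if self.strength_s <= 0:
            raise ValueError("strength_s must be positive")
        if self.n_generations < 0 or self.n_populations < 1:
            raise ValueError("n_generations >= 0 and n_populations >= 1 required")

    @property
    def n_loci(self) -> int:
        return self.n_loci_selected + self.n_loci_neutral


@dataclass
class Population:
    """Haplotype state of one population at one generation.

    ``haplotypes`` is a (2*n_individuals, n_loci) uint8 array; rows 2i and
    2i+1 are the two haplotypes of individual i; 1 marks the beneficial /
    derived allele.
    """

    haplotypes: np.ndarray
    generation: int = 0

    def __post_init__(self):
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        if self.haplotypes.ndim != 2 or self.haplotypes.shape[0] % 2:
            raise ValueError("haplotypes must be a (2N, L) array")
        if not np.isin(self.haplotypes, (0, 1)).all():
            raise ValueError("haplotype entries must be 0 or 1")

    @property
    def n_individuals(self) -> int:
        return self.haplotypes.shape[0] // 2

    def allele_freqs(self) -> np.ndarray:
        return self.haplotypes.mean(axis=0)


@dataclass
class SimResult:
    """Allele-frequency trajectories of a full run.

    ``trajectories`` has shape (n_populations, n_generations + 1, n_loci);
    index 0 on the time axis is the initial state.
    """

    trajectories: np.ndarray
    locus_selected: np.ndarray
    params: SimParams
    final_populations: list[Population] = field(default_factory=list)


def fitness(m, params: SimParams):
    """Relative viability of an individual carrying ``m`` beneficial alleles."""
    m = np.asarray(m, dtype=float)
    z = (m - params.optimum_mu) ** 2 * params.effect_x**2 / (2.0 * params.strength_s)
    return np.exp(-z)


def init_population(params: SimParams, rng: np.random.Generator) -> Population:
    """Bernoulli(init_freq) alleles; ``exact_init`` forces the exact per-locus count."""
    shape = (2 * params.n_individuals, params.n_loci)
    if params.exact_init:
        k = int(round(params.init_freq * shape[0]))
        hap = np.zeros(shape, dtype=np.uint8)
        for j in range(params.n_loci):
            hap[rng.permutation(shape[0])[:k], j] = 1
    else:
        hap = (rng.random(shape) < params.init_freq).astype(np.uint8)
    return Population(haplotypes=hap, generation=0)


def _gametes(parent_haps: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """One recombinant gamete per parent.

    ``parent_haps`` is (k, 2, L): the two haplotypes of each chosen parent.
    The source haplotype starts at random and switches between adjacent
    loci with probability ``rate``.
    """
    k, _, L = parent_haps.shape
    start = rng.integers(0, 2, size=(k, 1))
    if L > 1:
        switches = rng.random((k, L - 1)) < rate
        source = (start + np.concatenate([np.zeros((k, 1), dtype=np.int64), np.cumsum(switches, axis=1)], axis=1)) % 2
    else:
        source = start
    return np.take_along_axis(parent_haps, source[:, None, :], axis=1)[:, 0, :]


def next_generation(pop: Population, params: SimParams, rng: np.random.Generator) -> Population:
    """Advance one generation of viability selection plus random mating.

    Parents are drawn with replacement with probability proportional to
    fitness (weights rescaled by their maximum, so selection acts only
    through relative fitness and cannot underflow unless every weight is
    zero).  Population size is constant.
    """
    N = pop.n_individuals
    L = params.n_loci
    sel = params.n_loci_selected
    m = pop.haplotypes[:, :sel].reshape(N, 2 * sel).sum(axis=1) if sel else np.zeros(N)
    w = fitness(m, params)
    wmax = w.max()
    if wmax == 0.0:
        raise DegenerateFitnessError("all parental fitness values underflowed to 0")
    prob = w / wmax
    prob /= prob.sum()

    parents = rng.choice(N, size=(N, 2), replace=True, p=prob)
    haps = pop.haplotypes.reshape(N, 2, L)
    child = np.empty((2 * N, L), dtype=np.uint8)
    child[0::2] = _gametes(haps[parents[:, 0]], params.recomb_rate, rng)
    child[1::2] = _gametes(haps[parents[:, 1]], params.recomb_rate, rng)
    return Population(haplotypes=child, generation=pop.generation + 1)


def run_simulation(params: SimParams) -> SimResult:
    """Run all populations from independent substreams of the master seed.

    Population ``i`` uses ``np.random.default_rng([seed, i])``, so runs are
    reproducible and populations statistically independent.
    """
    traj = np.empty((params.n_populations, params.n_generations + 1, params.n_loci))
    finals: list[Population] = []
    for i in range(params.n_populations):
        rng = np.random.default_rng([params.seed, i])
        pop = init_population(params, rng)
        traj[i, 0] = pop.allele_freqs()
        for g in range(params.n_generations):
            pop = next_generation(pop, params, rng)
            traj[i, g + 1] = pop.allele_freqs()
        finals.append(pop)
    selected = np.zeros(params.n_loci, dtype=bool)
    selected[: params.n_loci_selected] = True
    return SimResult(trajectories=traj, locus_selected=selected, params=params, final_populations=finals)


def population_to_panel(pops: list[Population], sample_size: int, rng: np.random.Generator,
                        locus_ids: Optional[list[str]] = None) -> SNPPanel:
    """Genotype-count panel from a random sample of individuals per population.

    Sampling is without replacement; the panel's reference allele is the
    beneficial/derived allele, so AA = two copies.
    """
    L = pops[0].haplotypes.shape[1]
    ids = locus_ids if locus_ids is not None else [f"L{j:03d}" for j in range(L)]
    counts = np.zeros((L, len(pops), 3))
    for j, pop in enumerate(pops):
        if sample_size > pop.n_individuals:
            raise ValueError("sample_size exceeds population size")
        take = rng.choice(pop.n_individuals, size=sample_size, replace=False)
        geno = pop.haplotypes.reshape(pop.n_individuals, 2, L)[take].sum(axis=1)  # 0,1,2 copies
        counts[:, j, 0] = (geno == 2).sum(axis=0)
        counts[:, j, 1] = (geno == 1).sum(axis=0)
        counts[:, j, 2] = (geno == 0).sum(axis=0)
    return SNPPanel(np.asarray(ids, dtype=object), [f"pop{j+1}" for j in range(len(pops))], counts)


def sim_fst_summary(result: SimResult, sample_size: int, rng: Optional[np.random.Generator] = None):
    """Per-locus theta at the final generation plus selected/neutral means.

    Returns (records, mean_theta_selected, mean_theta_neutral); means are
    over loci with defined theta (NaN if none).
    """
    if rng is None:
        rng = np.random.default_rng([result.params.seed, 10_007])
    panel = population_to_panel(result.final_populations, sample_size, rng)
    records = panel_fst(panel)
    theta = records["theta"].to_numpy()
    sel = result.locus_selected
    with np.errstate(invalid="ignore"):
        mean_sel = float(np.nanmean(theta[sel])) if np.isfinite(theta[sel]).any() else float("nan")
        mean_neu = float(np.nanmean(theta[~sel])) if np.isfinite(theta[~sel]).any() else float("nan")
    return records, mean_sel, mean_neu
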