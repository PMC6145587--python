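"""Wright-Fisher dynamics of the hybrid population.

Life cycle per discrete generation: diploid parents produce an effectively
infinite gamete pool in which each genotype contributes in proportion to
its frequency times its fitness (soft selection), transmitting haplotypes
according to the meiosis transmission tensor.  Zygotes are then formed by
multinomial sampling of gametes from the pool; sampling N ordered gamete
pairs at once is distributionally identical to drawing 2N gametes and
pairing them sequentially, and is what the stochastic step does.  The
deterministic limit (N -> infinity) skips the sampling: next-generation
genotype frequencies are the random-union product of pool frequencies.

A run starts from the one-time admixture of two monomorphic parental
populations (parental 1 at fraction i_p) and ends when the population is
monomorphic (stochastic) or the leading haplotype exceeds 1 - 1e-8
(deterministic), recording when each DMI was resolved (first loss of a
derived A_k or B_k allele) and when all polymorphism was lost.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .fitness import FitnessParams, fitness_landscape
from .haplotypes import ALLELES, ANCESTRAL, N_HAPLOTYPES, PARENTAL1, PARENTAL2
from .linkage import LinkageArchitecture, recombination_tensor

#: single-DMI (two-locus) parental haplotypes: A1b1a2b2 and a1B1a2b2
SINGLE_DMI_PARENTS = (8, 4)

_DEFAULT_FIXATION_TOL = 1e-8


@dataclass(frozen=True)
class SimulationConfig:
    """Full specification of one simulation scenario.

    N : population size in diploid individuals, or None for the
        deterministic (infinite-N) recursion.
    i_p : founding contribution of parental population 1, in [0, 1].
    i_q : optional three-genotype initialization — both parental homozygotes
        at fraction i_q each and the ancestral homozygote at 1 - 2 i_q.
    parental_haplotypes : founding homozygote haplotypes; the four-locus
        default is (A1b1A2b2, a1B1a2B2), the two-locus sub-model uses
        ``SINGLE_DMI_PARENTS``.
    """

    params: FitnessParams = field(default_factory=FitnessParams)
    arch: LinkageArchitecture = field(default_factory=LinkageArchitecture.unlinked)
    N: int | None = 5000
    i_p: float = 0.5
    i_q: float | None = None
    parental_haplotypes: tuple[int, int] = (PARENTAL1, PARENTAL2)
    max_generations: int = 1_000_000
    fixation_tol: float = _DEFAULT_FIXATION_TOL

    def __post_init__(self) -> None:
        if self.N is not None and self.N < 1:
            raise ValueError("N must be a positive integer (or None)")
        if not 0.0 <= self.i_p <= 1.0:
            raise ValueError("i_p must lie in [0, 1]")
        if self.i_q is not None and not 0.0 <= 2 * self.i_q <= 1.0:
            raise ValueError("i_q requires 2*i_q <= 1")
        h1, h2 = self.parental_haplotypes
        if not (0 <= h1 < N_HAPLOTYPES and 0 <= h2 < N_HAPLOTYPES) or h1 == h2:
            raise ValueError("parental haplotypes must be two distinct indices 0-15")

    @property
    def deterministic(self) -> bool:
        return self.N is None


def single_dmi_config(
    r: float, params: FitnessParams | None = None, **kwargs
) -> SimulationConfig:
    """Two-locus sub-model: only A1 and B1 segregate, at recombination rate r.

    The remaining loci are monomorphic ancestral, so the four-locus engine
    reduces exactly to the two-locus model.
    """
    arch = LinkageArchitecture(("A1", "B1", "A2", "B2"), (r, 0.5, 0.5))
    return SimulationConfig(
        params=params or FitnessParams(),
        arch=arch,
        parental_haplotypes=SINGLE_DMI_PARENTS,
        **kwargs,
    )


@dataclass
class PopulationState:
    """Population at one generation.

    ``geno`` is the ordered 16 x 16 genotype table: integer counts summing
    to N for stochastic runs, frequencies summing to 1 for deterministic
    ones.  Haplotype frequencies are the induced marginals.
    """

    t: int
    geno: np.ndarray
    N: int | None

    @property
    def haplotype_freqs(self) -> np.ndarray:
        hap = self.geno.sum(axis=0) + self.geno.sum(axis=1)
        total = hap.sum()
        return hap / total

    @property
    def haplotype_counts(self) -> np.ndarray:
        if self.N is None:
            raise ValueError("deterministic state has no counts")
        return self.geno.sum(axis=0) + self.geno.sum(axis=1)

    @property
    def monomorphic(self) -> bool:
        f = self.haplotype_freqs
        if self.N is None:
            return bool(f.max() > 1.0 - _DEFAULT_FIXATION_TOL)
        return bool(f.max() == 1.0)


def initialize_population(config: SimulationConfig) -> PopulationState:
    """Founding population: two (or, with i_q, three) homozygous genotypes."""
    h1, h2 = config.parental_haplotypes
    if config.i_q is not None:
        fractions = {h1: config.i_q, h2: config.i_q, ANCESTRAL: 1.0 - 2 * config.i_q}
    else:
        fractions = {h1: config.i_p, h2: 1.0 - config.i_p}
    if config.deterministic:
        geno = np.zeros((N_HAPLOTYPES, N_HAPLOTYPES))
        for h, f in fractions.items():
            geno[h, h] = f
        return PopulationState(t=0, geno=geno, N=None)
    N = config.N
    geno = np.zeros((N_HAPLOTYPES, N_HAPLOTYPES), dtype=np.int64)
    haps = list(fractions)
    counts = [round(N * fractions[h]) for h in haps[:-1]]
    counts.append(N - sum(counts))
    for h, c in zip(haps, counts):
        geno[h, h] = c
    if config.i_q is None and 0.0 < config.i_p < 1.0 and (counts[0] in (0, N)):
        warnings.warn(
            f"i_p = {config.i_p} rounds to a monomorphic start at N = {N}",
            stacklevel=2,
        )
    return PopulationState(t=0, geno=geno, N=N)


def gamete_pool(
    state: PopulationState, params: FitnessParams, arch: LinkageArchitecture
) -> np.ndarray:
    """Haplotype distribution of the infinite gamete pool after soft selection."""
    W = fitness_landscape(params)
    T = recombination_tensor(arch).reshape(N_HAPLOTYPES**2, N_HAPLOTYPES)
    fw = (state.geno * W).ravel()
    pool = fw @ T
    return pool / pool.sum()


def step_deterministic(
    state: PopulationState, params: FitnessParams, arch: LinkageArchitecture
) -> PopulationState:
    """One generation of the infinite-population recursion."""
    pool = gamete_pool(state, params, arch)
    return PopulationState(t=state.t + 1, geno=np.outer(pool, pool), N=None)


def step_stochastic(
    state: PopulationState,
    params: FitnessParams,
    arch: LinkageArchitecture,
    rng: np.random.Generator,
) -> PopulationState:
    """One generation of the finite-N model: multinomial zygote sampling."""
    if state.N is None:
        raise ValueError("stochastic step requires integer counts (finite N)")
    pool = gamete_pool(state, params, arch)
    probs = np.outer(pool, pool).ravel()
    geno = rng.multinomial(state.N, probs).reshape(N_HAPLOTYPES, N_HAPLOTYPES)
    return PopulationState(t=state.t + 1, geno=geno, N=state.N)


@dataclass
class OutcomeRecord:
    """End state of one replicate.

    ``fixed_haplotype`` is None when the run hit the generation cap without
    fixing (outcome "unresolved").  Resolution time of DMI k is the first
    generation at which derived allele A_k or B_k was absent; None when the
    conflict was never resolved within the run.
    """

    fixed_haplotype: int | None
    outcome: str
    resolution_times: tuple[int | None, int | None]
    fixation_time: int | None
    n_generations: int
    replicate: int | None = None
    trajectory: np.ndarray | None = None

    @property
    def hybrid_speciation(self) -> bool:
        from .observables import is_hybrid_speciation

        return self.fixed_haplotype is not None and is_hybrid_speciation(
            self.fixed_haplotype
        )


def _outcome_label(fixed: int | None) -> str:
    if fixed is None:
        return "unresolved"
    from .observables import classify_haplotype

    return classify_haplotype(fixed)


def run_replicate(
    config: SimulationConfig,
    rng: np.random.Generator | int | None = None,
    record_trajectory: bool = False,
    stop_at: str = "fixation",
) -> OutcomeRecord:
    """Run one replicate to absorption.

    Stochastic runs end when the population is monomorphic (exact integer
    counts); deterministic runs when the leading haplotype frequency exceeds
    1 - fixation_tol, or, failing that, at max_generations with the explicit
    outcome "unresolved".  ``stop_at="resolution"`` ends the run as soon as
    both DMIs are resolved (used when only resolution times are needed).
    """
    if stop_at not in ("fixation", "resolution"):
        raise ValueError("stop_at must be 'fixation' or 'resolution'")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    W = fitness_landscape(config.params).ravel()
    T = recombination_tensor(config.arch).reshape(N_HAPLOTYPES**2, N_HAPLOTYPES)
    state = initialize_population(config)
    deterministic = config.deterministic
    N = config.N
    two_N = None if deterministic else 2 * N
    tol = config.fixation_tol

    geno = state.geno
    res_times: list[int | None] = [None, None]
    fixed: int | None = None
    fixation_time: int | None = None
    traj: list[np.ndarray] | None = [] if record_trajectory else None
    t = 0
    while True:
        hap = geno.sum(axis=0) + geno.sum(axis=1)
        if deterministic:
            hap = hap / hap.sum()
        if traj is not None:
            traj.append(hap if deterministic else hap / two_N)
        derived = hap @ ALLELES  # derived-allele dosage per locus
        for k in range(2):
            if res_times[k] is None:
                a, b = derived[2 * k], derived[2 * k + 1]
                if deterministic:
                    if a < tol or b < tol:
                        res_times[k] = t
                elif a == 0 or b == 0:
                    res_times[k] = t
        if deterministic:
            if hap.max() > 1.0 - tol:
                fixed = int(hap.argmax())
                fixation_time = t
                break
        elif hap.max() == two_N:
            fixed = int(hap.argmax())
            fixation_time = t
            break
        if stop_at == "resolution" and res_times[0] is not None and res_times[1] is not None:
            break
        if t >= config.max_generations:
            break
        # --- one generation ---
        fw = geno.ravel() * W
        pool = fw @ T
        pool = pool / pool.sum()
        if deterministic:
            geno = np.outer(pool, pool)
        else:
            probs = np.outer(pool, pool).ravel()
            geno = rng.multinomial(N, probs).reshape(N_HAPLOTYPES, N_HAPLOTYPES)
        t += 1

    return OutcomeRecord(
        fixed_haplotype=fixed,
        outcome=_outcome_label(fixed),
        resolution_times=(res_times[0], res_times[1]),
        fixation_time=fixation_time,
        n_generations=t,
        trajectory=np.array(traj) if traj is not None else None,
    )


def run_replicates(
    config: SimulationConfig,
    reps: int,
    base_seed: int | np.random.SeedSequence | None = None,
    record_trajectory: bool = False,
    stop_at: str = "fixation",
) -> list[OutcomeRecord]:
    """Run ``reps`` independent replicates.

    Per-replicate random streams are spawned from a single base seed
    (children of ``np.random.SeedSequence(base_seed)`` in replicate order),
    so replicate i is re-runnable in isolation from (base_seed, i).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    ss = (
        base_seed
        if isinstance(base_seed, np.random.SeedSequence)
        else np.random.SeedSequence(base_seed)
    )
    records = []
    for i, child in enumerate(ss.spawn(reps)):
        rec = run_replicate(
            config,
            rng=np.random.default_rng(child),
            record_trajectory=record_trajectory,
            stop_at=stop_at,
        )
        rec.replicate = i
        records.append(rec)
    return records
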