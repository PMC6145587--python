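"""Introgression of an unlinked neutral marker into the hybrid species.

The barrier strength of a freshly sorted hybrid population is measured by
the fate of a neutral marker carried by a single parental migrant.  The
marker locus sits on its own chromosome (recombination rate 0.5 to every
selected locus), so the state space doubles to 32 haplotypes: (selected
four-locus haplotype) x (marker allele).  Selection sees only the selected
loci; the marker hitchhikes.

A migrant homozygous for a parental haplotype and for the marker replaces
one resident of the monomorphic hybrid population (N constant), and the
run continues until the marker is lost or fixed.  The reference point is
p_n = 2 copies / 2N = 1/N, the fixation probability of the same neutral
marker appearing in a resident individual; a fixation probability below
p_n quantifies the barrier against introgression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import binomtest
from statsmodels.stats.proportion import proportion_confint

from .fitness import FitnessParams, fitness_landscape
from .haplotypes import HYBRID_1, N_HAPLOTYPES, PARENTAL1
from .linkage import LinkageArchitecture, recombination_tensor

#: marker transmission for an unlinked locus: M[mi, mj, mh]
_MARKER_T = np.zeros((2, 2, 2))
_MARKER_T[0, 0, 0] = _MARKER_T[1, 1, 1] = 1.0
_MARKER_T[0, 1, :] = _MARKER_T[1, 0, :] = 0.5

N_MARKED = 2 * N_HAPLOTYPES  # 32 marked haplotypes, index = 2*h + marker


def marked_index(h: int, marker: int) -> int:
    """Index of four-locus haplotype ``h`` carrying marker allele ``marker``."""
    return 2 * h + marker


def marked_transmission_tensor(arch: LinkageArchitecture) -> np.ndarray:
    """32-haplotype transmission tensor: selected-loci meiosis times
    independent assortment of the unlinked marker."""
    T16 = recombination_tensor(arch)
    T32 = (
        T16[:, None, :, None, :, None] * _MARKER_T[None, :, None, :, None, :]
    ).reshape(N_MARKED, N_MARKED, N_MARKED)
    return T32


def marked_fitness_landscape(params: FitnessParams) -> np.ndarray:
    """32 x 32 fitness table; the marker is neutral."""
    return np.kron(fitness_landscape(params), np.ones((2, 2)))


def marked_gamete_pool(
    geno32: np.ndarray, params: FitnessParams, arch: LinkageArchitecture
) -> np.ndarray:
    """Gamete pool of the 32-haplotype system (soft selection)."""
    W = marked_fitness_landscape(params)
    T = marked_transmission_tensor(arch).reshape(N_MARKED**2, N_MARKED)
    fw = (geno32 * W).ravel()
    pool = fw @ T
    return pool / pool.sum()


@dataclass(frozen=True)
class MarkerExperimentResult:
    """Marker fixation probability after a single migration event."""

    n_fixed: int
    n_replicates: int
    N: int
    p_fix: float
    ci_low: float
    ci_high: float
    p_neutral: float  # baseline p_n = 1/N
    relative: float  # p_fix / p_n
    p_value: float  # exact binomial test of p_fix == p_n
    significant: bool  # after Bonferroni correction over n_tests
    n_tests: int


def introgression_experiment(
    params: FitnessParams,
    arch: LinkageArchitecture,
    N: int,
    reps: int = 100_000,
    base_seed: int | np.random.SeedSequence | None = None,
    migrant: int = PARENTAL1,
    resident: int = HYBRID_1,
    alpha: float = 0.05,
    n_tests: int = 1,
    max_generations: int = 10_000_000,
) -> MarkerExperimentResult:
    """Fate of a neutral marker brought in by one homozygous migrant.

    ``n_tests`` is the Bonferroni correction count when the experiment is
    one cell of a parameter grid (the grid size is the artifact's own; it
    is recorded in the result).  ``migrant == resident`` is the neutral
    control whose fixation probability equals p_n.
    """
    if not 0 <= resident < N_HAPLOTYPES or not 0 <= migrant < N_HAPLOTYPES:
        raise ValueError("resident and migrant must be haplotype indices 0-15")
    if N < 2:
        raise ValueError("N must be at least 2 (one migrant among residents)")
    W = marked_fitness_landscape(params).ravel()
    T = marked_transmission_tensor(arch).reshape(N_MARKED**2, N_MARKED)
    ss = (
        base_seed
        if isinstance(base_seed, np.random.SeedSequence)
        else np.random.SeedSequence(base_seed)
    )
    res_idx = marked_index(resident, 0)
    mig_idx = marked_index(migrant, 1)
    marker_mask = np.arange(N_MARKED) % 2 == 1
    two_N = 2 * N

    n_fixed = 0
    for child in ss.spawn(reps):
        rng = np.random.default_rng(child)
        geno = np.zeros((N_MARKED, N_MARKED), dtype=np.int64)
        geno[res_idx, res_idx] = N - 1
        geno[mig_idx, mig_idx] = 1
        for _ in range(max_generations):
            hap = geno.sum(axis=0) + geno.sum(axis=1)
            m = int(hap[marker_mask].sum())
            if m == 0:
                break
            if m == two_N:
                n_fixed += 1
                break
            fw = geno.ravel() * W
            pool = fw @ T
            pool = pool / pool.sum()
            probs = np.outer(pool, pool).ravel()
            geno = rng.multinomial(N, probs).reshape(N_MARKED, N_MARKED)
        else:
            raise RuntimeError("marker did not absorb within max_generations")

    p_fix = n_fixed / reps
    lo, hi = proportion_confint(n_fixed, reps, alpha=alpha, method="beta")
    p_n = 1.0 / N
    test = binomtest(n_fixed, reps, p_n)
    return MarkerExperimentResult(
        n_fixed=n_fixed,
        n_replicates=reps,
        N=N,
        p_fix=p_fix,
        ci_low=float(lo),
        ci_high=float(hi),
        p_neutral=p_n,
        relative=p_fix / p_n,
        p_value=float(test.pvalue),
        significant=bool(test.pvalue < alpha / n_tests),
        n_tests=n_tests,
    )


def neutral_fixation_baseline(
    N: int,
    reps: int = 100_000,
    base_seed: int | None = None,
    copies: int = 2,
    alpha: float = 0.05,
) -> tuple[float, float, float]:
    """Fixation probability of a neutral allele starting at ``copies``/2N.

    Pure single-locus Wright-Fisher drift (the p_n baseline of the marker
    experiment: a neutral marker appearing in one homozygous resident).
    Vectorized across replicates; returns (estimate, ci_low, ci_high).
    """
    rng = np.random.default_rng(base_seed)
    two_N = 2 * N
    x = np.full(reps, copies, dtype=np.int64)
    active = (x > 0) & (x < two_N)
    while active.any():
        x[active] = rng.binomial(two_N, x[active] / two_N)
        active = (x > 0) & (x < two_N)
    k = int((x == two_N).sum())
    lo, hi = proportion_confint(k, reps, alpha=alpha, method="beta")
    return k / reps, float(lo), float(hi)
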