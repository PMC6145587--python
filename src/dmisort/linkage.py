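"""Linkage architectures and meiosis.

A linkage architecture is the order of the four loci along a chromosome
together with the recombination rates of the three adjacent intervals.
Crossovers occur independently in each interval (no interference), so the
recombination rate between two loci separated by a middle locus follows the
composite rule r_XY = r_XW (1 - r_WY) + r_WY (1 - r_XW).  Loci on different
chromosomes are encoded by an intervening rate of 0.5 (free recombination).

There are 24 ways to order the four loci on a chromosome, but only six
distinct architectures up to chromosome reversal, exchange of the two DMI
labels, and joint exchange of the A and B roles.  The canonical six are
named by the relative arrangement of the two incompatibilities (Adjacent /
Crossed / Nested) and the letter pattern of the loci along the chromosome.

Haplotype indices and strings always use model locus order A1 B1 A2 B2;
chromosomal order lives only in the architecture.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .haplotypes import (
    ALLELES,
    LOCI,
    N_HAPLOTYPES,
    PARENTAL1,
    PARENTAL2,
    derived_count,
    haplotype_index,
    haplotype_string,
)

#: canonical chromosomal locus orders of the six architectures
CANONICAL_ORDERS: dict[str, tuple[str, str, str, str]] = {
    "Adjacent ABAB": ("A1", "B1", "A2", "B2"),
    "Adjacent ABBA": ("A1", "B1", "B2", "A2"),
    "Crossed AABB": ("A1", "A2", "B1", "B2"),
    "Crossed ABBA": ("A1", "B2", "B1", "A2"),
    "Nested ABAB": ("A1", "B2", "A2", "B1"),
    "Nested AABB": ("A1", "A2", "B2", "B1"),
}

#: the main text once calls the hybrid-speciation-prone crossed layout
#: "Crossed ABAB"; treated as a synonym of "Crossed AABB"
ARCHITECTURE_SYNONYMS = {"Crossed ABAB": "Crossed AABB"}


def composite_recomb(r_xw: float, r_wy: float) -> float:
    """Recombination rate between loci X and Y separated by a single locus W.

    Assumes independent crossovers in the two intervals:
    r_XY = r_XW (1 - r_WY) + r_WY (1 - r_XW).
    """
    for r in (r_xw, r_wy):
        if not 0.0 <= r <= 0.5:
            raise ValueError(f"recombination rate {r} outside [0, 0.5]")
    return r_xw * (1.0 - r_wy) + r_wy * (1.0 - r_xw)


def _swap_dmi(order: tuple[str, ...]) -> tuple[str, ...]:
    m = {"A1": "A2", "A2": "A1", "B1": "B2", "B2": "B1"}
    return tuple(m[x] for x in order)


def _swap_roles(order: tuple[str, ...]) -> tuple[str, ...]:
    m = {"A1": "B1", "B1": "A1", "A2": "B2", "B2": "A2"}
    return tuple(m[x] for x in order)


def order_orbit(order: tuple[str, ...]) -> frozenset[tuple[str, ...]]:
    """All images of a locus order under reversal, DMI exchange and A<->B exchange."""
    orbit = {tuple(order)}
    while True:
        new = set()
        for o in orbit:
            new.update({tuple(reversed(o)), _swap_dmi(o), _swap_roles(o)})
        if new <= orbit:
            return frozenset(orbit)
        orbit |= new


def classify_order(order: tuple[str, ...]) -> str:
    """Canonical architecture name of an arbitrary locus order."""
    if sorted(order) != sorted(LOCI):
        raise ValueError(f"order must be a permutation of {LOCI}, got {order}")
    orbit = order_orbit(order)
    for name, canonical in CANONICAL_ORDERS.items():
        if canonical in orbit:
            return name
    raise AssertionError("unreachable: every order belongs to one of six classes")


@dataclass(frozen=True)
class LinkageArchitecture:
    """Chromosomal locus order plus the three adjacent-interval rates."""

    order: tuple[str, str, str, str]
    rates: tuple[float, float, float]

    def __post_init__(self) -> None:
        if sorted(self.order) != sorted(LOCI):
            raise ValueError(f"order must be a permutation of {LOCI}")
        if len(self.rates) != 3:
            raise ValueError("exactly three adjacent-interval rates required")
        for r in self.rates:
            if not 0.0 <= r <= 0.5:
                raise ValueError(f"recombination rate {r} outside [0, 0.5]")

    @property
    def name(self) -> str:
        """Canonical architecture class of the locus order."""
        return classify_order(self.order)

    @classmethod
    def equidistant(cls, name: str, r: float) -> "LinkageArchitecture":
        """Canonical single-chromosome architecture with equal interval rates."""
        name = ARCHITECTURE_SYNONYMS.get(name, name)
        if name not in CANONICAL_ORDERS:
            raise ValueError(
                f"unknown architecture {name!r}; choose from {sorted(CANONICAL_ORDERS)}"
            )
        return cls(CANONICAL_ORDERS[name], (r, r, r))

    @classmethod
    def separate_chromosomes(cls, r1: float, r2: float) -> "LinkageArchitecture":
        """One DMI per chromosome: A1-B1 at rate r1, A2-B2 at rate r2."""
        return cls(("A1", "B1", "A2", "B2"), (r1, 0.5, r2))

    @classmethod
    def unlinked(cls) -> "LinkageArchitecture":
        """All four loci on different chromosomes."""
        return cls(("A1", "B1", "A2", "B2"), (0.5, 0.5, 0.5))

    def pairwise_rate(self, locus_x: str, locus_y: str) -> float:
        """Recombination fraction between any two loci (composite rule)."""
        i, j = sorted((self.order.index(locus_x), self.order.index(locus_y)))
        if i == j:
            raise ValueError("pairwise rate needs two distinct loci")
        r = self.rates[i]
        for interval in range(i + 1, j):
            r = composite_recomb(r, self.rates[interval])
        return r

    def expected_crossovers(self) -> float:
        """Mean number of crossover events per gamete (sum of interval rates)."""
        return float(sum(self.rates))


def enumerate_architectures(r: float = 0.5) -> list[LinkageArchitecture]:
    """The six canonical single-chromosome architectures, equidistant at rate r."""
    return [LinkageArchitecture.equidistant(name, r) for name in CANONICAL_ORDERS]


def count_equivalence_classes() -> int:
    """Number of distinct locus orders up to the three architecture symmetries."""
    orbits = {order_orbit(p) for p in itertools.permutations(LOCI)}
    return len(orbits)


def gamete_distribution(
    genotype: tuple[int, int], arch: LinkageArchitecture
) -> np.ndarray:
    """Probability vector over the 16 gamete haplotypes produced by a genotype.

    Meiosis picks the starting strand uniformly and then crosses over
    independently in each of the three intervals with that interval's rate.
    """
    i, j = genotype
    # strand alleles in chromosomal position space
    locus_idx = [LOCI.index(loc) for loc in arch.order]
    strands = np.array(
        [[ALLELES[h, l] for l in locus_idx] for h in (i, j)], dtype=np.int64
    )
    out = np.zeros(N_HAPLOTYPES)
    for start in (0, 1):
        for pattern in itertools.product((0, 1), repeat=3):
            p = 0.5
            for c, r in zip(pattern, arch.rates):
                p *= r if c else 1.0 - r
            if p == 0.0:
                continue
            strand = start
            alleles_chrom = []
            for pos in range(4):
                alleles_chrom.append(strands[strand, pos])
                if pos < 3 and pattern[pos]:
                    strand = 1 - strand
            # back to model order
            bits = [0, 0, 0, 0]
            for pos, l in enumerate(locus_idx):
                bits[l] = int(alleles_chrom[pos])
            out[haplotype_index(*bits)] += p
    return out


_TENSOR_CACHE: dict[tuple, np.ndarray] = {}


def recombination_tensor(arch: LinkageArchitecture) -> np.ndarray:
    """Transmission tensor T[i, j, h] = P(gamete h | parent genotype (i, j)).

    Cached per architecture; rows (i, j) sum to 1 and T is symmetric in its
    first two indices.
    """
    key = (arch.order, arch.rates)
    if key not in _TENSOR_CACHE:
        T = np.empty((N_HAPLOTYPES, N_HAPLOTYPES, N_HAPLOTYPES))
        for i in range(N_HAPLOTYPES):
            for j in range(i, N_HAPLOTYPES):
                T[i, j] = T[j, i] = gamete_distribution((i, j), arch)
        T.setflags(write=False)
        _TENSOR_CACHE[key] = T
    return _TENSOR_CACHE[key]


def f2_breakdown_table(arch: LinkageArchitecture) -> pd.DataFrame:
    """Recombinant haplotypes produced by a single crossover in an F1 individual.

    The F1 genotype is parental haplotype 1 (A1b1A2b2) over parental
    haplotype 2 (a1B1a2B2).  For each of the three intervals the table lists
    the two single-crossover products and flags those that are relatively
    epistasis-free (at most one derived allele, hence no incompatible pair).
    """
    locus_idx = [LOCI.index(loc) for loc in arch.order]
    strands = np.array(
        [[ALLELES[h, l] for l in locus_idx] for h in (PARENTAL1, PARENTAL2)],
        dtype=np.int64,
    )
    rows = []
    for interval in range(3):
        for start in (0, 1):
            bits = [0, 0, 0, 0]
            for pos, l in enumerate(locus_idx):
                strand = start if pos <= interval else 1 - start
                bits[l] = int(strands[strand, pos])
            h = haplotype_index(*bits)
            rows.append(
                {
                    "interval": interval,
                    "between": f"{arch.order[interval]}-{arch.order[interval + 1]}",
                    "haplotype": h,
                    "haplotype_name": haplotype_string(h),
                    "epistasis_free": derived_count(h) <= 1,
                }
            )
    return pd.DataFrame(rows)
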