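"""Four-locus haplotype encoding.

The model tracks four diallelic loci A1, B1, A2, B2.  At each locus the
derived allele is written upper-case (``A1``) and the ancestral allele
lower-case (``a1``).  A haplotype is one of the 16 combinations and is
encoded as an integer index 0-15 with bit layout (most significant first)

    index = 8*A1 + 4*B1 + 2*A2 + 1*B2

where each bit is 1 for the derived allele.  Haplotype strings are always
written in model locus order A1 B1 A2 B2 (e.g. ``"A1b1a2B2"``), regardless
of the chromosomal order of the loci, which is a property of the linkage
architecture only.
"""

from __future__ import annotations

import itertools

import numpy as np

#: locus names in model order
LOCI = ("A1", "B1", "A2", "B2")

N_HAPLOTYPES = 16

#: ALLELES[h, l] == 1 if haplotype h carries the derived allele at locus l
ALLELES = np.array(
    [[(h >> (3 - l)) & 1 for l in range(4)] for h in range(N_HAPLOTYPES)],
    dtype=np.int64,
)

#: DERIVED_MASK[l] — boolean over haplotypes carrying derived allele at locus l
DERIVED_MASK = ALLELES.T.astype(bool)

# named haplotypes
ANCESTRAL = 0  # a1b1a2b2
PARENTAL1 = 10  # A1b1A2b2
PARENTAL2 = 5  # a1B1a2B2
HYBRID_1 = 9  # A1b1a2B2
HYBRID_2 = 6  # a1B1A2b2
DOUBLE_INCOMPATIBLE = 15  # A1B1A2B2

#: the two haplotypes whose fixation constitutes hybrid speciation
HYBRID_HAPLOTYPES = (HYBRID_1, HYBRID_2)


def haplotype_index(a1: int, b1: int, a2: int, b2: int) -> int:
    """Index of the haplotype with the given derived-allele indicators."""
    for x in (a1, b1, a2, b2):
        if x not in (0, 1):
            raise ValueError("allele indicators must be 0 or 1")
    return 8 * a1 + 4 * b1 + 2 * a2 + b2


def haplotype_string(h: int) -> str:
    """Human-readable haplotype name, e.g. ``haplotype_string(9) == 'A1b1a2B2'``."""
    if not 0 <= h < N_HAPLOTYPES:
        raise ValueError(f"haplotype index out of range: {h}")
    return "".join(
        loc if ALLELES[h, l] else loc.lower() for l, loc in enumerate(LOCI)
    )


def haplotype_from_string(s: str) -> int:
    """Inverse of :func:`haplotype_string`; accepts any locus order in the string."""
    if len(s) != 8:
        raise ValueError(f"expected an 8-character haplotype string, got {s!r}")
    alleles = {}
    for i in range(0, 8, 2):
        token = s[i : i + 2]
        locus = token.capitalize()
        if locus not in LOCI or locus in alleles:
            raise ValueError(f"invalid haplotype string: {s!r}")
        alleles[locus] = int(token[0].isupper())
    return haplotype_index(*(alleles[loc] for loc in LOCI))


HAPLOTYPE_STRINGS = tuple(haplotype_string(h) for h in range(N_HAPLOTYPES))


def derived_count(h: int) -> int:
    """Number of derived alleles carried by haplotype ``h``."""
    return int(ALLELES[h].sum())


def genotypes_unordered() -> list[tuple[int, int]]:
    """The 136 unordered genotypes (i <= j)."""
    return list(itertools.combinations_with_replacement(range(N_HAPLOTYPES), 2))
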