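"""Genotype fitness under two pairwise Dobzhansky-Muller incompatibilities.

A genotype is an unordered pair of haplotypes (i, j).  Its fitness is
multiplicative over the two DMIs k in {1, 2}:

    w_ij = prod_k (1 + alpha_k)^Xk (1 + beta_k)^Yk (1 + phi_k(n_k) * eps_k)^n_k

with Xk the number of derived A_k alleles in the genotype (0, 1 or 2), Yk
the number of derived B_k alleles, and n_k = Xk * Yk the number of
incompatible allele pairs (0, 1, 2 or 4).  alpha_k and beta_k are the direct
selection coefficients of the derived alleles, eps_k in (-1, 0] is the
(negative) epistasis coefficient of DMI k, and phi_k(n) in [0, 1] is a
dominance weight: phi == 1 for all n gives a codominant incompatibility,
phi(1) == 0 masks the epistasis in the double heterozygote (a recessive
incompatibility; n = 1, 2, 4 correspond to the H0, H1 and H2 classes of
Turelli & Orr).

Selection is soft: fitness only ever enters the dynamics relative to the
population mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .haplotypes import ALLELES, HAPLOTYPE_STRINGS, LOCI, N_HAPLOTYPES

_VALID_N = (0, 1, 2, 4)


@dataclass(frozen=True)
class DominanceScheme:
    """Dominance weights phi(n) of the epistatic interaction of one DMI.

    ``table`` maps the number of incompatible allele pairs n in {0, 1, 2, 4}
    to a weight in [0, 1].  Arbitrary tables are accepted; the two presets
    used throughout are :meth:`codominant` and :meth:`recessive`.
    """

    table: dict[int, float]
    name: str = "custom"

    def __post_init__(self) -> None:
        if set(self.table) != set(_VALID_N):
            raise ValueError(f"dominance table must have keys {_VALID_N}")
        for n, v in self.table.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"phi({n}) = {v} outside [0, 1]")

    def phi(self, n: int) -> float:
        if n not in _VALID_N:
            raise ValueError(
                f"invalid incompatible-pair count n={n}; must be one of {_VALID_N}"
            )
        return self.table[n]

    @classmethod
    def codominant(cls) -> "DominanceScheme":
        """Epistasis fully expressed in every carrier genotype: phi(n) = 1."""
        return cls({n: 1.0 for n in _VALID_N}, name="codominant")

    @classmethod
    def recessive(cls) -> "DominanceScheme":
        """Epistasis masked in the double heterozygote: phi(1) = 0, else 1."""
        return cls({0: 1.0, 1: 0.0, 2: 1.0, 4: 1.0}, name="recessive")

    @classmethod
    def from_name(cls, name: str) -> "DominanceScheme":
        try:
            return {"codominant": cls.codominant, "recessive": cls.recessive}[name]()
        except KeyError:
            raise ValueError(
                f"unknown dominance scheme {name!r}; use 'codominant' or 'recessive'"
            ) from None


def phi_value(scheme: DominanceScheme, n: int) -> float:
    """Dominance weight phi(n) for ``n`` incompatible allele pairs."""
    return scheme.phi(n)


@dataclass(frozen=True)
class FitnessParams:
    """Selection parameters of the two-DMI model.

    alpha, beta : per-DMI direct selection coefficients of the derived A_k
        and B_k alleles (dimensionless; > -1).
    epsilon : per-DMI epistasis coefficients, each in (-1, 0].
        epsilon = -0.99 is the quasi-lethal extreme.
    dominance : per-DMI dominance scheme of the epistatic interaction.
    """

    alpha: tuple[float, float] = (0.001, 0.001)
    beta: tuple[float, float] = (0.001, 0.001)
    epsilon: tuple[float, float] = (-0.2, -0.2)
    dominance: tuple[DominanceScheme, DominanceScheme] = field(
        default_factory=lambda: (DominanceScheme.codominant(),) * 2
    )

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "epsilon"):
            vals = getattr(self, name)
            if len(vals) != 2 or not all(np.isfinite(v) for v in vals):
                raise ValueError(f"{name} must be two finite values, got {vals}")
        for name in ("alpha", "beta"):
            if any(v <= -1.0 for v in getattr(self, name)):
                raise ValueError(f"{name} must exceed -1 (positive fitness)")
        for e in self.epsilon:
            if not -1.0 < e <= 0.0:
                raise ValueError(
                    f"epsilon must lie in (-1, 0] (negative epistasis), got {e}"
                )
        if len(self.dominance) != 2:
            raise ValueError("one dominance scheme per DMI required")
        for e, dom in zip(self.epsilon, self.dominance):
            for n in _VALID_N[1:]:
                if 1.0 + dom.phi(n) * e <= 0.0:
                    raise ValueError("1 + phi(n)*epsilon must stay positive")

    @classmethod
    def symmetric(
        cls,
        s: float = 0.001,
        epsilon: float = -0.2,
        dominance: str | DominanceScheme = "codominant",
    ) -> "FitnessParams":
        """Equal direct selection on all four derived alleles, equal epistasis."""
        dom = (
            DominanceScheme.from_name(dominance)
            if isinstance(dominance, str)
            else dominance
        )
        return cls((s, s), (s, s), (epsilon, epsilon), (dom, dom))


def genotype_fitness(i: int, j: int, params: FitnessParams) -> float:
    """Fitness w_ij of the (unordered) genotype made of haplotypes i and j."""
    w = 1.0
    for k in range(2):
        X = int(ALLELES[i, 2 * k] + ALLELES[j, 2 * k])
        Y = int(ALLELES[i, 2 * k + 1] + ALLELES[j, 2 * k + 1])
        n = X * Y
        w *= (
            (1.0 + params.alpha[k]) ** X
            * (1.0 + params.beta[k]) ** Y
            * (1.0 + params.dominance[k].phi(n) * params.epsilon[k]) ** n
        )
    return w


def fitness_landscape(params: FitnessParams) -> np.ndarray:
    """Symmetric 16 x 16 table of genotype fitnesses."""
    W = np.empty((N_HAPLOTYPES, N_HAPLOTYPES))
    for i in range(N_HAPLOTYPES):
        for j in range(i, N_HAPLOTYPES):
            W[i, j] = W[j, i] = genotype_fitness(i, j, params)
    return W


def landscape_to_tsv(params: FitnessParams, path) -> None:
    """Write the 16 x 16 fitness landscape as a labelled TSV matrix."""
    import pandas as pd

    W = fitness_landscape(params)
    pd.DataFrame(W, index=HAPLOTYPE_STRINGS, columns=HAPLOTYPE_STRINGS).to_csv(
        path, sep="\t", float_format="%.12g"
    )


def _allele_to_locus(allele: str) -> tuple[int, bool]:
    """Parse an allele name like 'A2' (derived) or 'b1' (ancestral)."""
    locus = allele.capitalize()
    if locus not in LOCI:
        raise ValueError(f"unknown allele {allele!r}; use e.g. 'A1' or 'b2'")
    return LOCI.index(locus), allele[0].isupper()


def marginal_allele_fitness(
    genotype_freqs: np.ndarray, allele: str, params: FitnessParams
) -> float:
    """Dosage-weighted mean fitness of the genotypes carrying ``allele``.

    ``genotype_freqs`` is the 16 x 16 ordered genotype-frequency matrix
    (summing to 1).  With c_ij the copy number (0, 1 or 2) of the allele in
    genotype (i, j), the marginal fitness is

        sum_ij f_ij w_ij c_ij / sum_ij f_ij c_ij .

    Returns NaN when the allele is absent from the population.  For a
    monomorphic population this reduces to the fitness of the single
    genotype present.
    """
    F = np.asarray(genotype_freqs, dtype=float)
    if F.shape != (N_HAPLOTYPES, N_HAPLOTYPES):
        raise ValueError("genotype_freqs must be a 16 x 16 matrix")
    locus, derived = _allele_to_locus(allele)
    carrier = ALLELES[:, locus] if derived else 1 - ALLELES[:, locus]
    C = carrier[:, None] + carrier[None, :]  # copy number per ordered genotype
    W = fitness_landscape(params)
    denom = float((F * C).sum())
    if denom <= 0.0:
        return float("nan")
    return float((F * W * C).sum() / denom)
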