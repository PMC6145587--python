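# Methods

## Model

`dmisort` simulates a single isolated population of `N` diploids in
discrete, non-overlapping generations. Four diallelic loci `A1, B1, A2, B2`
carry derived alleles (upper-case) introduced by two parental populations:
parental 1 is fixed for `A1b1A2b2`, parental 2 for `a1B1a2B2`. Derived
`A_k` and `B_k` are the two partners of incompatibility `k` (negative
pairwise epistasis); the two-locus sub-model (a single DMI) is the special
case in which the loci of the second DMI never segregate
(`single_dmi_config`).

Genotype fitness is multiplicative over loci and DMIs:

    w_ij = prod_k (1+alpha_k)^X_k (1+beta_k)^Y_k (1+phi_k(n_k) eps_k)^(n_k)

with `X_k`, `Y_k` the derived-allele dosages of the genotype at the loci of
DMI `k` and `n_k = X_k Y_k` the number of incompatible allele pairs
(0, 1, 2 or 4 — the classical H0/H1/H2 dominance classes correspond to
n = 1, 2, 4). The dominance table `phi(n)` applies to the epistasis only;
direct effects are always multiplicative. Two presets cover the cases of
interest: codominant (`phi = 1` everywhere) and recessive (`phi(1) = 0`:
the F1 double heterozygote is masked). Arbitrary tables in [0, 1] are
accepted since intermediate dominance is biologically possible, but only
the presets are exercised by the test suite. `eps` is validated to
(-1, 0]: the model space is negative epistasis with strictly positive
fitness; -0.99 serves as the quasi-lethal extreme.

### Life cycle

1. **Soft selection / gamete pool.** Parents contribute gametes in
   proportion to genotype frequency times fitness, normalized by mean
   fitness. Population size is constant (no hard selection).
2. **Meiosis.** A linkage architecture orders the four loci along a
   chromosome and assigns each of the three adjacent intervals a
   recombination rate `r in [0, 0.5]`. Crossovers occur independently per
   interval (no interference), which makes the non-adjacent rate obey the
   composite rule `r_XY = r_XW(1-r_WY) + r_WY(1-r_XW)`. Loci on different
   chromosomes are encoded by interior rates of 0.5. Exactly six
   architectures exist up to chromosome reversal, DMI-index exchange and
   joint A/B role exchange; the package names them Adjacent/Crossed/Nested
   x letter pattern and verifies the enumeration by exhausting all 24
   orders. Haplotype labels are always written in model order
   `A1 B1 A2 B2`; chromosomal order lives only in the architecture.
3. **Zygote sampling.** The stochastic step draws the N zygotes as one
   multinomial over ordered gamete pairs with cell probabilities
   `pool_i * pool_j`. This is distributionally identical to drawing 2N
   gametes from the pool and pairing them sequentially (i.i.d. gametes make
   the pairs i.i.d.), and both views are equivalent to the textbook
   Wright-Fisher scheme. The deterministic (N -> infinity) recursion skips
   the sampling: next-generation genotype frequencies are the random-union
   product of pool frequencies.

### Initial conditions and termination

The founding population consists of `round(N * i_p)` parental-1
homozygotes and the remainder parental-2 homozygotes (deterministic
rounding — `i_p` is treated as an exact contribution; at small N this
quantizes `i_p`, and a start that rounds to monomorphism triggers a
warning). An optional three-genotype variant puts both parental
homozygotes at fraction `i_q` each over an ancestral-homozygote background.

Stochastic runs end when one haplotype reaches count 2N; loss and fixation
are detected on exact integer counts, with no tolerance. Deterministic
runs end when the leading haplotype frequency exceeds `1 - 1e-8`, with a
cap of 1e6 generations after which the run reports the explicit outcome
"unresolved" (the recursion has no intrinsic stopping rule, so the package
supplies one; the threshold is far below any frequency reachable by drift
at the population sizes of interest and far above the accumulation of
float error per generation).

## Observables

DMI `k` is **resolved** at the first generation where derived `A_k` or
`B_k` is absent (frequency below 1e-8 in deterministic runs). **Hybrid
speciation** is the fixation of `A1b1a2B2` or `a1B1A2b2` — each carries one
incompatibility against either parent. The 16 haplotypes partition by
allele content into ancestral / parental-1 / parental-2 / hybrid (2) /
epistasis-free F2 (4, one derived allele) / first-DMI (3) / second-DMI (3)
/ doubly incompatible classes; the partition depends only on allele
content, not on the architecture.

Replicate statistics use exact Clopper-Pearson binomial intervals (95% by
default). Conditional mean times (e.g. time to hybrid speciation) are
withheld for outcome classes with fewer than 4 events, where a mean is
noise. The independent-DMI prediction converts single-DMI fixation
frequencies into the probability that two independent DMIs sort
reciprocally, `2 P(Ab) P(aB)`.

**Marginal allele fitness** has no unique definition for diploids; the
package uses the dosage-weighted mean fitness of carrier genotypes,
`sum f_ij w_ij c_ij / sum f_ij c_ij` with `c_ij` the allele's copy number.
This reduces to the genotype fitness in a monomorphic population, returns
NaN for an absent allele, and reproduces the expected qualitative ordering
of early-generation marginal fitnesses across architectures (e.g. `A2`,
`B1` advantaged under Adjacent ABAB; `A1`, `A2` under Adjacent ABBA).

## Stability of the hybrid equilibrium

Local stability of a monomorphic resident (normally a sorted hybrid) is
assessed numerically: seed the deterministic recursion with an invading
haplotype at `delta = 1e-6`, iterate up to 200 generations, and fit the
per-generation geometric growth factor from the tail of the trajectory
(mean successive log-ratio over the second half, stopping early if the
invading material exceeds 1e-3 or underflows). The fitted quantity is the
**total frequency of alleles absent from the resident** rather than the
literal invader-haplotype frequency: at first order in `delta` this is the
linear invading subsystem whose dominant eigenvalue governs invasion,
whereas the invader haplotype itself is a second-order quantity that
recombination erodes even under complete neutrality. Under this definition
the fully neutral model gives growth exactly 1 (flagged "marginal" within
1e-6), and the verdict — stable iff all 15 invaders decline — is
independent of the dominance scheme, because a rare invader facing a
homozygous resident only ever forms n = 0 or n = 2 incompatible pairs,
never the masked double-heterozygote class.

## Introgression barrier

The barrier strength of the sorted hybrid population is the fixation
probability of a neutral marker carried by a single parental migrant. The
marker sits on its own chromosome (rate 0.5 to all selected loci), doubling
the state space to 32 marked haplotypes; the marked transmission tensor
factorizes into selected-loci meiosis times independent assortment, and the
marked system reduces exactly to the 16-haplotype engine when the marker is
monomorphic (tested). The migrant, homozygous for a parental haplotype and
the marker, replaces one resident immediately before selection, keeping N
constant (the replacement rule is the package's choice; with identical
residents the "uniformly chosen" victim is immaterial). Runs continue to
marker loss or fixation. The reference is `p_n = 2/(2N) = 1/N`, the
fixation probability of the same marker appearing in a resident; deviation
is tested with an exact binomial test, Bonferroni-corrected across the
cells of whatever parameter grid the experiment is part of (the correction
count is recorded in the output, since the appropriate denominator is the
user's own grid size). The default replicate count is 1e5 per cell,
a 10x scale-down of the published experiment, with CIs reported.

## Reproducibility and seeding

All randomness flows from one base seed through `numpy` `SeedSequence`
spawning: replicate `i` of a run uses child `i`, and sweep cell `j` uses
`SeedSequence(base_seed, spawn_key=(j,))`, so any replicate or cell can be
re-run in isolation and full sweeps are bit-reproducible. Sweep TSVs carry
a `#`-comment header with the full configuration, seed and package
version; sweeps resume per finished cell, and a failing cell is reported
in its row without aborting the sweep.

## Test statistics and problem sizes

The simulator itself is the study's data generator; tests run it at the
published parameter values (s = 0.001, eps = -0.2 or -0.99, i_p = 0.5,
N = 50 … 50000) with replicate counts chosen per check: 1000 replicates
for the N = 50 timing and the quasi-lethal check, 50 replicates at
N = 50000 (where hybrid speciation is nearly certain and times vary
little), 300 replicates per grid point for the recombination-optimum
curve, 500-800 replicates for directional contrasts, and 1e5 single-locus
replicates for the neutral baseline. Exact invariants (LD decay by (1-r)
per generation, Mendelian marginals, symmetry relabelings, the composite
recombination rule) are asserted to float precision against independent
enumeration oracles. Monte-Carlo assertions under fixed seeds use wide
intervals (3-4 sigma, or 99.9% exact CIs) so that a correct implementation
fails only with negligible probability while real biases are still caught.

## Known limitations

- No mutation, no recurrent migration, no ecological selection: the model
  isolates the purging dynamics of a one-time admixture event.
- Constant N (soft selection). Purging-induced population decline, which
  would make hybrid speciation rarer, is outside the model.
- No crossover interference, no sex differences in recombination; at most
  the four selected loci plus one neutral marker.
- The stability analysis is numeric; no closed-form stability condition is
  provided.
- Timing results at large N are dominated by the final fixation sweep of
  weakly selected alleles (s = 0.001), so reported "time to hybrid
  speciation" means are sensitive to nothing else the model does after
  resolution; they agree with single-locus sweep-time oracles.
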