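"""Engine: initialization, gamete pool, deterministic and stochastic steps,
and whole-replicate runs, checked against classical population-genetic
oracles (LD decay, neutral fixation, sampling distributions)."""

import numpy as np
import pytest
from scipy import stats

from dmisort import (
    FitnessParams,
    LinkageArchitecture,
    OutcomeRecord,
    PARENTAL1,
    PARENTAL2,
    SimulationConfig,
    gamete_pool,
    initialize_population,
    run_replicate,
    run_replicates,
    single_dmi_config,
    step_deterministic,
    step_stochastic,
)
from dmisort.haplotypes import ALLELES, ANCESTRAL


class TestInitialization:
    def test_symmetric_split(self, default_params):
        config = SimulationConfig(params=default_params, N=100, i_p=0.5)
        state = initialize_population(config)
        assert state.geno[PARENTAL1, PARENTAL1] == 50
        assert state.geno[PARENTAL2, PARENTAL2] == 50
        assert state.geno.sum() == 100

    def test_single_parent_is_monomorphic(self, default_params):
        config = SimulationConfig(params=default_params, N=100, i_p=1.0)
        state = initialize_population(config)
        assert state.monomorphic
        assert state.haplotype_freqs[PARENTAL1] == 1.0

    def test_three_genotype_variant(self, default_params):
        """i_q start: both parental homozygotes at i_q, ancestral at 1 - 2 i_q."""
        config = single_dmi_config(0.1, params=default_params, N=100, i_q=0.2)
        state = initialize_population(config)
        assert state.geno[8, 8] == 20  # A1b1a2b2 homozygote
        assert state.geno[4, 4] == 20  # a1B1a2b2 homozygote
        assert state.geno[ANCESTRAL, ANCESTRAL] == 60

    def test_degenerate_rounding_warns(self, default_params):
        config = SimulationConfig(params=default_params, N=100, i_p=0.001)
        with pytest.warns(UserWarning, match="monomorphic start"):
            initialize_population(config)

    def test_deterministic_frequencies(self, default_params):
        config = SimulationConfig(params=default_params, N=None, i_p=0.3)
        state = initialize_population(config)
        assert state.geno[PARENTAL1, PARENTAL1] == pytest.approx(0.3)
        assert state.geno.sum() == pytest.approx(1.0)

    def test_invalid_ip_rejected(self, default_params):
        with pytest.raises(ValueError):
            SimulationConfig(params=default_params, i_p=1.2)


class TestGametePool:
    def test_monomorphic_pool_is_point_mass(self, default_params):
        config = SimulationConfig(params=default_params, N=100, i_p=1.0)
        state = initialize_population(config)
        pool = gamete_pool(state, default_params, config.arch)
        assert pool[PARENTAL1] == pytest.approx(1.0)

    def test_neutral_pool_conserves_allele_frequencies(self, neutral_params):
        config = SimulationConfig(
            params=neutral_params,
            arch=LinkageArchitecture.equidistant("Adjacent ABAB", 0.2),
            N=None,
            i_p=0.3,
        )
        state = initialize_population(config)
        pool = gamete_pool(state, neutral_params, config.arch)
        assert np.allclose(pool @ ALLELES, state.haplotype_freqs @ ALLELES)

    @pytest.mark.parametrize("r", [0.0, 0.1, 0.3, 0.5])
    def test_neutral_ld_decay_per_generation(self, neutral_params, r):
        """Classical result: once the population mates at random (from the
        first offspring generation onward), two-locus linkage disequilibrium
        decays exactly by (1 - r) per generation in the neutral model.  The
        founding homozygotes themselves transmit their haplotypes unchanged."""
        config = single_dmi_config(r, params=neutral_params, N=None, i_p=0.5)
        state = initialize_population(config)

        def ld(p):
            # loci A1, B1; D = p(AB) p(ab) - p(Ab) p(aB)
            A = ALLELES[:, 0].astype(bool)
            B = ALLELES[:, 1].astype(bool)
            return p[A & B].sum() * p[~A & ~B].sum() - p[A & ~B].sum() * p[~A & B].sum()

        assert ld(state.haplotype_freqs) == pytest.approx(-0.25)
        # founders are homozygous: the first gamete pool keeps D unchanged
        state = step_deterministic(state, neutral_params, config.arch)
        d = ld(state.haplotype_freqs)
        assert d == pytest.approx(-0.25)
        for _ in range(3):
            state = step_deterministic(state, neutral_params, config.arch)
            d_next = ld(state.haplotype_freqs)
            assert d_next == pytest.approx((1 - r) * d, abs=1e-14)
            d = d_next


class TestSteps:
    def test_monomorphic_is_deterministic_fixed_point(self, default_params):
        config = SimulationConfig(params=default_params, N=None, i_p=1.0)
        state = initialize_population(config)
        nxt = step_deterministic(state, default_params, config.arch)
        assert np.allclose(nxt.geno, state.geno)
        assert nxt.t == 1

    def test_point_mass_pool_gives_monomorphic_offspring(self, default_params, rng):
        config = SimulationConfig(params=default_params, N=500, i_p=1.0)
        state = initialize_population(config)
        nxt = step_stochastic(state, default_params, config.arch, rng)
        assert nxt.monomorphic

    def test_counts_sum_to_n(self, default_params, rng):
        config = SimulationConfig(params=default_params, N=777, i_p=0.4)
        state = initialize_population(config)
        nxt = step_stochastic(state, default_params, config.arch, rng)
        assert nxt.geno.sum() == 777
        assert (nxt.geno >= 0).all()

    def test_one_step_mean_matches_deterministic(self, default_params, rng):
        """Averaged over many draws, the stochastic step reproduces the
        deterministic recursion (law of large numbers)."""
        arch = LinkageArchitecture.equidistant("Adjacent ABAB", 0.1)
        config = SimulationConfig(params=default_params, arch=arch, N=200, i_p=0.5)
        state = initialize_population(config)
        pool = gamete_pool(state, default_params, arch)
        n_draws = 3000
        acc = np.zeros(16)
        for _ in range(n_draws):
            acc += step_stochastic(state, default_params, arch, rng).haplotype_freqs
        mean = acc / n_draws
        se = np.sqrt(pool * (1 - pool) / (2 * 200 * n_draws))
        assert (np.abs(mean - pool) < 4 * se + 1e-12).all()

    def test_small_n_genotype_distribution_matches_multinomial(
        self, neutral_params, rng
    ):
        """One stochastic generation at N = 2 follows the exact multinomial
        over ordered gamete pairs (chi-square against enumerated pmf)."""
        config = single_dmi_config(0.0, params=neutral_params, N=2, i_p=0.5)
        state = initialize_population(config)
        pool = gamete_pool(state, neutral_params, config.arch)
        probs = np.outer(pool, pool).ravel()
        counts = np.zeros(256)
        n_draws = 4000
        for _ in range(n_draws):
            nxt = step_stochastic(state, neutral_params, config.arch, rng)
            # genotype of the first of the two individuals: sample a cell
            flat = nxt.geno.ravel()
            counts += flat / 2
        keep = probs > 0
        chi2 = ((counts[keep] - n_draws * probs[keep]) ** 2 / (n_draws * probs[keep])).sum()
        crit = stats.chi2.ppf(0.999, keep.sum() - 1)
        assert chi2 < crit


class TestRunReplicate:
    def test_monomorphic_start_fixes_immediately(self, default_params):
        config = SimulationConfig(params=default_params, N=50, i_p=1.0)
        rec = run_replicate(config, rng=0)
        assert rec.fixed_haplotype == PARENTAL1
        assert rec.fixation_time == 0
        assert rec.outcome == "parental-1"
        assert not rec.hybrid_speciation
        assert rec.resolution_times == (0, 0)

    def test_two_locus_resolution_time_zero_for_absent_dmi(self, default_params):
        config = single_dmi_config(0.1, params=default_params, N=100)
        rec = run_replicate(config, rng=1)
        assert rec.resolution_times[1] == 0  # loci of DMI 2 never segregate

    def test_resolution_before_fixation(self, default_params):
        config = SimulationConfig(
            params=default_params,
            arch=LinkageArchitecture.equidistant("Adjacent ABAB", 0.1),
            N=100,
        )
        for rec in run_replicates(config, 20, base_seed=3):
            assert rec.fixation_time is not None
            for rt in rec.resolution_times:
                assert rt is not None and rt <= rec.fixation_time

    def test_deterministic_goldilocks_fixes_hybrid(self, default_params):
        config = SimulationConfig(
            params=default_params,
            arch=LinkageArchitecture.equidistant("Adjacent ABAB", 0.1),
            N=None,
        )
        rec = run_replicate(config)
        assert rec.outcome == "hybrid"

    def test_deterministic_adjacent_abba_fixes_parental(self, default_params):
        config = SimulationConfig(
            params=default_params,
            arch=LinkageArchitecture.equidistant("Adjacent ABBA", 0.1),
            N=None,
        )
        rec = run_replicate(config)
        assert rec.fixed_haplotype == PARENTAL1

    def test_deterministic_cap_reports_unresolved(self, default_params):
        config = SimulationConfig(
            params=default_params,
            arch=LinkageArchitecture.equidistant("Adjacent ABAB", 0.1),
            N=None,
            max_generations=5,
        )
        rec = run_replicate(config)
        assert rec.outcome == "unresolved"
        assert rec.fixed_haplotype is None

    def test_trajectory_recording(self, default_params):
        config = SimulationConfig(params=default_params, N=80)
        rec = run_replicate(config, rng=5, record_trajectory=True)
        assert rec.trajectory is not None
        assert rec.trajectory.shape == (rec.n_generations + 1, 16)
        assert np.allclose(rec.trajectory.sum(axis=1), 1.0)

    def test_neutral_fixation_probability_equals_initial_frequency(
        self, neutral_params
    ):
        """Neutral Wright-Fisher oracle: a haplotype at initial frequency p
        fixes with probability p (single segregating locus)."""
        config = SimulationConfig(
            params=neutral_params,
            N=100,
            i_p=0.3,
            parental_haplotypes=(8, ANCESTRAL),  # differ at locus A1 only
        )
        records = run_replicates(config, 800, base_seed=9)
        k = sum(r.fixed_haplotype == 8 for r in records)
        se = np.sqrt(0.3 * 0.7 / 800)
        assert abs(k / 800 - 0.3) < 3.5 * se

    def test_replicates_reproducible(self, default_params):
        config = SimulationConfig(params=default_params, N=60)
        a = run_replicates(config, 5, base_seed=11)
        b = run_replicates(config, 5, base_seed=11)
        assert [r.fixed_haplotype for r in a] == [r.fixed_haplotype for r in b]
        assert [r.fixation_time for r in a] == [r.fixation_time for r in b]

    def test_parental_exchange_symmetry_deterministic(self, default_params):
        """Relabeling parental roles (A<->B with DMI index swap) and mapping
        i_p -> 1 - i_p leaves the deterministic dynamics invariant up to the
        haplotype permutation."""
        arch = LinkageArchitecture.equidistant("Adjacent ABAB", 0.1)
        perm = np.array(
            [8 * (h & 1) + 4 * ((h >> 1) & 1) + 2 * ((h >> 2) & 1) + ((h >> 3) & 1)
             for h in range(16)]
        )  # A1<->B2, B1<->A2 (bit reversal)
        c1 = SimulationConfig(params=default_params, arch=arch, N=None, i_p=0.35)
        c2 = SimulationConfig(params=default_params, arch=arch, N=None, i_p=0.65)
        s1, s2 = initialize_population(c1), initialize_population(c2)
        for _ in range(40):
            s1 = step_deterministic(s1, default_params, arch)
            s2 = step_deterministic(s2, default_params, arch)
            assert np.allclose(s1.haplotype_freqs, s2.haplotype_freqs[perm])

    def test_stop_at_resolution(self, default_params):
        config = single_dmi_config(0.5, params=default_params, N=100)
        rec = run_replicate(config, rng=2, stop_at="resolution")
        assert rec.resolution_times[0] is not None
        assert rec.n_generations == rec.resolution_times[0]
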