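"""Unit and property tests for the agent-based simulator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from culturesim import EXTINCT, ParameterSet, TransmissionMode, run_simulation
from culturesim.simulate import (demographic_step, initialize_population,
                                 mutate, partner_set, transmission_step,
                                 variant_choice_probabilities)

from conftest import make_population
from _oracles import (enumerate_one_step_transmission, total_variation)


class TestInitialization:
    def test_founders_are_monomorphic(self, rng):
        pop = initialize_population(ParameterSet(N=50), rng)
        assert pop.size == 50
        assert (pop.variants == 1).all()
        assert (pop.parents == -1).all()

    def test_single_individual(self, rng):
        pop = initialize_population(ParameterSet(N=1), rng)
        assert pop.size == 1 and pop.variants.shape == (5, 1)

    def test_age_groups_uniform(self, rng):
        # each group ~ Binomial(N, 1/5); check within 4 sigma at N=10000
        pop = initialize_population(ParameterSet(N=10_000), rng)
        sigma = np.sqrt(10_000 * 0.2 * 0.8)
        assert np.all(np.abs(pop.age_counts - 2000) < 4 * sigma)
        assert pop.age_counts.sum() == 10_000


class TestPartnerSets:
    def test_vertical_has_no_lifetime_partners(self):
        pop = make_population([1, 2, 3])
        assert partner_set(pop, 0, "vertical").size == 0

    def test_mixed_resolves_per_event(self):
        pop = make_population([1, 2, 3])
        with pytest.raises(ValueError):
            partner_set(pop, 0, "mixed")

    def test_oldest_individual_has_no_oblique_partners(self):
        pop = make_population([5, 5, 3])
        assert partner_set(pop, 0, "oblique").size == 0

    def test_sole_member_of_age_group_has_no_horizontal_partners(self):
        pop = make_population([2, 3, 3, 4])
        assert partner_set(pop, 0, "horizontal").size == 0

    def test_oblique_excludes_parent_brute_force(self):
        # N=10: focal 0 in group 2 with living parent (index 5) in group 4
        ages = [2, 1, 2, 3, 3, 4, 4, 5, 5, 5]
        parents = [5, -1, -1, -1, -1, -1, -1, -1, -1, -1]
        pop = make_population(ages, parents)
        got = set(partner_set(pop, 0, "oblique"))
        expected = {j for j in range(10) if ages[j] > 2} - {5}
        assert got == expected

    def test_age_neutral_is_everyone_but_self(self):
        pop = make_population([1, 2, 3, 4, 5])
        assert set(partner_set(pop, 2, "age_neutral")) == {0, 1, 3, 4}


class TestChoiceProbabilities:
    def test_unbiased_equals_partner_frequencies(self):
        partners = np.array([1, 1, 2, 2, 2])
        probs = variant_choice_probabilities(partners, k_hat=2, b=0.0)
        assert np.allclose(probs, [0.4, 0.6, 0, 0, 0])

    @given(st.floats(min_value=0, max_value=0.05),
           st.integers(min_value=1, max_value=5))
    @settings(derandomize=True, max_examples=30)
    def test_uniform_frequencies_are_a_fixed_point(self, b, k_hat):
        # at the relative majority 1/k_hat the conformity term vanishes
        partners = np.repeat(np.arange(1, k_hat + 1), 12)
        probs = variant_choice_probabilities(partners, k_hat=k_hat, b=b)
        expected = np.zeros(5)
        expected[:k_hat] = 1.0 / k_hat
        assert np.allclose(probs, expected)

    def test_conformity_weight_direct_evaluation(self):
        # frequencies (0.5, 0.3, 0.2), k_hat=5, b=0.02:
        # raw weights 0.53, 0.31, 0.20; absent variants clamp from -0.02 to 0
        partners = np.array([1] * 5 + [2] * 3 + [3] * 2)
        probs = variant_choice_probabilities(partners, k_hat=5, b=0.02)
        raw = np.array([0.53, 0.31, 0.20, 0.0, 0.0])
        assert np.allclose(probs, raw / raw.sum())

    def test_empty_partner_set_rejected(self):
        with pytest.raises(ValueError):
            variant_choice_probabilities(np.array([], int), k_hat=1, b=0.0)


class TestMutation:
    def test_faithful_copy_at_mu_zero(self, rng):
        assert all(mutate(v, 0.0, rng) == v for v in range(1, 6))

    def test_full_mutation_is_uniform(self, rng):
        draws = np.array([mutate(3, 1.0, rng) for _ in range(100_000)])
        freqs = np.bincount(draws, minlength=6)[1:] / draws.size
        sigma = np.sqrt(0.2 * 0.8 / draws.size)
        assert np.all(np.abs(freqs - 0.2) < 4 * sigma)

    def test_retention_probability(self, rng):
        # retention = 1 - mu + mu/5 = 0.92 at mu = 0.1
        draws = np.array([mutate(3, 0.1, rng) for _ in range(100_000)])
        retained = np.mean(draws == 3)
        sigma = np.sqrt(0.92 * 0.08 / draws.size)
        assert abs(retained - 0.92) < 4 * sigma

    def test_exclude_current_universe(self, rng):
        draws = np.array([mutate(3, 1.0, rng, include_current=False)
                          for _ in range(20_000)])
        assert not (draws == 3).any()
        freqs = np.bincount(draws, minlength=6)[[1, 2, 4, 5]] / draws.size
        assert np.all(np.abs(freqs - 0.25) < 4 * np.sqrt(0.25 * 0.75 / draws.size))


class TestDemography:
    def test_all_in_oldest_group_goes_extinct(self):
        pop = make_population([5] * 8)
        assert demographic_step(pop, ParameterSet(N=8), seed=0) is EXTINCT

    def test_no_hazard_deaths_at_p_death_zero(self):
        pop = make_population([1, 2, 3, 4] * 5)
        out = demographic_step(pop, ParameterSet(N=20, p_death=0.0), seed=1)
        assert out.size == 20
        # ageing only: original cohort all advanced one class, no newborns
        assert (out.age_counts == [0, 5, 5, 5, 5]).all()

    def test_hazard_death_fraction_binomial(self):
        # fixed cohort in group 2 (nobody ages out); survivors are exactly
        # those found in group 3 afterwards
        n, p_death = 2000, 0.1
        params = ParameterSet(N=n, p_death=p_death)
        survived = 0
        for seed in range(10):
            pop = make_population([2] * n)
            out = demographic_step(pop, params, seed=seed)
            survived += int((out.ages == 3).sum())
        total = 10 * n
        died = total - survived
        sigma = np.sqrt(total * p_death * (1 - p_death))
        assert abs(died - total * p_death) < 4 * sigma

    def test_newborns_inherit_parent_variants(self):
        # slot s fixed on variant s+1 for everyone; with mu=0, newborns
        # replacing the aged-out group-5 cohort must keep that pattern
        variants = (np.arange(1, 6)[:, None] * np.ones((1, 6), np.int64))
        pop = make_population([2, 2, 2, 5, 5, 5], variants=variants)
        out = demographic_step(pop, ParameterSet(N=6, mu=0.0, p_death=0.0),
                               seed=3)
        assert out.size == 6
        assert (out.variants == variants).all()
        assert (out.age_counts == [3, 0, 3, 0, 0]).all()

    def test_age_pyramid_emerges(self, small_params):
        # with a positive hazard the long-run mean age structure is monotone
        params = small_params.replace(N=100)
        pop = initialize_population(params, np.random.default_rng(0))
        totals = np.zeros(5)
        steps = 1200
        for t in range(steps):
            out = demographic_step(pop, params, seed=10_000 + t)
            assert out is not EXTINCT
            pop = transmission_step(out, params, seed=50_000 + t)
            if t >= 200:
                totals += pop.age_counts
        means = totals / (steps - 200)
        assert np.all(np.diff(means) < 0), f"not pyramid-shaped: {means}"


class TestTransmissionStep:
    def test_no_interactions_at_p_w_zero(self, rng):
        params = ParameterSet(N=40, p_w=0.0)
        pop = initialize_population(params, rng)
        pop.variants[:] = rng.integers(1, 6, pop.variants.shape)
        out = transmission_step(pop, params, seed=4)
        assert (out.variants == pop.variants).all()

    def test_monomorphic_is_absorbing_without_mutation(self, rng):
        params = ParameterSet(N=40, mu=0.0, p_w=1.0, b=0.02)
        pop = initialize_population(params, rng)
        out = transmission_step(pop, params, seed=5)
        assert (out.variants == 1).all()

    def test_vertical_slot_never_changes_in_lifetime(self, rng):
        params = ParameterSet(N=40, mu=1.0, p_w=1.0)
        pop = initialize_population(params, rng)
        out = transmission_step(pop, params, seed=6)
        assert (out.variants[0] == pop.variants[0]).all()
        assert not (out.variants[1:] == pop.variants[1:]).all()

    @pytest.mark.parametrize("rule,slot,ages,parents", [
        ("h", 1, [2, 2, 2, 2], None),
        ("o", 2, [1, 2, 3, 3], [2, -1, -1, -1]),
        ("n", 3, [1, 2, 3, 4], None),
    ])
    def test_one_step_matches_exhaustive_enumeration(self, rule, slot, ages,
                                                     parents):
        """Brute-force oracle over all orders and partner choices, mu=0."""
        p_w = 0.7
        start = [1, 1, 2, 2]
        exact = enumerate_one_step_transmission(ages, parents or [-1] * 4,
                                                start, rule, p_w)
        params = ParameterSet(N=4, mu=0.0, p_w=p_w)
        reps = 40_000
        observed: dict[tuple, float] = {}
        variants = np.ones((5, 4), np.int64)
        variants[slot] = start
        for seed in range(reps):
            pop = make_population(ages, parents or None, variants.copy())
            out = transmission_step(pop, params, seed=seed)
            key = tuple(np.bincount(out.variants[slot], minlength=6)[1:])
            observed[key] = observed.get(key, 0.0) + 1.0 / reps
        assert total_variation(exact, observed) < 0.02


class TestFullRuns:
    def test_counts_conserved_every_step(self, small_params):
        traj = run_simulation(small_params, seed=2)
        assert traj
        assert (traj.counts.sum(axis=2) == small_params.N).all()

    def test_monomorphic_absorbing_full_run(self, small_params):
        traj = run_simulation(small_params.replace(mu=0.0), seed=3)
        assert (traj.counts[:, :, 0] == small_params.N).all()
        assert (traj.counts[:, :, 1:] == 0).all()

    def test_seed_determinism_bit_identical(self, small_params):
        a = run_simulation(small_params, seed=11)
        b = run_simulation(small_params, seed=11)
        assert np.array_equal(a.counts, b.counts)
        assert np.array_equal(a.final_age_counts, b.final_age_counts)
        c = run_simulation(small_params, seed=12)
        assert not np.array_equal(a.counts, c.counts)

    def test_certain_death_goes_extinct(self):
        params = ParameterSet(N=10, p_death=1.0, burn_in_steps=0,
                              recorded_steps=10)
        assert run_simulation(params, seed=0) is EXTINCT
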