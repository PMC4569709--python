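"""Coda transmission mechanisms, biases, innovation and the scenario grid."""

import numpy as np
import pytest
from dataclasses import replace

from codaclans import DemographyParams, Scenario, scenario_grid
from codaclans.demography import CALF_AGE_LIMIT, step_year
from codaclans.experiments import initialize_run
from codaclans.learning import (
    LEVELS,
    SYMBOL_SIZE,
    assign_symbols,
    individual_learning,
    inherit_from_mother,
    innovate,
    oblique_learn,
    tutor_pool,
)


class TestScenarioGrid:
    def test_twenty_distinct_scenarios(self):
        grid = scenario_grid()
        assert len(grid) == 20
        assert [s.abm_id for s in grid] == list(range(1, 21))
        combos = {(s.mechanism, s.biases, s.level) for s in grid}
        assert len(combos) == 20, "grid must be a bijection onto distinct configurations"

    def test_null_models(self):
        grid = scenario_grid()
        assert grid[0].mechanism == "individual" and not grid[0].biases
        assert grid[1].mechanism == "genetic" and not grid[1].biases

    @pytest.mark.parametrize(
        "abm_id, biases",
        [
            (3, frozenset()),
            (6, frozenset({"homophily"})),
            (9, frozenset({"conformism"})),
            (12, frozenset({"symbolic"})),
            (15, frozenset({"homophily", "conformism"})),
            (18, frozenset({"homophily", "symbolic"})),
        ],
    )
    def test_bias_blocks(self, abm_id, biases):
        for offset, level in enumerate(LEVELS):
            s = Scenario.from_abm_id(abm_id + offset)
            assert s.mechanism == "oblique"
            assert s.biases == biases
            assert s.level == level

    def test_predefined_clans_only_at_clan_level(self):
        for s in scenario_grid():
            if s.level == "predefined_clan":
                assert s.predefined_clans == 3
            else:
                assert s.predefined_clans is None

    @pytest.mark.parametrize("bad", [0, 21, -3])
    def test_out_of_range_abm_id(self, bad):
        with pytest.raises(ValueError):
            Scenario.from_abm_id(bad)

    def test_inconsistent_scenarios_rejected(self):
        with pytest.raises(ValueError):
            Scenario(3, "oblique")  # oblique needs a level
        with pytest.raises(ValueError):
            Scenario(1, "individual", level="unit")
        with pytest.raises(ValueError):
            Scenario(1, "individual", ilearn=1.5)


class TestIndividualLearning:
    def test_half_fill_at_initialization(self, rng):
        rep = individual_learning(np.zeros(62), rng=rng)
        assert np.count_nonzero(rep >= 0) == 62
        assert (rep > 0).sum() <= 31
        # 31 elements were drawn (a draw may be ~0 with tiny probability)
        assert rep.max() <= 100 and rep.min() >= 0

    def test_zero_fill_fraction_keeps_repertoire(self, rng):
        rep = individual_learning(np.zeros(62), fill_fraction=0.0, rng=rng)
        assert np.all(rep == 0)

    def test_fixed_repertoire_warns_and_noop(self, rng):
        rep = np.full(62, 7.0)
        with pytest.warns(RuntimeWarning):
            out = individual_learning(rep, rng=rng, fixed=True)
        assert np.all(out == 7.0)


class TestGeneticInheritance:
    def test_exact_copy(self):
        mother = np.linspace(0, 100, 62)
        calf = inherit_from_mother(np.zeros(62), mother)
        assert np.array_equal(calf, mother)

    def test_missing_mother_is_error(self):
        with pytest.raises(ValueError):
            inherit_from_mother(np.zeros(62), None)

    def test_perfect_heredity_limit(self):
        """In the genetic scenario with innovation off, a fixed calf equals its mother."""
        scenario = replace(Scenario.from_abm_id(2), ilearn=0.0)
        pop = initialize_run(scenario, DemographyParams(n0=200), np.random.default_rng(3))
        rng = np.random.default_rng(3)
        mother_of = {}
        for _ in range(8):
            step_year(pop, scenario, rng)
            for i in range(pop.n):
                aid = int(pop.ids[i])
                mid = int(pop.mother_id[i])
                if mid >= 0 and aid not in mother_of:
                    j = int(np.searchsorted(pop.ids, mid))
                    if j < pop.n and pop.ids[j] == mid:
                        mother_of[aid] = pop.repertoires[j].copy()
        checked = 0
        for i in range(pop.n):
            aid = int(pop.ids[i])
            if pop.repertoire_fixed[i] and aid in mother_of and pop.age[i] in (3, 4, 5):
                assert np.array_equal(pop.repertoires[i], mother_of[aid])
                checked += 1
        assert checked > 0


class TestInnovation:
    def test_default_rate_replaces_one_element(self, rng):
        rep = np.zeros(62)
        innovate(rep, ilearn=0.02, rng=rng)
        assert np.count_nonzero(rep) <= 1  # one draw, possibly ~0
        rep2 = np.full(62, 50.0)
        innovate(rep2, ilearn=0.02, rng=rng)
        assert (rep2 != 50.0).sum() == 1

    def test_zero_rate_is_identity(self, rng):
        rep = np.full(62, 33.0)
        innovate(rep, ilearn=0.0, rng=rng)
        assert np.all(rep == 33.0)

    def test_values_bounded(self, rng):
        rep = np.zeros(62)
        for _ in range(200):
            innovate(rep, ilearn=0.1, rng=rng)
        assert rep.min() >= 0 and rep.max() <= 100


class TestObliqueLearning:
    def test_single_tutor_full_copy_at_age_zero(self, rng):
        tutor = np.linspace(0, 100, 62)
        rep = oblique_learn(np.zeros(62), 0, tutor[None, :], rng=rng)
        assert np.array_equal(rep, tutor)

    def test_zeroed_elements_are_sampled_too(self, rng):
        tutor = np.zeros(62)
        tutor[:5] = 90.0
        rep = oblique_learn(np.full(62, 50.0), 0, tutor[None, :], rng=rng)
        assert np.all(rep[5:] == 0), "zeros in the tutor repertoire are copied"

    def test_partial_replacement_at_older_ages(self, rng):
        pool = np.full((4, 62), 80.0)
        rep = np.zeros(62)
        oblique_learn(rep, 1, pool, replace_fraction=1 / 3, rng=rng)
        assert (rep == 80.0).sum() == round(62 / 3)

    def test_empty_pool_rejected(self, rng):
        with pytest.raises(ValueError):
            oblique_learn(np.zeros(62), 0, np.empty((0, 62)), rng=rng)
        with pytest.raises(ValueError):
            oblique_learn(np.zeros(62), 5, np.ones((3, 62)), rng=rng)

    def test_conformist_updates_favour_commonest_coda(self, rng):
        """Monte-Carlo: the highest-mean coda is re-sampled most often."""
        pool = np.tile(np.linspace(1, 40, 62), (5, 1))
        pool[:, 5] = 95.0  # coda 5 clearly the most common
        counts = np.zeros(62)
        for _ in range(400):
            rep = np.full(62, -1.0)
            oblique_learn(rep, 1, pool, conformist=True, rng=rng)
            counts += rep != -1.0
        assert counts.argmax() == 5
        # selection frequencies increase with pool mean usage overall
        order = np.argsort(pool.mean(axis=0))
        assert counts[order[-5:]].mean() > counts[order[:5]].mean()

    def test_conformist_copies_pool_consensus(self, rng):
        pool = np.vstack([np.full(62, 20.0), np.full(62, 61.0)])
        rep = np.full(62, -1.0)
        oblique_learn(rep, 2, pool, conformist=True, rng=rng)
        changed = rep != -1.0
        assert np.all(rep[changed] == np.round(pool.mean(axis=0)[changed]))

    def test_zero_exponent_reduces_to_uniform_selection(self, rng):
        """The conformist selection weights flatten at exponent zero."""
        pool = np.tile(np.linspace(1, 100, 62), (3, 1))
        counts = np.zeros(62)
        n_rounds = 600
        for _ in range(n_rounds):
            rep = np.full(62, -1.0)
            oblique_learn(rep, 1, pool, conformist=True, conformity_exponent=0.0, rng=rng)
            counts += rep != -1.0
        expected = n_rounds * round(62 / 3) / 62
        assert np.all(np.abs(counts - expected) < 6 * np.sqrt(expected))


class TestTutorPools:
    def _pop(self, abm_id, n0=240):
        scenario = Scenario.from_abm_id(abm_id)
        pop = initialize_run(scenario, DemographyParams(n0=n0), np.random.default_rng(8))
        return pop, scenario

    def test_unit_level_pool_is_own_unit_adults(self):
        pop, _ = self._pop(4)
        calf = int(np.flatnonzero(pop.age < CALF_AGE_LIMIT)[0])
        pool = tutor_pool(pop, calf, level="unit", homophily=False, rng=np.random.default_rng(0))
        assert pool.size > 0
        assert np.all(pop.unit_id[pool] == pop.unit_id[calf])
        assert np.all(pop.age[pool] >= CALF_AGE_LIMIT)
        assert calf not in pool

    def test_clan_level_pool_is_own_clan_adults(self):
        pop, _ = self._pop(5)
        calf = int(np.flatnonzero(pop.age < CALF_AGE_LIMIT)[0])
        pool = tutor_pool(pop, calf, level="predefined_clan", homophily=False, rng=np.random.default_rng(0))
        assert pool.size > 0
        assert np.all(pop.clan_id[pool] == pop.clan_id[calf])
        assert np.all(pop.age[pool] >= CALF_AGE_LIMIT)

    def test_population_level_pool_is_all_adults(self):
        pop, _ = self._pop(3)
        calf = int(np.flatnonzero(pop.age < CALF_AGE_LIMIT)[0])
        pool = tutor_pool(pop, calf, level="population", homophily=False, rng=np.random.default_rng(0))
        assert pool.size == int((pop.age >= CALF_AGE_LIMIT).sum())

    def test_homophily_pool_adds_most_similar_unit(self):
        pop, _ = self._pop(6)
        calf = int(np.flatnonzero(pop.age < CALF_AGE_LIMIT)[0])
        pool = tutor_pool(pop, calf, level="population", homophily=True, rng=np.random.default_rng(0))
        units = set(int(u) for u in np.unique(pop.unit_id[pool]))
        assert int(pop.unit_id[calf]) in units
        assert len(units) == 2, "own unit plus the single most-similar other unit"


class TestSymbols:
    def test_symbols_are_six_distinct_codas_at_100(self):
        scenario = Scenario.from_abm_id(12)
        pop = initialize_run(scenario, DemographyParams(n0=240), np.random.default_rng(9))
        members = pop.unit_members()
        for uid, symbol in pop.unit_symbol.items():
            assert symbol is not None and len(set(symbol.tolist())) == SYMBOL_SIZE
            idx = members[uid]
            assert np.all(pop.repertoires[np.ix_(idx, symbol)] == 100.0)

    def test_symbols_drawn_independently_per_unit(self):
        scenario = Scenario.from_abm_id(12)
        pop = initialize_run(scenario, DemographyParams(n0=600), np.random.default_rng(10))
        symbols = [tuple(sorted(s.tolist())) for s in pop.unit_symbol.values()]
        assert len(set(symbols)) > 1

    def test_symbol_enforced_after_every_learning_phase(self):
        """Calves always end a learning year holding their unit's symbol.

        Checked right after repertoire composition (migration later in the
        year can move an already-taught agent into a unit with a different
        badge, which is expected: repertoires are personal, badges are not
        relearned by adults).
        """
        from codaclans.demography import births
        from codaclans.learning import compose_repertoires

        scenario = Scenario.from_abm_id(13)
        pop = initialize_run(scenario, DemographyParams(n0=240), np.random.default_rng(11))
        rng = np.random.default_rng(11)
        for _ in range(6):
            births(pop, rng)
            compose_repertoires(pop, scenario, rng)
            members = pop.unit_members()
            for uid, idx in members.items():
                symbol = pop.unit_symbol[uid]
                calves = idx[pop.age[idx] < CALF_AGE_LIMIT]
                assert np.all(pop.repertoires[np.ix_(calves, symbol)] == 100.0)
            step_year(pop, scenario, rng)


class TestComposeLifecycle:
    def test_repertoire_changes_three_years_then_freezes(self):
        """A calf's repertoire changes at ages 0-2 and never afterwards."""
        scenario = Scenario.from_abm_id(1)
        pop = initialize_run(scenario, DemographyParams(n0=300), np.random.default_rng(12))
        rng = np.random.default_rng(12)
        history = {}
        for _ in range(8):
            step_year(pop, scenario, rng)
            for i in range(pop.n):
                aid = int(pop.ids[i])
                history.setdefault(aid, []).append((int(pop.age[i]), pop.repertoires[i].copy()))
        full = [h for h in history.values() if len(h) >= 6 and h[0][0] == 1]
        assert full, "need calves observed from birth year onward"
        for h in full:
            by_age = dict(h)
            changes = [age for age in sorted(by_age) if age + 1 in by_age and not np.array_equal(by_age[age], by_age[age + 1])]
            assert all(age + 1 <= CALF_AGE_LIMIT for age in changes), (
                f"repertoire changed after fixing at ages {changes}"
            )
            for age in sorted(by_age):
                if age > CALF_AGE_LIMIT:
                    assert np.array_equal(by_age[age], by_age[CALF_AGE_LIMIT])

    def test_all_frequencies_stay_bounded(self, small_pop):
        for abm in (1, 2, 9, 15, 19):
            pop, scenario = small_pop(n0=150, abm_id=abm, seed=abm)
            rng = np.random.default_rng(abm)
            for _ in range(12):
                step_year(pop, scenario, rng)
            assert pop.repertoires.min() >= 0
            assert pop.repertoires.max() <= 100
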