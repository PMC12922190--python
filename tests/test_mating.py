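"""Mating avoidance, mate sampling and both OCS solvers."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from breedsim import (
    expected_offspring_inbreeding, expected_offspring_kinship_to_population,
    avoid_matings_quantile, avoid_sib_matings, sample_matings,
    ocs_deterministic, contributions_to_matings, ocs_evolutionary,
    pedigree_kinship,
)
from breedsim.evaluation import KinshipMatrix
from breedsim.genome import Pedigree, MALE, FEMALE
from breedsim.mating import OCSSolution, _largest_remainder, _ea_select_sets


def _toy_pedigree():
    ped = Pedigree()
    ped.add(np.full(4, -1), np.full(4, -1),
            np.array([MALE, MALE, FEMALE, FEMALE]), 0)
    # 4,5 full sibs (0 x 2); 6 half sib of 4 via sire 0; 7 unrelated-ish (1 x 3)
    ped.add(np.array([0, 0, 0, 1]), np.array([2, 2, 3, 3]),
            np.array([MALE, FEMALE, FEMALE, FEMALE]), 1)
    return ped


class TestExpectedOffspring:
    def test_inbreeding_is_parental_kinship(self):
        ped = _toy_pedigree()
        K = pedigree_kinship(ped, np.arange(8))
        assert expected_offspring_inbreeding(0, 3, K) == 0.0
        assert expected_offspring_inbreeding(4, 5, K) == pytest.approx(0.25)
        # parent x own offspring
        assert expected_offspring_inbreeding(0, 5, K) == pytest.approx(0.25)

    def test_kinship_to_population_is_parent_mean(self):
        mk = {1: 0.1, 2: 0.1, 3: 0.2, 4: 0.0}
        assert expected_offspring_kinship_to_population(1, 2, mk) == pytest.approx(0.1)
        assert expected_offspring_kinship_to_population(4, 3, mk) == pytest.approx(0.1)

    def test_matches_simulated_offspring_pedigree_entry(self):
        """Registering the hypothetical offspring and computing its mean
        kinship to the cohort agrees with the parents'-mean shortcut."""
        ped = _toy_pedigree()
        cohort = np.arange(4, 8)
        K = pedigree_kinship(ped, cohort)
        mk = {int(i): float(K.values[r].mean()) for r, i in enumerate(cohort)}
        shortcut = expected_offspring_kinship_to_population(4, 6, mk)
        child = ped.add(np.array([4]), np.array([6]), np.array([MALE]), 2)[0]
        K2 = pedigree_kinship(ped, np.concatenate([cohort, [child]]))
        direct = float(K2.values[-1, :-1].mean())
        assert shortcut == pytest.approx(direct)


class TestQuantileAvoidance:
    def test_ninety_percent_quantile_exclusion_count(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=(400, 100))  # 40,000 distinct pair values
        allowed = avoid_matings_quantile(values, q=0.9)
        assert (~allowed).sum() == 4000

    def test_q_one_allows_all(self):
        values = np.random.default_rng(1).normal(size=(5, 5))
        assert avoid_matings_quantile(values, q=1.0).all()

    def test_all_equal_values_all_allowed(self):
        assert avoid_matings_quantile(np.full((4, 4), 0.3), q=0.5).all()

    def test_invalid_quantile(self):
        with pytest.raises(ValueError):
            avoid_matings_quantile(np.zeros((2, 2)), q=0.0)


class TestSibAvoidance:
    def test_levels(self):
        ped = _toy_pedigree()
        sires, dams = np.array([4, 6]), np.array([5, 7])
        full = avoid_sib_matings(ped, sires, dams, "full")
        half = avoid_sib_matings(ped, sires, dams, "half")
        assert not full[0, 0]          # 4 x 5 are full sibs
        assert full[1, 0]              # 6 x 5 share only the sire
        assert not half[1, 0]          # ... excluded at half-sib level
        assert half[0, 1] and full[0, 1]  # 4 x 7 unrelated

    def test_founders_never_counted_as_sibs(self):
        ped = _toy_pedigree()
        assert avoid_sib_matings(ped, np.array([0, 1]), np.array([2, 3]),
                                 "half").all()

    def test_matches_bruteforce_parent_comparison(self):
        ped = _toy_pedigree()
        sires, dams = np.array([0, 1, 4, 6]), np.array([2, 3, 5, 7])
        mask = avoid_sib_matings(ped, sires, dams, "half")
        for i, s in enumerate(sires):
            for j, d in enumerate(dams):
                shared = ((ped.sire[s] == ped.sire[d] and ped.sire[s] >= 0)
                          or (ped.dam[s] == ped.dam[d] and ped.dam[s] >= 0))
                assert mask[i, j] == (not shared)


class TestSampleMatings:
    def test_uniform_expectation(self):
        sires, dams = np.arange(40), np.arange(100, 200)
        allowed = np.ones((40, 100), dtype=bool)
        plan = sample_matings(allowed, sires, dams, 40_000, seed=3)
        counts = np.array([plan.contributions.get(int(s), 0) for s in sires])
        se = np.sqrt(40_000 * (1 / 40) * (39 / 40))
        assert np.all(np.abs(counts - 1000) < 5 * se)
        assert plan.pairs.shape == (40_000, 2)

    def test_single_allowed_pair(self):
        allowed = np.zeros((2, 2), dtype=bool)
        allowed[1, 0] = True
        plan = sample_matings(allowed, np.array([10, 11]), np.array([20, 21]),
                              50, seed=0)
        assert np.all(plan.pairs == [11, 20])

    def test_determinism(self):
        allowed = np.ones((3, 4), dtype=bool)
        a = sample_matings(allowed, np.arange(3), np.arange(10, 14), 30, seed=9)
        b = sample_matings(allowed, np.arange(3), np.arange(10, 14), 30, seed=9)
        assert np.array_equal(a.pairs, b.pairs)


def _random_ocs_instance(seed, n_m=5, n_f=4):
    rng = np.random.default_rng(seed)
    n = n_m + n_f
    B = rng.normal(size=(n, n))
    K = B @ B.T / n * 0.05 + np.eye(n) * 0.05
    ids = np.arange(n)
    kin = KinshipMatrix(values=K, kind="pedigree", ids=ids)
    u = rng.normal(size=n_m)
    return u, ids[:n_m], ids[n_m:], kin


def _grid_search_ocs(u, male_ids, female_ids, kin, thr, steps=24):
    """Refining simplex grid search oracle for the male contributions."""
    n_m, n_f = male_ids.size, female_ids.size
    K = kin.values
    cf = np.full(n_f, 0.5 / n_f)
    Kmm = K[:n_m, :n_m]
    b = 2.0 * K[:n_m, n_m:] @ cf
    q0 = float(cf @ K[n_m:, n_m:] @ cf)

    def coan(c):
        return float(c @ Kmm @ c + b @ c + q0)

    def compositions(total, parts):
        if parts == 1:
            yield (total,)
            return
        for head in range(total + 1):
            for rest in compositions(total - head, parts - 1):
                yield (head,) + rest

    center = np.full(n_m, 0.5 / n_m)
    width = 0.5
    best, best_gain = None, -np.inf
    for _ in range(5):
        lo = np.maximum(center - width, 0.0)
        for comp in compositions(steps, n_m):
            c = lo + np.array(comp) / steps * (2 * width)
            if c.sum() <= 0:
                continue
            c = 0.5 * c / c.sum()
            if coan(c) <= thr + 1e-9:
                gain = float(c @ u)
                if gain > best_gain:
                    best_gain, best = gain, c
        if best is None:
            break
        center, width = best, width / 4
    return best, best_gain


class TestOCSDeterministic:
    def test_slack_constraint_is_lp_corner(self):
        u, m_ids, f_ids, kin = _random_ocs_instance(0)
        sol = ocs_deterministic(u, m_ids, f_ids, kin, delta_kin=10.0,
                                current_mean_kinship=0.0)
        top = m_ids[np.argmax(u)]
        assert sol.contributions[np.argmax(u)] == pytest.approx(0.5)
        assert sol.achieved_gain == pytest.approx(0.5 * u.max())
        assert sol.feasible

    def test_symmetric_candidates_get_uniform_contributions(self):
        n_m, n_f = 4, 3
        K = np.eye(n_m + n_f) * 0.5
        kin = KinshipMatrix(values=K, kind="pedigree", ids=np.arange(n_m + n_f))
        u = np.ones(n_m)
        sol = ocs_deterministic(u, np.arange(n_m), np.arange(n_m, n_m + n_f),
                                kin, delta_kin=0.0, current_mean_kinship=0.08)
        assert sol.feasible
        assert np.allclose(sol.contributions, 0.125, atol=1e-4)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_matches_grid_search_oracle(self, seed):
        u, m_ids, f_ids, kin = _random_ocs_instance(seed)
        f_bar = float(kin.values.mean())
        sol = ocs_deterministic(u, m_ids, f_ids, kin, delta_kin=0.004,
                                current_mean_kinship=f_bar)
        _, gain_grid = _grid_search_ocs(u, m_ids, f_ids, kin,
                                        thr=f_bar + 0.004)
        assert sol.achieved_kinship <= f_bar + 0.004 + 1e-6
        assert sol.achieved_gain == pytest.approx(gain_grid, abs=1e-3)

    def test_gain_monotone_in_constraint(self):
        """The gain achieved cannot increase when the kinship cap tightens."""
        u, m_ids, f_ids, kin = _random_ocs_instance(7)
        f_bar = float(kin.values.mean())
        gains = [ocs_deterministic(u, m_ids, f_ids, kin, dk, f_bar).achieved_gain
                 for dk in (0.007, 0.006, 0.005, 0.004, 0.003)]
        assert np.all(np.diff(gains) <= 1e-6)

    def test_infeasible_returns_min_kinship(self):
        u, m_ids, f_ids, kin = _random_ocs_instance(4)
        sol = ocs_deterministic(u, m_ids, f_ids, kin, delta_kin=-10.0,
                                current_mean_kinship=0.0)
        assert not sol.feasible


class TestContributionsToMatings:
    def test_uniform_contributions(self):
        sol = OCSSolution(male_ids=np.arange(40),
                          contributions=np.full(40, 0.5 / 40),
                          achieved_gain=0.0, achieved_kinship=0.0)
        plan = contributions_to_matings(sol, np.arange(100, 200), 1000, seed=0)
        counts = [plan.contributions[int(i)] for i in range(40)]
        assert counts == [25] * 40
        dcounts = [plan.contributions[int(i)] for i in range(100, 200)]
        assert dcounts == [10] * 100

    def test_unequal_contributions(self):
        sol = OCSSolution(male_ids=np.array([1, 2]),
                          contributions=np.array([0.3, 0.2]),
                          achieved_gain=0.0, achieved_kinship=0.0)
        plan = contributions_to_matings(sol, np.array([5, 6]), 1000, seed=1)
        assert plan.contributions[1] == 600
        assert plan.contributions[2] == 400

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.01, max_value=1.0), min_size=2,
                    max_size=10),
           st.integers(min_value=1, max_value=500))
    def test_largest_remainder_property(self, weights, total):
        w = np.array(weights)
        counts = _largest_remainder(w, total)
        exact = w / w.sum() * total
        assert counts.sum() == total
        assert np.all(np.abs(counts - exact) < 1.0)


class TestOCSEvolutionary:
    @staticmethod
    def _toy(seed=0, n=8):
        rng = np.random.default_rng(seed)
        ebv = rng.normal(size=n)
        B = rng.normal(size=(n, n))
        G = B @ B.T / n + np.eye(n) * 0.2
        sexes = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        return ebv, KinshipMatrix(values=G, kind="genomic"), sexes

    def test_theta_zero_is_truncation_selection(self):
        ebv, G, sexes = self._toy()
        plan = ocs_evolutionary(ebv, G, sexes, theta=0.0, n_males=2,
                                n_females=2, n_offspring=20, seed=1)
        males = set(np.unique(plan.pairs[:, 0]).tolist())
        top_males = set(np.argsort(-ebv[:4])[:2].tolist())
        assert males == top_males

    def test_theta_ninety_minimizes_group_coancestry(self):
        ebv, G, sexes = self._toy(seed=3)
        plan = ocs_evolutionary(ebv, G, sexes, theta=90.0, n_males=2,
                                n_females=2, n_offspring=20, seed=2)
        from breedsim.mating import _group_coancestry
        K2 = G.values / 2
        males = np.unique(plan.pairs[:, 0])
        females = np.unique(plan.pairs[:, 1])
        achieved = _group_coancestry(K2, males, females)
        best = min(_group_coancestry(K2, np.array(m), np.array(f))
                   for m in itertools.combinations(range(4), 2)
                   for f in itertools.combinations(range(4, 8), 2))
        assert achieved == pytest.approx(best, abs=1e-12)

    def test_matches_exhaustive_enumeration_at_30_degrees(self):
        """8-candidate toy: the selected sets attain the exhaustively
        enumerated optimum of the normalised cos/sin objective."""
        from breedsim.mating import _group_coancestry, _set_gain
        ebv, G, sexes = self._toy(seed=5)
        K2 = G.values / 2
        combos = [(np.array(m), np.array(f))
                  for m in itertools.combinations(range(4), 2)
                  for f in itertools.combinations(range(4, 8), 2)]
        # corners as the implementation defines them
        gain_corner = max(combos, key=lambda mf: _set_gain(ebv, *mf))
        gain_max = _set_gain(ebv, *gain_corner)
        coan_at_gain = _group_coancestry(K2, *gain_corner)
        coan_min = min(_group_coancestry(K2, *mf) for mf in combos)
        div_corner = min(combos, key=lambda mf: _group_coancestry(K2, *mf))
        gain_at_div = _set_gain(ebv, *div_corner)
        th = np.deg2rad(30.0)

        def objective(m, f):
            gn = (_set_gain(ebv, m, f) - gain_at_div) / (gain_max - gain_at_div)
            cn = ((_group_coancestry(K2, m, f) - coan_min)
                  / (coan_at_gain - coan_min))
            return np.cos(th) * gn - np.sin(th) * cn

        best = max(objective(m, f) for m, f in combos)
        plan = ocs_evolutionary(ebv, G, sexes, theta=30.0, n_males=2,
                                n_females=2, n_offspring=20, seed=4)
        males = np.unique(plan.pairs[:, 0])
        females = np.unique(plan.pairs[:, 1])
        assert objective(males, females) == pytest.approx(best, abs=1e-12)

    def test_elitism_trace_nondecreasing(self):
        rng = np.random.default_rng(6)
        vals = rng.normal(size=12)
        _, _, trace = _ea_select_sets(
            lambda m, f: float(vals[m].sum() - vals[f].sum()),
            np.arange(6), np.arange(6, 12), 2, 2, rng, max_iter=100,
            stop_after=30)
        assert np.all(np.diff(trace) >= 0)

    def test_too_many_parents_raises(self):
        ebv, G, sexes = self._toy()
        with pytest.raises(ValueError):
            ocs_evolutionary(ebv, G, sexes, 30.0, n_males=5, n_females=2,
                             n_offspring=10, seed=0)
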