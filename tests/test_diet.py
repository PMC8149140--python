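"""Gut-content statistics: worked examples, decomposition identities,
permutation validity."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from fishtroph.diet import (build_diet_matrix, diet_distance_matrix,
                            diet_diversity, mean_fullness,
                            occurrence_frequency, amundsen_points,
                            permanova, prey_accumulation,
                            prey_specific_abundance, simper,
                            transform_arcsine_sqrt, vacuity_index)
from fishtroph.records import GutSample


def gut(fid, items, pop="P", tl=15.0):
    return GutSample(fid, pop, tl, fullness=float(sum(items.values())),
                     items=items)


def empty_gut(fid, pop="P"):
    return GutSample(fid, pop, 15.0, fullness=0.0, items={})


@pytest.fixture()
def simple_matrix():
    guts = [gut("f1", {"X": 30.0, "Y": 30.0}),
            gut("f2", {"X": 10.0, "Y": 50.0}),
            gut("f3", {"Y": 40.0}),
            empty_gut("f4")]
    return build_diet_matrix(guts)


class TestVacuityAndFullness:
    def test_no_empty_guts_is_zero(self):
        guts = [gut(f"f{i}", {"X": 50.0}) for i in range(22)]
        assert vacuity_index(guts) == 0.0

    def test_all_empty_is_hundred(self):
        assert vacuity_index([empty_gut(f"f{i}") for i in range(5)]) == 100.0

    def test_four_of_nineteen(self):
        guts = [empty_gut(f"e{i}") for i in range(4)]
        guts += [gut(f"f{i}", {"X": 40.0}) for i in range(15)]
        assert vacuity_index(guts) == pytest.approx(100 * 4 / 19)

    def test_mean_fullness_with_and_without_empties(self):
        guts = [empty_gut("e"), gut("f", {"X": 100.0})]
        assert mean_fullness(guts)[0] == pytest.approx(50.0)
        assert mean_fullness(guts, include_empty=False)[0] == \
            pytest.approx(100.0)

    def test_beta_fullness_expectation(self, rng):
        vals = 100 * rng.beta(5, 2, size=10_000)
        guts = [gut(f"f{i}", {"X": float(v)}) for i, v in enumerate(vals)]
        assert mean_fullness(guts)[0] == pytest.approx(100 * 5 / 7, rel=0.02)


class TestAmundsenStatistics:
    def test_occurrence_denominator_excludes_empty(self, simple_matrix):
        assert occurrence_frequency(simple_matrix, "X") == pytest.approx(
            100 * 2 / 3)
        assert occurrence_frequency(simple_matrix, "Y") == 100.0

    def test_prey_specific_abundance_hand_case(self, simple_matrix):
        # X held by f1 (30 of 60) and f2 (10 of 60): 40/120
        assert prey_specific_abundance(simple_matrix, "X") == \
            pytest.approx(100 * 40 / 120)

    def test_pi_ignores_guts_without_category(self, simple_matrix):
        guts = [gut("f1", {"X": 30.0, "Y": 30.0}),
                gut("f2", {"X": 10.0, "Y": 50.0}),
                gut("g9", {"Y": 77.0})]
        m2 = build_diet_matrix(guts)
        assert prey_specific_abundance(m2, "X") == \
            prey_specific_abundance(simple_matrix, "X")

    def test_exclusive_heavy_feeder_marks_specialisation(self):
        guts = [gut("f1", {"X": 90.0}),
                gut("f2", {"Y": 50.0}), gut("f3", {"Y": 60.0})]
        m = build_diet_matrix(guts)
        assert occurrence_frequency(m, "X") == pytest.approx(100 / 3)
        assert prey_specific_abundance(m, "X") == 100.0

    def test_point_count_equals_present_categories(self, simple_matrix):
        pts = amundsen_points(simple_matrix)
        assert len(pts) == 2
        assert set(pts["category"]) == {"X", "Y"}


class TestDiversityAndTransform:
    def test_monophagous_fish_have_zero_diversity(self):
        guts = [gut(f"f{i}", {"X": 50.0}) for i in range(3)]
        h = diet_diversity(build_diet_matrix(guts))["per_fish"]
        assert np.allclose(h, 0.0)

    def test_four_equal_items_give_ln4(self):
        g = gut("f1", {"a": 20.0, "b": 20.0, "c": 20.0, "d": 20.0})
        others = [gut("f2", {"a": 10.0}), gut("f3", {"b": 10.0})]
        h = diet_diversity(build_diet_matrix([g] + others))["per_fish"]
        assert h.loc["f1"] == pytest.approx(np.log(4))

    def test_arcsine_sqrt_values(self):
        out = transform_arcsine_sqrt(np.array([0.0, 0.25, 1.0]))
        assert out == pytest.approx([0.0, np.arcsin(0.5), np.pi / 2])

    def test_arcsine_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            transform_arcsine_sqrt(np.array([1.2]))


class TestPermanova:
    def test_univariate_euclidean_equals_anova_f(self, rng):
        y = np.concatenate([rng.normal(0, 1, 10), rng.normal(1, 1, 12),
                            rng.normal(2, 1, 9)])
        labels = np.repeat(["a", "b", "c"], [10, 12, 9])
        d = np.abs(y[:, None] - y[None, :])
        res = permanova(d, labels, n_perm=99, seed=0)
        f_cls = sps.f_oneway(y[:10], y[10:22], y[22:]).statistic
        assert res.pseudo_F == pytest.approx(f_cls, rel=1e-9)

    def test_identical_separated_groups_minimal_p(self):
        rows = np.vstack([np.tile([10.0, 0.0, 0.0], (6, 1)),
                          np.tile([0.0, 10.0, 0.0], (6, 1))])
        d = np.linalg.norm(rows[:, None] - rows[None, :], axis=2)
        labels = np.repeat(["a", "b"], 6)
        res = permanova(d, labels, n_perm=199, seed=1)
        assert res.p == pytest.approx(1 / 200)

    def test_null_type_one_error(self, rng):
        hits = 0
        reps = 300
        for i in range(reps):
            y = rng.normal(size=(18, 3))
            d = np.linalg.norm(y[:, None] - y[None, :], axis=2)
            labels = rng.permutation(np.repeat(["a", "b", "c"], 6))
            hits += permanova(d, labels, n_perm=99, seed=i).p <= 0.05
        assert 0.02 < hits / reps < 0.09

    def test_agrees_with_scikit_bio(self, rng):
        from skbio.stats.distance import DistanceMatrix as SkbioDM
        from skbio.stats.distance import permanova as skbio_permanova
        y = np.vstack([rng.normal(0, 1, (8, 3)),
                       rng.normal(1.0, 1, (8, 3))])
        d = np.linalg.norm(y[:, None] - y[None, :], axis=2)
        labels = list(np.repeat(["a", "b"], 8))
        ours = permanova(d, labels, n_perm=99, seed=3)
        theirs = skbio_permanova(SkbioDM(d), labels, permutations=99)
        assert ours.pseudo_F == pytest.approx(
            float(theirs["test statistic"]), rel=1e-9)


class TestSimper:
    def test_single_differing_category_contributes_all(self):
        a = np.tile([10.0, 5.0, 0.0], (5, 1))
        b = np.tile([10.0, 5.0, 8.0], (5, 1))
        res = simper(np.vstack([a, b]), np.repeat(["A", "B"], 5))
        top = res.contributions.iloc[0]
        total = res.overall["average_dissimilarity"].iloc[0]
        assert top["category"] == "v2"
        assert top["contribution"] == pytest.approx(total)

    def test_decomposition_identity_random_matrices(self, rng):
        for _ in range(30):
            mat = rng.uniform(0, 10, size=(12, 5))
            labels = rng.permutation(np.repeat(["A", "B", "C"], 4))
            res = simper(mat, labels)
            for _, row in res.overall.iterrows():
                s = res.contributions.loc[
                    res.contributions["pair"] == row["pair"],
                    "contribution"].sum()
                assert s == pytest.approx(row["average_dissimilarity"],
                                          abs=1e-9)

    def test_matches_bruteforce_cross_pair_average(self, rng):
        from fishtroph.stats import bray_curtis
        mat = rng.uniform(0, 5, size=(9, 4))
        labels = np.repeat(["A", "B"], [4, 5])
        res = simper(mat, labels)
        manual = np.mean([bray_curtis(mat[i], mat[j])
                          for i in range(4) for j in range(4, 9)])
        assert res.overall["average_dissimilarity"].iloc[0] == \
            pytest.approx(manual, abs=1e-12)


class TestPreyAccumulation:
    def test_endpoint_equals_observed_richness(self, rng):
        pres = rng.uniform(size=(10, 6)) < 0.4
        pres[:, 0] = True
        curve = prey_accumulation(pres)
        s_obs = (pres.sum(axis=0) > 0).sum()
        assert curve["expected_richness"].iloc[-1] == pytest.approx(s_obs)

    def test_first_point_is_mean_per_gut_richness(self, rng):
        pres = rng.uniform(size=(8, 5)) < 0.5
        curve = prey_accumulation(pres)
        assert curve["expected_richness"].iloc[0] == pytest.approx(
            pres.sum(axis=1).mean())

    def test_monotone_non_decreasing(self, rng):
        pres = rng.uniform(size=(15, 7)) < 0.3
        curve = prey_accumulation(pres)["expected_richness"].to_numpy()
        assert np.all(np.diff(curve) >= -1e-12)

    def test_matches_resampling_oracle(self, rng):
        pres = rng.uniform(size=(12, 6)) < 0.35
        m = 5
        exact = prey_accumulation(pres, m_values=[m])[
            "expected_richness"].iloc[0]
        draws = [np.any(pres[rng.choice(12, m, replace=False)], axis=0).sum()
                 for _ in range(4000)]
        assert exact == pytest.approx(np.mean(draws), abs=0.1)


class TestCompositionScope:
    def test_empty_gut_changes_only_vacuity(self, simple_matrix):
        guts = [gut("f1", {"X": 30.0, "Y": 30.0}),
                gut("f2", {"X": 10.0, "Y": 50.0}),
                gut("f3", {"Y": 40.0})]
        with_empty = guts + [empty_gut("f9")]
        m1, m2 = build_diet_matrix(guts), build_diet_matrix(with_empty)
        assert m1.values.equals(m2.values)
        assert vacuity_index(guts) == 0.0
        assert vacuity_index(with_empty) == pytest.approx(25.0)

    def test_distance_matrix_covers_nonempty_fish_only(self, simple_matrix):
        d = diet_distance_matrix(simple_matrix)
        assert len(d.labels) == 3
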