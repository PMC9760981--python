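"""Metrics, loss rate, meiboscore, RMSE, Mann-Whitney, t-SNE diagnostics."""

from itertools import combinations

import numpy as np
import pytest
from scipy import stats

from meibseg import (LossRateRecord, compare_groups, domain_embedding,
                     loss_rate_rmse, meiboscore, mg_loss_rate, region_metrics)
from meibseg.evaluation import aggregate_metrics


class TestRegionMetrics:
    def test_perfect_prediction(self):
        mask = np.zeros((8, 8), dtype=np.uint8)
        mask[2:6, 2:6] = 2
        rec = region_metrics(mask, mask, 2)
        assert (rec.dsc, rec.recall, rec.precision) == (1.0, 1.0, 1.0)

    def test_disjoint_regions_score_zero(self):
        pred = np.zeros((8, 8), dtype=np.uint8)
        truth = np.zeros((8, 8), dtype=np.uint8)
        pred[:2] = 1
        truth[6:] = 1
        rec = region_metrics(pred, truth, 1)
        assert (rec.dsc, rec.recall, rec.precision) == (0.0, 0.0, 0.0)

    def test_hand_counted_fixture(self):
        # |P|=6, |T|=4, |P∩T|=3 -> dsc 0.6, recall 0.75, precision 0.5
        pred = np.zeros((8, 8), dtype=np.uint8)
        truth = np.zeros((8, 8), dtype=np.uint8)
        truth[0, 0:4] = 2
        pred[0, 1:4] = 2
        pred[1, 0:3] = 2
        rec = region_metrics(pred, truth, 2)
        assert rec.dsc == pytest.approx(0.6)
        assert rec.recall == pytest.approx(0.75)
        assert rec.precision == pytest.approx(0.5)

    def test_matches_counting_oracle_on_random_masks(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            pred = rng.integers(0, 3, size=(10, 10)).astype(np.uint8)
            truth = rng.integers(0, 3, size=(10, 10)).astype(np.uint8)
            for region in (1, 2):
                rec = region_metrics(pred, truth, region)
                inter = sum(1 for i in range(10) for j in range(10)
                            if pred[i, j] == region and truth[i, j] == region)
                np_ = int((pred == region).sum())
                nt = int((truth == region).sum())
                if nt == 0:
                    assert not rec.defined
                    continue
                assert rec.recall == pytest.approx(inter / nt, abs=1e-12)
                if np_:
                    assert rec.precision == pytest.approx(inter / np_, abs=1e-12)
                assert rec.dsc == pytest.approx(2 * inter / (np_ + nt), abs=1e-12)

    def test_dsc_is_harmonic_mean_of_precision_recall(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            pred = rng.integers(0, 3, size=(12, 12)).astype(np.uint8)
            truth = rng.integers(0, 3, size=(12, 12)).astype(np.uint8)
            rec = region_metrics(pred, truth, 2)
            if rec.defined and rec.precision > 0 and rec.recall > 0:
                hm = (2 * rec.precision * rec.recall
                      / (rec.precision + rec.recall))
                assert rec.dsc == pytest.approx(hm, abs=1e-12)

    def test_empty_truth_region_flagged_and_excluded(self):
        pred = np.full((4, 4), 2, dtype=np.uint8)
        truth = np.zeros((4, 4), dtype=np.uint8)
        rec = region_metrics(pred, truth, 2)
        assert not rec.defined
        agg = aggregate_metrics([rec])
        assert agg["n_excluded"] == 1
        assert np.isnan(agg["dsc_mean"])


class TestMgLossRate:
    def test_direct_count(self):
        # 80 eyelid-area pixels, 60 glandular -> 1 - 60/80 = 0.25
        mask = np.zeros((10, 10), dtype=np.uint8)
        flat = mask.ravel()
        flat[:60] = 2
        flat[60:80] = 1
        assert mg_loss_rate(mask) == pytest.approx(0.25)

    def test_extremes(self):
        no_glands = np.ones((8, 8), dtype=np.uint8)
        assert mg_loss_rate(no_glands) == 1.0
        all_glands = np.full((8, 8), 2, dtype=np.uint8)
        assert mg_loss_rate(all_glands) == 0.0

    def test_undefined_without_eyelid(self):
        with pytest.raises(ValueError):
            mg_loss_rate(np.zeros((8, 8), dtype=np.uint8))

    def test_invariant_under_flips_and_rotations(self, phantom):
        base = mg_loss_rate(phantom.mask)
        for transformed in (phantom.mask[::-1], phantom.mask[:, ::-1],
                            np.rot90(phantom.mask), phantom.mask.T):
            assert mg_loss_rate(transformed) == base


class TestMeiboscore:
    def test_reference_points(self):
        assert meiboscore(0.0) == 0
        assert meiboscore(0.5) == 2
        assert meiboscore(1.0) == 3

    def test_grade_boundaries_at_thirds(self):
        eps = 1e-9
        assert meiboscore(eps) == 1
        assert meiboscore(1 / 3) == 1
        assert meiboscore(1 / 3 + eps) == 2
        assert meiboscore(2 / 3) == 2
        assert meiboscore(2 / 3 + eps) == 3

    def test_monotone_with_four_grades_spaced_by_one_third(self):
        grid = np.linspace(0, 1, 20001)
        grades = np.array([meiboscore(r) for r in grid])
        assert np.all(np.diff(grades) >= 0)
        assert set(grades) == {0, 1, 2, 3}
        transitions = grid[1:][np.diff(grades) > 0]
        spacings = np.diff(transitions)
        assert spacings == pytest.approx([1 / 3, 1 / 3], abs=1e-3)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            meiboscore(1.5)


class TestLossRateRmse:
    def test_zero_when_perfect(self):
        recs = [LossRateRecord("a", 0.4, 0.4), LossRateRecord("b", 0.1, 0.1)]
        assert loss_rate_rmse(recs) == 0.0

    def test_hand_arithmetic(self):
        recs = [LossRateRecord("a", 0.2, 0.1), LossRateRecord("b", 0.5, 0.5)]
        assert loss_rate_rmse(recs) == pytest.approx(np.sqrt(0.01 / 2))

    def test_homogeneity(self):
        rng = np.random.default_rng(5)
        true = rng.uniform(0, 0.5, size=20)
        err = rng.uniform(-0.1, 0.1, size=20)
        r1 = loss_rate_rmse([LossRateRecord(str(i), t + e, t)
                             for i, (t, e) in enumerate(zip(true, err))])
        r2 = loss_rate_rmse([LossRateRecord(str(i), t + 2 * e, t)
                             for i, (t, e) in enumerate(zip(true, err))])
        assert r2 == pytest.approx(2 * r1)

    def test_matches_two_pass_oracle_on_1000_pairs(self):
        rng = np.random.default_rng(6)
        pred = rng.uniform(0, 1, size=1000)
        true = rng.uniform(0, 1, size=1000)
        recs = [LossRateRecord(str(i), p, t)
                for i, (p, t) in enumerate(zip(pred, true))]
        acc = 0.0
        for p, t in zip(pred, true):
            acc += (p - t) ** 2
        assert loss_rate_rmse(recs) == pytest.approx(np.sqrt(acc / 1000),
                                                     abs=1e-12)

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            loss_rate_rmse([])

    def test_grades_consistent_with_rates(self):
        rec = LossRateRecord("a", 0.5, 0.9)
        assert rec.predicted_grade == 2
        assert rec.true_grade == 3


def brute_force_mw_p(a, b):
    """Exact two-sided Mann-Whitney p by enumerating group assignments,
    computing U by pairwise comparison counts (independent of rank formula)."""
    pooled = list(a) + list(b)
    n_a = len(a)

    def u_of(group_a_vals, group_b_vals):
        u = 0.0
        for x in group_a_vals:
            for y in group_b_vals:
                u += 1.0 if x > y else (0.5 if x == y else 0.0)
        return u

    u_obs = u_of(a, b)
    us = []
    idx_all = set(range(len(pooled)))
    for idx in combinations(range(len(pooled)), n_a):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in idx_all - set(idx)]
        us.append(u_of(ga, gb))
    us = np.array(us)
    eps = 1e-9
    return min(1.0, 2 * min(np.mean(us <= u_obs + eps),
                            np.mean(us >= u_obs - eps)))


class TestCompareGroups:
    def test_identical_samples_not_significant(self):
        res = compare_groups([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.p_value > 0.9
        assert not res.significant

    def test_complete_separation_gives_zero_u(self):
        res = compare_groups([1, 2, 3], [101, 102, 103])
        assert res.u_statistic == 0.0

    def test_small_sample_p_matches_exact_enumeration(self):
        rng = np.random.default_rng(7)
        cases = []
        for n, m in [(2, 2), (3, 3), (4, 4), (5, 5), (3, 7), (2, 8)]:
            cases.append((rng.normal(size=n), rng.normal(size=m)))
        # include ties
        cases.append((np.array([1, 1, 2, 3]), np.array([1, 2, 2, 4])))
        cases.append((np.array([5, 5, 5]), np.array([5, 5, 5, 5])))
        for a, b in cases:
            res = compare_groups(a, b)
            assert res.p_value == pytest.approx(brute_force_mw_p(a, b),
                                                abs=1e-12)

    def test_large_sample_uses_tie_corrected_asymptotics(self):
        rng = np.random.default_rng(8)
        a = rng.normal(0, 1, size=60)
        b = rng.normal(1, 1, size=60)
        res = compare_groups(a, b)
        expected = stats.mannwhitneyu(a, b, alternative="two-sided",
                                      method="asymptotic").pvalue
        assert res.p_value == pytest.approx(float(expected), rel=1e-9)
        assert res.significant

    def test_rejects_tiny_samples(self):
        with pytest.raises(ValueError):
            compare_groups([1.0], [2.0, 3.0])

    def test_significance_threshold_is_one_percent(self):
        res = compare_groups(list(range(10)), list(range(20, 30)))
        assert res.p_value < 0.01 and res.significant


class TestDomainEmbedding:
    def test_row_count_and_label_alignment(self, phantom_pool_a,
                                           phantom_pool_b):
        coords, labels, _ = domain_embedding(phantom_pool_a[:10],
                                             phantom_pool_b[:10], seed=0)
        assert coords.shape == (20, 2)
        assert labels.sum() == 10

    def test_distinct_styles_separate(self, phantom_pool_a, phantom_pool_b):
        _, _, score = domain_embedding(phantom_pool_a, phantom_pool_b, seed=0)
        assert score > 0

    def test_random_split_of_one_style_does_not_separate(self, style_a):
        from meibseg import generate_dataset
        pool = generate_dataset(30, None, style_a, seed=50)
        _, _, score = domain_embedding(pool[:15], pool[15:], seed=0)
        assert abs(score) < 0.2

    def test_rejects_too_few_images(self, phantom_pool_a):
        with pytest.raises(ValueError):
            domain_embedding(phantom_pool_a[:2], phantom_pool_a[:2], seed=0)
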