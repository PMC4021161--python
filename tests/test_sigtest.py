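import numpy as np
import pytest

from landsig import (
    ActivityVector,
    LandscapeTestResult,
    RandomSALIPool,
    SALIVector,
    TestConfig,
    build_random_pool,
    cliff_significance,
    compute_sali,
    gen_landscape,
    ks_two_sample,
    landscape_validity_test,
    per_iteration_check,
    quantile_interval_test,
    similarity_matrix,
)
from landsig.synthdata import LandscapeSpec

from conftest import brute_ks_statistic


def make_pool(per_iter: np.ndarray, seed=0) -> RandomSALIPool:
    mask = np.isfinite(per_iter)
    n_pairs = per_iter.shape[1]
    # smallest m with that many pairs (tests construct exact layouts)
    m = int((1 + np.sqrt(1 + 8 * n_pairs)) / 2)
    return RandomSALIPool(per_iteration=per_iter, per_iteration_mask=mask,
                          accumulated=per_iter[mask], n_iterations=per_iter.shape[0],
                          seed=seed, n_molecules=m)


def make_sali(values, m) -> SALIVector:
    values = np.asarray(values, float)
    return SALIVector(pair_index=np.column_stack(np.triu_indices(m, 1)),
                      values=values, defined_mask=np.isfinite(values), n_molecules=m)


class TestKSTwoSample:
    def test_identical_samples(self):
        x = np.array([0.3, 1.0, 2.5, 2.5, 7.0])
        D, p = ks_two_sample(x, x)
        assert D == 0.0 and p == pytest.approx(1.0)

    def test_disjoint_supports(self):
        D, _ = ks_two_sample([1, 2, 3], [10, 11, 12])
        assert D == pytest.approx(1.0)

    def test_interleaved_hand_case(self):
        D, _ = ks_two_sample([1, 3], [2, 4])
        assert D == pytest.approx(0.5)

    def test_statistic_matches_brute_force_ecdf_scan(self):
        rng = np.random.default_rng(17)
        for n, k in [(10, 25), (200, 1000), (999, 37)]:
            x = rng.normal(size=n)
            y = rng.normal(0.2, 1.3, size=k)
            D, _ = ks_two_sample(x, y)
            assert D == pytest.approx(brute_ks_statistic(x, y), abs=1e-12)
        # with heavy ties
        x = rng.integers(0, 5, 300).astype(float)
        y = rng.integers(0, 5, 500).astype(float)
        D, _ = ks_two_sample(x, y)
        assert D == pytest.approx(brute_ks_statistic(x, y), abs=1e-12)

    def test_asymptotic_pvalue_agrees_with_r(self):
        """Frozen oracle: ks.test in R on the same two samples reports
        D = 0.169583333333, p = 0.00494871072013 (asymptotic two-sided).
        The statistic must match exactly; the p-value to the accuracy the
        two asymptotic formulations share."""
        rng = np.random.default_rng(12345)
        x = np.round(rng.normal(0, 1, 120), 6)
        y = np.round(rng.normal(0.3, 1.2, 800), 6)
        D, p = ks_two_sample(x, y)
        assert D == pytest.approx(0.169583333333, abs=1e-9)
        assert p == pytest.approx(0.00494871072013, rel=0.15)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            ks_two_sample([], [1.0])


class TestLandscapeValidity:
    def test_pool_equal_to_observed_is_not_valid(self):
        obs = make_sali(np.array([1.0, 2.0, 3.0]), m=3)
        pool = make_pool(np.tile([1.0, 2.0, 3.0], (10, 1)))
        cfg = TestConfig(n_iterations=10)
        res = landscape_validity_test(obs, pool, cfg)
        assert res.p_value == pytest.approx(1.0)
        assert not res.valid

    def test_result_invariant_enforced(self):
        with pytest.raises(ValueError, match="valid"):
            LandscapeTestResult(ks_statistic=0.5, p_value=0.01, alpha=0.05,
                                valid=False, n_observed=10, n_random=100)

    def test_all_undefined_rejected(self):
        obs = make_sali(np.array([np.nan, np.nan, np.nan]), m=3)
        pool = make_pool(np.ones((5, 3)))
        with pytest.raises(ValueError, match="undefined"):
            landscape_validity_test(obs, pool, TestConfig(n_iterations=5))

    def test_decisions_invariant_under_id_relabeling(self):
        spec = LandscapeSpec(kind="planted_sar", m=20, noise_sd=0.5, seed=3)
        fps, acts = gen_landscape(spec)
        cfg = TestConfig(n_iterations=50, seed=5)
        sim = similarity_matrix(fps)
        base = landscape_validity_test(compute_sali(acts, sim, cfg),
                                       build_random_pool(acts, sim, cfg), cfg)
        new_ids = [f"renamed_{i}" for i in range(20)]
        acts2 = ActivityVector(new_ids, acts.values)
        from landsig import SimilarityMatrix
        sim2 = SimilarityMatrix(new_ids, sim.values)
        rel = landscape_validity_test(compute_sali(acts2, sim2, cfg),
                                      build_random_pool(acts2, sim2, cfg), cfg)
        assert rel.p_value == base.p_value and rel.valid == base.valid


class TestCliffSignificance:
    def _landscape(self, valid, alpha=0.05):
        p = 0.01 if valid else 0.5
        return LandscapeTestResult(ks_statistic=0.2, p_value=p, alpha=alpha,
                                   valid=valid, n_observed=3, n_random=30)

    def test_empirical_p_matches_direct_count(self):
        obs = make_sali([5.0, 1.0, 3.0], m=3)
        per_iter = np.zeros((10, 3))
        per_iter[:, 0] = [6, 7, 8, 4, 4, 4, 4, 4, 4, 4]   # 3 of 10 strictly greater
        per_iter[:, 1] = 2.0                                # all greater -> p=1
        per_iter[:, 2] = 1.0                                # none greater -> p=0
        cfg = TestConfig(n_iterations=10, threshold_quantile=0.5)
        res = cliff_significance(obs, make_pool(per_iter), self._landscape(True), cfg)
        assert res.pairs["empirical_p"].tolist() == [0.3, 1.0, 0.0]
        assert res.pairs["n_greater"].tolist() == [3, 10, 0]
        # pair 1 (p=1) can never be significant
        assert not res.pairs.loc[1, "significant"]

    def test_equal_random_values_do_not_count_as_greater(self):
        obs = make_sali([2.0, 2.0, 2.0], m=3)
        per_iter = np.full((4, 3), 2.0)
        cfg = TestConfig(n_iterations=4)
        res = cliff_significance(obs, make_pool(per_iter), self._landscape(True), cfg)
        assert (res.pairs["n_greater"] == 0).all()

    def test_significant_implies_above_threshold(self):
        rng = np.random.default_rng(1)
        obs = make_sali(rng.exponential(1.0, 45), m=10)
        per_iter = rng.exponential(1.0, (40, 45))
        cfg = TestConfig(n_iterations=40)
        res = cliff_significance(obs, make_pool(per_iter), self._landscape(True), cfg)
        assert (res.pairs["significant"] <= res.pairs["above_threshold"]).all()
        assert res.f_significant <= res.f_magnitude

    def test_f_significant_na_when_landscape_invalid(self):
        obs = make_sali([5.0, 1.0, 3.0], m=3)
        per_iter = np.zeros((10, 3))
        cfg = TestConfig(n_iterations=10)
        res = cliff_significance(obs, make_pool(per_iter), self._landscape(False), cfg)
        assert res.f_significant is None
        assert res.f_magnitude is not None

    def test_f_magnitude_near_one_minus_q_for_distinct_values(self):
        rng = np.random.default_rng(2)
        n_pairs = 45  # m = 10
        obs = make_sali(rng.permutation(np.linspace(0.1, 9.0, n_pairs)), m=10)
        per_iter = rng.exponential(1.0, (20, n_pairs))
        cfg = TestConfig(n_iterations=20, threshold_quantile=0.95)
        res = cliff_significance(obs, make_pool(per_iter), self._landscape(True), cfg)
        assert abs(res.f_magnitude - 0.05) <= 1.0 / n_pairs

    def test_threshold_is_type7_quantile(self):
        obs = make_sali(np.arange(1.0, 46.0), m=10)  # 1..45
        per_iter = np.zeros((5, 45))
        cfg = TestConfig(n_iterations=5, threshold_quantile=0.95)
        res = cliff_significance(obs, make_pool(per_iter), self._landscape(True), cfg)
        assert res.threshold_value == pytest.approx(1 + 0.95 * 44)  # 42.8

    def test_monotone_in_observed_value(self):
        rng = np.random.default_rng(4)
        pool_col = rng.exponential(1.0, 50)
        counts = []
        for v in [0.1, 0.5, 1.0, 2.0, 5.0]:
            counts.append(int((pool_col > v).sum()))
        assert counts == sorted(counts, reverse=True)


class TestQuantileIntervalTest:
    def test_hand_cases_on_1_to_100(self):
        pool = np.arange(1.0, 101.0)
        # type-7 quantiles of 1..100 at 0.05 / 0.95 are 5.95 and 95.05
        assert quantile_interval_test(96.5, pool, 0.05, 0.95) is True
        assert quantile_interval_test(50.0, pool, 0.05, 0.95) is False
        assert quantile_interval_test(5.0, pool, 0.05, 0.95) is True
        assert quantile_interval_test(200.0, pool, 0.05, 0.95) is True

    def test_errors(self):
        with pytest.raises(ValueError, match="lo"):
            quantile_interval_test(1.0, [1.0, 2.0], 0.9, 0.1)
        with pytest.raises(ValueError, match="nonempty"):
            quantile_interval_test(1.0, [], 0.05, 0.95)


class TestPerIterationCheck:
    def test_single_iteration_indistinguishable_from_itself(self):
        per_iter = np.array([[1.0, 2.0, 3.0]])
        assert per_iteration_check(make_pool(per_iter), TestConfig(n_iterations=1)) == 0

    def test_flat_pool_indistinguishable(self):
        per_iter = np.zeros((6, 3))
        assert per_iteration_check(make_pool(per_iter), TestConfig(n_iterations=6)) == 0

    def test_matches_brute_force_recomputation(self):
        spec = LandscapeSpec(kind="random", m=15, seed=21)
        fps, acts = gen_landscape(spec)
        sim = similarity_matrix(fps)
        cfg = TestConfig(n_iterations=40, seed=31)
        pool = build_random_pool(acts, sim, cfg)
        count = per_iteration_check(pool, cfg)
        brute = sum(
            ks_two_sample(pool.per_iteration[k][pool.per_iteration_mask[k]],
                          pool.accumulated)[1] < cfg.alpha
            for k in range(cfg.n_iterations))
        assert count == brute
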