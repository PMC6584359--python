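import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trfpid import infotheory as it
from trfpid import synthetic_data as syn


class TestCopulaNormalize:
    def test_standard_normal_marginals(self, rng):
        x = rng.exponential(size=1000)
        c = it.copula_normalize(x)
        assert abs(c.mean()) < 0.05
        assert abs(c.std() - 1) < 0.1

    def test_monotone_transform_invariance(self, rng):
        x = rng.standard_normal(500)
        np.testing.assert_array_equal(it.copula_normalize(x),
                                      it.copula_normalize(np.exp(x)))

    def test_sorted_stays_sorted(self, rng):
        x = np.sort(rng.standard_normal(200))
        c = it.copula_normalize(x)
        assert np.all(np.diff(c) >= 0)

    def test_constant_channel_raises(self):
        with pytest.raises(ValueError):
            it.copula_normalize(np.ones(100))

    def test_heavy_ties_warn(self, rng):
        x = np.round(rng.standard_normal(1000), 0)
        with pytest.warns(UserWarning, match="tied"):
            it.copula_normalize(x)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=15, deadline=None)
    def test_rank_preservation(self, seed):
        x = np.random.default_rng(seed).standard_normal(100)
        c = it.copula_normalize(x)
        np.testing.assert_array_equal(np.argsort(x), np.argsort(c))


class TestMiGaussianCopula:
    def test_independent_near_zero(self, rng):
        x, y = rng.standard_normal((2, 10_000))
        assert it.mi_gaussian_copula(x, y) < 0.01

    def test_correlated_gaussian_oracle(self, rng):
        # closed form: -0.5 log2(1 - rho^2) = 1.198 bits at rho = 0.9
        n, rho = 100_000, 0.9
        x = rng.standard_normal(n)
        y = rho * x + np.sqrt(1 - rho ** 2) * rng.standard_normal(n)
        expected = -0.5 * np.log2(1 - rho ** 2)
        assert it.mi_gaussian_copula(x, y) == pytest.approx(expected,
                                                            abs=0.02)

    def test_monotone_invariance(self, rng):
        x = rng.standard_normal(2000)
        y = 0.5 * x + rng.standard_normal(2000)
        a = it.mi_gaussian_copula(x, y)
        b = it.mi_gaussian_copula(np.exp(x), y ** 3)
        assert a == b

    def test_deterministic_monotone_pair_does_not_crash(self, rng):
        x = rng.standard_normal(1000)
        mi = it.mi_gaussian_copula(x, np.exp(x))
        assert np.isfinite(mi)
        assert mi > 1.0   # at the estimator ceiling for this n

    def test_discrete_target(self, rng):
        labels = rng.integers(0, 2, size=5000)
        x = labels * 2.0 + 0.3 * rng.standard_normal(5000)
        mi = it.mi_gaussian_copula(x, labels)
        assert 0.5 < mi <= 1.05

    def test_collinear_channels_named(self, rng):
        x = rng.standard_normal(500)
        with pytest.raises(np.linalg.LinAlgError, match="collinear"):
            it.mi_gaussian_copula(np.column_stack([x, x]),
                                  rng.standard_normal(500))

    def test_nonnegative_after_bias_correction(self, rng):
        for seed in range(10):
            r = np.random.default_rng(seed)
            assert it.mi_gaussian_copula(r.standard_normal(500),
                                         r.standard_normal(500)) > -0.005


class TestBinnedMi:
    def test_independent_below_bias_bound(self, rng):
        # oracle: Miller-Madow bias (n_bins-1)(n_classes-1) / (2 n ln 2)
        n, n_bins, n_classes = 10_000, 4, 4
        x = rng.standard_normal(n)
        labels = rng.integers(0, n_classes, size=n)
        bias = (n_bins - 1) * (n_classes - 1) / (2 * n * np.log(2))
        assert it.binned_mi(x, labels, n_bins) < 3 * bias

    def test_perfect_separation_gives_class_entropy(self, rng):
        labels = np.repeat(np.arange(4), 2500)
        x = labels + rng.uniform(0, 0.1, size=10_000)
        assert it.binned_mi(x, labels, 4) == pytest.approx(2.0, abs=0.01)

    def test_single_bin_zero(self, rng):
        x = rng.standard_normal(1000)
        labels = rng.integers(0, 4, size=1000)
        assert it.binned_mi(x, labels, 1) == 0.0

    def test_too_few_distinct_values(self):
        x = np.tile([0.0, 1.0], 500)
        labels = np.random.default_rng(0).integers(0, 2, 1000)
        with pytest.raises(ValueError, match="distinct"):
            it.binned_mi(x, labels, 4)


class TestPidCcs:
    def test_identical_sources(self):
        x, y, t = syn.simulate_pid_triplet(100_000, "redundant", 0.9, seed=5)
        pid = it.pid_ccs(x, y, t, n_mc=100_000, seed=1)
        assert pid.redundancy == pytest.approx(pid.mi_x, abs=0.01)
        assert abs(pid.unique_x) < 0.01
        assert abs(pid.unique_y) < 0.01
        assert abs(pid.synergy) < 0.01

    def test_unique_structure(self):
        x, y, t = syn.simulate_pid_triplet(100_000, "unique_x", 0.8, seed=6)
        pid = it.pid_ccs(x, y, t, n_mc=100_000, seed=1)
        assert abs(pid.redundancy) < 0.02
        assert abs(pid.unique_y) < 0.02
        assert pid.unique_x > 0.3

    def test_synergistic_structure(self):
        x, y, t = syn.simulate_pid_triplet(100_000, "synergistic", 0.8,
                                           seed=7)
        pid = it.pid_ccs(x, y, t, n_mc=100_000, seed=1)
        assert pid.synergy > 5 * pid.redundancy
        assert pid.synergy > 0.5

    def test_lattice_identities(self, rng):
        x = rng.standard_normal(3000)
        y = 0.4 * x + rng.standard_normal(3000)
        t = 0.5 * x + 0.5 * y + rng.standard_normal(3000)
        pid = it.pid_ccs(x, y, t, n_mc=10_000, seed=0)
        assert pid.mi_x == pytest.approx(pid.redundancy + pid.unique_x,
                                         abs=1e-9)
        assert pid.mi_y == pytest.approx(pid.redundancy + pid.unique_y,
                                         abs=1e-9)
        assert pid.mi_joint == pytest.approx(
            pid.redundancy + pid.unique_x + pid.unique_y + pid.synergy,
            abs=1e-9)

    def test_deterministic(self, rng):
        x, y, t = rng.standard_normal((3, 2000))
        a = it.pid_ccs(x, y, t, n_mc=5000, seed=9)
        b = it.pid_ccs(x, y, t, n_mc=5000, seed=9)
        assert a.as_dict() == b.as_dict()

    def test_discrete_target(self, rng):
        labels = rng.integers(0, 4, size=8000)
        x = labels + 0.5 * rng.standard_normal(8000)
        y = x + 2.0 * rng.standard_normal(8000)
        pid = it.pid_ccs(x, y, labels, n_mc=50_000, seed=2)
        # y is a noisy copy of x: its info should be mostly redundant
        assert pid.redundancy > 0.5 * pid.mi_y
        assert pid.mi_x > pid.mi_y

    def test_mc_error_shrinks_with_n_mc(self, rng):
        x = rng.standard_normal(2000)
        y = 0.5 * x + rng.standard_normal(2000)
        t = 0.7 * x + rng.standard_normal(2000)
        reds_small = [it.pid_ccs(x, y, t, n_mc=2000, seed=s).redundancy
                      for s in range(12)]
        reds_big = [it.pid_ccs(x, y, t, n_mc=16_000, seed=s).redundancy
                    for s in range(12)]
        ratio = np.var(reds_small) / np.var(reds_big)
        assert ratio > 2.0    # expect ~8x with 8x the samples


class TestCoinformation:
    def test_identical_sources_equal_marginal(self, rng):
        x = rng.standard_normal(5000)
        t = 0.6 * x + rng.standard_normal(5000)
        coi = it.coinformation(x, x.copy() + 1e-12 * rng.standard_normal(5000),
                               t)
        mi = it.mi_gaussian_copula(x, t)
        assert coi == pytest.approx(mi, abs=0.02)

    def test_independent_near_zero(self, rng):
        x, y, t = rng.standard_normal((3, 10_000))
        assert abs(it.coinformation(x, y, t)) < 0.01

    def test_equals_redundancy_minus_synergy(self, rng):
        x = rng.standard_normal(3000)
        y = 0.3 * x + rng.standard_normal(3000)
        t = 0.5 * (x + y) + rng.standard_normal(3000)
        pid = it.pid_ccs(x, y, t, n_mc=5000, seed=0)
        assert it.coinformation(x, y, t) == pytest.approx(
            pid.redundancy - pid.synergy, abs=1e-9)


class TestPermutationThreshold:
    def test_constant_stat(self, rng):
        thr = it.permutation_threshold(rng.standard_normal(1000),
                                       rng.standard_normal(1000),
                                       lambda a, b: 0.42, n_perm=50,
                                       min_shift=200, seed=0)
        assert thr == pytest.approx(0.42)

    def test_deterministic(self, rng):
        a, b = rng.standard_normal((2, 1000))

        def stat(u, v):
            return np.corrcoef(u, v)[0, 1]

        t1 = it.permutation_threshold(a, b, stat, n_perm=100, seed=3)
        t2 = it.permutation_threshold(a, b, stat, n_perm=100, seed=3)
        assert t1 == t2

    def test_short_series_rejected(self, rng):
        with pytest.raises(ValueError):
            it.permutation_threshold(np.ones(100), np.ones(100),
                                     lambda a, b: 0.0, min_shift=200)


class TestNormalizePid:
    def test_self_redundancy_ratio_one(self):
        x, y, t = syn.simulate_pid_triplet(50_000, "redundant", 0.8, seed=2)
        pid = it.pid_ccs(x, y, t, n_mc=50_000, seed=0)
        norm = it.normalize_pid(pid, pid.mi_x)
        assert norm.redundancy == pytest.approx(1.0, abs=0.02)

    def test_scaling(self, rng):
        x, y, t = rng.standard_normal((3, 2000))
        y = y + 0.5 * t
        pid = it.pid_ccs(x, y, t, n_mc=5000, seed=0)
        norm = it.normalize_pid(pid, 2 * pid.mi_joint)
        assert norm.mi_joint == pytest.approx(0.5)

    def test_negative_reference_unique_gives_ratio_above_one(self, rng):
        # reference with slightly negative unique info: red / mi_ref > 1
        x = rng.standard_normal(50_000)
        t = 0.8 * x + 0.6 * rng.standard_normal(50_000)
        y = x + 0.05 * rng.standard_normal(50_000)   # near-copy reference
        pid = it.pid_ccs(x, y, t, n_mc=100_000, seed=4)
        if pid.unique_y < 0:
            norm = it.normalize_pid(pid, pid.mi_y)
            assert norm.redundancy > 1.0

    def test_invalid_reference(self):
        pid = it.PIDResult(0.1, 0.0, 0.0, 0.0, 0.1, 0.1, 0.1)
        with pytest.raises(ValueError):
            it.normalize_pid(pid, 0.0)
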