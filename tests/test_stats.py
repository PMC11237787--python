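"""Two-group statistics: normality gate, Hodges-Lehmann, rank tests."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from inkcog.errors import InsufficientDataError, UndefinedStatisticError
from inkcog.stats import (
    chi_square,
    compare_feature,
    hodges_lehmann,
    mann_whitney,
    normality_test,
    significant_features,
    spearman,
)


class TestNormalityGate:
    def test_needs_four_observations(self):
        with pytest.raises(InsufficientDataError):
            normality_test([1.0, 2.0, 3.0])

    def test_constant_sample_is_degenerate_non_normal(self):
        assert normality_test([5.0] * 20) == 0.0

    def test_type_one_error_near_nominal_on_normal_data(self, rng):
        rejections = sum(
            normality_test(rng.normal(10, 2, 200)) < 0.05 for _ in range(400)
        )
        # binomial(400, .05): mean 20, 3 SE ~ 13
        assert 7 <= rejections <= 33

    def test_power_against_lognormal(self, rng):
        rejections = sum(
            normality_test(rng.lognormal(0, 1, 500)) < 0.05 for _ in range(100)
        )
        assert rejections >= 99


class TestHodgesLehmann:
    def test_unit_shift_between_small_samples(self):
        # 9 pairwise differences of {2,3,4}-{1,2,3}: median is 1
        hl = hodges_lehmann([1, 2, 3], [2, 3, 4])
        assert hl.estimate == 1.0

    def test_matches_brute_force_median_of_pairwise_differences(self, rng):
        for _ in range(200):
            n, m = int(rng.integers(2, 12)), int(rng.integers(2, 12))
            hc = rng.normal(0, 3, n)
            mci = rng.normal(1, 3, m)
            oracle = float(
                np.median(sorted(b - a for a in hc for b in mci))
            )
            assert hodges_lehmann(hc, mci).estimate == pytest.approx(oracle)

    def test_shift_equivariance_and_range(self, rng):
        hc = rng.normal(0, 1, 30)
        mci = rng.normal(0.5, 1, 25)
        base = hodges_lehmann(hc, mci)
        for c in (-3.0, 2.5, 10.0):
            shifted = hodges_lehmann(hc, mci + c)
            assert shifted.estimate == pytest.approx(base.estimate + c)
        diffs = [b - a for a in hc for b in mci]
        assert min(diffs) <= base.estimate <= max(diffs)
        assert base.ci_low <= base.estimate <= base.ci_high

    def test_shift_recovery_at_large_n(self, rng):
        delta = 200.0
        hc = rng.lognormal(6, 0.5, 500)
        mci = hc * 0 + rng.lognormal(6, 0.5, 500) + delta
        est = hodges_lehmann(hc, mci).estimate
        assert abs(est - delta) / delta < 0.10


class TestMannWhitney:
    def _brute_force_exact_p(self, hc, mci):
        """Exact two-sided p by enumerating all group reassignments."""
        pooled = np.concatenate([hc, mci])
        n = len(hc)
        u_obs = sps.mannwhitneyu(mci, hc, alternative="two-sided").statistic
        nm = len(hc) * len(mci)
        dev_obs = abs(u_obs - nm / 2)
        count = total = 0
        for idx in itertools.combinations(range(len(pooled)), n):
            mask = np.zeros(len(pooled), dtype=bool)
            mask[list(idx)] = True
            u = sps.mannwhitneyu(
                pooled[~mask], pooled[mask], alternative="two-sided"
            ).statistic
            total += 1
            count += abs(u - nm / 2) >= dev_obs - 1e-9
        return count / total

    def test_exact_route_matches_enumeration_oracle(self, rng):
        for _ in range(5):
            hc = rng.normal(0, 1, 5)
            mci = rng.normal(0.8, 1, 5)
            _, p, method = mann_whitney(hc, mci)
            assert method == "exact"
            assert p == pytest.approx(self._brute_force_exact_p(hc, mci), abs=1e-9)

    def test_approximation_close_to_exact_at_small_n(self, rng):
        diffs = []
        for _ in range(20):
            hc = rng.normal(0, 1, 10)
            mci = rng.normal(0.5, 1, 12)
            _, p_exact, _ = mann_whitney(hc, mci)
            res = sps.mannwhitneyu(mci, hc, alternative="two-sided", method="asymptotic")
            diffs.append(abs(p_exact - res.pvalue))
        assert max(diffs) < 0.05

    def test_invariant_under_strictly_monotone_transform(self, rng):
        hc = rng.lognormal(0, 1, 40)
        mci = rng.lognormal(0.3, 1, 35)
        _, p_raw, _ = mann_whitney(hc, mci)
        _, p_log, _ = mann_whitney(np.log(hc), np.log(mci))
        assert p_raw == pytest.approx(p_log, abs=1e-12)


class TestCompareFeature:
    def test_identical_samples_no_shift_high_p(self, rng):
        x = rng.normal(50, 5, 30)
        comp = compare_feature(x, x.copy())
        assert comp.hl.estimate == 0.0
        assert comp.p_value > 0.9
        assert not comp.significant

    def test_gate_routes_normal_data_to_t_test(self, rng):
        comp = compare_feature(rng.normal(0, 1, 200), rng.normal(0.3, 1, 200))
        assert comp.test_used == "t"

    def test_gate_routes_skewed_data_to_mann_whitney(self, rng):
        comp = compare_feature(rng.lognormal(0, 1, 200), rng.lognormal(0.3, 1, 200))
        assert comp.test_used == "mann_whitney"

    def test_empty_or_tiny_group_rejected(self):
        with pytest.raises(InsufficientDataError):
            compare_feature([1.0, 2.0], [1.0, 2.0, 3.0, 4.0])


class TestSignificanceFilter:
    def test_preserves_catalog_order(self):
        comps = [("f03", 0.0005), ("f01", 0.2), ("f06", 0.01), ("f17", 0.049)]
        assert significant_features(comps) == ["f03", "f06", "f17"]

    def test_all_null_is_empty(self):
        assert significant_features([(f"f{i}", 0.5) for i in range(17)]) == []

    def test_matches_brute_force_filter(self, rng):
        ps = rng.random(100)
        comps = [(f"f{i}", p) for i, p in enumerate(ps)]
        oracle = [f"f{i}" for i, p in enumerate(ps) if p < 0.05]
        assert significant_features(comps) == oracle


class TestCategoricalAndCorrelation:
    def test_proportional_table_has_zero_statistic(self):
        stat, p = chi_square([[10, 20], [30, 60]])
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_diagonal_table_hand_computation(self):
        # Pearson formula on [[10,0],[0,10]]: every cell contributes 5
        stat, p = chi_square([[10, 0], [0, 10]])
        assert stat == pytest.approx(20.0)
        assert p == pytest.approx(sps.chi2.sf(20.0, 1))

    def test_zero_expected_cell_is_error(self):
        with pytest.raises(UndefinedStatisticError):
            chi_square([[0, 5], [0, 10]])

    def test_chi_square_null_calibration(self, rng):
        rejections = 0
        for _ in range(300):
            a = rng.multinomial(50, [0.5, 0.5])
            b = rng.multinomial(60, [0.5, 0.5])
            _, p = chi_square([a, b])
            rejections += p < 0.05
        assert 3 <= rejections <= 28  # binomial(300,.05) +- ~3 SE

    def test_spearman_perfect_monotone(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        assert spearman(x, x)[0] == pytest.approx(1.0)
        assert spearman(x, [-v for v in x])[0] == pytest.approx(-1.0)

    def test_spearman_matches_rank_formula(self, rng):
        x = rng.normal(size=50)
        y = x + rng.normal(size=50)
        rho, _ = spearman(x, y)
        rx, ry = sps.rankdata(x), sps.rankdata(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(oracle, abs=1e-12)

    def test_spearman_constant_vector_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            spearman([1.0] * 6, [1, 2, 3, 4, 5, 6])
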