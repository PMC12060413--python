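"""Rank tests, t-tests and regression against oracles and invariants."""
import math

import numpy as np
import pytest
import scipy.stats as sps

from rteshift.intervals import ValidationError
from rteshift.stats import (
    dunn_pairwise,
    kruskal_wallis,
    linregress,
    mann_whitney,
    t_test,
)


class TestMannWhitney:
    def test_separated_groups_exact(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6], mode="exact")
        assert res.statistic_value == 0.0
        assert res.p == pytest.approx(0.1)  # 2/20 rank assignments as extreme

    def test_identical_multisets_p1(self):
        res = mann_whitney([1, 1, 2, 3], [1, 1, 2, 3], mode="exact")
        assert res.p == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            mann_whitney([], [1.0])

    def test_normal_approx_close_to_exact(self):
        rng = np.random.default_rng(12)
        x = rng.normal(0, 1, 7)
        y = rng.normal(1.2, 1, 7)
        p_exact = mann_whitney(x, y, mode="exact").p
        p_norm = mann_whitney(x, y, mode="normal_approx").p
        assert p_norm == pytest.approx(p_exact, rel=0.10)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(13)
        x, y = rng.normal(0, 1, 9), rng.normal(0.8, 1, 11)
        r1 = mann_whitney(x, y, mode="normal_approx")
        r2 = mann_whitney(np.exp(x), np.exp(y), mode="normal_approx")
        assert r1.p == pytest.approx(r2.p) and r1.statistic_value == r2.statistic_value


class TestKruskalWallis:
    def test_handworked_h(self):
        res = kruskal_wallis([[1, 2], [3, 4], [5, 6]])
        assert res.statistic_value == pytest.approx(4.571, abs=5e-4)

    def test_identical_groups(self):
        res = kruskal_wallis([[2, 2], [2, 2], [2, 2]])
        assert res.statistic_value == 0.0 and res.p == 1.0

    def test_fewer_than_three_groups_rejected(self):
        with pytest.raises(ValidationError):
            kruskal_wallis([[1, 2], [3, 4]])

    def test_matches_scipy_with_ties(self):
        rng = np.random.default_rng(14)
        groups = [rng.integers(0, 6, 12).astype(float) for _ in range(4)]
        res = kruskal_wallis(groups)
        ref = sps.kruskal(*groups)
        assert res.statistic_value == pytest.approx(ref.statistic, rel=1e-10)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_monotone_relation_to_mann_whitney_with_k2_semantics(self):
        # H for two groups is the square of the MW z-statistic up to ties;
        # check ordering of p-values across shifted datasets
        rng = np.random.default_rng(15)
        base = rng.normal(0, 1, 10)
        p_mw, p_kw = [], []
        for shift in (0.2, 0.8, 1.6):
            x, y = base, base + shift
            p_mw.append(mann_whitney(x, y, mode="normal_approx").p)
            p_kw.append(sps.kruskal(x, y).pvalue)
        assert np.argsort(p_mw).tolist() == np.argsort(p_kw).tolist()


class TestDunn:
    def test_identical_pair_z_zero(self):
        pairs = dunn_pairwise([[1, 2, 3], [1, 2, 3], [10, 11, 12]], adjust="none")
        z12 = [z for i, j, z, p in pairs if (i, j) == (0, 1)][0]
        p12 = [p for i, j, z, p in pairs if (i, j) == (0, 1)][0]
        assert z12 == pytest.approx(0.0) and p12 == pytest.approx(1.0)

    def test_symmetric_configuration(self):
        pairs = dunn_pairwise([[1, 2], [3, 4], [5, 6]], adjust="none")
        z = {(i, j): abs(zv) for i, j, zv, _ in pairs}
        assert z[(0, 1)] == pytest.approx(z[(1, 2)])

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(16)
        groups = [rng.normal(m, 1, 8) for m in (0, 0.5, 2.0)]
        raw = dunn_pairwise(groups, adjust="none")
        adj = dunn_pairwise(groups, adjust="holm")
        for (_, _, _, p_raw), (_, _, _, p_adj) in zip(raw, adj):
            assert p_adj >= p_raw - 1e-12


class TestTTestAndRegression:
    def test_paired_identical_p1(self):
        res = t_test([1, 2, 3], [1, 2, 3], paired=True)
        assert res.statistic_value == 0.0 and res.p == 1.0

    def test_welch_matches_scipy(self):
        rng = np.random.default_rng(17)
        x, y = rng.normal(0, 1, 10), rng.normal(1, 2, 14)
        res = t_test(x, y)
        ref = sps.ttest_ind(x, y, equal_var=False)
        assert res.statistic_value == pytest.approx(ref.statistic, rel=1e-10)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_student_matches_scipy(self):
        rng = np.random.default_rng(18)
        x, y = rng.normal(0, 1, 8), rng.normal(0.5, 1, 8)
        res = t_test(x, y, equal_var=True)
        ref = sps.ttest_ind(x, y, equal_var=True)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_zero_variance_flagged(self):
        with pytest.warns(UserWarning):
            res = t_test([1, 1, 1], [2, 2, 2])
        assert res.p == 0.0

    def test_perfect_line(self):
        x = np.arange(5.0)
        slope, intercept, r2, p = linregress(x, 2 * x)
        assert slope == pytest.approx(2.0) and r2 == pytest.approx(1.0)

    def test_linregress_matches_scipy(self):
        rng = np.random.default_rng(19)
        x = rng.normal(0, 1, 30)
        y = 0.7 * x + rng.normal(0, 0.5, 30)
        slope, intercept, r2, p = linregress(x, y)
        ref = sps.linregress(x, y)
        assert slope == pytest.approx(ref.slope, rel=1e-10)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_degenerate_x_warns(self):
        with pytest.warns(UserWarning):
            slope, *_ = linregress([1, 1, 1], [1, 2, 3])
        assert math.isnan(slope)
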