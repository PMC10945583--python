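"""Statistics core vs brute-force oracles and library cross-checks."""
import math

import numpy as np
import pytest
from scipy import stats as sps

from thcdosim import (linreg_ftest, one_way_anova, sem, sidak_adjust,
                      two_way_anova)
from thcdosim.errors import ConfigurationError, DegenerateDesignError


class TestSem:
    @pytest.mark.parametrize("values,expected", [
        ([1, 1, 1], 0.0),
        ([0, 2], 1.0),
    ])
    def test_examples(self, values, expected):
        assert sem(values) == pytest.approx(expected)

    def test_printed_across_behavior_sem(self):
        assert round(sem([10.3, 11.6, 4.5]), 1) == 2.2

    def test_single_value_not_available(self):
        assert math.isnan(sem([3.0]))


class TestOneWayAnova:
    def test_identical_groups_give_f_zero(self):
        res = one_way_anova([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        assert res["group"].f == 0.0
        assert res["group"].p == 1.0

    def test_two_groups_f_equals_t_squared(self, rng):
        a, b = rng.normal(0, 1, 8), rng.normal(0.5, 1, 8)
        res = one_way_anova([a, b])
        t, p = sps.ttest_ind(a, b)
        assert res["group"].f == pytest.approx(t ** 2, rel=1e-10)
        assert res["group"].p == pytest.approx(p, rel=1e-10)

    def test_matches_brute_force_and_scipy(self, rng):
        groups = [rng.normal(m, 1, n) for m, n in ((0, 5), (1, 7), (2, 6))]
        res = one_way_anova(groups)
        # brute-force sums of squares
        allx = np.concatenate(groups)
        ssb = sum(len(g) * (g.mean() - allx.mean()) ** 2 for g in groups)
        ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
        f_oracle = (ssb / 2) / (ssw / (len(allx) - 3))
        assert res["group"].f == pytest.approx(f_oracle, abs=1e-10)
        f_sp, p_sp = sps.f_oneway(*groups)
        assert res["group"].f == pytest.approx(f_sp, rel=1e-12)
        assert res["group"].p == pytest.approx(p_sp, rel=1e-12)

    def test_singleton_group_rejected(self):
        with pytest.raises(DegenerateDesignError):
            one_way_anova([[1.0], [1, 2, 3]])

    def test_location_scale_invariance(self, rng):
        groups = [rng.normal(m, 1, 6) for m in (0, 1)]
        f0 = one_way_anova(groups)["group"].f
        shifted = [g + 100.0 for g in groups]
        scaled = [g * 3.0 for g in groups]
        assert one_way_anova(shifted)["group"].f == pytest.approx(f0, rel=1e-9)
        assert one_way_anova(scaled)["group"].f == pytest.approx(f0, rel=1e-9)


class TestTwoWayAnova:
    def _long(self, cube):
        """cube[a, b, r] -> aligned value/factor arrays."""
        vals, fa, fb, subj = [], [], [], []
        a, b, r = cube.shape
        for i in range(a):
            for j in range(b):
                for k in range(r):
                    vals.append(cube[i, j, k])
                    fa.append(f"a{i}")
                    fb.append(f"b{j}")
                    subj.append(f"s{i}_{k}")
        return np.array(vals), np.array(fa), np.array(fb), np.array(subj)

    def test_all_equal_cells_give_zero_f(self):
        cube = np.full((2, 3, 4), 7.0)
        vals, fa, fb, _ = self._long(cube)
        res = two_way_anova(vals, fa, fb)
        assert all(e.f == 0.0 and e.p == 1.0 for e in res.effects)

    def test_additive_data_has_no_interaction(self, rng):
        a_eff = np.array([0.0, 2.0])
        b_eff = np.array([0.0, 1.0, 3.0])
        cube = (a_eff[:, None, None] + b_eff[None, :, None]
                + np.zeros((2, 3, 4)))
        vals, fa, fb, _ = self._long(cube)
        res = two_way_anova(vals, fa, fb)
        assert res["A:B"].f == pytest.approx(0.0, abs=1e-10)
        assert res["A"].f > 0 and res["B"].f > 0

    def test_2x2_matches_projection_oracle(self, rng):
        cube = rng.normal(0, 1, (2, 2, 5))
        vals, fa, fb, _ = self._long(cube)
        res = two_way_anova(vals, fa, fb)
        gm = cube.mean()
        ma = cube.mean(axis=(1, 2))
        mb = cube.mean(axis=(0, 2))
        mc = cube.mean(axis=2)
        ss_a = 10 * ((ma - gm) ** 2).sum()
        ss_b = 10 * ((mb - gm) ** 2).sum()
        ss_ab = 5 * ((mc - ma[:, None] - mb[None, :] + gm) ** 2).sum()
        ss_err = ((cube - mc[:, :, None]) ** 2).sum()
        assert res["A"].ss == pytest.approx(ss_a, abs=1e-10)
        assert res["B"].ss == pytest.approx(ss_b, abs=1e-10)
        assert res["A:B"].ss == pytest.approx(ss_ab, abs=1e-10)
        assert res.ss_residual == pytest.approx(ss_err, abs=1e-10)
        f_a = (ss_a / 1) / (ss_err / 16)
        assert res["A"].f == pytest.approx(f_a, rel=1e-12)

    def test_repeated_measures_blocks_subject_variance(self, rng):
        # subject offsets inflate the naive error term but not the
        # blocked one, so blocking must increase the within-factor F
        cube = rng.normal(0, 0.2, (2, 3, 6))
        cube += np.array([0.0, 1.5])[:, None, None]  # A effect
        cube += np.linspace(0, 2, 3)[None, :, None]  # B (within) effect
        subj_off = rng.normal(0, 3.0, (2, 6))
        cube += subj_off[:, None, :]
        vals, fa, fb, subj = self._long(cube)
        plain = two_way_anova(vals, fa, fb)
        blocked = two_way_anova(vals, fa, fb, subject=subj)
        assert blocked["B"].f > plain["B"].f
        # SS decomposition stays exact
        parts = (blocked["A"].ss + blocked["B"].ss + blocked["A:B"].ss
                 + blocked.ss_residual)
        ss_subj = blocked.ss_total - parts
        assert ss_subj > 0

    def test_unbalanced_rejected(self):
        vals = np.arange(7.0)
        fa = np.array(["x"] * 4 + ["y"] * 3)
        fb = np.array(["u", "u", "v", "v", "u", "v", "v"])
        with pytest.raises(Exception):
            two_way_anova(vals, fa, fb)


class TestSidak:
    @pytest.mark.parametrize("p,m,expected", [
        (0.05, 1, 0.05),
        (0.01, 3, 0.029701),
        (0.5, 2, 0.75),
    ])
    def test_examples(self, p, m, expected):
        assert sidak_adjust(p, m) == pytest.approx(expected, abs=1e-12)

    def test_monotone_and_conservative(self):
        ps = np.linspace(0.001, 0.5, 20)
        for p in ps:
            assert sidak_adjust(p, 3) >= p
            assert sidak_adjust(p, 5) >= sidak_adjust(p, 3)
        adj = [sidak_adjust(p, 4) for p in ps]
        assert all(a <= b for a, b in zip(adj, adj[1:]))

    def test_caps_at_one(self):
        assert sidak_adjust(0.9, 50) == 1.0

    def test_invalid_inputs(self):
        with pytest.raises(ConfigurationError):
            sidak_adjust(1.5, 2)
        with pytest.raises(ConfigurationError):
            sidak_adjust(0.05, 0)


class TestLinregFtest:
    def test_perfect_line(self):
        res = linreg_ftest([0, 1, 2, 3], [1, 3, 5, 7])
        assert res.r_squared == pytest.approx(1.0)
        assert res.slope == pytest.approx(2.0)
        assert res.p < 1e-10

    def test_constant_y(self):
        res = linreg_ftest([0, 1, 2, 3], [4, 4, 4, 4])
        assert res.f == 0.0
        assert res.slope == 0.0

    def test_matches_scipy_and_t_squared(self, rng):
        x = rng.normal(0, 1, 12)
        y = 0.8 * x + rng.normal(0, 0.5, 12)
        res = linreg_ftest(x, y)
        lr = sps.linregress(x, y)
        assert res.slope == pytest.approx(lr.slope, rel=1e-10)
        assert res.intercept == pytest.approx(lr.intercept, rel=1e-10)
        assert res.p == pytest.approx(lr.pvalue, rel=1e-9)
        # F for the slope is the square of its t statistic
        t = lr.slope / lr.stderr
        assert res.f == pytest.approx(t ** 2, rel=1e-9)

    def test_constant_x_rejected(self):
        with pytest.raises(DegenerateDesignError):
            linreg_ftest([2, 2, 2, 2], [1, 2, 3, 4])
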