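"""Allometric fits, power screening, Wilcoxon comparisons, CCC and TLS."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from quadvol.allometry import (compare_voxel_distributions, fit_linear, fit_log,
                               lins_ccc, power_screen, tls_fit)


class TestFitLinear:
    def test_perfect_line(self):
        x = np.linspace(1, 10, 10)
        res = fit_linear(x, 2 * x + 1)
        assert np.isclose(res.slope, 2) and np.isclose(res.intercept, 1)
        assert np.isclose(res.r_squared, 1) and res.rmse_g < 1e-10

    def test_constant_response_flagged(self):
        res = fit_linear(np.arange(5.0) + 1, np.full(5, 3.0))
        assert res.r_squared == 0 and res.degenerate

    def test_zero_predictor_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            fit_linear(np.ones(5), np.arange(5.0))

    def test_matches_normal_equations_oracle(self, rng):
        x = rng.uniform(0, 5, size=10)
        y = rng.uniform(0, 100, size=10)
        res = fit_linear(x, y)
        A = np.column_stack([np.ones(10), x])
        beta = np.linalg.solve(A.T @ A, A.T @ y)
        assert abs(res.intercept - beta[0]) < 1e-10
        assert abs(res.slope - beta[1]) < 1e-10


class TestFitLog:
    def test_exact_power_law_recovered(self):
        v = np.geomspace(1e-4, 1e-2, 20)
        res = fit_log(v, 800 * (v / 1e-3) ** 1.3)
        assert abs(res.slope - 1.3) < 1e-9
        assert np.isclose(res.r_squared, 1.0)
        assert res.rmse_g < 1e-6

    def test_recovers_exponent_under_lognormal_noise(self):
        r = np.random.default_rng(42)
        v = 1e-3 * np.exp(r.normal(0, 1.0, size=288))
        b = 800 * (v / 1e-3) * np.exp(r.normal(0, 0.5, size=288))
        res = fit_log(v, b)
        assert abs(res.slope - 1.0) < 0.1

    def test_outlier_strictly_degrades_fit(self):
        v = np.geomspace(1e-4, 1e-2, 20)
        b = 800 * (v / 1e-3)
        clean = fit_log(v, b)
        spoiled = b.copy()
        spoiled[10] *= 10
        assert fit_log(v, spoiled).r_squared < clean.r_squared

    def test_nonpositive_inputs_listed(self):
        with pytest.raises(ValueError, match="indices \\[1\\]"):
            fit_log(np.array([1.0, -1.0, 2.0]), np.array([1.0, 2.0, 3.0]))

    def test_semilog_variant(self):
        v = np.geomspace(1e-4, 1e-2, 15)
        b = 5 + 2 * np.log(v)
        res = fit_log(v, b, semilog=True)
        assert res.form == "semilog"
        assert abs(res.slope - 2) < 1e-9


class TestPowerScreen:
    def test_f_squared_identity(self):
        res = power_screen(fit_linear(np.arange(10.0), np.arange(10.0) * 2 + 1))
        assert res.f_squared == np.inf and res.achieved_power == 1.0
        base = fit_linear(np.arange(10.0), np.arange(10.0))
        half = power_screen(base.__class__(**{**base.__dict__, "r_squared": 0.5}))
        assert np.isclose(half.f_squared, 1.0)

    def test_null_power_equals_alpha(self):
        base = fit_linear(np.arange(10.0), np.arange(10.0))
        null = power_screen(base.__class__(**{**base.__dict__, "r_squared": 0.0}),
                            alpha=0.05)
        assert np.isclose(null.achieved_power, 0.05, atol=1e-12)
        assert not null.significant

    def test_matches_poisson_mixture_oracle(self):
        """Noncentral-F tail via its Poisson mixture of central F variates."""
        base = fit_linear(np.arange(288.0), np.arange(288.0))
        res = power_screen(base.__class__(**{**base.__dict__, "r_squared": 0.30,
                                             "n": 288}))
        f2 = 0.30 / 0.70
        lam = f2 * 288
        crit = stats.f.isf(0.05, 1, 286)
        oracle = sum(
            stats.poisson.pmf(j, lam / 2) * stats.f.sf(crit / (1 + 2 * j), 1 + 2 * j, 286)
            for j in range(400)
        )
        assert abs(res.achieved_power - oracle) < 1e-6

    def test_monotone_in_r_squared_and_n(self):
        base = fit_linear(np.arange(30.0), np.arange(30.0))
        powers = [
            power_screen(base.__class__(**{**base.__dict__, "r_squared": r2,
                                           "n": n})).achieved_power
            for r2, n in [(0.1, 30), (0.2, 30), (0.2, 60), (0.4, 60)]
        ]
        assert powers == sorted(powers)


class TestWilcoxonTable:
    def test_identical_columns_give_p_one(self, rng):
        col = rng.uniform(0, 1, size=10)
        table = compare_voxel_distributions(np.column_stack([col, col]))
        assert table.iloc[0, 1] == 1.0

    def test_all_positive_shift_matches_enumeration_oracle(self):
        """n = 8 plots, column B = A + 1 everywhere: the exact two-sided p
        equals the full enumeration over all 2^8 sign assignments."""
        a = np.arange(8, dtype=float)
        mat = np.column_stack([a + 1.0, a])
        table = compare_voxel_distributions(mat)
        # enumeration: W+ statistic over every sign assignment of ranks 1..8
        ranks = np.arange(1, 9)
        w_obs = ranks.sum()  # all differences positive
        count_ge = sum(
            1 for signs in itertools.product([0, 1], repeat=8)
            if (ranks * np.array(signs)).sum() >= w_obs
        )
        one_sided = count_ge / 2**8
        assert one_sided == 1 / 2**8
        assert np.isclose(table.iloc[0, 1], 2 * one_sided)

    def test_nested_doubling_all_pairs_significant(self, rng):
        pts_volumes = []
        for _ in range(100):
            pts = rng.uniform(0, 0.3, size=(150, 3))
            from quadvol.volumes import VoxelParams, voxel_size_sweep
            _, vols = voxel_size_sweep(pts, VoxelParams(edge_lengths=(0.01, 0.02, 0.04)),
                                       (0, 0, 0))
            pts_volumes.append([vols[0.01], vols[0.02], vols[0.04]])
        table = compare_voxel_distributions(np.array(pts_volumes))
        off_diag = table.to_numpy()[~np.eye(3, dtype=bool)]
        assert (off_diag < 0.05).all()

    def test_symmetry_and_diagonal(self, rng):
        mat = rng.uniform(0, 1, size=(12, 3))
        table = compare_voxel_distributions(mat)
        assert np.allclose(table.to_numpy(), table.to_numpy().T)
        assert np.allclose(np.diag(table.to_numpy()), 1.0)


class TestLinsCcc:
    def test_perfect_concordance_and_discordance(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert np.isclose(lins_ccc(x, x), 1.0)
        y = np.array([-1.5, -0.5, 0.5, 1.5])
        assert np.isclose(lins_ccc(y, -y), -1.0)

    def test_hand_moment_oracle(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.1, 2.1, 2.9, 4.2])
        cov = ((x - x.mean()) * (y - y.mean())).mean()
        expected = 2 * cov / (x.var() + y.var() + (x.mean() - y.mean()) ** 2)
        assert np.isclose(lins_ccc(x, y), expected)

    def test_never_exceeds_pearson_in_magnitude(self, rng):
        for _ in range(20):
            x = rng.normal(0, 1, 30)
            y = rng.normal(0, 2, 30) + 0.5 * x
            r = np.corrcoef(x, y)[0, 1]
            assert abs(lins_ccc(x, y)) <= abs(r) + 1e-12

    def test_equals_pearson_when_moments_match(self, rng):
        x = rng.normal(0, 1, 50)
        y = rng.normal(0, 1, 50)
        # standardise both to identical means and variances
        x = (x - x.mean()) / x.std()
        y = (y - y.mean()) / y.std()
        assert np.isclose(lins_ccc(x, y), np.corrcoef(x, y)[0, 1])


class TestTlsFit:
    def test_noiseless_line(self, rng):
        x = rng.uniform(0, 10, 30)
        line = tls_fit(x, 3 * x - 2)
        assert np.isclose(line.slope, 3) and np.isclose(line.intercept, -2)

    def test_vertical_data_flagged(self):
        line = tls_fit(np.full(10, 2.0), np.linspace(0, 1, 10))
        assert line.vertical and np.isinf(line.slope)

    def test_axis_swap_inverts_slope(self, rng):
        x = rng.uniform(0, 1, 40)
        y = 2 * x + rng.normal(0, 0.05, 40)
        assert np.isclose(tls_fit(x, y).slope, 1 / tls_fit(y, x).slope)

    def test_orthogonal_residual_beats_both_ols_orientations(self, rng):
        def orth_ss(x, y, slope, intercept):
            return (((y - slope * x - intercept) ** 2) / (1 + slope**2)).sum()

        for _ in range(10):
            x = rng.uniform(0, 1, 25)
            y = 1.5 * x + rng.normal(0, 0.3, 25)
            tls = tls_fit(x, y)
            ss_tls = orth_ss(x, y, tls.slope, tls.intercept)
            ols = fit_linear(x, y)
            ss_xy = orth_ss(x, y, ols.slope, ols.intercept)
            inv = fit_linear(y, x)  # x = a + b y -> y = (x - a)/b
            ss_yx = orth_ss(x, y, 1 / inv.slope, -inv.intercept / inv.slope)
            assert ss_tls <= ss_xy + 1e-12
            assert ss_tls <= ss_yx + 1e-12
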