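import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from arboreml.genetics import (
    accuracy,
    coefficients_of_variation,
    correlate_breeding_values,
    delta_method_se,
    heritability,
    type_b_correlation,
)


class TestHeritability:
    def test_published_height_values(self):
        # RCBD and sub-blocking variance components for height
        assert heritability(0.405, 0.0, 2.315) == pytest.approx(0.149, abs=5e-4)
        # components are printed rounded to 3 decimals, so the ratio can
        # differ from the printed h2 in the last digit
        assert heritability(0.407, 0.0, 1.995) == pytest.approx(0.170, abs=1e-3)

    def test_heterogeneous_uses_trial_mean(self):
        h = heritability(1.0, 0.0, [1.0, 3.0])  # mean residual = 2
        assert h == pytest.approx(1.0 / 3.0)

    def test_zero_additive(self):
        assert heritability(0.0, 0.1, 1.0) == 0.0

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            heritability(0.0, 0.0, 0.0)

    @given(
        a=st.floats(0.01, 5),
        ae=st.floats(0, 5),
        e=st.floats(0.01, 5),
        k=st.floats(0.1, 10),
    )
    def test_scale_invariance(self, a, ae, e, k):
        assert heritability(k * a, k * ae, k * e) == pytest.approx(
            heritability(a, ae, e), rel=1e-9
        )

    def test_monotone_decreasing_in_residual(self):
        hs = [heritability(0.4, 0.1, e) for e in (1.0, 2.0, 3.0)]
        assert hs[0] > hs[1] > hs[2]


class TestTypeB:
    def test_no_gxe(self):
        assert type_b_correlation(0.5, 0.0) == 1.0

    def test_published_dbh_values(self):
        assert type_b_correlation(0.727, 0.077) == pytest.approx(0.904, abs=5e-4)

    def test_symmetric_case(self):
        assert type_b_correlation(0.3, 0.3) == 0.5

    def test_monotone_decreasing_in_interaction(self):
        rs = [type_b_correlation(0.4, x) for x in (0.0, 0.2, 0.4)]
        assert rs[0] > rs[1] > rs[2]

    def test_zero_denominator(self):
        with pytest.raises(ValueError):
            type_b_correlation(0.0, 0.0)


class TestCV:
    def test_variance_over_mean_convention(self):
        cv_a, cv_p, cv_e = coefficients_of_variation(0.405, 2.72, 2.315, 7.4)
        assert cv_a == pytest.approx(100 * 0.405 / 7.4, rel=1e-9)  # ~5.5%
        assert cv_p == pytest.approx(100 * 2.72 / 7.4, rel=1e-9)

    def test_large_phenotypic_cv(self):
        _, cv_p, _ = coefficients_of_variation(0.7, 10.0, 9.3, 8.8)
        assert cv_p == pytest.approx(113.6, abs=0.1)  # ~114% as reported for DBH

    def test_zero_variance(self):
        cv_a, _, _ = coefficients_of_variation(0.0, 1.0, 1.0, 5.0)
        assert cv_a == 0.0

    def test_sd_variant(self):
        cv_a, _, _ = coefficients_of_variation(4.0, 9.0, 1.0, 10.0, use_sd=True)
        assert cv_a == pytest.approx(20.0)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            coefficients_of_variation(1, 2, 1, 0.0)


class TestAccuracy:
    def test_perfect_prediction(self):
        assert accuracy(0.0, 0.0, 0.5) == pytest.approx(1.0)

    def test_no_information(self):
        f = 0.125
        assert accuracy((1 + f) * 0.5, f, 0.5) == pytest.approx(0.0)

    def test_arithmetic(self):
        assert accuracy(0.75 * 0.4, 0.0, 0.4) == pytest.approx(0.5)

    def test_negative_radicand_clipped(self):
        assert accuracy(10.0, 0.0, 0.5) == 0.0

    def test_zero_additive_rejected(self):
        with pytest.raises(ValueError):
            accuracy(0.1, 0.0, 0.0)


class TestDeltaMethod:
    def test_linear_transform_exact(self):
        a = np.array([2.0, -1.0, 0.5])
        cov = np.array([[0.2, 0.05, 0.0], [0.05, 0.3, 0.01], [0.0, 0.01, 0.1]])
        se = delta_method_se(lambda th: float(a @ th), np.array([1.0, 2.0, 3.0]), cov)
        assert se == pytest.approx(np.sqrt(a @ cov @ a), rel=1e-6)

    def test_h2_toy_matches_symbolic_gradient(self):
        theta = np.array([0.4, 2.0])  # (V_A, V_E)
        cov = np.diag([0.01, 0.04])

        def h2(th):
            return th[0] / (th[0] + th[1])

        se = delta_method_se(h2, theta, cov)
        s = theta.sum()
        g = np.array([theta[1] / s**2, -theta[0] / s**2])
        assert se == pytest.approx(np.sqrt(g @ cov @ g), rel=1e-5)

    def test_zero_covariance(self):
        se = delta_method_se(lambda th: th[0] ** 2, np.array([1.0]), np.zeros((1, 1)))
        assert se == 0.0

    def test_boundary_rows_make_se_unavailable(self):
        cov = np.array([[0.1, np.nan], [np.nan, np.nan]])
        se = delta_method_se(lambda th: th.sum(), np.array([1.0, 0.0]), cov)
        assert np.isnan(se)

    def test_agrees_with_monte_carlo(self):
        """Delta-method SE within 10% of parametric-resampling SE."""
        rng = np.random.default_rng(0)
        theta = np.array([0.4, 0.1, 2.0])
        cov = np.diag([0.02**2, 0.015**2, 0.06**2])

        def h2(th):
            return th[0] / (th[0] + th[1] + th[2])

        se = delta_method_se(h2, theta, cov)
        draws = rng.multivariate_normal(theta, cov, 100_000)
        mc = np.std([h2(d) for d in draws])
        assert se == pytest.approx(mc, rel=0.1)


class TestBreedingValueCorrelations:
    def test_identical_to_latitude(self):
        rng = np.random.default_rng(1)
        lat = rng.uniform(30, 35, 20)
        tab = pd.DataFrame({"lat": lat, "long": rng.uniform(-95, -90, 20), "bv_ht": lat})
        out = correlate_breeding_values(tab)
        assert out["correlations"].loc["lat", "bv_ht"] == pytest.approx(1.0)

    def test_null_simulation_mean_abs_correlation_small(self):
        rs = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            tab = pd.DataFrame(
                {
                    "lat": rng.uniform(30, 35, 1000),
                    "long": rng.uniform(-95, -90, 1000),
                    "bv": rng.standard_normal(1000),
                }
            )
            out = correlate_breeding_values(tab)
            rs.append(abs(out["correlations"].loc["lat", "bv"]))
        assert np.mean(rs) < 0.1

    def test_perfect_quadratic_surface(self):
        rng = np.random.default_rng(2)
        lat = rng.uniform(30, 35, 40)
        lon = rng.uniform(-95, -90, 40)
        bv = 1.0 + 0.2 * lat**2 - 0.1 * lon**2 + 0.05 * lat * lon
        out = correlate_breeding_values(pd.DataFrame({"lat": lat, "long": lon, "bv": bv}))
        assert out["surface_r2"]["bv"] == pytest.approx(1.0, abs=1e-10)

    def test_constant_column_reported_missing(self):
        tab = pd.DataFrame(
            {"lat": [30.0, 31, 32], "long": [-91.0, -92, -93], "bv": [1.0, 1.0, 1.0]}
        )
        out = correlate_breeding_values(tab)
        assert np.isnan(out["correlations"].loc["lat", "bv"])

    def test_too_few_parents(self):
        with pytest.raises(ValueError):
            correlate_breeding_values(pd.DataFrame({"lat": [1.0], "long": [2.0]}))
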