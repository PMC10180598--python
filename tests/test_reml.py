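import numpy as np
import pytest

from arboreml.covariance import RandomTerm, ResidualSpec, TrialGrid, assemble_residual, incidence
from arboreml.reml import PedigreeMixedModel, information_criteria, restricted_loglik

from _oracles import brute_force_reml, dense_restricted_loglik, dense_V


def _one_way(n_groups=15, per_group=6, s2g=2.0, s2e=1.0, seed=0):
    rng = np.random.default_rng(seed)
    groups = np.repeat(np.arange(n_groups), per_group)
    y = 5.0 + rng.normal(0, np.sqrt(s2g), n_groups)[groups] + rng.normal(
        0, np.sqrt(s2e), n_groups * per_group
    )
    Z, lev = incidence(groups)
    term = RandomTerm(name="grp", levels=lev, Z=Z)
    X = np.ones((len(y), 1))
    return y, X, term


class TestRestrictedLoglik:
    def test_matches_balanced_anova_closed_form(self):
        """On a balanced one-way layout the REML maximum equals the
        ANOVA mean-square estimator (textbook closed form)."""
        y, X, term = _one_way()
        model = PedigreeMixedModel(y, X, [term], ResidualSpec(kind="iid_simple"))
        res = model.fit()
        g, m = 15, 6
        ybar_i = y.reshape(g, m).mean(1)
        msw = ((y.reshape(g, m) - ybar_i[:, None]) ** 2).sum() / (g * m - g)
        msb = m * ((ybar_i - y.mean()) ** 2).sum() / (g - 1)
        assert res.theta["sigma2_e"] == pytest.approx(msw, abs=1e-6)
        assert res.theta["sigma2_grp"] == pytest.approx((msb - msw) / m, abs=1e-6)

    def test_translation_invariance(self):
        y, X, term = _one_way(seed=3)
        residual = ResidualSpec(kind="iid_simple")
        theta = [1.5, 0.8]
        l0 = restricted_loglik(y, X, [term], residual, theta)
        l1 = restricted_loglik(y + 17.3, X, [term], residual, theta)
        assert l1 == pytest.approx(l0, abs=1e-8)

    def test_zero_spatial_variance_reduces_to_iid(self):
        rng = np.random.default_rng(1)
        cells = [(r, c) for r in range(4) for c in range(5)]
        y = rng.normal(0, 1, 20)
        X = np.ones((20, 1))
        g = TrialGrid(
            trial_id="T",
            n_rows=4,
            n_cols=5,
            obs_idx=np.arange(20),
            row_pos=np.array([r for r, _ in cells]),
            col_pos=np.array([c for _, c in cells]),
        )
        Z, lev = incidence(np.repeat([0, 1], 10))
        term = RandomTerm(name="grp", levels=lev, Z=Z)
        l_ar1 = restricted_loglik(
            y, X, [term], ResidualSpec(kind="ar1_plus_iid", grids=[g]), [0.4, 0.0, 0.5, 0.5, 1.3]
        )
        l_iid = restricted_loglik(y, X, [term], ResidualSpec(kind="iid_simple"), [0.4, 1.3])
        assert l_ar1 == pytest.approx(l_iid, abs=1e-8)

    def test_agrees_with_dense_formula(self):
        y, X, term = _one_way(seed=9)
        theta = np.array([1.1, 0.7])
        engine = restricted_loglik(y, X, [term], ResidualSpec(kind="iid_simple"), theta)
        V = theta[0] * term.observation_covariance() + theta[1] * np.eye(len(y))
        assert engine == pytest.approx(dense_restricted_loglik(y, X, V), abs=1e-8)

    def test_rank_deficient_X_dropped(self):
        y, X, term = _one_way(seed=5)
        X2 = np.column_stack([X, X, np.zeros(len(y))])
        model = PedigreeMixedModel(
            y, X2, [term], ResidualSpec(kind="iid_simple"), x_names=["a", "b", "c"]
        )
        assert model.rank_X == 1
        assert set(model.dropped_columns) == {"b", "c"}


def _spatial_halfsib_instance(seed=0, n_rows=6, n_cols=8, n_fam=6):
    """Small single-trial half-sib dataset with an AR1 field."""
    from arboreml.covariance import ar1_matrix

    rng = np.random.default_rng(seed)
    n = n_rows * n_cols
    fams = rng.integers(0, n_fam, n)
    F, lev = incidence(fams)
    dam = rng.normal(0, np.sqrt(0.8), n_fam)
    a = 0.5 * dam[fams] + rng.normal(0, np.sqrt(0.6 * 0.8), n)
    Lr = np.linalg.cholesky(ar1_matrix(0.5, n_rows))
    Lc = np.linalg.cholesky(ar1_matrix(0.3, n_cols))
    field = np.sqrt(0.5) * (Lr @ rng.standard_normal((n_rows, n_cols)) @ Lc.T)
    y = 3.0 + a + field.ravel() + rng.normal(0, 1.0, n)
    X = np.ones((n, 1))
    term = RandomTerm(
        name="additive",
        levels=lev,
        Z=F,
        diag_weight=0.75,
        U=0.5 * np.asarray(F.todense()),
    )
    grid = TrialGrid(
        trial_id="T",
        n_rows=n_rows,
        n_cols=n_cols,
        obs_idx=np.arange(n),
        row_pos=np.repeat(np.arange(n_rows), n_cols),
        col_pos=np.tile(np.arange(n_cols), n_rows),
    )
    residual = ResidualSpec(kind="ar1_plus_iid", grids=[grid])
    return y, X, term, residual, grid


class TestFit:
    def test_brute_force_oracle_equivalence(self):
        """AI-REML matches a dense Nelder-Mead optimiser over the full
        covariance parameterisation on a <=60-observation instance."""
        y, X, term, residual, grid = _spatial_halfsib_instance(seed=4, n_rows=6, n_cols=8)
        model = PedigreeMixedModel(y, X, [term], residual)
        res = model.fit()

        M = term.observation_covariance()

        def residual_builder(th_res):
            return assemble_residual(
                residual,
                {
                    "sigma2_eps": max(th_res[0], 0.0),
                    "rho_row": np.clip(th_res[1], -0.98, 0.98),
                    "rho_col": np.clip(th_res[2], -0.98, 0.98),
                    "sigma2_e": max(th_res[3], 1e-8),
                },
                len(y),
            )

        bounds = [(0, 20), (0, 20), (-0.98, 0.98), (-0.98, 0.98), (1e-8, 20)]
        vy = float(np.var(y))
        starts = [
            [vy / 3, vy / 3, 0.1, 0.1, vy / 3],
            [0.1, 0.5, 0.4, 0.4, 1.0],
            [1.0, 0.1, -0.2, 0.3, 0.5],
        ]
        best_llf, _ = brute_force_reml(y, X, [M], residual_builder, 4, starts, bounds)
        # cross-check the engine's own optimum on the dense likelihood
        th = res.theta.to_numpy()
        dense_at_engine = dense_restricted_loglik(
            y, X, dense_V(th, [M], residual_builder)
        )
        assert dense_at_engine == pytest.approx(res.llf, abs=1e-6)
        assert res.llf == pytest.approx(best_llf, abs=1e-4)

    def test_monotone_likelihood_trace(self):
        y, X, term, residual, _ = _spatial_halfsib_instance(seed=8)
        res = PedigreeMixedModel(y, X, [term], residual).fit()
        diffs = np.diff(res.llf_trace)
        assert (diffs >= -1e-8).all()

    def test_zero_additive_variance_hits_boundary(self):
        rng = np.random.default_rng(12)
        n, n_fam = 240, 12
        fams = np.repeat(np.arange(n_fam), n // n_fam)
        F, lev = incidence(fams)
        y = rng.normal(0, 1.0, n)  # no family signal at all
        term = RandomTerm(
            name="additive", levels=lev, Z=F, diag_weight=0.75,
            U=0.5 * np.asarray(F.todense()),
        )
        res = PedigreeMixedModel(
            y, np.ones((n, 1)), [term], ResidualSpec(kind="iid_simple")
        ).fit()
        # with no signal the variance lands at (or pressed onto) zero
        assert res.theta["sigma2_additive"] <= 0.05

    def test_nested_model_never_has_lower_loglik(self):
        y, X, term, residual, grid = _spatial_halfsib_instance(seed=2)
        res_small = PedigreeMixedModel(y, X, [term], residual).fit()
        hetero = ResidualSpec(kind="ar1_plus_hetero", grids=[grid])
        res_big = PedigreeMixedModel(y, X, [term], hetero).fit()
        assert res_big.llf >= res_small.llf - 1e-6

    def test_nonconvergence_reported_not_raised(self):
        y, X, term, residual, _ = _spatial_halfsib_instance(seed=6)
        res = PedigreeMixedModel(y, X, [term], residual).fit(maxiter=1)
        assert res.converged is False
        assert res.n_iter == 1


class TestMME:
    def test_tiny_instance_equals_gls_and_conditional_expectation(self):
        """MME solutions equal the direct generalised-least-squares and
        conditional-expectation formulas computed on dense V."""
        rng = np.random.default_rng(42)
        n = 8
        fams = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        F, lev = incidence(fams)
        y = rng.normal(5, 1, n) + np.array([0.8] * 4 + [-0.8] * 4)
        X = np.column_stack([np.ones(n), rng.normal(0, 1, n)])
        term = RandomTerm(
            name="additive", levels=lev, Z=F, diag_weight=0.75,
            U=0.5 * np.asarray(F.todense()),
        )
        model = PedigreeMixedModel(y, X, [term], ResidualSpec(kind="iid_simple"))
        s2a, s2e = 0.9, 1.1
        mme = model.solve_mme(np.array([s2a, s2e]))

        V = s2a * term.observation_covariance() + s2e * np.eye(n)
        Vi = np.linalg.inv(V)
        beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        assert np.allclose(mme.beta.to_numpy(), beta, atol=1e-8)

        # dam breeding values: u = Cov(a_dam, y) V^-1 (y - X beta),
        # with Cov(a_dam, y_offspring) = sigma2_A / 2
        cov_uy = s2a * 0.5 * np.asarray(F.todense()).T
        u = cov_uy @ Vi @ (y - X @ beta)
        dam_blups = mme.blups["additive"]
        assert np.allclose(dam_blups.to_numpy(), u, atol=1e-8)

    def test_parent_blup_proportional_to_offspring_mean_deviation(self):
        rng = np.random.default_rng(3)
        n = 6
        fams = np.array([0, 0, 0, 1, 1, 1])
        F, lev = incidence(fams)
        y = 4.0 + rng.normal(0, 1, n)
        term = RandomTerm(
            name="additive", levels=lev, Z=F, diag_weight=0.75,
            U=0.5 * np.asarray(F.todense()),
        )
        model = PedigreeMixedModel(
            y, np.ones((n, 1)), [term], ResidualSpec(kind="iid_simple")
        )
        theta = np.array([0.8, 1.2])
        mme = model.solve_mme(theta)
        blups = mme.blups["additive"].to_numpy()
        dev = np.array([y[:3].mean(), y[3:].mean()]) - float(mme.beta.iloc[0])
        # balanced single-factor case: dam BLUPs are a common shrinkage
        # factor times family-mean deviations, hence proportional
        ratio = blups / dev
        assert ratio[0] == pytest.approx(ratio[1], rel=1e-8)
        assert np.sign(blups[0]) == np.sign(dev[0])

    def test_shrinkage_limit(self):
        y, X, term, residual, _ = _spatial_halfsib_instance(seed=10)
        model = PedigreeMixedModel(y, X, [term], residual)
        mme = model.solve_mme(np.array([1e-10, 0.2, 0.3, 0.3, 1.0]))
        assert np.abs(mme.blups["additive"].to_numpy()).max() < 1e-6


class TestInformationCriteria:
    def test_aic_arithmetic(self):
        aic, _ = information_criteria(-100.0, 3, 50)
        assert aic == 206.0

    def test_bic_arithmetic(self):
        _, bic = information_criteria(-100.0, 3, 100)
        assert bic == pytest.approx(3 * np.log(100) + 200, abs=1e-9)

    def test_zero_parameters(self):
        aic, bic = information_criteria(-42.0, 0, 10)
        assert aic == 84.0 and bic == 84.0

    def test_invalid_df(self):
        with pytest.raises(ValueError):
            information_criteria(-1.0, 2, 1)
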