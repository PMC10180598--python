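import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from arboreml.covariance import (
    RandomTerm,
    ResidualSpec,
    TrialGrid,
    ar1_matrix,
    ar1_matrix_derivative,
    assemble_residual,
    incidence,
)


class TestAR1:
    def test_power_law(self):
        assert ar1_matrix(0.5, 4)[0, 2] == pytest.approx(0.25)

    def test_zero_rho_identity(self):
        assert np.array_equal(ar1_matrix(0.0, 5), np.eye(5))

    def test_determinant_closed_form(self):
        det = np.linalg.det(ar1_matrix(0.8, 3))
        assert det == pytest.approx((1 - 0.8**2) ** 2)  # = 0.1296

    def test_rho_out_of_range(self):
        with pytest.raises(ValueError):
            ar1_matrix(1.0, 3)

    def test_derivative_matches_finite_difference(self):
        rho, h = 0.6, 1e-6
        num = (ar1_matrix(rho + h, 5) - ar1_matrix(rho - h, 5)) / (2 * h)
        assert np.allclose(ar1_matrix_derivative(rho, 5), num, atol=1e-6)


def _grid(n_rows, n_cols, obs_cells, trial="T", offset=0):
    obs_cells = np.asarray(obs_cells)
    return TrialGrid(
        trial_id=trial,
        n_rows=n_rows,
        n_cols=n_cols,
        obs_idx=np.arange(len(obs_cells)) + offset,
        row_pos=obs_cells[:, 0],
        col_pos=obs_cells[:, 1],
    )


class TestAssembleResidual:
    def test_zero_spatial_reduces_to_nugget_diagonal(self):
        g = _grid(2, 2, [(0, 0), (0, 1), (1, 0), (1, 1)])
        spec = ResidualSpec(kind="ar1_plus_iid", grids=[g])
        R = assemble_residual(
            spec, {"sigma2_eps": 0.0, "rho_row": 0.5, "rho_col": 0.3, "sigma2_e": 1.7}, 4
        )
        assert np.allclose(R, 1.7 * np.eye(4))

    def test_zero_correlation_gives_scaled_identity(self):
        g = _grid(2, 2, [(0, 0), (0, 1), (1, 0), (1, 1)])
        spec = ResidualSpec(kind="ar1_plus_iid", grids=[g])
        R = assemble_residual(
            spec, {"sigma2_eps": 0.6, "rho_row": 0.0, "rho_col": 0.0, "sigma2_e": 0.4}, 4
        )
        assert np.allclose(R, np.eye(4))

    def test_hand_computed_kronecker_entries(self):
        # 2x2 grid, rho_row=0.5, rho_col=0.4, sigma2_eps=1, no nugget
        g = _grid(2, 2, [(0, 0), (0, 1), (1, 0), (1, 1)])
        spec = ResidualSpec(kind="ar1_plus_iid", grids=[g])
        R = assemble_residual(
            spec, {"sigma2_eps": 1.0, "rho_row": 0.5, "rho_col": 0.4, "sigma2_e": 0.0}, 4
        )
        assert R[0, 1] == pytest.approx(0.4)  # same row, adjacent column
        assert R[0, 2] == pytest.approx(0.5)  # same column, adjacent row
        assert R[0, 3] == pytest.approx(0.2)  # diagonal cell pair

    def test_heterogeneous_nuggets_block_diagonal(self):
        g1 = _grid(1, 2, [(0, 0), (0, 1)], trial="A")
        g2 = _grid(1, 2, [(0, 0), (0, 1)], trial="B", offset=2)
        spec = ResidualSpec(kind="ar1_plus_hetero", grids=[g1, g2], per_trial_spatial=True)
        R = assemble_residual(
            spec,
            {
                "sigma2_eps(A)": 0.0,
                "rho_row(A)": 0.0,
                "rho_col(A)": 0.0,
                "sigma2_eps(B)": 0.0,
                "rho_row(B)": 0.0,
                "rho_col(B)": 0.0,
                "sigma2_e(A)": 1.0,
                "sigma2_e(B)": 3.0,
            },
            4,
        )
        assert np.allclose(np.diag(R), [1, 1, 3, 3])
        assert np.allclose(R[:2, 2:], 0)  # no correlation between trials

    def test_restriction_matches_full_then_subset(self):
        """Assembling AR1xAR1 on observed cells equals building the full
        Kronecker product and deleting missing cells (brute force)."""
        rng = np.random.default_rng(7)
        for _ in range(5):
            nr, nc = rng.integers(2, 6, 2)
            keep = rng.random(nr * nc) < 0.7
            if keep.sum() == 0:
                continue
            cells = [(i // nc, i % nc) for i in range(nr * nc) if keep[i]]
            rr, rc = rng.uniform(-0.8, 0.8, 2)
            g = _grid(int(nr), int(nc), cells)
            spec = ResidualSpec(kind="ar1_plus_iid", grids=[g])
            R = assemble_residual(
                spec,
                {"sigma2_eps": 1.3, "rho_row": rr, "rho_col": rc, "sigma2_e": 0.2},
                len(cells),
            )
            full = 1.3 * np.kron(ar1_matrix(rr, nr), ar1_matrix(rc, nc)) + 0.2 * np.eye(nr * nc)
            idx = np.flatnonzero(keep)
            assert np.allclose(R, full[np.ix_(idx, idx)])

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown residual kind"):
            ResidualSpec(kind="matern")


class TestRandomTerm:
    def test_low_rank_factor_matches_observation_covariance(self):
        labels = ["f1", "f1", "f2", "f2", "f2"]
        Z, levels = incidence(labels)
        # half-sib collapse: 0.25 FF' + 0.75 I
        term = RandomTerm(
            name="additive",
            levels=levels,
            Z=Z,
            diag_weight=0.75,
            U=0.5 * np.asarray(Z.todense()),
        )
        c, U = term.low_rank_factor()
        M = c * np.eye(5) + U @ U.T
        expect = 0.75 * np.eye(5) + 0.25 * np.asarray((Z @ Z.T).todense())
        assert np.allclose(M, expect)

    def test_identity_term_covariance(self):
        Z, levels = incidence(["a", "b", "a"])
        term = RandomTerm(name="rep", levels=levels, Z=Z)
        M = term.observation_covariance()
        assert np.allclose(M, [[1, 0, 1], [0, 1, 0], [1, 0, 1]])

    def test_general_G_factorisation(self):
        G = np.array([[1.0, 0.5], [0.5, 1.0]])
        Z, levels = incidence(["a", "b", "b"])
        term = RandomTerm(name="additive", levels=levels, Z=Z, G=G)
        c, U = term.low_rank_factor()
        assert np.allclose(c * np.eye(3) + U @ U.T, term.observation_covariance())


@given(
    rho_r=st.floats(-0.9, 0.9),
    rho_c=st.floats(-0.9, 0.9),
    s_eps=st.floats(0.0, 3.0),
    s_e=st.floats(0.05, 3.0),
)
def test_assembled_residual_is_psd(rho_r, rho_c, s_eps, s_e):
    cells = [(r, c) for r in range(3) for c in range(4)]
    g = _grid(3, 4, cells)
    spec = ResidualSpec(kind="ar1_plus_iid", grids=[g])
    R = assemble_residual(
        spec,
        {"sigma2_eps": s_eps, "rho_row": rho_r, "rho_col": rho_c, "sigma2_e": s_e},
        12,
    )
    w = np.linalg.eigvalsh(R)
    assert w.min() >= -1e-8 * max(np.trace(R), 1.0)
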