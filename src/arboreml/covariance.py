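"""Random-effect and residual covariance structures.

The residual of a spatial mixed model on a planting grid is modelled as
a separable first-order autoregressive field plus an independent nugget:

    R_t = sigma2_eps * (Sigma_row(rho_r) (x) Sigma_col(rho_c)) | observed cells
          + sigma2_e * I

per trial, with zero correlation between trials (block-diagonal R).
``Sigma(rho)`` is the AR1 correlation matrix with entries rho**|i-j|.
The nugget is shared across trials (``ar1_plus_iid``) or trial-specific
(``ar1_plus_hetero``); ``iid_simple`` drops the autoregressive part
entirely.  Missing cells are dropped from R by restriction to the
observed cells, never imputed.

Random terms carry an incidence matrix Z and a level covariance (the
numerator relationship matrix A for the additive term, identity for
design factors), enough to form the phenotypic covariance

    V = sum_k sigma2_k Z_k G_k Z_k' + R.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "ar1_matrix",
    "ar1_matrix_derivative",
    "RandomTerm",
    "TrialGrid",
    "ResidualSpec",
    "assemble_residual",
    "assemble_G",
]

RESIDUAL_KINDS = ("iid_simple", "ar1_plus_iid", "ar1_plus_hetero")


def ar1_matrix(rho: float, n: int) -> np.ndarray:
    """AR1 correlation matrix: entry (i, j) = rho**|i-j|.

    Positive definite for |rho| < 1 (determinant (1-rho^2)**(n-1)).
    """
    if abs(rho) >= 1:
        raise ValueError(f"|rho| must be < 1, got {rho}")
    if n < 1:
        raise ValueError("n must be >= 1")
    lags = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    return rho ** lags if rho != 0 else np.eye(n)


def ar1_matrix_derivative(rho: float, n: int) -> np.ndarray:
    """Elementwise derivative of :func:`ar1_matrix` with respect to rho:
    |i-j| * rho**(|i-j|-1), zero on the diagonal."""
    if abs(rho) >= 1:
        raise ValueError(f"|rho| must be < 1, got {rho}")
    lags = np.abs(np.subtract.outer(np.arange(n), np.arange(n))).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = lags * rho ** np.maximum(lags - 1, 0)
    d[lags == 0] = 0.0
    return d


@dataclass
class TrialGrid:
    """Observed cells of one trial, for residual assembly.

    ``obs_idx`` are positions in the global observation vector belonging
    to this trial; ``row_pos``/``col_pos`` are the matching 0-based grid
    coordinates.
    """

    trial_id: str
    n_rows: int
    n_cols: int
    obs_idx: np.ndarray
    row_pos: np.ndarray
    col_pos: np.ndarray

    @property
    def n_obs(self) -> int:
        return len(self.obs_idx)

    def ar1_kron_restricted(self, rho_row: float, rho_col: float) -> np.ndarray:
        """(Sigma_row (x) Sigma_col) restricted to the observed cells."""
        sr = ar1_matrix(rho_row, self.n_rows)
        sc = ar1_matrix(rho_col, self.n_cols)
        return sr[np.ix_(self.row_pos, self.row_pos)] * sc[np.ix_(self.col_pos, self.col_pos)]

    def ar1_kron_drow(self, rho_row: float, rho_col: float) -> np.ndarray:
        dr = ar1_matrix_derivative(rho_row, self.n_rows)
        sc = ar1_matrix(rho_col, self.n_cols)
        return dr[np.ix_(self.row_pos, self.row_pos)] * sc[np.ix_(self.col_pos, self.col_pos)]

    def ar1_kron_dcol(self, rho_row: float, rho_col: float) -> np.ndarray:
        sr = ar1_matrix(rho_row, self.n_rows)
        dc = ar1_matrix_derivative(rho_col, self.n_cols)
        return sr[np.ix_(self.row_pos, self.row_pos)] * dc[np.ix_(self.col_pos, self.col_pos)]


@dataclass
class ResidualSpec:
    """Residual structure declaration.

    Parameters appear in the engine's theta vector in this order:
    ``(sigma2_eps, rho_row, rho_col)`` -- shared or repeated per trial
    when ``per_trial_spatial`` -- followed by the nugget(s)
    ``sigma2_e`` (one, or one per trial for ``ar1_plus_hetero``).
    """

    kind: str
    grids: list = field(default_factory=list)  # list[TrialGrid]; empty for iid_simple
    per_trial_spatial: bool = False

    def __post_init__(self):
        if self.kind not in RESIDUAL_KINDS:
            raise ValueError(f"unknown residual kind {self.kind!r}; expected {RESIDUAL_KINDS}")
        if self.kind != "iid_simple" and not self.grids:
            raise ValueError(f"residual kind {self.kind!r} requires trial grids")

    @property
    def has_ar1(self) -> bool:
        return self.kind != "iid_simple"

    @property
    def n_trials(self) -> int:
        return len(self.grids)

    def parameter_names(self) -> list[str]:
        names: list[str] = []
        if self.has_ar1:
            if self.per_trial_spatial:
                for g in self.grids:
                    names += [
                        f"sigma2_eps({g.trial_id})",
                        f"rho_row({g.trial_id})",
                        f"rho_col({g.trial_id})",
                    ]
            else:
                names += ["sigma2_eps", "rho_row", "rho_col"]
        if self.kind == "ar1_plus_hetero":
            names += [f"sigma2_e({g.trial_id})" for g in self.grids]
        else:
            names += ["sigma2_e"]
        return names


def assemble_residual(spec: ResidualSpec, params: dict, n_obs: int) -> np.ndarray:
    """Dense residual covariance R for a full parameter dictionary.

    ``params`` maps each name from :meth:`ResidualSpec.parameter_names`
    to its value.  Used for audits and as the reference path in tests;
    the REML engine works with the per-trial blocks directly.
    """
    R = np.zeros((n_obs, n_obs))
    if spec.kind == "iid_simple":
        if spec.grids:
            for g in spec.grids:
                R[g.obs_idx, g.obs_idx] += params["sigma2_e"]
            return R
        np.fill_diagonal(R, params["sigma2_e"])
        return R
    for g in spec.grids:
        if spec.per_trial_spatial:
            s2 = params[f"sigma2_eps({g.trial_id})"]
            rr = params[f"rho_row({g.trial_id})"]
            rc = params[f"rho_col({g.trial_id})"]
        else:
            s2, rr, rc = params["sigma2_eps"], params["rho_row"], params["rho_col"]
        nug = (
            params[f"sigma2_e({g.trial_id})"]
            if spec.kind == "ar1_plus_hetero"
            else params["sigma2_e"]
        )
        block = s2 * g.ar1_kron_restricted(rr, rc) + nug * np.eye(g.n_obs)
        R[np.ix_(g.obs_idx, g.obs_idx)] = block
    return R


@dataclass
class RandomTerm:
    """One random term of the mixed model.

    ``Z`` (n x q, sparse) maps observations to term levels; the level
    covariance is the identity unless ``G`` is given (the additive term
    passes the relationship matrix restricted to its levels).  The
    engine exploits ``diag_weight``/``U`` when set: the term's
    observation covariance is then

        Z G Z' = diag_weight * I + U U'

    which is how the open-pollinated half-sib additive term collapses
    (family incidence U = 0.5 * F, diagonal 0.75).
    """

    name: str
    levels: list
    Z: sp.csr_matrix
    G: np.ndarray | None = None
    diag_weight: float = 0.0
    U: np.ndarray | None = None

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def observation_covariance(self) -> np.ndarray:
        """Dense observation covariance at unit variance; reference path
        for audits and tests."""
        if self.U is not None:
            return self.diag_weight * np.eye(self.U.shape[0]) + self.U @ self.U.T
        Zd = np.asarray(self.Z.todense())
        if self.G is None:
            return Zd @ Zd.T
        return Zd @ self.G @ Zd.T

    def low_rank_factor(self) -> tuple[float, np.ndarray]:
        """(c, U) with Z G Z' = c*I + U U'."""
        if self.U is not None:
            return self.diag_weight, self.U
        Zd = np.asarray(self.Z.todense())
        if self.G is None:
            return 0.0, Zd
        w, v = np.linalg.eigh(self.G)
        w = np.clip(w, 0.0, None)
        return 0.0, Zd @ (v * np.sqrt(w))


def incidence(labels, levels=None) -> tuple[sp.csr_matrix, list]:
    """0/1 incidence matrix from a label vector (one level per obs)."""
    labels = pd.Series(labels).astype(str)
    if levels is None:
        levels = sorted(labels.unique())
    lookup = {v: i for i, v in enumerate(levels)}
    rows = np.arange(len(labels))
    cols = labels.map(lookup).to_numpy()
    if np.any(pd.isna(cols)):
        missing = labels[pd.isna(pd.Series(cols))].unique()
        raise ValueError(f"labels without a level: {missing[:5]}")
    Z = sp.csr_matrix(
        (np.ones(len(labels)), (rows, cols.astype(int))), shape=(len(labels), len(levels))
    )
    return Z, list(levels)


def assemble_G(terms: list[RandomTerm], kinship=None) -> list[RandomTerm]:
    """Validate a term list against the available kinship matrix.

    The additive term (named ``"additive"``) must carry a level
    covariance or a low-rank factor derived from one; identity terms
    must not carry G.  Returns the list unchanged on success.
    """
    for t in terms:
        if t.name == "additive":
            if t.G is None and t.U is None:
                if kinship is None:
                    raise ValueError("additive term requires a kinship matrix")
                t.G = kinship.submatrix(t.levels)
        elif t.G is not None:
            raise ValueError(f"term {t.name!r} must have identity level covariance")
    return terms
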