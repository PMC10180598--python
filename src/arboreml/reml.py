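"""Restricted maximum likelihood engine for pedigree mixed models.

The model is

    y = X beta + sum_k Z_k u_k + e,    u_k ~ N(0, sigma2_k G_k),
    e ~ N(0, R(sigma2_eps, rho_row, rho_col, sigma2_e))

with G_k the numerator relationship matrix A for the additive term and
the identity for design factors, and R iid or separable-AR1-plus-nugget
per trial (see :mod:`arboreml.covariance`).  The restricted
log-likelihood (constant ``-(n - p)/2 * log(2*pi)`` omitted) is

    logL_R = -1/2 [ log|V| + log|X' V^-1 X| + y' P y ],
    P = V^-1 - V^-1 X (X' V^-1 X)^-1 X' V^-1.

Estimation uses average-information (AI) REML: Newton-type steps with
the average-information matrix

    AI_jk = 1/2 (Py)' dV/dtheta_j P dV/dtheta_k (Py)

and the REML score

    score_j = -1/2 [ tr(P dV/dtheta_j) - (Py)' dV/dtheta_j (Py) ],

safeguarded by step halving and Levenberg damping so the likelihood
never decreases across accepted iterations.  Variances are kept in
[0, inf) and correlations in [-0.98, 0.98]; a variance pressed against
zero is pinned there and flagged as a boundary estimate (its standard
error is reported unavailable), mirroring how REML software prints
"0 (NA)" components.

Every term's observation covariance is handled as ``c*I + U U'``
(diagonal plus low rank), so V factorises by the Woodbury identity with
per-trial dense blocks only for the AR1 residual.  At the study's scale
(a few thousand trees) one likelihood evaluation costs a handful of
block Cholesky factorisations.

Fixed effects, random-effect predictions (BLUE/BLUP) and prediction
error variances come from Henderson's mixed-model equations assembled
at the REML estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.sparse as sp

from scipy.linalg.lapack import dpotri

from .covariance import RandomTerm, ResidualSpec

__all__ = [
    "PedigreeMixedModel",
    "MixedModelResults",
    "MMEResult",
    "restricted_loglik",
    "information_criteria",
]

RHO_BOUND = 0.98
_VAR_FLOOR = 0.0


def _chol_inverse(ch) -> np.ndarray:
    """Full inverse from a Cholesky factor (LAPACK dpotri)."""
    c, lower = ch
    inv, info = dpotri(c, lower=lower)
    if info != 0:  # pragma: no cover
        raise np.linalg.LinAlgError("dpotri failed")
    if lower:
        return np.tril(inv) + np.tril(inv, -1).T
    return np.triu(inv) + np.triu(inv, 1).T


def information_criteria(logl_r: float, t: int, v: float) -> tuple[float, float]:
    """Akaike and Bayesian information criteria on the REML scale.

    ``t`` is the number of variance parameters and ``v`` the residual
    degrees of freedom (observations minus fixed-effect rank); natural
    logarithms throughout:

        AIC = 2 t - 2 logL_R,   BIC = t ln(v) - 2 logL_R.
    """
    if v <= 1:
        raise ValueError(f"residual degrees of freedom must exceed 1, got {v}")
    return 2.0 * t - 2.0 * logl_r, t * float(np.log(v)) - 2.0 * logl_r


class _Factor:
    """Cached Woodbury factorisation of V(theta) for one parameter point."""

    def __init__(self, model: "PedigreeMixedModel", theta: np.ndarray):
        self.model = model
        self.theta = np.asarray(theta, dtype=float)
        m = model
        gammas = self.theta[: m.n_terms]
        res = m._residual_params(self.theta)
        self.gammas = gammas
        self.res = res

        diag_base = float(sum(g * c for g, (c, _) in zip(gammas, m._term_factors)))

        # --- diagonal / block-diagonal part D -------------------------------
        self.diagonal_only = not m.residual.has_ar1
        n = m.nobs
        if self.diagonal_only:
            d = np.full(n, diag_base)
            d += res["nugget_per_obs"]
            if np.any(d <= 0):
                raise np.linalg.LinAlgError("non-positive diagonal in D")
            self.d = d
            self.logdet_D = float(np.log(d).sum())
        else:
            self.block_chol = []
            self.logdet_D = 0.0
            self.S_blocks = []  # AR1 kron blocks, reused for derivatives
            for gi, g in enumerate(m.residual.grids):
                s2, rr, rc = res["spatial"][gi]
                nug = res["nugget"][gi]
                S = g.ar1_kron_restricted(rr, rc)
                block = s2 * S + (nug + diag_base) * np.eye(g.n_obs)
                c, low = sla.cho_factor(block, lower=True, check_finite=False)
                self.block_chol.append((c, low))
                self.S_blocks.append(S)
                self.logdet_D += 2.0 * float(np.log(np.diag(c)).sum())

        # --- low-rank part --------------------------------------------------
        self.U_raw = m._U_raw  # n x q, unscaled columns
        scale = np.concatenate(
            [np.full(U.shape[1], np.sqrt(max(g, 0.0))) for g, (c, U) in zip(gammas, m._term_factors)]
        ) if m._U_raw.shape[1] else np.zeros(0)
        self.col_scale = scale
        # one batched block-solve for U, X and y
        bundle = np.concatenate([self.U_raw, m.X, m.y[:, None]], axis=1)
        bundle_di = self.solve_D(bundle)
        q_all = self.U_raw.shape[1]
        self.Udi_raw = bundle_di[:, :q_all]
        Xdi = bundle_di[:, q_all:-1]
        ydi = bundle_di[:, -1]
        Us = self.U_raw * scale
        Tdi = self.Udi_raw * scale
        q = Us.shape[1]
        self.Us = Us
        self.Tdi = Tdi
        if q:
            W = np.eye(q) + Us.T @ Tdi
            cW, lowW = sla.cho_factor(W, lower=True, check_finite=False)
            self.cW = (cW, lowW)
            self.logdet_W = 2.0 * float(np.log(np.diag(cW)).sum())
        else:
            self.cW = None
            self.logdet_W = 0.0
        self.logdet_V = self.logdet_D + self.logdet_W

        # --- REML projection pieces ----------------------------------------
        X, y = m.X, m.y
        if q:
            corr = sla.cho_solve(
                self.cW, self.Us.T @ np.concatenate([Xdi, ydi[:, None]], axis=1),
                check_finite=False,
            )
            self.VinvX = Xdi - self.Tdi @ corr[:, :-1]
            self.Vinvy = ydi - self.Tdi @ corr[:, -1]
        else:
            self.VinvX = Xdi
            self.Vinvy = ydi
        K = X.T @ self.VinvX
        cK, lowK = sla.cho_factor(K, lower=True, check_finite=False)
        self.cK = (cK, lowK)
        self.logdet_K = 2.0 * float(np.log(np.diag(cK)).sum())
        self.beta = sla.cho_solve(self.cK, X.T @ self.Vinvy, check_finite=False)
        self.Py = self.Vinvy - self.VinvX @ sla.cho_solve(
            self.cK, X.T @ self.Vinvy, check_finite=False
        )
        self.yPy = float(y @ self.Py)
        self.llf = -0.5 * (self.logdet_V + self.logdet_K + self.yPy)
        self._PU = None

    # -- linear algebra helpers ---------------------------------------------
    def solve_D(self, B: np.ndarray) -> np.ndarray:
        B = np.asarray(B, dtype=float)
        one_d = B.ndim == 1
        if one_d:
            B = B[:, None]
        if self.diagonal_only:
            out = B / self.d[:, None]
        else:
            out = np.empty_like(B)
            for g, ch in zip(self.model.residual.grids, self.block_chol):
                out[g.obs_idx] = sla.cho_solve(ch, B[g.obs_idx], check_finite=False)
        return out[:, 0] if one_d else out

    def solve_V(self, B: np.ndarray) -> np.ndarray:
        B = np.asarray(B, dtype=float)
        one_d = B.ndim == 1
        if one_d:
            B = B[:, None]
        Bdi = self.solve_D(B)
        if self.Us.shape[1]:
            out = Bdi - self.Tdi @ sla.cho_solve(self.cW, self.Us.T @ Bdi, check_finite=False)
        else:
            out = Bdi
        return out[:, 0] if one_d else out

    def apply_P(self, B: np.ndarray) -> np.ndarray:
        B = np.asarray(B, dtype=float)
        one_d = B.ndim == 1
        if one_d:
            B = B[:, None]
        VB = self.solve_V(B)
        out = VB - self.VinvX @ sla.cho_solve(self.cK, self.VinvX.T @ B, check_finite=False)
        return out[:, 0] if one_d else out

    def PU_all(self) -> np.ndarray:
        """P @ U_raw for all term columns, via the cached Woodbury
        pieces (avoids re-solving the block systems)."""
        if self._PU is None:
            Udi = self.Udi_raw
            if self.Us.shape[1]:
                VinvU = Udi - self.Tdi @ sla.cho_solve(
                    self.cW, self.Us.T @ Udi, check_finite=False
                )
            else:
                VinvU = Udi
            self._PU = VinvU - self.VinvX @ sla.cho_solve(
                self.cK, self.VinvX.T @ self.U_raw, check_finite=False
            )
        return self._PU

    # -- traces ---------------------------------------------------------------
    def trace_Vinv(self) -> float:
        if self.diagonal_only:
            tr_d = float((1.0 / self.d).sum())
        else:
            tr_d = sum(float(np.trace(_chol_inverse(ch))) for ch in self.block_chol)
        if not self.Us.shape[1]:
            return tr_d
        TtT = self.Tdi.T @ self.Tdi
        return tr_d - float(np.trace(sla.cho_solve(self.cW, TtT, check_finite=False)))

    def trace_P(self) -> float:
        tr_v = self.trace_Vinv()
        M = self.VinvX.T @ self.VinvX
        return tr_v - float(np.trace(sla.cho_solve(self.cK, M, check_finite=False)))

    def P_blocks(self) -> list[np.ndarray]:
        """Diagonal blocks of P per trial grid (AR1 models only)."""
        blocks = []
        WT = (
            sla.cho_solve(self.cW, self.Tdi.T, check_finite=False)
            if self.Us.shape[1]
            else None
        )
        KX = sla.cho_solve(self.cK, self.VinvX.T, check_finite=False)
        for g, ch in zip(self.model.residual.grids, self.block_chol):
            Vinv_tt = _chol_inverse(ch)
            if WT is not None:
                Vinv_tt = Vinv_tt - self.Tdi[g.obs_idx] @ WT[:, g.obs_idx]
            P_tt = Vinv_tt - self.VinvX[g.obs_idx] @ KX[:, g.obs_idx]
            blocks.append(P_tt)
        return blocks


@dataclass
class MMEResult:
    """Solutions of Henderson's mixed-model equations at fixed theta."""

    beta: pd.Series
    blups: dict
    pev: dict
    coefficient_dim: int


class PedigreeMixedModel:
    """Gaussian mixed model with pedigree and spatial covariance structures.

    Parameters
    ----------
    y : array (n,)
        Observations (one trait).
    X : array (n, p)
        Fixed-effect design.  Rank-deficient columns are dropped with a
        warning recorded in ``dropped_columns``.
    terms : list of RandomTerm
        Random-effect terms; variance parameters follow term order.
    residual : ResidualSpec
        Residual structure; its parameters follow the term variances in
        the theta vector (correlations bounded by +-0.98).
    x_names : list of str, optional
        Fixed-effect column names.
    """

    def __init__(self, y, X, terms, residual: ResidualSpec, x_names=None):
        y = np.asarray(y, dtype=float)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y lengths differ")
        if x_names is None:
            x_names = [f"x{i}" for i in range(X.shape[1])]
        # pivoted-QR rank detection; dependent columns dropped, rank logged
        q, r, piv = sla.qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
        rank = int((diag > tol).sum())
        keep = np.sort(piv[:rank])
        self.dropped_columns = [x_names[i] for i in sorted(set(range(X.shape[1])) - set(keep))]
        self.X = X[:, keep]
        self.x_names = [x_names[i] for i in keep]
        self.rank_X = rank
        self.y = y
        self.nobs = len(y)
        self.terms = list(terms)
        self.residual = residual
        if residual.has_ar1:
            covered = np.concatenate([g.obs_idx for g in residual.grids])
            if len(covered) != self.nobs or len(np.unique(covered)) != self.nobs:
                raise ValueError("AR1 residual requires grid coordinates for every observation")
        self._term_factors = [t.low_rank_factor() for t in self.terms]
        self._U_raw = (
            np.concatenate([U for _, U in self._term_factors], axis=1)
            if self.terms
            else np.zeros((self.nobs, 0))
        )
        self._term_slices = []
        start = 0
        for _, U in self._term_factors:
            self._term_slices.append(slice(start, start + U.shape[1]))
            start += U.shape[1]
        self.param_names = [f"sigma2_{t.name}" for t in self.terms] + residual.parameter_names()
        self.param_kinds = [
            "corr" if name.startswith("rho") else "var" for name in self.param_names
        ]
        self.n_terms = len(self.terms)
        self.n_params = len(self.param_names)

    # ------------------------------------------------------------------
    def _residual_params(self, theta: np.ndarray) -> dict:
        res = self.residual
        pos = self.n_terms
        out: dict = {"spatial": [], "nugget": []}
        if res.has_ar1:
            if res.per_trial_spatial:
                for _ in res.grids:
                    out["spatial"].append(tuple(theta[pos : pos + 3]))
                    pos += 3
            else:
                shared = tuple(theta[pos : pos + 3])
                pos += 3
                out["spatial"] = [shared] * res.n_trials
        if res.kind == "ar1_plus_hetero":
            for _ in res.grids:
                out["nugget"].append(float(theta[pos]))
                pos += 1
        else:
            nug = float(theta[pos])
            pos += 1
            out["nugget"] = [nug] * max(res.n_trials, 1)
        if pos != self.n_params:
            raise ValueError("theta length mismatch")
        nug_per_obs = np.empty(self.nobs)
        if res.grids:
            for g, nug in zip(res.grids, out["nugget"]):
                nug_per_obs[g.obs_idx] = nug
        else:
            nug_per_obs[:] = out["nugget"][0]
        out["nugget_per_obs"] = nug_per_obs
        return out

    def loglike(self, theta) -> float:
        """Restricted log-likelihood at ``theta`` (constant omitted)."""
        return _Factor(self, np.asarray(theta, dtype=float)).llf

    def start_values(self) -> np.ndarray:
        """Equal split of the OLS residual variance across variance
        parameters; correlations start at 0.1."""
        beta, *_ = np.linalg.lstsq(self.X, self.y, rcond=None)
        resid = self.y - self.X @ beta
        v = float(resid.var(ddof=min(self.X.shape[1], self.nobs - 1)))
        n_var = sum(k == "var" for k in self.param_kinds)
        theta = np.empty(self.n_params)
        for i, kind in enumerate(self.param_kinds):
            theta[i] = v / max(n_var, 1) if kind == "var" else 0.1
        return theta

    # ------------------------------------------------------------------
    def _derivatives(self, fac: _Factor, active: np.ndarray):
        """Score vector and average-information matrix at ``fac.theta``."""
        m = self
        Py = fac.Py
        n_act = int(active.sum())
        idx_act = np.flatnonzero(active)
        v_list = np.zeros((m.nobs, n_act))
        traces = np.zeros(n_act)

        need_trP = any(
            (j < m.n_terms and m._term_factors[j][0] != 0.0)
            or m.param_names[j].startswith("sigma2_e")
            for j in idx_act
        )
        trP = fac.trace_P() if (need_trP and fac.diagonal_only) else None
        P_blocks = None
        if not fac.diagonal_only:
            P_blocks = fac.P_blocks()
            trP = sum(float(np.trace(b)) for b in P_blocks)

        res = fac.res
        # batch the low-rank trace solves over all active terms
        term_js = [j for j in idx_act if j < m.n_terms]
        if term_js:
            PU_full = fac.PU_all()
        for a, j in enumerate(idx_act):
            name = m.param_names[j]
            if j < m.n_terms:
                c, U = m._term_factors[j]
                v = U @ (U.T @ Py)
                if c != 0.0:
                    v = v + c * Py
                v_list[:, a] = v
                PU = PU_full[:, m._term_slices[j]]
                traces[a] = float(np.einsum("ij,ij->", U, PU)) + (c * trP if c != 0.0 else 0.0)
            elif name.startswith("sigma2_eps"):
                tidx = self._grid_index(name)
                v = np.zeros(m.nobs)
                tr = 0.0
                for gi, g in enumerate(m.residual.grids):
                    if tidx is not None and gi != tidx:
                        continue
                    S = fac.S_blocks[gi]
                    v[g.obs_idx] = S @ Py[g.obs_idx]
                    tr += float(np.einsum("ij,ij->", P_blocks[gi], S))
                v_list[:, a] = v
                traces[a] = tr
            elif name.startswith("rho_row") or name.startswith("rho_col"):
                tidx = self._grid_index(name)
                is_row = name.startswith("rho_row")
                v = np.zeros(m.nobs)
                tr = 0.0
                for gi, g in enumerate(m.residual.grids):
                    if tidx is not None and gi != tidx:
                        continue
                    s2, rr, rc = res["spatial"][gi]
                    dS = g.ar1_kron_drow(rr, rc) if is_row else g.ar1_kron_dcol(rr, rc)
                    dS = s2 * dS
                    v[g.obs_idx] = dS @ Py[g.obs_idx]
                    tr += float(np.einsum("ij,ij->", P_blocks[gi], dS))
                v_list[:, a] = v
                traces[a] = tr
            elif name.startswith("sigma2_e("):
                tidx = self._grid_index(name)
                g = m.residual.grids[tidx]
                v = np.zeros(m.nobs)
                v[g.obs_idx] = Py[g.obs_idx]
                v_list[:, a] = v
                traces[a] = float(np.trace(P_blocks[tidx]))
            elif name == "sigma2_e":
                v_list[:, a] = Py
                traces[a] = trP if trP is not None else fac.trace_P()
            else:  # pragma: no cover
                raise RuntimeError(f"unhandled parameter {name}")

        score = -0.5 * (traces - Py @ v_list)
        Pv = fac.apply_P(v_list) if n_act else v_list
        ai = 0.5 * (v_list.T @ Pv)
        return score, ai

    def _grid_index(self, name: str) -> int | None:
        if "(" not in name:
            return None
        label = name[name.index("(") + 1 : -1]
        for i, g in enumerate(self.residual.grids):
            if g.trial_id == label:
                return i
        raise KeyError(name)

    # ------------------------------------------------------------------
    def fit(
        self,
        start=None,
        maxiter: int = 200,
        tol: float = 1e-6,
        verbose: bool = False,
    ) -> "MixedModelResults":
        """Maximise the restricted likelihood by safeguarded AI-REML.

        Returns a :class:`MixedModelResults`; non-convergence within
        ``maxiter`` is reported through ``converged=False``, never
        silently.
        """
        theta = np.asarray(start, dtype=float) if start is not None else self.start_values()
        theta = self._project(theta)
        fac = _Factor(self, theta)
        pinned = np.zeros(self.n_params, dtype=bool)
        converged = False
        n_iter = 0
        trace: list[float] = [fac.llf]
        grad_norm = np.inf
        prev_gain = None  # for geometric step extrapolation

        for n_iter in range(1, maxiter + 1):
            active = ~pinned
            score, ai = self._derivatives(fac, active)
            grad_norm = float(np.max(np.abs(score))) if score.size else 0.0

            # release pinned parameters whose score has turned positive
            if pinned.any():
                score_all, _ = self._derivatives(fac, np.ones(self.n_params, dtype=bool))
                release = pinned & (score_all > 1e-4)
                release &= np.array([k == "var" for k in self.param_kinds])
                if release.any():
                    pinned &= ~release
                    self._sync_spatial_pins(pinned)
                    active = ~pinned
                    score, ai = self._derivatives(fac, active)

            new_fac = None
            damping = 0.0
            for _attempt in range(8):
                try:
                    ai_d = ai + damping * np.eye(ai.shape[0])
                    delta = np.linalg.solve(ai_d, score)
                except np.linalg.LinAlgError:
                    damping = max(10 * damping, 1e-4 * (np.trace(ai) / max(ai.shape[0], 1) + 1e-8))
                    continue
                # AI convergence is linear on flat likelihood ridges; if
                # successive gains shrink geometrically with ratio r, the
                # extrapolated step 1/(1-r) largely removes the crawl.
                first = 1.0
                if prev_gain is not None and len(trace) >= 2:
                    last_gain = trace[-1] - trace[-2]
                    if prev_gain > 0 and 0.0 < last_gain:
                        r = last_gain / prev_gain
                        if 0.05 < r < 0.995:
                            first = float(np.clip(1.0 / (1.0 - r), 1.0, 16.0))
                steps = [first] + [0.5**k for k in range(25)]
                for step in steps:
                    cand = theta.copy()
                    cand[active] = theta[active] + step * delta
                    cand = self._project(cand)
                    try:
                        cand_fac = _Factor(self, cand)
                    except (np.linalg.LinAlgError, ValueError):
                        continue
                    if cand_fac.llf >= fac.llf - 1e-10:
                        new_fac = cand_fac
                        new_theta = cand
                        break
                if new_fac is not None:
                    break
                damping = max(10 * damping, 1e-4 * (np.trace(ai) / max(ai.shape[0], 1) + 1e-8))
            if new_fac is None:
                break  # no improving step found; treat as stationary

            d_llf = new_fac.llf - fac.llf
            d_theta = float(np.max(np.abs(new_theta - theta) / (np.abs(theta) + 1.0)))
            prev_gain = trace[-1] - trace[-2] if len(trace) >= 2 else None
            theta, fac = new_theta, new_fac
            trace.append(fac.llf)

            # pin variances pressed to the boundary with negative score
            for j in range(self.n_params):
                if (
                    self.param_kinds[j] == "var"
                    and theta[j] <= _VAR_FLOOR + 1e-12
                    and not pinned[j]
                ):
                    sc_j, _ = self._derivatives(fac, np.arange(self.n_params) == j)
                    if sc_j[0] <= 0:
                        theta[j] = 0.0
                        pinned[j] = True
            self._sync_spatial_pins(pinned)
            if verbose:
                print(f"iter {n_iter}: logL_R={fac.llf:.6f} dllf={d_llf:.2e} dtheta={d_theta:.2e}")
            # converged when both the likelihood and the parameters have
            # stabilised; a likelihood gain at the numerical noise floor
            # counts even if a statistically flat ridge direction still
            # lets parameters drift
            if d_llf < tol and (d_theta < tol or d_llf < 1e-9):
                converged = True
                break

        # asymptotic covariance from the AI matrix over free parameters
        free = ~pinned
        theta_cov = np.full((self.n_params, self.n_params), np.nan)
        try:
            _, ai_free = self._derivatives(fac, free)
            cov_free = np.linalg.inv(ai_free)
            ix = np.flatnonzero(free)
            theta_cov[np.ix_(ix, ix)] = cov_free
        except np.linalg.LinAlgError:
            pass

        return MixedModelResults(
            model=self,
            theta=theta,
            theta_cov=theta_cov,
            boundary=pinned.copy(),
            llf=fac.llf,
            converged=converged,
            n_iter=n_iter,
            grad_norm=grad_norm,
            llf_trace=trace,
        )

    def _sync_spatial_pins(self, pinned: np.ndarray) -> None:
        """AR1 correlations are only identified while their spatial
        variance is free: pin/release each rho with its sigma2_eps."""
        for j, name in enumerate(self.param_names):
            if name.startswith("sigma2_eps"):
                suffix = name[len("sigma2_eps"):]
                for k, nm in enumerate(self.param_names):
                    if nm in (f"rho_row{suffix}", f"rho_col{suffix}"):
                        pinned[k] = pinned[j]

    def _project(self, theta: np.ndarray) -> np.ndarray:
        out = theta.copy()
        for i, kind in enumerate(self.param_kinds):
            if kind == "var":
                out[i] = max(out[i], _VAR_FLOOR)
            else:
                out[i] = float(np.clip(out[i], -RHO_BOUND, RHO_BOUND))
        return out

    # ------------------------------------------------------------------
    def solve_mme(self, theta, compute_pev: bool = True) -> MMEResult:
        """Solve Henderson's mixed-model equations at ``theta``.

        The coefficient matrix is ``W' R^-1 W`` plus the block diagonal
        of ``G_k^-1 / sigma2_k``; its inverse provides the prediction
        error variances.  Terms whose variance sits at the zero boundary
        contribute BLUPs of exactly zero and are excluded from the
        system.  The additive term uses the sparse pedigree inverse of A
        over *all* pedigree members when available, so parents without
        records receive breeding values too.
        """
        theta = np.asarray(theta, dtype=float)
        res = self._residual_params(theta)
        n = self.nobs

        # terms represented as c*I + U U' without a pedigree system fold
        # their diagonal part (e.g. the Mendelian half-sib variance) into R
        extra_diag = 0.0
        for k, term in enumerate(self.terms):
            if (
                theta[k] > 0
                and term.U is not None
                and term.G is None
                and getattr(term, "mme_factory", None) is None
            ):
                extra_diag += theta[k] * term.diag_weight

        # R^-1 action as a dense block-diagonal (or diagonal) matrix
        if not self.residual.has_ar1:
            rinv_diag = 1.0 / (res["nugget_per_obs"] + extra_diag)
            Rinv_blocks = None
        else:
            Rinv_blocks = []
            for gi, g in enumerate(self.residual.grids):
                s2, rr, rc = res["spatial"][gi]
                block = s2 * g.ar1_kron_restricted(rr, rc) + (
                    res["nugget"][gi] + extra_diag
                ) * np.eye(g.n_obs)
                Rinv_blocks.append(np.linalg.inv(block))

        def rinv_dot(B: np.ndarray) -> np.ndarray:
            if Rinv_blocks is None:
                return B * rinv_diag[:, None]
            out = np.empty_like(B)
            for g, Ri in zip(self.residual.grids, Rinv_blocks):
                out[g.obs_idx] = Ri @ B[g.obs_idx]
            return out

        def term_system(term):
            """(Z, Ginv_unit, levels) at unit variance, cached per term."""
            cache = getattr(term, "_mme_cache", None)
            if cache is not None:
                return cache
            if getattr(term, "mme_factory", None) is not None:
                Z, Ginv, levels = term.mme_factory()
                cache = (np.asarray(Z.todense()), np.asarray(Ginv.todense()), levels)
            elif term.G is not None:
                cache = (np.asarray(term.Z.todense()), np.linalg.inv(term.G), term.levels)
            elif term.U is not None:
                # collapsed c*I + U U' term: the U-coefficients are the
                # level effects (dam breeding values for the half-sib
                # additive term); the c*I part lives in R
                cache = (term.U, np.eye(term.U.shape[1]), term.levels)
            else:
                Zd = np.asarray(term.Z.todense())
                cache = (Zd, np.eye(Zd.shape[1]), term.levels)
            term._mme_cache = cache
            return cache

        design_blocks = [("(fixed)", self.X, None, None)]
        for k, term in enumerate(self.terms):
            gamma = theta[k]
            if gamma <= 0:
                continue
            Z, Ginv_unit, levels = term_system(term)
            design_blocks.append((term.name, Z, Ginv_unit / gamma, levels))

        W = np.concatenate([b[1] for b in design_blocks], axis=1)
        dim = W.shape[1]
        RinvW = rinv_dot(W)
        C = W.T @ RinvW
        pos = self.X.shape[1]
        slices = {"(fixed)": slice(0, pos)}
        for name, Z, Ginv, levels in design_blocks[1:]:
            sl = slice(pos, pos + Z.shape[1])
            C[sl, sl] += Ginv
            slices[name] = sl
            pos += Z.shape[1]
        rhs = RinvW.T @ self.y
        cC = sla.cho_factor(C, lower=True, check_finite=False)
        sol = sla.cho_solve(cC, rhs, check_finite=False)

        beta = pd.Series(sol[slices["(fixed)"]], index=self.x_names, name="blue")
        blups: dict = {}
        pev: dict = {}
        if compute_pev:
            Cinv_diag = np.diag(sla.cho_solve(cC, np.eye(dim), check_finite=False))
        for name, Z, Ginv, levels in design_blocks[1:]:
            sl = slices[name]
            blups[name] = pd.Series(sol[sl], index=levels, name=name)
            if compute_pev:
                pev[name] = pd.Series(np.maximum(Cinv_diag[sl], 0.0), index=levels, name=f"pev_{name}")
        for k, term in enumerate(self.terms):
            if term.name not in blups:  # boundary term: zero effects, zero PEV
                levels = term_system(term)[2]
                blups[term.name] = pd.Series(0.0, index=levels, name=term.name)
                pev[term.name] = pd.Series(0.0, index=levels, name=f"pev_{term.name}")
        return MMEResult(beta=beta, blups=blups, pev=pev, coefficient_dim=dim)


def restricted_loglik(y, X, terms, residual: ResidualSpec, theta) -> float:
    """Restricted log-likelihood ``-1/2 [log|V| + log|X'V^-1 X| + y'Py]``
    (additive constant omitted) for the given structures."""
    return PedigreeMixedModel(y, X, terms, residual).loglike(theta)


class MixedModelResults:
    """REML fit results: variance parameters, uncertainty, criteria, and
    (lazily) BLUE/BLUP/PEV from the mixed-model equations."""

    def __init__(
        self,
        model: PedigreeMixedModel,
        theta: np.ndarray,
        theta_cov: np.ndarray,
        boundary: np.ndarray,
        llf: float,
        converged: bool,
        n_iter: int,
        grad_norm: float,
        llf_trace: list,
    ):
        self.model = model
        self.theta = pd.Series(theta, index=model.param_names, name="estimate")
        self.theta_cov = pd.DataFrame(
            theta_cov, index=model.param_names, columns=model.param_names
        )
        self.boundary = pd.Series(boundary, index=model.param_names, name="boundary")
        self.llf = float(llf)
        self.converged = bool(converged)
        self.n_iter = int(n_iter)
        self.grad_norm = float(grad_norm)
        self.llf_trace = list(llf_trace)
        self.t = model.n_params
        self.df_resid = model.nobs - model.rank_X
        self.aic, self.bic = information_criteria(self.llf, self.t, self.df_resid)
        self._mme: MMEResult | None = None
        self._mme_pev = False

    @property
    def theta_se(self) -> pd.Series:
        var = np.diag(self.theta_cov.to_numpy())
        se = np.sqrt(np.where(var >= 0, var, np.nan))
        se = np.where(self.boundary.to_numpy(), np.nan, se)
        return pd.Series(se, index=self.theta.index, name="se")

    def _ensure_mme(self, compute_pev: bool = True) -> MMEResult:
        if self._mme is None or (compute_pev and not self._mme_pev):
            self._mme = self.model.solve_mme(self.theta.to_numpy(), compute_pev=compute_pev)
            self._mme_pev = compute_pev
        return self._mme

    @property
    def fe_params(self) -> pd.Series:
        """Fixed-effect BLUEs (generalised least squares at theta-hat)."""
        return self._ensure_mme(compute_pev=False).beta

    def blup(self, term: str) -> pd.Series:
        return self._ensure_mme().blups[term]

    def pev(self, term: str) -> pd.Series:
        return self._ensure_mme().pev[term]

    @property
    def blups(self) -> dict:
        return self._ensure_mme().blups

    def variance_components(self) -> pd.DataFrame:
        """Table of variance parameters with SEs and boundary flags."""
        return pd.DataFrame(
            {
                "estimate": self.theta,
                "se": self.theta_se,
                "boundary": self.boundary,
            }
        )

    def to_dict(self) -> dict:
        """JSON-serialisable summary (parameters, criteria, convergence)."""
        return {
            "theta": self.theta.to_dict(),
            "theta_se": {k: (None if not np.isfinite(v) else v) for k, v in self.theta_se.items()},
            "boundary": {k: bool(v) for k, v in self.boundary.items()},
            "logL_R": self.llf,
            "t": self.t,
            "df_resid": self.df_resid,
            "aic": self.aic,
            "bic": self.bic,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "llf_trace": self.llf_trace,
        }

    def summary(self) -> str:
        lines = []
        m = self.model
        lines.append("Pedigree mixed model (REML)")
        lines.append("=" * 64)
        lines.append(f"No. observations: {m.nobs:>8}    Fixed-effect rank: {m.rank_X}")
        lines.append(
            f"logL_R: {self.llf:>12.4f}    AIC: {self.aic:.4f}    BIC: {self.bic:.4f}"
        )
        lines.append(
            f"Converged: {self.converged}    iterations: {self.n_iter}    "
            f"max|score|: {self.grad_norm:.3g}"
        )
        lines.append("-" * 64)
        lines.append(f"{'Variance parameter':<28}{'Estimate':>12}{'SE':>12}{'':>8}")
        for name in self.theta.index:
            se = self.theta_se[name]
            flag = "  (bound)" if self.boundary[name] else ""
            se_s = f"{se:12.4f}" if np.isfinite(se) else "         NA"
            lines.append(f"{name:<28}{self.theta[name]:>12.4f}{se_s}{flag}")
        lines.append("-" * 64)
        lines.append(f"{'Fixed effect':<28}{'BLUE':>12}")
        for name, val in self.fe_params.items():
            lines.append(f"{str(name):<28}{val:>12.4f}")
        if m.dropped_columns:
            lines.append(f"Dropped (rank-deficient): {m.dropped_columns}")
        return "\n".join(lines)
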