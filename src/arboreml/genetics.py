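"""Quantitative-genetic parameters derived from variance components.

For a multi-environment individual-tree model the phenotypic variance is
taken as sigma2_P = sigma2_A + sigma2_AE + sigma2_E -- deliberately
excluding replicate/row/column design variances -- where sigma2_E is the
residual nugget (the among-trial average for heterogeneous-residual
models).  From it:

* narrow-sense heritability    h2  = sigma2_A / sigma2_P
* type-B genetic correlation   r_B = sigma2_A / (sigma2_A + sigma2_AE)
* breeding-value accuracy      r_i = sqrt(1 - PEV_i / ((1 + f_i) sigma2_A))

Coefficients of variation follow the convention of the source analyses,
dividing the *variance* component by the trait mean (x100 for percent):
CV_X = 100 * sigma2_X / mean.  This is not the textbook sd/mean ratio; a
conventional variant is available via ``use_sd=True``.

Standard errors of any smooth function of the variance parameters come
from the delta method with a numerically differentiated gradient and the
asymptotic parameter covariance of the REML fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "heritability",
    "type_b_correlation",
    "coefficients_of_variation",
    "accuracy",
    "delta_method_se",
    "GeneticParams",
    "genetic_parameters",
    "correlate_breeding_values",
]


def _mean_residual(sigma2_e) -> float:
    """Across-trial (unweighted) mean for heterogeneous residuals."""
    arr = np.atleast_1d(np.asarray(sigma2_e, dtype=float))
    return float(arr.mean())


def heritability(sigma2_a: float, sigma2_ae: float, sigma2_e) -> float:
    """Narrow-sense heritability sigma2_A / (sigma2_A + sigma2_AE + sigma2_E).

    ``sigma2_e`` may be a scalar or a per-trial sequence, in which case
    its unweighted mean enters the denominator.
    """
    sigma2_a = float(sigma2_a)
    sigma2_ae = float(sigma2_ae)
    se = _mean_residual(sigma2_e)
    if sigma2_a < 0 or sigma2_ae < 0 or se < 0:
        raise ValueError("variance components must be nonnegative")
    denom = sigma2_a + sigma2_ae + se
    if denom == 0:
        raise ValueError("all variance components are zero")
    return sigma2_a / denom


def type_b_correlation(sigma2_a: float, sigma2_ae: float) -> float:
    """Type-B genetic correlation sigma2_A / (sigma2_A + sigma2_AE)."""
    denom = float(sigma2_a) + float(sigma2_ae)
    if denom <= 0:
        raise ValueError("sigma2_A + sigma2_AE must be positive")
    return float(sigma2_a) / denom


def coefficients_of_variation(
    sigma2_a: float,
    sigma2_p: float,
    sigma2_e,
    trait_mean: float,
    use_sd: bool = False,
) -> tuple[float, float, float]:
    """(CV_A, CV_P, CV_E) in percent.

    Default divides the variance component by the trait mean (x100),
    matching the convention of the source analyses; ``use_sd=True``
    switches to the conventional 100*sd/mean.
    """
    if trait_mean <= 0:
        raise ValueError("trait mean must be positive")
    se = _mean_residual(sigma2_e)
    vals = np.array([sigma2_a, sigma2_p, se], dtype=float)
    if use_sd:
        vals = np.sqrt(vals)
    out = 100.0 * vals / trait_mean
    return float(out[0]), float(out[1]), float(out[2])


def accuracy(pev, f, sigma2_a: float) -> np.ndarray:
    """Breeding-value accuracy r_i = sqrt(1 - PEV_i / ((1 + f_i) sigma2_A)).

    A negative radicand (possible when the PEV exceeds the prior
    variance) is clipped to zero.  ``pev`` and ``f`` broadcast.
    """
    if sigma2_a <= 0:
        raise ValueError("sigma2_A must be positive")
    pev = np.asarray(pev, dtype=float)
    f = np.asarray(f, dtype=float)
    if np.any(pev < 0) or np.any(f < 0):
        raise ValueError("pev and f must be nonnegative")
    rad = 1.0 - pev / ((1.0 + f) * sigma2_a)
    return np.sqrt(np.clip(rad, 0.0, None))


def delta_method_se(func, theta, theta_cov) -> float:
    """Delta-method standard error of ``func(theta)``.

    The gradient is computed by central differences with step
    ``1e-5 * (|theta_i| + 1e-8)`` per coordinate.  ``theta_cov`` rows
    containing non-finite entries (boundary parameters) make the SE
    unavailable (NaN).
    """
    theta = np.asarray(theta, dtype=float)
    cov = np.asarray(theta_cov, dtype=float)
    if not np.all(np.isfinite(cov)):
        return float("nan")
    g = np.empty_like(theta)
    for i in range(len(theta)):
        h = 1e-5 * (abs(theta[i]) + 1e-8)
        up = theta.copy()
        dn = theta.copy()
        up[i] += h
        dn[i] -= h
        g[i] = (func(up) - func(dn)) / (2 * h)
    var = float(g @ cov @ g)
    return float(np.sqrt(max(var, 0.0)))


@dataclass
class GeneticParams:
    """Genetic-parameter report for one fitted model and trait."""

    sigma2_a: float
    sigma2_ae: float
    sigma2_e: float  # (mean) residual nugget
    sigma2_p: float
    h2: float
    h2_se: float
    rb: float
    rb_se: float
    cv_a: float
    cv_p: float
    cv_e: float
    trait_mean: float

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def genetic_parameters(results, trait_mean: float) -> GeneticParams:
    """Compute the full parameter report from a REML fit.

    ``results`` is a :class:`~arboreml.reml.MixedModelResults` whose
    model contains an ``additive`` term; the additive-by-trial
    interaction (``family_x_trial``/``additive_x_trial``) contributes
    sigma2_AE when present, zero otherwise.  SEs use the delta method
    over the fit's asymptotic parameter covariance; parameters pinned at
    a boundary make the SE unavailable for functions that involve them.
    """
    names = list(results.theta.index)
    theta = results.theta.to_numpy()

    def find(prefixes):
        return [i for i, n in enumerate(names) if any(n.startswith(p) for p in prefixes)]

    ia = find(["sigma2_additive"])
    if not ia:
        raise ValueError("fit has no additive term")
    iae = find(["sigma2_family_x_trial", "sigma2_additive_x_trial"])
    ie = find(["sigma2_e"])
    ie = [i for i in ie if not names[i].startswith("sigma2_eps")]

    def h2_fn(th):
        ae = th[iae[0]] if iae else 0.0
        return th[ia[0]] / (th[ia[0]] + ae + np.mean([th[i] for i in ie]))

    def rb_fn(th):
        ae = th[iae[0]] if iae else 0.0
        return th[ia[0]] / (th[ia[0]] + ae)

    s2a = float(theta[ia[0]])
    s2ae = float(theta[iae[0]]) if iae else 0.0
    s2e = float(np.mean([theta[i] for i in ie]))
    s2p = s2a + s2ae + s2e
    h2 = heritability(s2a, s2ae, [theta[i] for i in ie])
    rb = type_b_correlation(s2a, s2ae) if (s2a + s2ae) > 0 else float("nan")

    # delta-method SEs over the free (non-boundary) parameters involved
    involved = ia + iae + ie
    sub = results.theta_cov.to_numpy()[np.ix_(involved, involved)]
    th_sub = theta[involved]

    def embed(fn):
        def wrapped(th_s):
            full = theta.copy()
            full[involved] = th_s
            return fn(full)

        return wrapped

    h2_se = delta_method_se(embed(h2_fn), th_sub, sub)
    rb_se = (
        delta_method_se(embed(rb_fn), th_sub, sub) if (s2a + s2ae) > 0 else float("nan")
    )
    cv_a, cv_p, cv_e = coefficients_of_variation(s2a, s2p, s2e, trait_mean)
    return GeneticParams(
        sigma2_a=s2a,
        sigma2_ae=s2ae,
        sigma2_e=s2e,
        sigma2_p=s2p,
        h2=h2,
        h2_se=h2_se,
        rb=rb,
        rb_se=rb_se,
        cv_a=cv_a,
        cv_p=cv_p,
        cv_e=cv_e,
        trait_mean=trait_mean,
    )


def correlate_breeding_values(bv_table: pd.DataFrame) -> dict:
    """Pearson correlations of parental breeding values with provenance
    coordinates, plus a quadratic clinal-surface fit.

    Parameters
    ----------
    bv_table : DataFrame
        One row per parent; must contain ``lat`` and ``long`` plus one or
        more breeding-value columns (any other numeric columns).

    Returns
    -------
    dict with
        ``correlations`` -- DataFrame of Pearson r (NaN for constant
        columns);
        ``p_values`` -- matching two-sided p-values;
        ``surface_r2`` -- dict per BV column: R-squared of the least
        squares fit  bv ~ 1 + lat^2 + long^2 + lat*long.
    """
    num = bv_table.select_dtypes(include=[np.number])
    if len(num) < 3:
        raise ValueError("need at least 3 parents with coordinates")
    cols = list(num.columns)
    k = len(cols)
    corr = pd.DataFrame(np.eye(k), index=cols, columns=cols)
    pval = pd.DataFrame(np.zeros((k, k)), index=cols, columns=cols)
    for i in range(k):
        for j in range(i + 1, k):
            xi, xj = num[cols[i]].to_numpy(), num[cols[j]].to_numpy()
            if np.std(xi) == 0 or np.std(xj) == 0:
                r, p = np.nan, np.nan
            else:
                r, p = stats.pearsonr(xi, xj)
            corr.iloc[i, j] = corr.iloc[j, i] = r
            pval.iloc[i, j] = pval.iloc[j, i] = p

    surface_r2 = {}
    if {"lat", "long"} <= set(cols):
        lat = num["lat"].to_numpy()
        lon = num["long"].to_numpy()
        Xq = np.column_stack([np.ones(len(num)), lat**2, lon**2, lat * lon])
        for col in cols:
            if col in ("lat", "long"):
                continue
            yv = num[col].to_numpy()
            coef, *_ = np.linalg.lstsq(Xq, yv, rcond=None)
            fitted = Xq @ coef
            sst = float(((yv - yv.mean()) ** 2).sum())
            ssr = float(((yv - fitted) ** 2).sum())
            surface_r2[col] = 1.0 - ssr / sst if sst > 0 else float("nan")
    return {"correlations": corr, "p_values": pval, "surface_r2": surface_r2}
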