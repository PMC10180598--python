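"""Synthetic open-pollinated progeny-trial generator.

Generates multi-site half-sib trial data with exactly the statistical
structure the analysis pipeline assumes, so every estimator can be
tested against a known truth:

* two test series with partially overlapping family sets (by default 32
  and 34 families sharing 21, i.e. 52 unique dams, mirroring a regional
  hardwood breeding population);
* per trial, a complete rectangular planting grid of single-tree plots
  tiled into complete blocks (default 30), families randomized within
  block, leftover cells planted as fillers;
* phenotype = trial mean + row/column gradients + competition class
  effect + block + row-band + column-band effects + additive genetic
  value + family-by-trial interaction + separable AR1 x AR1 spatial
  field + iid nugget;
* additive values follow the half-sib decomposition: dam breeding
  values ~ N(0, sigma2_A), offspring = dam/2 + Mendelian deviation
  ~ N(0, 3/4 sigma2_A) (sires unknown and unrelated);
* spatially uniform Bernoulli mortality (optionally clustered); dead
  trees keep their position but lose growth traits.

Row-band and column-band environmental effects are generated on the
default incomplete sub-blocking bands, so the sub-blocking models are
correctly specified for simulated data.  Every generated component is
stored per tree and sums exactly to the phenotype.

:func:`recovery_experiment` refits a chosen model over many simulated
replicates and reports bias, empirical spread, mean reported SE and
+-2 SE coverage per variance parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .covariance import ar1_matrix
from .geometry import _bands, _fold_bands
from .genetics import delta_method_se, heritability
from .models import ProgenyTrialData, ProgenyTrialModel, TrialLayout, build_model_spec
from .pedigree import Pedigree

__all__ = ["SimulationConfig", "SimulatedDataset", "simulate", "recovery_experiment"]

_PROVENANCES = ["AR", "MS", "TX", "LA"]


@dataclass
class SimulationConfig:
    """Study conditions for the generator.

    Grid sizes, block count, family numbers and overlap mirror the
    motivating trial series; variance defaults are on the height scale
    (metres).  ``trial_grids`` maps trial id -> (series, n_rows,
    n_cols).
    """

    trial_grids: dict = field(
        default_factory=lambda: {
            "S1A": (1, 40, 30),
            "S1B": (1, 30, 48),
            "S2A": (2, 20, 60),
            "S2B": (2, 25, 30),
        }
    )
    n_blocks: int = 30
    n_families_series1: int = 32
    n_families_series2: int = 34
    n_shared_families: int = 21
    # true variance parameters (height scale)
    sigma2_a: float = 0.4
    sigma2_ae: float = 0.2
    sigma2_rep: float = 0.4
    sigma2_row: float = 0.2
    sigma2_col: float = 0.2
    sigma2_eps: float = 0.5
    rho_row: float = 0.5
    rho_col: float = 0.5
    sigma2_e: float = 2.0
    # fixed structure
    trial_means: dict | None = None
    x_slope: float = 0.01
    y_slope: float = 0.01
    competition_effects: tuple = (0.0, 0.0, 0.0, 0.0, 0.0)
    mortality: float = 0.25
    clustered_mortality: bool = False
    # band granularity for the generated row/column environmental effects
    block_rows: int = 5
    block_cols: int = 5
    seed: int = 0

    def __post_init__(self):
        for name in (
            "sigma2_a",
            "sigma2_ae",
            "sigma2_rep",
            "sigma2_row",
            "sigma2_col",
            "sigma2_eps",
            "sigma2_e",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not (abs(self.rho_row) < 1 and abs(self.rho_col) < 1):
            raise ValueError("|rho| must be < 1")
        if not 0 <= self.mortality < 1:
            raise ValueError("mortality must be in [0, 1)")
        if self.n_shared_families > min(self.n_families_series1, self.n_families_series2):
            raise ValueError("shared families exceed series family count")

    @property
    def true_h2(self) -> float:
        return heritability(self.sigma2_a, self.sigma2_ae, self.sigma2_e)


@dataclass
class SimulatedDataset:
    """Generated phenotypes plus every latent component."""

    records: pd.DataFrame
    pedigree: Pedigree
    layouts: dict
    dam_values: pd.Series
    dam_meta: pd.DataFrame  # provenance state and coordinates per dam
    components: pd.DataFrame  # per planted tree, exact decomposition
    config: SimulationConfig

    def true_theta(self, param_names) -> dict:
        """True value for each engine parameter name (shared-spatial
        SUB-model parameterisation)."""
        c = self.config
        lookup = {
            "sigma2_additive": c.sigma2_a,
            "sigma2_family_x_trial": c.sigma2_ae,
            "sigma2_rep_in_trial": c.sigma2_rep,
            "sigma2_subrow": c.sigma2_row,
            "sigma2_subcol": c.sigma2_col,
            "sigma2_rowblock": c.sigma2_row,
            "sigma2_colblock": c.sigma2_col,
            "sigma2_eps": c.sigma2_eps,
            "rho_row": c.rho_row,
            "rho_col": c.rho_col,
            "sigma2_e": c.sigma2_e,
        }
        return {name: lookup[name] for name in param_names if name in lookup}

    def data(self) -> ProgenyTrialData:
        return ProgenyTrialData(self.records, self.pedigree, self.layouts)


def _block_tiling(n_rows: int, n_cols: int, n_blocks: int) -> tuple[int, int]:
    """Factor ``n_blocks`` into row x column tiers giving the squarest
    blocks for this grid."""
    best = None
    for a in range(1, n_blocks + 1):
        if n_blocks % a:
            continue
        b = n_blocks // a
        if a > n_rows or b > n_cols:
            continue
        ratio = abs(np.log((n_rows / a) / (n_cols / b)))
        if best is None or ratio < best[0]:
            best = (ratio, a, b)
    if best is None:
        raise ValueError(f"cannot tile {n_rows}x{n_cols} into {n_blocks} blocks")
    return best[1], best[2]


def simulate(config: SimulationConfig | None = None, **overrides) -> SimulatedDataset:
    """Generate one synthetic multi-site half-sib dataset.

    The same seed reproduces the dataset bit-for-bit.  Keyword overrides
    are applied on top of ``config`` (or the defaults).
    """
    if config is None:
        config = SimulationConfig(**overrides)
    elif overrides:
        config = SimulationConfig(**{**asdict(config), **overrides})
    rng = np.random.default_rng(config.seed)

    # --- families and pedigree -----------------------------------------
    n_unique = (
        config.n_families_series1 + config.n_families_series2 - config.n_shared_families
    )
    dams = [f"DAM{i + 1:03d}" for i in range(n_unique)]
    shared = dams[: config.n_shared_families]
    only1 = dams[
        config.n_shared_families : config.n_shared_families
        + (config.n_families_series1 - config.n_shared_families)
    ]
    only2 = dams[config.n_shared_families + len(only1) :]
    series_families = {1: shared + only1, 2: shared + only2}
    dam_bv = pd.Series(
        rng.normal(0.0, np.sqrt(config.sigma2_a), n_unique), index=dams, name="dam_bv"
    )
    dam_prov = pd.Series(
        [_PROVENANCES[i % len(_PROVENANCES)] for i in range(n_unique)], index=dams
    )
    dam_lat = pd.Series(rng.uniform(30.5, 35.0, n_unique), index=dams)
    dam_long = pd.Series(rng.uniform(-95.0, -89.5, n_unique), index=dams)

    trial_ids = list(config.trial_grids)
    means = config.trial_means or {
        t: m for t, m in zip(trial_ids, [8.9, 5.8, 6.4, 8.3, 7.1, 6.0][: len(trial_ids)])
    }
    ae_draws: dict = {}
    layouts: dict = {}
    rec_rows = []
    comp_rows = []
    ped_rows = []

    for trial in trial_ids:
        series, n_rows, n_cols = config.trial_grids[trial]
        fams = series_families[1 if series == 1 else 2]
        tiers_r, tiers_c = _block_tiling(n_rows, n_cols, config.n_blocks)
        layouts[trial] = TrialLayout(
            n_rows=n_rows,
            n_cols=n_cols,
            row_tiers=tiers_r,
            col_tiers=tiers_c,
            block_rows=config.block_rows,
            block_cols=config.block_cols,
        )
        row_band = _bands(n_rows, tiers_r)
        col_band = _bands(n_cols, tiers_c)
        block_of = row_band[:, None] * tiers_c + col_band[None, :]  # 0-based block index

        # random effects for this trial
        block_eff = rng.normal(0.0, np.sqrt(config.sigma2_rep), tiers_r * tiers_c)
        sub_r = _fold_bands(n_rows, config.block_rows)
        sub_c = _fold_bands(n_cols, config.block_cols)
        rowband_eff = rng.normal(0.0, np.sqrt(config.sigma2_row), sub_r.max() + 1)
        colband_eff = rng.normal(0.0, np.sqrt(config.sigma2_col), sub_c.max() + 1)
        for fam in fams:
            ae_draws[(fam, trial)] = rng.normal(0.0, np.sqrt(config.sigma2_ae))

        # separable AR1 field via per-axis Cholesky factorisation
        Lr = np.linalg.cholesky(ar1_matrix(config.rho_row, n_rows))
        Lc = np.linalg.cholesky(ar1_matrix(config.rho_col, n_cols))
        field = np.sqrt(config.sigma2_eps) * (Lr @ rng.standard_normal((n_rows, n_cols)) @ Lc.T)
        nugget = rng.normal(0.0, np.sqrt(config.sigma2_e), (n_rows, n_cols))

        # family placement: one tree per family per block, fillers elsewhere
        fam_of = np.full((n_rows, n_cols), None, dtype=object)
        for b in range(tiers_r * tiers_c):
            cells = np.argwhere(block_of == b)
            rng.shuffle(cells)
            order = list(fams)
            rng.shuffle(order)
            for i, (r, c) in enumerate(cells):
                fam_of[r, c] = order[i] if i < len(order) else None

        # mortality thinning
        if config.clustered_mortality and config.mortality > 0:
            base = rng.random((n_rows, n_cols))
            smooth = base.copy()
            smooth[1:] = 0.5 * smooth[1:] + 0.5 * base[:-1]
            thresh = np.quantile(smooth, config.mortality)
            alive = smooth > thresh
        else:
            alive = rng.random((n_rows, n_cols)) >= config.mortality

        # competition class from the realized stocking
        living = alive.astype(int)
        comp = np.zeros_like(living)
        comp[1:, :] += living[:-1, :]
        comp[:-1, :] += living[1:, :]
        comp[:, 1:] += living[:, :-1]
        comp[:, :-1] += living[:, 1:]

        mid_r = (n_rows + 1) / 2.0
        mid_c = (n_cols + 1) / 2.0
        for r in range(n_rows):
            for c in range(n_cols):
                fam = fam_of[r, c]
                is_filler = fam is None
                is_alive = bool(alive[r, c])
                tree_id = f"{trial}_{r + 1}_{c + 1}"
                if not is_filler:
                    mendel = rng.normal(0.0, np.sqrt(0.75 * config.sigma2_a))
                    add = 0.5 * dam_bv[fam] + mendel
                    ae = ae_draws[(fam, trial)]
                else:
                    add = ae = 0.0
                fixed = (
                    means[trial]
                    + config.x_slope * ((r + 1) - mid_r)
                    + config.y_slope * ((c + 1) - mid_c)
                    + config.competition_effects[int(comp[r, c])]
                )
                env = (
                    block_eff[block_of[r, c]]
                    + rowband_eff[sub_r[r]]
                    + colband_eff[sub_c[c]]
                    + field[r, c]
                    + nugget[r, c]
                )
                pheno = fixed + add + ae + env
                if not is_filler and is_alive and pheno <= 0:
                    # a non-positive height is not a viable tree; record it
                    # as dead (Gaussian-tail event, ~1e-4 of trees)
                    is_alive = False
                status = "filler" if is_filler else ("live" if is_alive else "dead")
                rec_rows.append(
                    {
                        "tree_id": tree_id,
                        "family": None if is_filler else fam,
                        "trial": trial,
                        "series": series,
                        "rep": f"B{block_of[r, c] + 1}",
                        "row": r + 1,
                        "col": c + 1,
                        "status": status,
                        "height_m": pheno if (is_alive and not is_filler) else np.nan,
                        "dbh_cm": np.nan,
                        "survival": np.nan if is_filler else float(is_alive),
                        "provenance": None if is_filler else dam_prov[fam],
                    }
                )
                comp_rows.append(
                    {
                        "tree_id": tree_id,
                        "trial": trial,
                        "fixed": fixed,
                        "additive": add,
                        "family_x_trial": ae,
                        "block": block_eff[block_of[r, c]],
                        "row_band": rowband_eff[sub_r[r]],
                        "col_band": colband_eff[sub_c[c]],
                        "spatial": field[r, c],
                        "nugget": nugget[r, c],
                        "phenotype": pheno,
                        "competition_class": int(comp[r, c]),
                    }
                )
                if not is_filler:
                    ped_rows.append({"id": tree_id, "dam": fam, "sire": ""})

    records = pd.DataFrame(rec_rows)
    # a crude allometric DBH so volume/DBH traits are exercisable
    live = records["height_m"].notna()
    records.loc[live, "dbh_cm"] = np.clip(
        1.2 * records.loc[live, "height_m"]
        + np.random.default_rng(config.seed + 1).normal(0, 1.0, int(live.sum())),
        0.1,
        None,
    )
    ped_frame = pd.DataFrame(
        [{"id": d, "dam": "", "sire": ""} for d in dams] + ped_rows
    )
    pedigree = Pedigree.from_frame(ped_frame)
    dam_meta = pd.DataFrame(
        {"dam_bv": dam_bv, "provenance": dam_prov, "lat": dam_lat, "long": dam_long}
    )
    components = pd.DataFrame(comp_rows)
    return SimulatedDataset(
        records=records,
        pedigree=pedigree,
        layouts=layouts,
        dam_values=dam_bv,
        dam_meta=dam_meta,
        components=components,
        config=config,
    )


def recovery_experiment(
    config: SimulationConfig | None = None,
    model: str = "SUBB",
    n_seeds: int = 50,
    trait: str = "height",
    base_seed: int = 0,
    fit_options: dict | None = None,
) -> pd.DataFrame:
    """Parameter-recovery report over repeated simulations.

    Simulates ``n_seeds`` datasets (seeds ``base_seed .. base_seed +
    n_seeds - 1``), fits the named model with spatial parameters shared
    across trials (matching the generator's single AR1 field
    correlation), and reports, per variance parameter: the truth, mean
    estimate, empirical SD, mean reported SE and the coverage of
    +-2 SE intervals (flagged when < 0.8).  A final row reports the
    narrow-sense heritability.  Raises if no replicate converges.
    """
    if config is None:
        config = SimulationConfig()
    estimates: list[dict] = []
    ses: list[dict] = []
    h2s: list[tuple[float, float]] = []
    n_converged = 0
    truth: dict = {}
    for i in range(n_seeds):
        ds = simulate(config, seed=base_seed + i)
        data = ds.data()
        m = ProgenyTrialModel(data, model, trait, shared_spatial=True)
        res = m.fit(**(fit_options or {}))
        if not res.converged:
            continue
        n_converged += 1
        truth = ds.true_theta(res.theta.index)
        estimates.append(res.theta.to_dict())
        ses.append(res.theta_se.to_dict())
        gp = res.genetic_params
        h2s.append((gp.h2, gp.h2_se))
    if n_converged == 0:
        raise RuntimeError("no replicate converged")

    est = pd.DataFrame(estimates)
    se = pd.DataFrame(ses)
    rows = []
    for name in est.columns:
        if name not in truth:
            continue
        tv = truth[name]
        e = est[name].to_numpy()
        s = se[name].to_numpy()
        ok = np.isfinite(s)
        cover = np.mean(np.abs(e[ok] - tv) <= 2 * s[ok]) if ok.any() else np.nan
        rows.append(
            {
                "parameter": name,
                "truth": tv,
                "mean_estimate": float(e.mean()),
                "empirical_sd": float(e.std(ddof=1)) if len(e) > 1 else np.nan,
                "mean_se": float(np.nanmean(s)),
                "coverage_2se": float(cover),
                "n_boundary": int((~ok).sum()),
                "flag_low_coverage": bool(cover < 0.8) if np.isfinite(cover) else True,
            }
        )
    h2_est = np.array([h for h, _ in h2s])
    h2_se = np.array([s for _, s in h2s])
    ok = np.isfinite(h2_se)
    h2_cover = (
        float(np.mean(np.abs(h2_est[ok] - config.true_h2) <= 2 * h2_se[ok]))
        if ok.any()
        else np.nan
    )
    rows.append(
        {
            "parameter": "h2",
            "truth": config.true_h2,
            "mean_estimate": float(h2_est.mean()),
            "empirical_sd": float(h2_est.std(ddof=1)) if len(h2_est) > 1 else np.nan,
            "mean_se": float(np.nanmean(h2_se)),
            "coverage_2se": h2_cover,
            "n_boundary": int((~ok).sum()),
            "flag_low_coverage": bool(h2_cover < 0.8) if np.isfinite(h2_cover) else True,
        }
    )
    report = pd.DataFrame(rows)
    report.attrs["n_converged"] = n_converged
    report.attrs["n_seeds"] = n_seeds
    return report
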