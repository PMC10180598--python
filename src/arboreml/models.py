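"""Named model suite and the high-level Model/Results interface.

Thirteen model specifications are encoded: the original randomized
complete block design baseline (``RCBD``) and twelve *post hoc*
variants that combine

* incomplete sub-blocking (``SUB*``) or complete row/column blocking
  (``BLK*``/``NNPCA*``) as extra random factors,
* a 0-4 nearest-neighbour competition index and/or distance principal
  components PC1-PC3 as fixed covariates (nested within trial), and
* a separable AR1 x AR1 spatial residual with a shared (``simple``) or
  trial-specific (``heterogeneous``) nugget.

All twelve post hoc variants share fixed effects ``intercept + trial +
x + y`` (coordinates nested in trial) and random ``additive (A),
family x trial, rep(trial)`` plus the scheme's row/column blocks; the
RCBD baseline has an intercept-only fixed part with random additive,
family x trial, rep(trial), trial(series), series and provenance and an
iid residual.

:class:`ProgenyTrialModel` assembles one trait/model combination from a
phenotype table, a pedigree and per-trial layout declarations, and
``fit()`` returns :class:`ProgenyTrialResults` -- the REML results
augmented with genetic parameters, breeding values and accuracies.
:func:`run_met` and :func:`run_single_site` drive whole-suite analyses
and the AIC/BIC comparison against the complete-blocking benchmark.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from . import geometry, spatial
from .covariance import RandomTerm, ResidualSpec, TrialGrid, incidence
from .genetics import GeneticParams, accuracy, genetic_parameters
from .pedigree import Pedigree, build_A, sort_pedigree
from .reml import MixedModelResults, PedigreeMixedModel

__all__ = [
    "ModelSpec",
    "MODEL_NAMES",
    "BENCHMARK_MODEL",
    "TRAIT_COLUMNS",
    "build_model_spec",
    "derive_traits",
    "TrialLayout",
    "ProgenyTrialData",
    "ProgenyTrialModel",
    "ProgenyTrialResults",
    "SuiteResult",
    "run_met",
    "run_single_site",
]

VOLUME_COEF = 0.02618  # dm^3 from DBH (cm) and height (m)

#: analysis trait -> phenotype column
TRAIT_COLUMNS = {
    "height": "height_m",
    "dbh": "dbh_cm",
    "volume": "log_volume",
    "survival": "survival",
}

BENCHMARK_MODEL = "BLOCKING"


@dataclass
class ModelSpec:
    """Declarative description of one model's terms and residual."""

    name: str
    fixed_terms: list
    random_terms: list
    residual: str
    blocking: str | None  # "incomplete" | "complete" | None

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "fixed_terms": list(self.fixed_terms),
            "random_terms": list(self.random_terms),
            "residual": self.residual,
            "blocking": self.blocking,
        }


_MET_FIXED = ["intercept", "x(trial)", "y(trial)", "trial"]
_SUB_RANDOM = ["additive", "family_x_trial", "rep(trial)", "subrow(trial)", "subcol(trial)"]
_BLK_RANDOM = ["additive", "family_x_trial", "rep(trial)", "rowblock(trial)", "colblock(trial)"]


def _spec(name, extra_fixed, random_terms, residual, blocking) -> ModelSpec:
    return ModelSpec(
        name=name,
        fixed_terms=_MET_FIXED + extra_fixed,
        random_terms=list(random_terms),
        residual=residual,
        blocking=blocking,
    )


_REGISTRY: dict[str, ModelSpec] = {
    "RCBD": ModelSpec(
        name="RCBD",
        fixed_terms=["intercept"],
        random_terms=[
            "additive",
            "family_x_trial",
            "rep(trial)",
            "trial(series)",
            "series",
            "provenance",
        ],
        residual="iid_simple",
        blocking=None,
    ),
    "SUBB": _spec("SUBB", [], _SUB_RANDOM, "ar1_plus_iid", "incomplete"),
    "SUBHETERO": _spec("SUBHETERO", [], _SUB_RANDOM, "ar1_plus_hetero", "incomplete"),
    "SUBNN": _spec("SUBNN", ["competition(trial)"], _SUB_RANDOM, "ar1_plus_iid", "incomplete"),
    "SUBNNHETERO": _spec(
        "SUBNNHETERO", ["competition(trial)"], _SUB_RANDOM, "ar1_plus_hetero", "incomplete"
    ),
    "SUBNNPCA1": _spec("SUBNNPCA1", ["pc1-3(trial)"], _SUB_RANDOM, "ar1_plus_hetero", "incomplete"),
    "SUBNNPCA2": _spec(
        "SUBNNPCA2",
        ["competition(trial)", "pc1-3(trial)"],
        _SUB_RANDOM,
        "ar1_plus_iid",
        "incomplete",
    ),
    "BLOCKING": _spec("BLOCKING", [], _BLK_RANDOM, "ar1_plus_iid", "complete"),
    "BLKHETERO": _spec("BLKHETERO", [], _BLK_RANDOM, "ar1_plus_hetero", "complete"),
    "BLKNN": _spec("BLKNN", ["competition(trial)"], _BLK_RANDOM, "ar1_plus_iid", "complete"),
    "BLKNNHETERO": _spec(
        "BLKNNHETERO", ["competition(trial)"], _BLK_RANDOM, "ar1_plus_hetero", "complete"
    ),
    "NNPCA1": _spec("NNPCA1", ["pc1-3(trial)"], _BLK_RANDOM, "ar1_plus_hetero", "complete"),
    "NNPCA2": _spec(
        "NNPCA2", ["competition(trial)", "pc1-3(trial)"], _BLK_RANDOM, "ar1_plus_iid", "complete"
    ),
}

_ALIASES = {
    "SUBBLOCKING": "SUBB",
    "SUBH": "SUBHETERO",
    "SUBNNH": "SUBNNHETERO",
    "BLK": "BLOCKING",
    "BLKH": "BLKHETERO",
    "BLKNNH": "BLKNNHETERO",
}

MODEL_NAMES = list(_REGISTRY)
POST_HOC_MODELS = [m for m in MODEL_NAMES if m != "RCBD"]


def build_model_spec(
    name: str,
    single_site: bool = False,
    pca2_simple_residual: bool = False,
) -> ModelSpec:
    """Return the named model specification.

    ``single_site`` strips multi-trial terms (trial fixed effect, the
    family-by-trial interaction, series/trial-in-series); the
    ``pca2_simple_residual`` flag reproduces the purely independent
    residual variant of the *PCA2 models.
    """
    key = _ALIASES.get(name.upper(), name.upper())
    if key not in _REGISTRY:
        raise KeyError(
            f"unknown model {name!r}; valid names: {MODEL_NAMES + sorted(_ALIASES)}"
        )
    spec = copy.deepcopy(_REGISTRY[key])
    if pca2_simple_residual and key in ("SUBNNPCA2", "NNPCA2"):
        spec.residual = "iid_simple"
    if single_site:
        spec.fixed_terms = [t for t in spec.fixed_terms if t != "trial"]
        spec.random_terms = [
            t for t in spec.random_terms if t not in ("family_x_trial", "trial(series)", "series")
        ]
    return spec


def derive_traits(records: pd.DataFrame) -> pd.DataFrame:
    """Add stem volume (dm^3) and its log transform to a phenotype table.

    volume = 0.02618 * DBH^2 * height  (DBH in cm, height in m); the
    analysis trait is ln(volume + 0.1).  Dead or filler trees keep
    missing growth traits; dead trees carry survival 0.
    """
    out = records.copy()
    ht = pd.to_numeric(out.get("height_m"), errors="raise")
    dbh = pd.to_numeric(out.get("dbh_cm"), errors="raise")
    if (ht.dropna() < 0).any() or (dbh.dropna() < 0).any():
        raise ValueError("negative height or DBH")
    out["volume_dm3"] = VOLUME_COEF * dbh**2 * ht
    out["log_volume"] = np.log(out["volume_dm3"] + 0.1)
    if "survival" not in out:
        out["survival"] = (out["status"] == "live").astype(float)
    dead = out["status"] == "dead"
    out.loc[dead, ["height_m", "dbh_cm", "volume_dm3", "log_volume"]] = np.nan
    out.loc[dead, "survival"] = 0.0
    return out


@dataclass
class TrialLayout:
    """Per-trial layout declaration (grid size, tier counts, sub-block
    dimensions, column direction)."""

    n_rows: int
    n_cols: int
    row_tiers: int = 5
    col_tiers: int = 5
    block_rows: int = 5
    block_cols: int = 5
    column_direction: str = "W_TO_E"


_STATUS_MAP = {"live": geometry.MEASURED, "dead": geometry.MISSING, "filler": geometry.FILLER}


class ProgenyTrialData:
    """Validated multi-trial dataset with geometry and spatial covariates.

    Built once from the phenotype table, pedigree and layouts and shared
    by all models/traits fitted on it.
    """

    def __init__(
        self,
        records: pd.DataFrame,
        pedigree: Pedigree,
        layouts: dict,
    ):
        records = derive_traits(records) if "log_volume" not in records else records.copy()
        records["trial"] = records["trial"].astype(str)
        self.records = records
        self.pedigree = sort_pedigree(pedigree)
        self._kinship = None
        self.layouts = {
            str(t): (lay if isinstance(lay, TrialLayout) else TrialLayout(**lay))
            for t, lay in layouts.items()
        }
        self.maps: dict = {}
        self.complete_blocks: dict = {}
        self.incomplete_blocks: dict = {}
        self._covariates: dict = {}
        for trial, lay in self.layouts.items():
            sub = records[records["trial"] == trial]
            if sub.empty:
                raise ValueError(f"no records for declared trial {trial!r}")
            grid_records = sub.copy()
            grid_records["status"] = (
                grid_records["status"].map(_STATUS_MAP).fillna(grid_records["status"])
            )
            tmap = geometry.build_complete_grid(
                grid_records,
                lay.n_rows,
                lay.n_cols,
                trial_id=trial,
                column_direction=lay.column_direction,
            )
            self.maps[trial] = tmap
            self.complete_blocks[trial] = geometry.assign_complete_blocks(
                tmap, lay.row_tiers, lay.col_tiers
            )
            self.incomplete_blocks[trial] = geometry.assign_incomplete_blocks(
                tmap, lay.block_rows, lay.block_cols
            )

    @property
    def trials(self) -> list:
        return list(self.layouts)

    @property
    def kinship(self):
        """Numerator relationship matrix (built on first use)."""
        if self._kinship is None:
            self._kinship = build_A(self.pedigree, assume_sorted=True)
        return self._kinship

    def covariates(self, trial: str) -> pd.DataFrame:
        """Spatial covariate table (pc1-3 + competition) for one trial."""
        if trial not in self._covariates:
            table, explained = spatial.spatial_covariates(self.maps[trial])
            table.attrs["explained_fraction"] = explained
            self._covariates[trial] = table
        return self._covariates[trial]

    def family_connectivity(self, trials=None) -> bool:
        """True when the trial set is connected through shared families."""
        trials = list(trials or self.trials)
        fams = {
            t: set(self.records.loc[self.records["trial"] == t, "family"].dropna().astype(str))
            for t in trials
        }
        seen = {trials[0]}
        frontier = [trials[0]]
        while frontier:
            t = frontier.pop()
            for u in trials:
                if u not in seen and fams[t] & fams[u]:
                    seen.add(u)
                    frontier.append(u)
        return len(seen) == len(trials)


def _observation_subset(data: ProgenyTrialData, trait: str, trials) -> pd.DataFrame:
    col = TRAIT_COLUMNS[trait]
    rec = data.records
    sub = rec[rec["trial"].isin([str(t) for t in trials])]
    sub = sub[sub["family"].notna() & (sub["status"] != "filler")]
    if trait == "survival":
        sub = sub[sub[col].notna()]
    else:
        sub = sub[(sub["status"] == "live") & sub[col].notna()]
    return sub.reset_index(drop=True)


def _is_open_pollinated(ped: Pedigree, obs_ids: set) -> bool:
    """True when every observed tree is a non-parent offspring of a
    founder dam with unknown sire (the pure half-sib layout)."""
    parents = set(p for p in ped.dams + ped.sires if p is not None)
    info = {i: (d, s) for i, d, s in zip(ped.ids, ped.dams, ped.sires)}
    for tid in obs_ids:
        d, s = info[tid]
        if d is None or s is not None or tid in parents:
            return False
        dd, ds = info[d]
        if dd is not None or ds is not None:
            return False
    return True


class ProgenyTrialModel:
    """Individual-tree pedigree mixed model for one trait and model spec.

    Statsmodels-style entry point: construct from data, call
    :meth:`fit`.  The heavy lifting (REML, mixed-model equations) lives
    in :class:`arboreml.reml.PedigreeMixedModel`; this class assembles
    the design from the trial geometry, spatial covariates, pedigree and
    the declarative :class:`ModelSpec`.

    Parameters
    ----------
    data : ProgenyTrialData
    spec : ModelSpec or str
        Model specification or its name.
    trait : str
        ``height``, ``dbh``, ``volume`` (log scale) or ``survival``.
    trials : sequence, optional
        Trial subset (defaults to all trials in ``data``).
    shared_spatial : bool
        Share the AR1 parameters (sigma2_eps, rho_row, rho_col) across
        trials instead of estimating them per trial.
    competition_numeric : bool
        Enter the 0-4 competition index as a numeric covariate instead
        of a 5-level factor.
    """

    def __init__(
        self,
        data: ProgenyTrialData,
        spec,
        trait: str,
        trials=None,
        shared_spatial: bool = False,
        competition_numeric: bool = False,
    ):
        if isinstance(spec, str):
            trials_all = list(trials or data.trials)
            spec = build_model_spec(spec, single_site=len(trials_all) == 1)
        self.spec = spec
        self.trait = trait
        self.data = data
        self.trials = [str(t) for t in (trials or data.trials)]
        if trait not in TRAIT_COLUMNS:
            raise KeyError(f"unknown trait {trait!r}; expected {list(TRAIT_COLUMNS)}")
        obs = _observation_subset(data, trait, self.trials)
        if obs.empty:
            raise ValueError(f"no observations for trait {trait!r}")
        self.obs = obs
        self.trait_mean = float(obs[TRAIT_COLUMNS[trait]].mean())
        self._competition_numeric = competition_numeric
        self._shared_spatial = shared_spatial
        y, X, x_names, terms, residual = self._assemble()
        self._engine = PedigreeMixedModel(y, X, terms, residual, x_names=x_names)

    # -- design assembly -------------------------------------------------
    def _fixed_design(self) -> tuple[np.ndarray, list]:
        obs = self.obs
        cols: list[np.ndarray] = []
        names: list[str] = []
        trials = self.trials
        need_cov = any(
            t.startswith(("competition", "pc1-3")) for t in self.spec.fixed_terms
        )
        cov = None
        if need_cov:
            cov = pd.concat([self.data.covariates(t) for t in trials], ignore_index=True)
            obs = obs.merge(cov, on=["trial", "row", "col"], how="left", suffixes=("", "_cov"))
        for token in self.spec.fixed_terms:
            if token == "intercept":
                cols.append(np.ones(len(obs)))
                names.append("intercept")
            elif token == "trial":
                for t in trials[1:]:
                    cols.append((obs["trial"] == t).to_numpy(float))
                    names.append(f"trial[{t}]")
            elif token in ("x(trial)", "y(trial)"):
                coord = "row" if token.startswith("x") else "col"
                for t in trials:
                    mask = (obs["trial"] == t).to_numpy(float)
                    vals = obs[coord].to_numpy(float)
                    centred = vals - (vals[mask > 0].mean() if mask.any() else 0.0)
                    cols.append(mask * centred)
                    names.append(f"{token[0]}[{t}]")
            elif token == "competition(trial)":
                if self._competition_numeric:
                    for t in trials:
                        mask = (obs["trial"] == t).to_numpy(float)
                        cols.append(mask * obs["competition"].to_numpy(float))
                        names.append(f"competition[{t}]")
                else:
                    for t in trials:
                        mask = obs["trial"] == t
                        classes = sorted(obs.loc[mask, "competition"].dropna().unique())
                        for c in classes[1:]:
                            cols.append(
                                (mask & (obs["competition"] == c)).to_numpy(float)
                            )
                            names.append(f"competition[{t}][{int(c)}]")
            elif token == "pc1-3(trial)":
                for t in trials:
                    mask = (obs["trial"] == t).to_numpy(float)
                    for pc in ("pc1", "pc2", "pc3"):
                        cols.append(mask * obs[pc].to_numpy(float))
                        names.append(f"{pc}[{t}]")
            else:
                raise KeyError(f"unknown fixed term {token!r}")
        return np.column_stack(cols), names

    def _random_terms(self) -> list:
        obs = self.obs
        data = self.data
        terms: list[RandomTerm] = []
        for token in self.spec.random_terms:
            if token == "additive":
                terms.append(self._additive_term())
            elif token == "family_x_trial":
                labels = obs["family"].astype(str) + ":" + obs["trial"].astype(str)
                Z, levels = incidence(labels)
                terms.append(RandomTerm(name="family_x_trial", levels=levels, Z=Z))
            elif token == "rep(trial)":
                labels = obs["trial"].astype(str) + ":" + obs["rep"].astype(str)
                Z, levels = incidence(labels)
                terms.append(RandomTerm(name="rep_in_trial", levels=levels, Z=Z))
            elif token in ("subrow(trial)", "subcol(trial)", "rowblock(trial)", "colblock(trial)"):
                source = (
                    data.incomplete_blocks if token.startswith("sub") else data.complete_blocks
                )
                attr = "row_block" if "row" in token else "col_block"
                labels = [
                    getattr(source[t], attr)[r - 1, c - 1]
                    for t, r, c in zip(obs["trial"], obs["row"], obs["col"])
                ]
                Z, levels = incidence(labels)
                terms.append(RandomTerm(name=token.replace("(trial)", ""), levels=levels, Z=Z))
            elif token == "trial(series)":
                labels = obs["series"].astype(str) + ":" + obs["trial"].astype(str)
                Z, levels = incidence(labels)
                terms.append(RandomTerm(name="trial_in_series", levels=levels, Z=Z))
            elif token == "series":
                Z, levels = incidence(obs["series"])
                terms.append(RandomTerm(name="series", levels=levels, Z=Z))
            elif token == "provenance":
                if "provenance" not in obs or obs["provenance"].isna().all():
                    raise ValueError("RCBD model requires a provenance column")
                Z, levels = incidence(obs["provenance"])
                terms.append(RandomTerm(name="provenance", levels=levels, Z=Z))
            else:
                raise KeyError(f"unknown random term {token!r}")
        return terms

    def _additive_term(self) -> RandomTerm:
        obs = self.obs
        data = self.data
        ped = data.pedigree
        obs_ids = [str(v) for v in obs["tree_id"]]
        if _is_open_pollinated(ped, set(obs_ids)):
            F, fams = incidence(obs["family"])
            term = RandomTerm(
                name="additive",
                levels=fams,
                Z=F,
                diag_weight=0.75,
                U=0.5 * np.asarray(F.todense()),
            )
        else:
            kin = data.kinship
            idx = kin.index_of(obs_ids)
            G = kin.A[np.ix_(idx, idx)]
            term = RandomTerm(
                name="additive",
                levels=obs_ids,
                Z=sp.identity(len(obs), format="csr"),
                G=G,
            )

        def mme_factory():
            # deferred: the full-pedigree system is only needed for BLUPs
            kin = data.kinship
            Z_ind, _ = incidence(obs_ids, levels=list(ped.ids))
            return Z_ind, kin.a_inverse(ped), list(ped.ids)

        term.mme_factory = mme_factory
        return term

    def _residual_spec(self) -> ResidualSpec:
        kind = self.spec.residual
        if kind == "iid_simple":
            return ResidualSpec(kind=kind)
        grids = []
        for t in self.trials:
            lay = self.data.layouts[t]
            mask = (self.obs["trial"] == t).to_numpy()
            grids.append(
                TrialGrid(
                    trial_id=t,
                    n_rows=lay.n_rows,
                    n_cols=lay.n_cols,
                    obs_idx=np.flatnonzero(mask),
                    row_pos=self.obs.loc[mask, "row"].to_numpy(int) - 1,
                    col_pos=self.obs.loc[mask, "col"].to_numpy(int) - 1,
                )
            )
        return ResidualSpec(
            kind=kind, grids=grids, per_trial_spatial=not self._shared_spatial
        )

    def _assemble(self):
        y = self.obs[TRAIT_COLUMNS[self.trait]].to_numpy(float)
        X, x_names = self._fixed_design()
        terms = self._random_terms()
        residual = self._residual_spec()
        return y, X, x_names, terms, residual

    # -- public API -------------------------------------------------------
    @classmethod
    def from_dataframe(
        cls, records: pd.DataFrame, pedigree: Pedigree, layouts: dict, spec, trait: str, **kw
    ) -> "ProgenyTrialModel":
        """Convenience constructor building the shared dataset first."""
        return cls(ProgenyTrialData(records, pedigree, layouts), spec, trait, **kw)

    def fit(self, **kw) -> "ProgenyTrialResults":
        engine_results = self._engine.fit(**kw)
        return ProgenyTrialResults(self, engine_results)

    def loglike(self, theta) -> float:
        return self._engine.loglike(theta)

    @property
    def nobs(self) -> int:
        return self._engine.nobs

    @property
    def param_names(self) -> list:
        return self._engine.param_names


class ProgenyTrialResults:
    """Fitted progeny-trial model: REML estimates plus genetic parameters.

    Delegates the variance-parameter, criteria and BLUE/BLUP surface to
    the underlying :class:`~arboreml.reml.MixedModelResults` and adds
    heritability, type-B correlation, CVs, breeding values and
    accuracies.
    """

    def __init__(self, model: ProgenyTrialModel, engine_results: MixedModelResults):
        self.model = model
        self._results = engine_results
        self._genetic: GeneticParams | None = None

    def __getattr__(self, name):
        return getattr(self._results, name)

    @property
    def genetic_params(self) -> GeneticParams:
        if self._genetic is None:
            self._genetic = genetic_parameters(self._results, self.model.trait_mean)
        return self._genetic

    def breeding_values(self, parents_only: bool = False) -> pd.DataFrame:
        """Breeding values with PEV and accuracy for pedigree members."""
        bv = self._results.blup("additive")
        pev = self._results.pev("additive")
        kin = self.model.data.kinship
        ids = list(bv.index)
        f = kin.f[kin.index_of(ids)]
        s2a = float(self.theta["sigma2_additive"])
        acc = (
            accuracy(pev.to_numpy(), f, s2a)
            if s2a > 0
            else np.zeros(len(ids))
        )
        out = pd.DataFrame(
            {"id": ids, "breeding_value": bv.to_numpy(), "pev": pev.to_numpy(), "accuracy": acc}
        )
        if parents_only:
            ped = self.model.data.pedigree
            parents = set(p for p in ped.dams + ped.sires if p is not None)
            out = out[out["id"].isin(parents)].reset_index(drop=True)
        return out

    def summary(self) -> str:
        head = (
            f"Model: {self.model.spec.name}   trait: {self.model.trait}   "
            f"trials: {','.join(self.model.trials)}\n"
        )
        gp = self.genetic_params
        tail = (
            "\nGenetic parameters\n"
            f"  V_A={gp.sigma2_a:.4f}  V_AE={gp.sigma2_ae:.4f}  V_E={gp.sigma2_e:.4f}  "
            f"V_P={gp.sigma2_p:.4f}\n"
            f"  h2={gp.h2:.4f} (se {gp.h2_se:.4f})   r_B={gp.rb:.4f}\n"
            f"  CV_A={gp.cv_a:.2f}%  CV_P={gp.cv_p:.2f}%  CV_E={gp.cv_e:.2f}%"
        )
        return head + self._results.summary() + tail


@dataclass
class SuiteResult:
    """Results of a multi-model suite run for one dataset."""

    fits: dict = field(default_factory=dict)  # (trait, model) -> ProgenyTrialResults
    failures: dict = field(default_factory=dict)

    def criteria_table(self) -> pd.DataFrame:
        """AIC/BIC per trait and model with deltas against the
        complete-blocking benchmark (exactly zero for the benchmark)."""
        rows = []
        for (trait, model), res in self.fits.items():
            rows.append(
                {
                    "trait": trait,
                    "model": model,
                    "logL_R": res.llf,
                    "t": res.t,
                    "aic": res.aic,
                    "bic": res.bic,
                    "converged": res.converged,
                }
            )
        table = pd.DataFrame(rows)
        if table.empty:
            return table
        deltas = []
        for trait, grp in table.groupby("trait"):
            bench = grp[grp["model"] == BENCHMARK_MODEL]
            g = grp.copy()
            if len(bench):
                g["delta_aic"] = g["aic"] - float(bench["aic"].iloc[0])
                g["delta_bic"] = g["bic"] - float(bench["bic"].iloc[0])
            else:
                g["delta_aic"] = np.nan
                g["delta_bic"] = np.nan
            deltas.append(g)
        return pd.concat(deltas, ignore_index=True)

    def parameter_table(self) -> pd.DataFrame:
        """Variance components and heritabilities per trait x model
        (the shape of a published genetic-parameter table)."""
        rows = []
        for (trait, model), res in self.fits.items():
            gp = res.genetic_params
            rows.append(
                {
                    "trait": trait,
                    "model": model,
                    "V_A": gp.sigma2_a,
                    "V_AE": gp.sigma2_ae,
                    "V_E": gp.sigma2_e,
                    "V_P": gp.sigma2_p,
                    "h2": gp.h2,
                    "h2_se": gp.h2_se,
                    "r_B": gp.rb,
                    "cv_a": gp.cv_a,
                    "cv_p": gp.cv_p,
                    "converged": res.converged,
                }
            )
        return pd.DataFrame(rows)


def average_breeding_values(
    suite: SuiteResult, trait: str, parents_only: bool = True
) -> pd.DataFrame:
    """Breeding values averaged over every fitted model for one trait.

    The multi-model average is the default input for breeding-value vs
    provenance-coordinate analyses; any single model's table can be
    used instead via ``ProgenyTrialResults.breeding_values``.
    """
    tables = [
        res.breeding_values(parents_only=parents_only)
        for (t, _), res in suite.fits.items()
        if t == trait
    ]
    if not tables:
        raise ValueError(f"no fits for trait {trait!r}")
    stacked = pd.concat(tables)
    out = stacked.groupby("id", as_index=False).agg(
        breeding_value=("breeding_value", "mean"),
        pev=("pev", "mean"),
        accuracy=("accuracy", "mean"),
        n_models=("breeding_value", "size"),
    )
    return out


def run_met(
    data: ProgenyTrialData,
    models=None,
    traits=("height",),
    trials=None,
    shared_spatial: bool = False,
    fit_options: dict | None = None,
) -> SuiteResult:
    """Fit the requested model suite on pooled multi-trial data.

    Requires at least two trials connected through shared families.
    Non-convergence is recorded (and warned about) without aborting the
    suite.
    """
    trials = [str(t) for t in (trials or data.trials)]
    if len(trials) < 2:
        raise ValueError("MET analysis requires at least two trials")
    if not data.family_connectivity(trials):
        raise ValueError("no family connectivity between the requested trials")
    models = list(models or MODEL_NAMES)
    out = SuiteResult()
    for trait in traits:
        for name in models:
            spec = build_model_spec(name)
            try:
                model = ProgenyTrialModel(
                    data, spec, trait, trials=trials, shared_spatial=shared_spatial
                )
                res = model.fit(**(fit_options or {}))
                if not res.converged:
                    warnings.warn(f"{name}/{trait}: REML did not converge", stacklevel=2)
                out.fits[(trait, spec.name)] = res
            except (np.linalg.LinAlgError, ValueError) as err:
                warnings.warn(f"{name}/{trait} failed: {err}", stacklevel=2)
                out.failures[(trait, name)] = str(err)
    return out


def run_single_site(
    data: ProgenyTrialData,
    trial,
    models=None,
    traits=("height",),
    shared_spatial: bool = False,
    fit_options: dict | None = None,
) -> SuiteResult:
    """Single-site analyses: the multi-trial terms are dropped."""
    trial = str(trial)
    models = list(models or MODEL_NAMES)
    out = SuiteResult()
    for trait in traits:
        for name in models:
            spec = build_model_spec(name, single_site=True)
            try:
                model = ProgenyTrialModel(
                    data, spec, trait, trials=[trial], shared_spatial=shared_spatial
                )
                res = model.fit(**(fit_options or {}))
                if not res.converged:
                    warnings.warn(f"{name}/{trait}: REML did not converge", stacklevel=2)
                out.fits[(trait, spec.name)] = res
            except (np.linalg.LinAlgError, ValueError) as err:
                warnings.warn(f"{name}/{trait} failed: {err}", stacklevel=2)
                out.failures[(trait, name)] = str(err)
    return out
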