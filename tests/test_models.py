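import json
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from arboreml import (
    MODEL_NAMES,
    ProgenyTrialData,
    ProgenyTrialModel,
    build_model_spec,
    derive_traits,
    run_met,
    run_single_site,
    simulate,
)

FIXTURE = Path(__file__).parent / "data" / "model_suite_table.json"


class TestModelSpecs:
    def test_all_thirteen_match_transcribed_scheme(self):
        """The machine-readable model table equals the fixture
        transcribed from the published scheme, term by term."""
        table = json.loads(FIXTURE.read_text())
        table.pop("_comment")
        assert sorted(table) == sorted(MODEL_NAMES)
        for name, expected in table.items():
            assert build_model_spec(name).to_dict() == expected

    def test_aliases_resolve(self):
        for alias, target in [
            ("SUBBLOCKING", "SUBB"),
            ("SUBH", "SUBHETERO"),
            ("BLK", "BLOCKING"),
            ("BLKNNH", "BLKNNHETERO"),
        ]:
            assert build_model_spec(alias).name == target

    def test_unknown_name_lists_valid(self):
        with pytest.raises(KeyError, match="RCBD"):
            build_model_spec("SPLINES")

    def test_single_site_drops_multi_trial_terms(self):
        spec = build_model_spec("SUBNN", single_site=True)
        assert "family_x_trial" not in spec.random_terms
        assert "trial" not in spec.fixed_terms
        rcbd = build_model_spec("RCBD", single_site=True)
        assert "series" not in rcbd.random_terms

    def test_pca2_prose_variant(self):
        spec = build_model_spec("NNPCA2", pca2_simple_residual=True)
        assert spec.residual == "iid_simple"


class TestDeriveTraits:
    def _rec(self, ht, dbh):
        return pd.DataFrame(
            {"status": ["live"], "height_m": [ht], "dbh_cm": [dbh], "survival": [1.0]}
        )

    def test_volume_constant(self):
        out = derive_traits(self._rec(10.0, 10.0))
        assert out["volume_dm3"].iloc[0] == pytest.approx(26.18)

    def test_zero_dbh_log_floor(self):
        out = derive_traits(self._rec(5.0, 0.0))
        assert out["volume_dm3"].iloc[0] == 0.0
        assert out["log_volume"].iloc[0] == pytest.approx(np.log(0.1))

    def test_volume_quadratic_in_dbh(self):
        v1 = derive_traits(self._rec(7.0, 5.0))["volume_dm3"].iloc[0]
        v2 = derive_traits(self._rec(7.0, 10.0))["volume_dm3"].iloc[0]
        assert v2 == pytest.approx(4 * v1)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            derive_traits(self._rec(-1.0, 5.0))

    def test_dead_trees_lose_growth_keep_survival_zero(self):
        rec = pd.DataFrame(
            {"status": ["dead"], "height_m": [3.0], "dbh_cm": [2.0], "survival": [0.0]}
        )
        out = derive_traits(rec)
        assert np.isnan(out["height_m"].iloc[0])
        assert out["survival"].iloc[0] == 0.0


@pytest.fixture(scope="module")
def met_suite(small_data):
    return run_met(
        small_data,
        models=["SUBB", "BLOCKING", "RCBD"],
        traits=("height",),
        shared_spatial=True,
    )


class TestSuiteRuns:
    def test_benchmark_deltas_exactly_zero(self, met_suite):
        crit = met_suite.criteria_table()
        bench = crit[crit["model"] == "BLOCKING"]
        assert (bench["delta_aic"] == 0.0).all()
        assert (bench["delta_bic"] == 0.0).all()

    def test_all_requested_fits_present(self, met_suite):
        assert {m for _, m in met_suite.fits} == {"SUBB", "BLOCKING", "RCBD"}
        assert not met_suite.failures

    def test_parameter_table_shape(self, met_suite):
        tab = met_suite.parameter_table()
        assert set(tab.columns) >= {"V_A", "V_AE", "V_E", "V_P", "h2", "h2_se", "r_B"}
        assert np.allclose(tab["V_P"], tab[["V_A", "V_AE", "V_E"]].sum(axis=1))

    def test_trial_subset_bookkeeping(self, small_data):
        m_all = ProgenyTrialModel(small_data, "SUBB", "height", shared_spatial=True)
        m_one = ProgenyTrialModel(small_data, "SUBB", "height", trials=["A"])
        n_a = (m_all.obs["trial"] == "A").sum()
        assert m_one.nobs == n_a
        assert m_one.obs["family"].nunique() <= m_all.obs["family"].nunique()

    def test_connectivity_error(self, small_dataset):
        rec = small_dataset.records.copy()
        # sever the family overlap: disjoint family names per trial
        mask = rec["trial"] == "B"
        rec.loc[mask, "family"] = rec.loc[mask, "family"].apply(
            lambda f: None if f is None else f + "_X"
        )
        ped_frame = small_dataset.pedigree.to_frame()
        extra = ped_frame[ped_frame["dam"] == ""].copy()
        extra["id"] = extra["id"] + "_X"
        trees = rec.loc[mask & rec["family"].notna(), ["tree_id", "family"]]
        ped2 = pd.concat(
            [
                ped_frame[~ped_frame["id"].isin(trees["tree_id"])],
                extra,
                pd.DataFrame({"id": trees["tree_id"], "dam": trees["family"], "sire": ""}),
            ]
        )
        from arboreml.pedigree import Pedigree

        data = ProgenyTrialData(rec, Pedigree.from_frame(ped2), small_dataset.layouts)
        with pytest.raises(ValueError, match="connectivity"):
            run_met(data, models=["SUBB"], traits=("height",))

    def test_met_requires_two_trials(self, small_data):
        with pytest.raises(ValueError, match="two trials"):
            run_met(small_data, models=["SUBB"], trials=["A"])

    def test_rcbd_has_iid_residual_and_series_terms(self, met_suite):
        res = met_suite.fits[("height", "RCBD")]
        names = list(res.theta.index)
        assert "sigma2_trial_in_series" in names
        assert "sigma2_series" in names
        assert "sigma2_provenance" in names
        assert not any(n.startswith("sigma2_eps") for n in names)


class TestSingleSite:
    def test_single_site_has_no_interaction_term(self, small_data):
        suite = run_single_site(
            small_data, "A", models=["SUBB"], traits=("height",), shared_spatial=True
        )
        res = suite.fits[("height", "SUBB")]
        assert "sigma2_family_x_trial" not in res.theta.index

    def test_met_and_single_site_additive_agree_in_direction(self, small_config):
        """Across replicate simulations, MET and single-site additive
        variance estimates are positively correlated."""
        met_est, single_est = [], []
        for seed in range(5):
            ds = simulate(small_config, seed=100 + seed)
            data = ds.data()
            met = ProgenyTrialModel(data, "SUBB", "height", shared_spatial=True).fit()
            sing = run_single_site(
                data, data.trials[0], models=["SUBB"], traits=("height",),
                shared_spatial=True,
            ).fits[("height", "SUBB")]
            met_est.append(met.theta["sigma2_additive"])
            single_est.append(sing.theta["sigma2_additive"])
        assert np.corrcoef(met_est, single_est)[0, 1] > 0


class TestBreedingValueSurface:
    def test_average_breeding_values_over_models(self, met_suite):
        from arboreml import average_breeding_values

        avg = average_breeding_values(met_suite, "height")
        assert (avg["n_models"] == 3).all()
        one = met_suite.fits[("height", "SUBB")].breeding_values(parents_only=True)
        assert set(avg["id"]) >= set(one["id"])

    def test_parent_breeding_values_join_provenance(self, small_dataset, small_data):
        res = ProgenyTrialModel(small_data, "SUBB", "height", shared_spatial=True).fit()
        bv = res.breeding_values(parents_only=True)
        meta = small_dataset.dam_meta
        joined = bv.merge(meta, left_on="id", right_index=True)
        assert len(joined) == len(bv)
        assert joined["accuracy"].between(0, 1).all()
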