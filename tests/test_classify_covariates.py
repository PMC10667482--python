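import dataclasses
import warnings

import numpy as np
import pandas as pd
import pytest

import microconfig as mc
from microconfig.classify_covariates import DA_STANDIN_NOTE


@pytest.fixture(scope="module")
def two_group_cohort():
    cohort = mc.generate_cohort(mc.small_spec(), seed=41)
    rel = mc.to_relative(mc.prevalence_filter(cohort.abundance))
    return cohort, rel


class TestRfClassify:
    def test_separated_configurations_low_oob(self, two_group_cohort):
        cohort, rel = two_group_cohort
        report = mc.rf_classify(rel, cohort.metadata["group"], n_trees=300, seed=0)
        assert report.oob_error <= 0.10

    def test_seeded_reproducibility(self, two_group_cohort):
        cohort, rel = two_group_cohort
        a = mc.rf_classify(rel, cohort.metadata["group"], n_trees=200, seed=3)
        b = mc.rf_classify(rel, cohort.metadata["group"], n_trees=200, seed=3)
        assert a.oob_error == b.oob_error
        pd.testing.assert_frame_equal(a.importance, b.importance)

    def test_votes_sum_to_one(self, two_group_cohort):
        cohort, rel = two_group_cohort
        report = mc.rf_classify(rel, cohort.metadata["group"], n_trees=200, seed=1)
        assert np.allclose(report.votes.sum(axis=1), 1.0)

    def test_importance_direction_tracks_planted_shift(self, two_group_cohort):
        cohort, rel = two_group_cohort
        report = mc.rf_classify(rel, cohort.metadata["group"], n_trees=300,
                                seed=0, top_m=15)
        top = report.importance.set_index("genus_id")
        planted_cd = set(cohort.truth.cd_genera)
        cd_hits = [g for g in top.index if g in planted_cd]
        assert cd_hits, "top importance list contains planted CD genera"
        assert (top.loc[cd_hits, "direction"] == "CD").all()

    def test_held_out_group_fraction(self):
        cohort = mc.generate_cohort(mc.small_spec(n_hs=20), seed=42)
        rel = mc.to_relative(mc.prevalence_filter(cohort.abundance))
        groups = cohort.metadata["group"]
        labels = groups[groups.isin(["control", "CD"])]
        held = list(groups.index[groups == "HS"])
        report = mc.rf_classify(rel, labels, predict_on=held, n_trees=300, seed=0)
        truth = cohort.truth.configuration.loc[held]
        expected_cd = (truth == "cd_like").mean()
        assert report.predicted_fraction["CD"] == pytest.approx(expected_cd, abs=0.15)

    def test_single_class_rejected(self, two_group_cohort):
        cohort, rel = two_group_cohort
        labels = pd.Series("control", index=rel.data.index)
        with pytest.raises(ValueError, match="two classes"):
            mc.rf_classify(rel, labels)


class TestDifferentialAbundanceStandin:
    def test_planted_shift_detected_with_direction(self, two_group_cohort):
        cohort, rel = two_group_cohort
        filtered = mc.prevalence_filter(cohort.abundance)
        out = mc.differential_abundance_standin(filtered, cohort.metadata["group"])
        out = out.set_index("genus_id")
        cd_present = [g for g in cohort.truth.cd_genera if g in out.index]
        assert (out.loc[cd_present, "q"] < 0.05).mean() >= 0.9
        assert (out.loc[cd_present, "direction"] == "CD").all()
        assert (out["method"] == DA_STANDIN_NOTE).all()

    def test_null_cohort_controls_false_positives(self, small_null_cohort):
        filtered = mc.prevalence_filter(small_null_cohort.abundance)
        labels = small_null_cohort.metadata["group"]
        two = labels[labels.isin(["control", "CD"])]
        out = mc.differential_abundance_standin(
            filtered.restrict_samples(two.index), two)
        assert out["significant"].sum() <= 0.05 * len(out) + 2

    def test_output_header_flags_standin(self, tmp_path, two_group_cohort):
        cohort, rel = two_group_cohort
        filtered = mc.prevalence_filter(cohort.abundance)
        out = mc.differential_abundance_standin(filtered, cohort.metadata["group"])
        path = tmp_path / "da.tsv"
        mc.classify_covariates.write_da_results(out, path)
        assert "NOT ANCOMBC" in path.read_text().splitlines()[0]


class TestImportExternalDaResults:
    def test_maps_alias_columns(self, tmp_path):
        p = tmp_path / "ancombc.tsv"
        p.write_text("taxon\tlfc\tpval\tpadj\ngA\t1.2\t0.001\t0.01\n")
        out = mc.import_external_da_results(p)
        assert list(out.columns) == ["genus_id", "effect", "p", "q", "method"]
        assert out.loc[0, "genus_id"] == "gA"
        assert out.loc[0, "effect"] == pytest.approx(1.2)

    def test_canonical_columns_pass_through(self, tmp_path):
        p = tmp_path / "da.tsv"
        p.write_text("genus_id\teffect\tp\tq\ngB\t-0.5\t0.2\t0.4\n")
        out = mc.import_external_da_results(p)
        assert out.loc[0, "q"] == pytest.approx(0.4)

    def test_missing_column_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("genus_id\teffect\tp\ngA\t1\t0.1\n")
        with pytest.raises(ValueError, match="'q'"):
            mc.import_external_da_results(p)


def hs_cohort(seed, null=False):
    spec = dataclasses.replace(mc.CohortSpec(), n_control_patients=1,
                               n_control_samples=1, n_cd_patients=0,
                               n_cd_samples=0, n_hs=55)
    gen = mc.generate_null_cohort if null else mc.generate_cohort
    return gen(spec, seed=seed)


class TestCovariateLogistic:
    def test_planted_or4_exposure_recovered_within_2se(self):
        recovered = 0
        for seed in range(10):
            cohort = hs_cohort(seed)
            hs = cohort.metadata[cohort.metadata["group"] == "HS"]
            outcome = cohort.truth.configuration.loc[hs.index]
            try:
                report = mc.covariate_logistic(outcome, "antibiotics_last_year", hs)
            except (ValueError, RuntimeError):
                continue
            row = report.table.set_index("term").loc["antibiotics_last_year"]
            # the model codes y=1 for the alphabetically-second level ("normal"),
            # so the planted OR-4-towards-cd_like exposure has log-odds -ln(4)
            recovered += abs(row["estimate"] - (-np.log(4))) <= 2 * row["std_error"]
        assert recovered >= 8

    def test_low_prevalence_binary_exposure_rejected(self):
        cohort = hs_cohort(0)
        hs = cohort.metadata[cohort.metadata["group"] == "HS"].copy()
        hs["rare_drug"] = False
        hs.iloc[:3, hs.columns.get_loc("rare_drug")] = True
        outcome = cohort.truth.configuration.loc[hs.index]
        with pytest.raises(ValueError, match="prevalence"):
            mc.covariate_logistic(outcome, "rare_drug", hs)

    def test_small_effect_continuous_exposure_rejected(self, rng):
        cohort = hs_cohort(1)
        hs = cohort.metadata[cohort.metadata["group"] == "HS"].copy()
        hs["noise_item"] = rng.normal(size=len(hs))
        outcome = cohort.truth.configuration.loc[hs.index]
        with pytest.raises(ValueError, match="Cohen"):
            mc.covariate_logistic(outcome, "noise_item", hs)

    def test_perfect_separation_flagged_with_penalized_refit(self):
        cohort = hs_cohort(2)
        hs = cohort.metadata[cohort.metadata["group"] == "HS"].copy()
        outcome = cohort.truth.configuration.loc[hs.index]
        hs["oracle"] = (outcome == "cd_like")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = mc.covariate_logistic(outcome, "oracle", hs, adjusters=("age",))
        assert report.separation
        assert report.penalized is not None
        assert np.isfinite(report.penalized["oracle"])

    def test_screen_skips_failing_exposures(self):
        cohort = hs_cohort(3)
        hs = cohort.metadata[cohort.metadata["group"] == "HS"].copy()
        hs["rare"] = False
        outcome = cohort.truth.configuration.loc[hs.index]
        out = mc.screen_covariates(outcome, hs,
                                   ["antibiotics_last_year", "rare"])
        assert set(out["exposure"]) <= {"antibiotics_last_year"}


class TestTaxonCovariateCorrelations:
    def test_planted_coupling_masked_significant(self, rng):
        n = 80
        ids = [f"s{i}" for i in range(n)]
        taxa = pd.DataFrame(rng.random((n, 5)),
                            index=ids, columns=[f"g{j}" for j in range(5)])
        cov = pd.DataFrame({"coupled": taxa["g0"] + rng.normal(0, 0.2, n),
                            "noise": rng.normal(size=n)}, index=ids)
        table = mc.AbundanceTable(taxa)
        rho, q, mask = mc.taxon_covariate_correlations(table, cov, ["g0", "g1"])
        assert mask.loc["g0", "coupled"]
        assert rho.loc["g0", "coupled"] > 0.5

    def test_covariate_identical_to_taxon_is_rho_one(self, rng):
        n = 30
        ids = [f"s{i}" for i in range(n)]
        taxa = pd.DataFrame({"g0": rng.random(n)}, index=ids)
        cov = pd.DataFrame({"same": taxa["g0"]}, index=ids)
        rho, _, _ = mc.taxon_covariate_correlations(
            mc.AbundanceTable(taxa), cov, ["g0"])
        assert rho.loc["g0", "same"] == pytest.approx(1.0)

    def test_constant_covariate_dropped_with_warning(self, rng):
        n = 30
        ids = [f"s{i}" for i in range(n)]
        taxa = pd.DataFrame({"g0": rng.random(n)}, index=ids)
        cov = pd.DataFrame({"flat": np.ones(n), "ok": rng.normal(size=n)}, index=ids)
        with pytest.warns(UserWarning, match="flat"):
            rho, _, _ = mc.taxon_covariate_correlations(
                mc.AbundanceTable(taxa), cov, ["g0"])
        assert list(rho.columns) == ["ok"]
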