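import numpy as np
import pandas as pd
import pytest
from scipy import stats

import gxenull as gx
from conftest import make_analysis_cohort, ols_oracle


def _tiny_frame(n=12, seed=0):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "grs": rng.normal(10, 2, n),
            "case": np.r_[np.zeros(n // 2), np.ones(n - n // 2)].astype(int),
            "age": rng.uniform(40, 70, n),
            "sex": rng.integers(0, 2, n),
        }
    )
    df["bmi_int"] = 0.02 * df["grs"] + 0.1 * df["case"] + rng.normal(size=n)
    df["bmi_raw"] = 27 + 4.6 * df["bmi_int"]
    return df


class TestStratifiedAssociation:
    def test_matches_normal_equations_oracle(self):
        df = _tiny_frame(n=12, seed=1)
        spec = gx.ModelSpec(covariates=("age",))
        fits = gx.fit_stratified_association(df, spec)
        for level in (0, 1):
            sub = df[df["case"] == level]
            X = np.column_stack([np.ones(len(sub)), sub["grs"], sub["age"]])
            beta, se, _ = ols_oracle(X, sub["bmi_int"].to_numpy())
            assert fits[level].beta == pytest.approx(beta[1], rel=1e-8)
            assert fits[level].se == pytest.approx(se[1], rel=1e-8)
            assert fits[level].n == len(sub)

    def test_null_cohort_betas_near_zero(self):
        cohort = make_analysis_cohort(
            gx.SimConfig(n_individuals=8000, n_variants=10, weight_scale=0.0, seed=2)
        )
        fits = gx.fit_stratified_association(cohort, gx.ModelSpec(covariates=()))
        for level in (0, 1):
            assert abs(fits[level].beta) < 3 * fits[level].se

    def test_empty_stratum_raises(self):
        df = _tiny_frame()
        df["case"] = 0
        with pytest.raises(gx.EmptyGroupError):
            gx.fit_stratified_association(df, gx.ModelSpec(covariates=()))


class TestInteractionModel:
    def test_matches_oracle_including_keller_terms(self):
        df = _tiny_frame(n=40, seed=3)
        spec = gx.ModelSpec(covariates=("age", "sex"), keller=True)
        res = gx.fit_interaction_model(df, spec, with_strata=False)
        g = df["grs"].to_numpy()
        e = df["case"].to_numpy(float)
        X = np.column_stack(
            [
                np.ones(40), g, e, g * e,
                df["age"], df["sex"],
                df["age"] * e, df["sex"] * e,
                df["age"] * g, df["sex"] * g,
            ]
        )
        beta, se, dof = ols_oracle(X, df["bmi_int"].to_numpy())
        assert res.beta_int == pytest.approx(beta[3], rel=1e-8)
        assert res.se_int == pytest.approx(se[3], rel=1e-8)
        t = beta[3] / se[3]
        assert res.p_int == pytest.approx(2 * stats.t.sf(abs(t), dof), rel=1e-8)

    def test_keller_equals_base_when_no_covariates(self):
        df = _tiny_frame(n=30, seed=4)
        base = gx.fit_interaction_model(
            df, gx.ModelSpec(covariates=()), with_strata=False
        )
        keller = gx.fit_interaction_model(
            df, gx.ModelSpec(covariates=(), keller=True), with_strata=False
        )
        assert base.beta_int == pytest.approx(keller.beta_int, rel=1e-12)

    def test_keller_agrees_with_base_under_independent_covariates(self):
        # null interaction, covariates independent of G and E: the Keller
        # fit should track the base fit to well within sampling noise
        diffs = []
        for seed in range(30):
            cohort = make_analysis_cohort(
                gx.SimConfig(
                    n_individuals=3000,
                    n_variants=10,
                    exposure_bmi_shift=0.0,
                    exposure_bmi_scale=1.0,
                    seed=100 + seed,
                )
            )
            spec = gx.ModelSpec(covariates=("age", "sex", "tdi"))
            base = gx.fit_interaction_model(cohort, spec, with_strata=False)
            kel = gx.fit_interaction_model(
                cohort,
                gx.ModelSpec(covariates=("age", "sex", "tdi"), keller=True),
                with_strata=False,
            )
            diffs.append((kel.beta_int - base.beta_int) / base.se_int)
        assert abs(np.mean(diffs)) < 0.5

    def test_constant_exposure_rejected(self):
        df = _tiny_frame()
        df["case"] = 1
        with pytest.raises(gx.InvalidSpecError):
            gx.fit_interaction_model(df, gx.ModelSpec(covariates=()))

    def test_collinear_design_names_offender(self):
        df = _tiny_frame(n=30, seed=5)
        df["age_copy"] = df["age"]
        with pytest.raises(gx.CollinearityError, match="age_copy"):
            gx.fit_interaction_model(
                df, gx.ModelSpec(covariates=("age", "age_copy"))
            )

    def test_categorical_covariate_uses_most_frequent_reference(self):
        df = _tiny_frame(n=60, seed=6)
        df["centre"] = (["C1", "C1", "C1", "C2", "C2", "C3"] * 10)
        res = gx.fit_interaction_model(
            df, gx.ModelSpec(covariates=("centre",)), with_strata=False
        )
        assert "centre[C2]" in res.params.index
        assert "centre[C1]" not in res.params.index  # reference level

    def test_severity_interaction_term_via_extra_interactions(self):
        cohort = make_analysis_cohort(gx.SimConfig(n_individuals=4000, seed=7))
        cases = cohort[cohort["case"] == 1].copy()
        cases["severity_f"] = cases["severity"].astype(float)
        spec = gx.ModelSpec(
            exposure="treated",
            covariates=("age", "sex"),
            extra_interactions=("severity_f",),
        )
        res = gx.fit_interaction_model(cases, spec, with_strata=False)
        assert "G:severity_f" in res.params.index
        assert np.isfinite(res.p_int)


class TestDecileContrast:
    def test_constant_shift_recovered_exactly(self):
        rng = np.random.default_rng(8)
        n = 400
        df = pd.DataFrame(
            {
                "grs": rng.normal(10, 2, n),
                "case": np.tile([0, 1], n // 2),
                "bmi_raw": rng.normal(27, 4, n),
            }
        )
        df["bmi_raw"] += 1.0 * df["case"]  # cases exactly +1 kg/m^2 everywhere
        deciles = gx.assign_deciles(df["grs"]).astype(float)
        out = gx.decile_contrast(df, deciles, gx.ModelSpec(covariates=()), adjust=False)
        # within each decile the exposure coefficient is the mean difference
        for label in ("bottom", "top"):
            d = {"bottom": 1, "top": 10}[label]
            sub = df[deciles == d]
            expected = (
                sub.loc[sub["case"] == 1, "bmi_raw"].mean()
                - sub.loc[sub["case"] == 0, "bmi_raw"].mean()
            )
            assert out[label][0] == pytest.approx(expected, rel=1e-10)

    def test_identical_distributions_give_null_contrasts(self):
        cohort = make_analysis_cohort(
            gx.SimConfig(
                n_individuals=20000,
                exposure_bmi_shift=0.0,
                exposure_bmi_scale=1.0,
                seed=9,
            )
        )
        out = gx.decile_contrast(
            cohort, cohort["grs_decile"].astype(float), gx.ModelSpec(covariates=())
        )
        for label in ("bottom", "top"):
            beta, se = out[label]
            assert abs(beta) < 3 * se

    def test_planted_interaction_widens_top_decile_gap(self):
        wins = 0
        trials = 30
        for seed in range(trials):
            cohort = make_analysis_cohort(
                gx.SimConfig(
                    n_individuals=8000,
                    n_variants=20,
                    true_interaction=0.05,
                    seed=200 + seed,
                )
            )
            out = gx.decile_contrast(
                cohort, cohort["grs_decile"].astype(float), gx.ModelSpec(covariates=())
            )
            wins += out["top"][0] > out["bottom"][0]
        assert wins >= int(0.9 * trials)

    def test_empty_cell_raises(self):
        df = _tiny_frame(n=40, seed=10)
        deciles = gx.assign_deciles(df["grs"]).astype(float)
        df.loc[deciles == 1, "case"] = 0  # no cases in bottom decile
        with pytest.raises(gx.EmptyCellError):
            gx.decile_contrast(df, deciles, gx.ModelSpec(covariates=()), adjust=False)


class TestPerSnpScan:
    def test_one_row_per_variant_and_bonferroni_threshold(self, small_cohort):
        bundle = gx.generate_cohort(gx.SimConfig(n_individuals=2000, n_variants=15, seed=5))
        w, d = gx.recode_to_increasing_allele(bundle.weights, bundle.dosages)
        scan = gx.per_snp_interaction_scan(
            d, small_cohort, gx.ModelSpec(covariates=("age",))
        )
        assert len(scan) == 15
        assert scan["bonferroni_threshold"].iloc[0] == pytest.approx(0.05 / 15)

    def test_monomorphic_variant_skipped(self, small_cohort):
        bundle = gx.generate_cohort(gx.SimConfig(n_individuals=2000, n_variants=15, seed=5))
        w, d = gx.recode_to_increasing_allele(bundle.weights, bundle.dosages)
        d = d.copy()
        d[d.columns[0]] = 1.0
        scan = gx.per_snp_interaction_scan(
            d, small_cohort, gx.ModelSpec(covariates=())
        )
        assert bool(scan.loc[scan["variant_id"] == d.columns[0], "skipped"].iloc[0])
        assert scan["bonferroni_threshold"].iloc[0] == pytest.approx(0.05 / 14)

    def test_planted_single_variant_interaction_is_flagged(self):
        hits, false_hits = 0, 0
        trials = 10
        for seed in range(trials):
            cfg = gx.SimConfig(
                n_individuals=20000,
                n_variants=8,
                exposure_bmi_shift=0.0,
                exposure_bmi_scale=1.0,
                seed=300 + seed,
            )
            bundle = gx.generate_cohort(cfg)
            phen = bundle.phenotypes.copy()
            target = bundle.dosages.columns[0]
            dose = bundle.dosages[target]
            # plant a strong single-variant interaction among cases
            phen["bmi_raw"] = phen["bmi_raw"] + 0.2 * cfg.bmi_sd * (
                dose - dose.mean()
            ) * phen["case"]
            cohort = gx.prepare_cohort(phen)
            scan = gx.per_snp_interaction_scan(
                bundle.dosages, cohort, gx.ModelSpec(covariates=())
            )
            flagged = set(scan.loc[scan["bonferroni_sig"], "variant_id"])
            hits += target in flagged
            false_hits += len(flagged - {target})
        assert hits >= 9
        assert false_hits <= 2


class TestUnitConversion:
    def test_zero_beta_zero_kg(self):
        assert gx.beta_to_weight_change(0.0, 10, 1.73, 4.6) == 0.0

    def test_height_squared_arithmetic(self):
        # 1 kg/m^2 at 1.73 m is 2.9929 kg
        assert gx.beta_to_weight_change(1.0, 1, 1.73, 1.0) == pytest.approx(2.9929)

    def test_ten_allele_worked_example(self):
        kg = gx.beta_to_weight_change(0.0255, 10, 1.73, 4.6)
        assert kg == pytest.approx(3.51, abs=0.005)

    def test_invalid_inputs_raise(self):
        with pytest.raises(gx.InvalidInputError):
            gx.beta_to_weight_change(0.1, 10, 0.0, 4.6)
        with pytest.raises(gx.InvalidInputError):
            gx.beta_to_weight_change(0.1, 10, 1.73, -1.0)

    def test_bonferroni_arithmetic(self):
        assert gx.bonferroni_threshold(73) == pytest.approx(6.849315e-4, rel=1e-6)
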