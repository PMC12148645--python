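"""z-normalization, design construction, FDR, effect matrices."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ufiber import (
    SimDesign,
    bh_fdr,
    build_design,
    compare_saf_lr,
    fit_all_bundles,
    fit_ticv_model,
    percent_change_table,
    relative_percent_change,
    sex_specific_slopes,
    simulate_cohort,
    z_transform,
)
from conftest import oracle_bh_stepup


class TestZTransform:
    def test_sample_sd_convention(self):
        assert np.allclose(z_transform([1, 2, 3]), [-1, 0, 1])

    def test_output_standardized(self):
        rng = np.random.default_rng(0)
        z = z_transform(rng.normal(3, 7, 200))
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_idempotence(self, seed):
        x = np.random.default_rng(seed).normal(5, 2, 50)
        assert np.max(np.abs(z_transform(z_transform(x)) - z_transform(x))) < 1e-12

    def test_zero_variance_names_column(self):
        with pytest.raises(ValueError, match="TICV"):
            z_transform(np.ones(10), name="TICV")


class TestBuildDesign:
    def _cohort(self, sex):
        n = len(sex)
        return pd.DataFrame(
            {
                "participant_id": [f"s{i}" for i in range(n)],
                "Age": np.linspace(6, 21, n),
                "Sex": sex,
                "TICV": np.linspace(1300, 1600, n),
            }
        )

    def test_all_female_zero_sex_columns(self):
        X = build_design(self._cohort([0] * 10))
        assert np.all(X[:, 2] == 0) and np.all(X[:, 3] == 0)

    def test_interaction_is_age_for_males(self):
        cohort = self._cohort([0, 1, 0, 1])
        cohort.loc[1, "Age"] = 10.0
        X = build_design(cohort)
        assert X[1, 3] == 10.0
        assert X[0, 3] == 0.0

    def test_single_sex_cohort_is_rank_deficient(self):
        X = build_design(self._cohort([1] * 10))
        assert np.linalg.matrix_rank(X) < X.shape[1]

    def test_missing_covariate_lists_participants(self):
        cohort = self._cohort([0, 1, 0, 1])
        cohort.loc[2, "TICV"] = np.nan
        with pytest.raises(ValueError, match="s2"):
            build_design(cohort)

    def test_bad_sex_coding_rejected(self):
        cohort = self._cohort([0, 1, 2, 1])
        with pytest.raises(ValueError, match="Sex"):
            build_design(cohort)


class TestBHFDR:
    def test_all_ones_rejects_nothing(self):
        _, reject = bh_fdr(np.ones(10))
        assert not reject.any()

    def test_single_small_p_rejected(self):
        q, reject = bh_fdr(np.array([0.04]))
        assert reject[0] and q[0] == pytest.approx(0.04)

    def test_stepup_enumeration_example(self):
        # largest i with p_(i) <= i*0.05/4 is 4, so everything is rejected
        _, reject = bh_fdr(np.array([0.01, 0.02, 0.03, 0.04]))
        assert reject.all()

    @pytest.mark.parametrize("trial_block", range(10))
    def test_matches_brute_force_stepup_oracle(self, trial_block):
        rng = np.random.default_rng(trial_block)
        for _ in range(100):
            m = rng.integers(1, 13)
            p = rng.random(m) ** rng.uniform(0.5, 3.0)
            q, reject = bh_fdr(p)
            q_oracle, reject_oracle = oracle_bh_stepup(p)
            assert np.allclose(q, q_oracle, atol=1e-12)
            assert np.array_equal(reject, reject_oracle)

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr(np.array([0.1, 1.2]))


class TestPercentChange:
    def test_arithmetic(self):
        assert relative_percent_change(-0.002, 0.4) == pytest.approx(-0.5)

    def test_zero_slope(self):
        assert relative_percent_change(0.0, 0.3) == 0.0

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            relative_percent_change(0.1, 0.0)

    def test_zero_noise_cohort_matches_generator(self, clean_cohort):
        cohort, features, echo = clean_cohort
        table = percent_change_table(features, cohort)
        row = table[
            (table.pathway == "AF") & (table.tier == "SAF") & (table.feature == "FA")
        ].iloc[0]
        beta1 = echo.betas[0, 0, 0, 1]
        saf_fa = features[
            (features.pathway == "AF") & (features.tier == "SAF") & (features.feature == "FA")
        ]["value"]
        expected = 100.0 * beta1 / saf_fa.mean()
        assert row.pct_change_per_year == pytest.approx(expected, rel=1e-9)


class TestCodingContract:
    def test_male_slope_from_printed_coefficients(self):
        """Sex coded 0=F/1=M: female slope is beta_age, male adds the
        interaction; -0.04 + 0.07 = 0.03 SD/year."""
        female, male = sex_specific_slopes(-0.04, 0.07)
        assert female == -0.04
        assert male == pytest.approx(0.03)

    def test_ticv_submodel_recovers_generative_slopes(self):
        cohort, _, _ = simulate_cohort(SimDesign(n_participants=5000, seed=4))
        fit = fit_ticv_model(cohort)
        # generator drives raw TICV with -0.04 and +0.07 SD/yr before the
        # final z-scaling, so standardized estimates keep sign and ratio
        assert fit.beta_age < 0 < fit.beta_agexsex
        assert fit.male_age_slope == pytest.approx(fit.beta_age + fit.beta_agexsex)
        assert fit.male_age_slope > 0


class TestFitAllBundles:
    def test_zero_noise_recovers_design_betas_exactly(self, clean_cohort):
        cohort, features, echo = clean_cohort
        res = fit_all_bundles(features, cohort, standardize=False)
        for p_idx, pathway in enumerate(echo.pathways):
            for t_idx, tier in enumerate(("SAF", "LR")):
                for f_idx, feature in enumerate(("FA", "MD", "AD", "RD", "ICVF", "ISOVF", "ODI")):
                    cell = res[
                        (res.pathway == pathway) & (res.tier == tier) & (res.feature == feature)
                    ].set_index("term")
                    truth = echo.betas[p_idx, t_idx, f_idx]
                    est = cell.loc[["intercept", "age", "sex", "interaction", "ticv"], "beta"]
                    assert np.allclose(est.to_numpy(), truth, atol=1e-9)

    def test_null_design_fdr_rejection_rate(self):
        """All beta = 0: FDR keeps the rejection fraction near its level."""
        betas = np.zeros((9, 2, 7, 5))
        fractions = []
        for seed in range(20):
            design = SimDesign(
                n_participants=150,
                pathways=tuple(f"P{i}" for i in range(9)),
                betas=betas,
                noise_sd=1.0,
                seed=seed,
            )
            cohort, features, _ = simulate_cohort(design)
            res = fit_all_bundles(features, cohort)
            sub = res[res.term.isin(["age", "sex", "interaction"])]
            fractions.append(sub["significant"].mean())
        assert np.mean(fractions) <= 0.05

    def test_strong_effects_detected(self):
        """Age slopes well above the noise floor are flagged across cells."""
        betas = np.zeros((3, 2, 7, 5))
        betas[:, :, :, 1] = 0.06  # strong age effect, every feature
        design = SimDesign(
            n_participants=616,
            pathways=("AF", "CST", "CC"),
            betas=betas,
            noise_sd=1.0,
            seed=17,
        )
        cohort, features, _ = simulate_cohort(design)
        res = fit_all_bundles(features, cohort)
        age = res[res.term == "age"]
        assert age["significant"].mean() >= 0.95

    def test_failed_cell_marked_without_aborting(self, clean_cohort):
        cohort, features, _ = clean_cohort
        broken = features.copy()
        # constant column cannot be z-scored -> cell fails, batch survives
        sel = (broken.pathway == "AF") & (broken.tier == "SAF") & (broken.feature == "ODI")
        broken.loc[sel, "value"] = 1.0
        res = fit_all_bundles(broken, cohort)
        failed = res[res.failed]
        assert set(failed.feature) == {"ODI"}
        assert len(res[~res.failed]) > 0

    def test_ticv_interaction_screen_runs(self, noisy_cohort):
        cohort, features, _ = noisy_cohort
        small = features[features.pathway == "AF"]
        res = fit_all_bundles(small, cohort, screen_ticv_interactions=True)
        assert not res.failed.any()


class TestCompareSAFLR:
    def test_low_noise_tier_difference_recovered(self):
        design = SimDesign(
            n_participants=400, pathways=("AF", "CST"), noise_sd=0.05, seed=21
        )
        cohort, features, _ = simulate_cohort(design)
        res = fit_all_bundles(features, cohort, standardize=False)
        comp = compare_saf_lr(res, term="age")
        # default betas give LR a +0.02 larger FA age slope than SAF
        fa = comp[(comp.pathway == "AF") & (comp.feature == "FA")].iloc[0]
        assert fa.beta_lr - fa.beta_saf == pytest.approx(0.02, abs=0.005)
        assert fa.significant

    def test_detects_designed_tier_difference(self, noisy_cohort):
        cohort, features, _ = noisy_cohort
        res = fit_all_bundles(features, cohort)
        comp = compare_saf_lr(res, term="age")
        assert {"t", "p", "q", "significant"} <= set(comp.columns)
        assert len(comp) == 3 * 7
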