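"""Partial correlations, Fisher z, and SAF-LR coupling specificity."""

import numpy as np
import pandas as pd
import pytest

from ufiber import (
    SimDesign,
    fisher_z,
    inter_feature_matrices,
    partial_correlation,
    run_specificity,
    simulate_cohort,
    specificity_ztest,
)
from ufiber.stats import FEATURES


class TestPartialCorrelation:
    def test_constant_covariates_reduce_to_pearson(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=100), rng.normal(size=100)
        res = partial_correlation(x, y, np.ones((100, 1)))
        assert res.r == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-12)

    def test_perfect_dependence_clipped_to_one(self):
        rng = np.random.default_rng(1)
        cov = rng.normal(size=(50, 3))
        x = rng.normal(size=50)
        y = x + cov @ np.array([1.0, -2.0, 0.5])
        res = partial_correlation(x, y, cov)
        assert res.r == pytest.approx(1.0)
        assert res.p == 0.0

    def test_matches_precision_matrix_oracle(self):
        """Trivariate Gaussian: r_xy.z = -Omega_xy / sqrt(Omega_xx Omega_yy)."""
        rng = np.random.default_rng(2)
        cov = np.array([[1.0, 0.5, 0.3], [0.5, 1.0, 0.4], [0.3, 0.4, 1.0]])
        data = rng.multivariate_normal(np.zeros(3), cov, size=2000)
        omega = np.linalg.inv(cov)
        oracle = -omega[0, 1] / np.sqrt(omega[0, 0] * omega[1, 1])
        res = partial_correlation(data[:, 0], data[:, 1], data[:, 2:])
        assert res.r == pytest.approx(oracle, abs=0.02)

    def test_pingouin_cross_check(self):
        import pingouin as pg

        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(size=(200, 4)), columns=["x", "y", "c1", "c2"])
        ours = partial_correlation(df.x, df.y, df[["c1", "c2"]].to_numpy())
        ref = pg.partial_corr(df, x="x", y="y", covar=["c1", "c2"])
        pcol = "p_val" if "p_val" in ref.columns else "p-val"
        assert ours.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert ours.p == pytest.approx(float(ref[pcol].iloc[0]), abs=1e-10)

    def test_converges_to_pearson_without_covariate_effect(self):
        rng = np.random.default_rng(4)
        n = 5000
        x, y = rng.normal(size=n), rng.normal(size=n)
        y = 0.4 * x + y
        cov = rng.normal(size=(n, 3))  # independent of x and y
        res = partial_correlation(x, y, cov)
        assert abs(res.r - np.corrcoef(x, y)[0, 1]) < 0.01

    def test_zero_residual_variance_rejected(self):
        cov = np.arange(30.0).reshape(-1, 1)
        with pytest.raises(ValueError, match="residual"):
            partial_correlation(cov.ravel() * 2, np.random.default_rng(0).normal(size=30), cov)


class TestFisherZ:
    def test_zero_maps_to_zero(self):
        assert fisher_z(0.0) == 0.0

    def test_odd_function(self):
        for r in (0.1, 0.5, 0.9, 0.999):
            assert fisher_z(-r) == -fisher_z(r)

    def test_closed_form_value(self):
        assert fisher_z(0.5) == pytest.approx(0.5493061, abs=1e-7)

    def test_tanh_roundtrip(self):
        for z in np.linspace(-4.9, 4.9, 23):
            assert fisher_z(np.tanh(z)) == pytest.approx(z, abs=1e-12)

    def test_unit_r_clipped_finite(self):
        assert np.isfinite(fisher_z(1.0))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fisher_z(1.5)


class TestSpecificityZTest:
    def test_equal_means_give_half_p(self):
        Z, p = specificity_ztest(0.3, [0.2, 0.4], N=100)
        assert Z == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(0.5)

    def test_se_scaling_at_n616(self):
        Z, _ = specificity_ztest(1.0 / np.sqrt(610), [0.0], N=616, k=3)
        assert Z == pytest.approx(1.0, abs=1e-12)

    def test_normal_quantile(self):
        _, p = specificity_ztest(1.6448536 / np.sqrt(610), [0.0], N=616)
        assert p == pytest.approx(0.05, abs=1e-6)

    def test_monotone_in_z_assoc(self):
        zs = [specificity_ztest(z, [0.1, 0.2], N=200)[0] for z in (0.0, 0.2, 0.5, 1.0)]
        assert all(a < b for a, b in zip(zs, zs[1:]))

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            specificity_ztest(0.5, [0.1], N=6)

    def test_empty_comparison_rejected(self):
        with pytest.raises(ValueError):
            specificity_ztest(0.5, [], N=100)


class TestInterFeatureMatrices:
    def test_within_tier_diagonals_are_unity(self, noisy_cohort):
        cohort, features, _ = noisy_cohort
        mats = inter_feature_matrices(features, cohort, "AF")
        assert np.allclose(np.diag(mats.saf_saf), 1.0)
        assert np.allclose(np.diag(mats.lr_lr), 1.0)
        assert np.allclose(mats.saf_saf, mats.saf_saf.T)

    def test_duplicated_tiers_give_unit_cross_diagonal(self):
        cohort, features, _ = simulate_cohort(
            SimDesign(n_participants=80, pathways=("AF", "CST", "CC"), seed=5)
        )
        dup = features.copy()
        # make the LR tier an exact copy of the SAF tier
        saf = dup[dup.tier == "SAF"].copy()
        lr = saf.copy()
        lr["tier"] = "LR"
        dup = pd.concat([saf, lr], ignore_index=True)
        mats = inter_feature_matrices(dup, cohort, "AF")
        assert np.allclose(np.diag(mats.saf_lr), 1.0)

    def test_recovers_design_feature_correlation(self):
        """With couplings off, estimated off-diagonals track the design."""
        design = SimDesign(n_participants=2000, pathways=("AF", "CST", "CC"), seed=6)
        cohort, features, echo = simulate_cohort(design)
        mats = inter_feature_matrices(features, cohort, "AF")
        est = mats.saf_saf.to_numpy()
        truth = echo.feature_correlation
        iu = np.triu_indices(7, k=1)
        assert np.mean(np.abs(est[iu] - truth[iu])) <= 0.05

    def test_missing_feature_column_rejected(self, noisy_cohort):
        cohort, features, _ = noisy_cohort
        incomplete = features[features.feature != "ODI"]
        with pytest.raises(ValueError, match="missing"):
            inter_feature_matrices(incomplete, cohort, "AF")


def _manual_specificity_oracle(features, cohort, feature):
    """Spreadsheet-style recomputation: residualize, correlate, atanh, Z."""
    from ufiber.stats import _pivot_features, z_transform

    wide = _pivot_features(features).loc[cohort["participant_id"].to_numpy()]
    C = np.column_stack(
        [
            np.ones(len(cohort)),
            cohort.Age.to_numpy(float),
            cohort.Sex.to_numpy(float),
            z_transform(cohort.TICV.to_numpy()),
        ]
    )
    pathways = sorted({p for (p, t, f) in wide.columns})

    def resid(col):
        y = wide[col].to_numpy(float)
        return y - C @ np.linalg.lstsq(C, y, rcond=None)[0]

    def z(col_a, col_b):
        ra, rb = resid(col_a), resid(col_b)
        r = float(np.corrcoef(ra, rb)[0, 1])
        return np.arctanh(np.clip(r, -(1 - 1e-15), 1 - 1e-15))

    N = len(cohort)
    rows = {}
    for lr_i in pathways:
        z_assoc = z((lr_i, "LR", feature), (lr_i, "SAF", feature))
        others_saf = [z((lr_i, "LR", feature), (p, "SAF", feature)) for p in pathways if p != lr_i]
        others_lr = [z((lr_i, "LR", feature), (p, "LR", feature)) for p in pathways if p != lr_i]
        rows[(lr_i, "saf")] = (z_assoc - np.mean(others_saf)) * np.sqrt(N - 6)
        rows[(lr_i, "lr")] = (z_assoc - np.mean(others_lr)) * np.sqrt(N - 6)
    return rows


class TestRunSpecificity:
    def test_matches_manual_oracle_on_small_table(self):
        design = SimDesign(
            n_participants=10,
            pathways=("A", "B", "C"),
            coupling_assoc=0.5,
            coupling_nonassoc=0.1,
            seed=9,
        )
        cohort, features, _ = simulate_cohort(design)
        out = run_specificity(features, cohort).set_index(["pathway", "hypothesis", "feature"])
        oracle = _manual_specificity_oracle(features, cohort, "FA")
        for (pathway, hyp), z_expected in oracle.items():
            got = out.loc[(pathway, hyp, "FA"), "Z"]
            assert got == pytest.approx(z_expected, abs=1e-10)

    def test_needs_three_pathways(self):
        design = SimDesign(n_participants=30, pathways=("A", "B"), seed=0)
        cohort, features, _ = simulate_cohort(design)
        with pytest.raises(ValueError, match="3 pathways"):
            run_specificity(features, cohort)

    def test_missing_partner_marked(self, noisy_cohort):
        cohort, features, _ = noisy_cohort
        pairing = {"AF": "AF", "CST": "CST", "CC": "nonexistent"}
        out = run_specificity(features, cohort, pairing=pairing)
        assert out[(out.pathway == "CC")]["missing"].all()
        assert not out[(out.pathway == "AF")]["missing"].any()

    def test_exchangeable_null_controls_rejections(self):
        """coupling_assoc == coupling_nonassoc: no pair is special."""
        fractions = []
        for seed in range(20):
            design = SimDesign(
                n_participants=616,
                pathways=tuple(f"P{i}" for i in range(6)),
                coupling_assoc=0.4,
                coupling_nonassoc=0.4,
                seed=100 + seed,
            )
            cohort, features, _ = simulate_cohort(design)
            out = run_specificity(features, cohort)
            fractions.append(out["significant"].mean())
        assert np.mean(fractions) <= 0.05

    def test_strong_coupling_gives_high_h1_power(self):
        design = SimDesign(
            n_participants=616,
            pathways=tuple(f"P{i}" for i in range(6)),
            coupling_assoc=0.8,
            coupling_nonassoc=0.2,
            seed=200,
        )
        cohort, features, _ = simulate_cohort(design)
        out = run_specificity(features, cohort)
        h1 = out[out.hypothesis == "saf"]
        assert h1["significant"].mean() >= 0.9

    def test_fdr_families_are_feature_by_hypothesis(self, noisy_cohort):
        """Decisions match a per-family brute-force recomputation."""
        from conftest import oracle_bh_stepup

        cohort, features, _ = noisy_cohort
        out = run_specificity(features, cohort)
        for (feature, hyp), sub in out.groupby(["feature", "hypothesis"]):
            ok = sub[~sub.missing.astype(bool)]
            q, reject = oracle_bh_stepup(ok["p_one_tailed"].to_numpy())
            assert np.array_equal(ok["significant"].to_numpy(), reject)
            assert np.allclose(ok["q"].to_numpy(dtype=float), q)


class TestCouplingConstruction:
    def test_associated_pairs_more_correlated(self):
        """a > c makes associated SAF-LR pairs beat non-associated ones."""
        gaps = []
        for seed in range(20):
            design = SimDesign(
                n_participants=2000,
                pathways=("A", "B", "C"),
                coupling_assoc=0.7,
                coupling_nonassoc=0.2,
                seed=seed,
            )
            cohort, features, _ = simulate_cohort(design)
            wide = features.pivot_table(
                index="participant_id", columns=["pathway", "tier", "feature"], values="value"
            )
            assoc = np.corrcoef(wide[("A", "SAF", "FA")], wide[("A", "LR", "FA")])[0, 1]
            nonassoc = np.corrcoef(wide[("A", "LR", "FA")], wide[("B", "SAF", "FA")])[0, 1]
            gaps.append(assoc - nonassoc)
        assert all(g > 0 for g in gaps)
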