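"""Standardized-beta models, covariate rules, partial Spearman, interactions,
longitudinal linear probability models."""

import numpy as np
import pandas as pd
import pytest

from omiclocks import (
    CohortConfig,
    InputError,
    associate,
    associate_all,
    interaction_model,
    longitudinal_onset,
    partial_spearman_matrix,
    simulate_cohort,
)
from omiclocks.config import DETERMINANTS, LAYERS


class TestAssociate:
    def test_outcome_equals_determinant(self, rng):
        x = rng.normal(size=100)
        res = associate(x, x)
        assert abs(res.beta - 1.0) < 1e-10
        assert res.p < 1e-30

    def test_standardized_beta_worked_example(self):
        res = associate([1.0, 2.0, 3.0, 4.0], [1.0, 1.0, 2.0, 2.0])
        assert abs(res.beta - 0.8944) < 1e-4

    def test_beta_equals_pearson_without_covariates(self, rng):
        x = rng.normal(size=200)
        y = 0.3 * x + rng.normal(size=200)
        res = associate(y, x)
        assert abs(res.beta - np.corrcoef(y, x)[0, 1]) < 1e-10

    def test_orthogonal_covariate_leaves_beta_unchanged(self):
        # determinant orthogonal to a balanced binary covariate
        x = np.array([1.0, -1.0, 1.0, -1.0, 2.0, -2.0, 2.0, -2.0])
        cov = np.array([0.0, 0.0, 1.0, 1.0, 0.0, 0.0, 1.0, 1.0])
        y = np.array([1.0, -0.5, 0.8, -1.2, 2.1, -1.9, 1.7, -2.3])
        assert abs(x @ cov - x.sum() * cov.mean() * 1) < 1e-12  # orthogonality
        res_plain = associate(y, x)
        res_cov = associate(y, x, covariates=cov[:, None])
        assert abs(res_plain.beta - res_cov.beta) < 1e-10

    def test_frisch_waugh_identity(self, rng):
        # covariate-adjusted beta equals regression of residualized outcome
        # on residualized determinant
        n = 300
        c = rng.normal(size=(n, 2))
        x = c @ [0.5, -0.3] + rng.normal(size=n)
        y = 0.2 * x + c @ [0.7, 0.1] + rng.normal(size=n)
        res = associate(y, x, covariates=c)

        def _resid(v):
            Z = np.column_stack([np.ones(n), c])
            return v - Z @ np.linalg.lstsq(Z, v, rcond=None)[0]

        xz = (x - x.mean()) / x.std(ddof=1)
        yz = (y - y.mean()) / y.std(ddof=1)
        rx, ry = _resid(xz), _resid(yz)
        beta_fw = (rx @ ry) / (rx @ rx)
        assert abs(res.beta - beta_fw) < 1e-8

    def test_complete_case_filtering(self, rng):
        y = rng.normal(size=50)
        x = rng.normal(size=50)
        y[:5] = np.nan
        res = associate(y, x)
        assert res.n == 45

    def test_constant_determinant_rejected(self, rng):
        with pytest.raises(InputError):
            associate(rng.normal(size=10), np.ones(10))


@pytest.fixture(scope="module")
def cohort_indicators():
    cohort, truth = simulate_cohort(CohortConfig(n=500), seed=50)
    table = truth.deviations.copy()
    table["composite_sum"] = table.sum(axis=1)
    table["composite_pc1"] = table.mean(axis=1)
    return cohort, table


class TestAssociateAll:

    def test_full_grid_shape(self, cohort_indicators):
        cohort, table = cohort_indicators
        out = associate_all(table, cohort)
        assert len(out) == len(DETERMINANTS) * 7  # 21 x 7 = 147
        assert list(out["determinant"].unique()) == list(DETERMINANTS)

    def test_deterministic(self, cohort_indicators):
        cohort, table = cohort_indicators
        out1 = associate_all(table, cohort)
        out2 = associate_all(table, cohort)
        pd.testing.assert_frame_equal(out1, out2)

    def test_type_one_error_calibration_under_global_null(self):
        cohort, truth = simulate_cohort(
            CohortConfig(n=2000, determinant_effects={}, shared_loadings={}),
            seed=51,
        )
        out = associate_all(truth.deviations, cohort)
        assert abs((out["p"] < 0.05).mean() - 0.05) < 0.03

    def test_planted_effect_recovered(self):
        cfg = CohortConfig(
            n=4000,
            determinant_effects={"bmi": {layer: 0.2 for layer in LAYERS}},
            shared_loadings={},
        )
        cohort, truth = simulate_cohort(cfg, seed=52)
        out = associate_all(truth.deviations, cohort)
        bmi = out[(out["determinant"] == "bmi")]
        assert np.allclose(bmi["beta"], 0.2, atol=0.05)

    def test_sex_covariate_rule(self):
        # when sex is the determinant the model must not also adjust for sex:
        # the reported beta then equals the plain correlation (sex as outcome)
        cohort, truth = simulate_cohort(CohortConfig(n=800), seed=53)
        ind = truth.deviations[["epigenetic"]]
        out = associate_all(ind, cohort, determinants=["sex"])
        sex = cohort["sex"].to_numpy(dtype=float)
        expected = np.corrcoef(sex, ind["epigenetic"])[0, 1]
        assert abs(out["beta"].iloc[0] - expected) < 1e-10

    def test_telomere_models_adjust_for_age(self):
        cohort, truth = simulate_cohort(CohortConfig(n=800), seed=54)
        # an age-correlated telomere indicator: adjusting for age must change
        # the estimate relative to the unadjusted fit
        ind = pd.DataFrame(
            {"telomere": truth.deviations["telomere"] + 0.05 * cohort["age"]},
            index=cohort.index,
        )
        with_rule = associate_all(ind, cohort, determinants=["bmi"])
        plain = associate(
            ind["telomere"], cohort["bmi"], covariates=cohort[["sex"]]
        )
        assert abs(with_rule["beta"].iloc[0] - plain.beta) > 1e-8

    def test_empty_panel_rejected(self, cohort_indicators):
        cohort, table = cohort_indicators
        with pytest.raises(InputError):
            associate_all(table, cohort, determinants=[])


class TestPartialSpearman:
    def test_self_correlation_is_one(self, null_cohort):
        cohort, truth = null_cohort
        corr, _ = partial_spearman_matrix(truth.deviations, cohort["sex"])
        assert np.allclose(np.diag(corr), 1.0)

    def test_symmetry(self, null_cohort):
        cohort, truth = null_cohort
        corr, _ = partial_spearman_matrix(truth.deviations, cohort["sex"])
        assert np.allclose(corr, corr.T, atol=1e-12)

    def test_constant_sex_reduces_to_plain_spearman(self):
        ind = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [3.0, 1.0, 2.0]})
        corr, _ = partial_spearman_matrix(ind, np.zeros(3), min_overlap=3)
        assert abs(corr.loc["a", "b"] - (-0.5)) < 1e-10

    def test_matches_pingouin_partial_correlation(self, null_cohort):
        # independent oracle: pingouin's rank-based partial correlation
        import pingouin as pg

        cohort, truth = null_cohort
        corr, _ = partial_spearman_matrix(truth.deviations, cohort["sex"])
        df = truth.deviations.copy()
        df["sex"] = cohort["sex"].astype(float)
        for a, b in [("telomere", "epigenetic"), ("proteomic", "metabolomic")]:
            expected = pg.partial_corr(
                df, x=a, y=b, covar="sex", method="spearman"
            )["r"].iloc[0]
            assert abs(corr.loc[a, b] - expected) < 1e-6

    def test_planted_cross_layer_correlation_recovered(self):
        s = np.sqrt(0.19)
        cfg = CohortConfig(
            n=5000,
            determinant_effects={},
            shared_loadings={"proteomic": s, "metabolomic": s},
        )
        cohort, truth = simulate_cohort(cfg, seed=55)
        corr, pval = partial_spearman_matrix(truth.deviations, cohort["sex"])
        assert 0.14 <= corr.loc["proteomic", "metabolomic"] <= 0.24
        assert pval.loc["proteomic", "metabolomic"] < 1e-10

    def test_sparse_pair_set_missing_with_warning(self, rng):
        ind = pd.DataFrame({"a": rng.normal(size=20), "b": rng.normal(size=20)})
        ind.loc[ind.index[5:], "b"] = np.nan
        with pytest.warns(UserWarning, match="complete subjects"):
            corr, _ = partial_spearman_matrix(ind, np.zeros(20), min_overlap=10)
        assert np.isnan(corr.loc["a", "b"])


class TestInteractionModel:
    def test_no_planted_interaction_gives_small_beta(self):
        cohort, truth = simulate_cohort(
            CohortConfig(n=2000, determinant_effects={}, shared_loadings={}),
            seed=56,
        )
        res = interaction_model(
            truth.deviations["proteomic"], cohort["bmi"], cohort["mdd_current"],
            cohort, indicator_name="proteomic", determinant_name="bmi",
        )
        # null interaction: keep within 3 SE of zero
        assert abs(res.beta) < 3 * res.se
        assert res.variant == "interaction"

    def test_subgroup_only_effect_detected(self):
        # effect b=0.3 only within the moderator=1 subgroup
        hits = 0
        for rep in range(20):
            rng = np.random.default_rng(600 + rep)
            cohort, truth = simulate_cohort(
                CohortConfig(n=2000, determinant_effects={}, shared_loadings={}),
                seed=600 + rep,
            )
            x = cohort["bmi"].to_numpy()
            xz = (x - x.mean()) / x.std(ddof=1)
            m = cohort["mdd_current"].to_numpy()
            y = 0.3 * xz * m + rng.normal(size=len(cohort))
            res = interaction_model(
                y, x, m, cohort, indicator_name="proteomic", determinant_name="bmi"
            )
            if res.beta > 0 and res.p < 0.05:
                hits += 1
        assert hits >= 18

    def test_constant_moderator_rejected(self, rng):
        cohort, truth = simulate_cohort(CohortConfig(n=100), seed=57)
        with pytest.raises(InputError):
            interaction_model(
                truth.deviations["proteomic"], cohort["bmi"], np.ones(100), cohort
            )


class TestLongitudinalOnset:
    def test_no_events_rejected(self, rng):
        with pytest.raises(InputError, match="no events"):
            longitudinal_onset(rng.normal(size=50), np.zeros(50), np.zeros(50))

    def test_independent_indicator_gives_null_beta(self, rng):
        n = 3000
        outcome = rng.binomial(1, 0.1, n)
        res = longitudinal_onset(
            rng.normal(size=n), outcome, rng.binomial(1, 0.66, n)
        )
        assert abs(res.beta) < 0.03
        assert res.variant == "longitudinal"

    def test_planted_risk_effect_detected(self):
        from omiclocks import FollowupConfig, simulate_followup

        cohort, truth = simulate_cohort(
            CohortConfig(n=4000, determinant_effects={}, shared_loadings={}),
            seed=58,
        )
        params = FollowupConfig(
            mortality_rate=0.15,
            age_logodds=0.0,
            deviation_logodds={"proteomic": 1.0},
        )
        out = simulate_followup(cohort, truth, params, seed=58)
        res = longitudinal_onset(
            truth.deviations["proteomic"], out["mortality_6y"], out["sex"],
            indicator_name="proteomic", outcome_name="mortality_6y",
        )
        assert res.beta > 0
        assert res.p < 1e-6
        assert res.beta_std is not None and res.beta_std > 0
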