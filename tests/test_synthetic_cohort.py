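"""Generator behaviour: determinism, planted structure, censoring, outcomes."""

import math

import numpy as np
import pandas as pd
import pytest

from omiclocks import (
    CohortConfig,
    ConfigurationError,
    FollowupConfig,
    InputError,
    LayerSimConfig,
    TelomereConfig,
    simulate_cohort,
    simulate_followup,
    simulate_omics_layer,
    simulate_telomere,
)
from omiclocks.cohort import validate_cohort
from omiclocks.config import DISEASE_CATEGORIES, LAYERS


class TestSimulateCohort:
    def test_null_model_has_no_determinant_deviation_correlation(self):
        cohort, truth = simulate_cohort(
            CohortConfig(n=1000, determinant_effects={}, shared_loadings={}), seed=1
        )
        for det in ("bmi", "smoking", "sex", "depression_severity"):
            for layer in LAYERS:
                r = np.corrcoef(cohort[det], truth.deviations[layer])[0, 1]
                assert abs(r) < 0.1

    def test_seeded_determinism(self):
        cfg = CohortConfig(n=200)
        c1, t1 = simulate_cohort(cfg, seed=5)
        c2, t2 = simulate_cohort(cfg, seed=5)
        pd.testing.assert_frame_equal(c1, c2)
        pd.testing.assert_frame_equal(t1.deviations, t2.deviations)

    def test_planted_cross_layer_correlation_recovered(self):
        # shared-factor loadings sqrt(0.15) on two layers plant cor = 0.15
        s = math.sqrt(0.15)
        cfg = CohortConfig(
            n=5000,
            determinant_effects={},
            shared_loadings={"proteomic": s, "metabolomic": s},
        )
        _, truth = simulate_cohort(cfg, seed=2)
        r = truth.deviations["proteomic"].corr(truth.deviations["metabolomic"])
        assert abs(r - 0.15) < 0.04

    def test_deviations_have_unit_variance(self):
        _, truth = simulate_cohort(CohortConfig(n=4000), seed=3)
        assert np.allclose(truth.deviations.var(ddof=1), 1.0, atol=0.1)

    def test_sex_marginal(self):
        cohort, _ = simulate_cohort(CohortConfig(n=5000), seed=4)
        assert abs(cohort["sex"].mean() - 0.66) < 0.03

    def test_unknown_determinant_rejected(self):
        cfg = CohortConfig(determinant_effects={"shoe_size": {"telomere": 0.1}})
        with pytest.raises(ConfigurationError, match="shoe_size"):
            simulate_cohort(cfg, seed=0)

    def test_tiny_cohort_rejected(self):
        with pytest.raises(InputError):
            simulate_cohort(CohortConfig(n=5), seed=0)

    def test_validate_cohort_passes_on_generated_table(self):
        cohort, truth = simulate_cohort(CohortConfig(n=100), seed=6)
        cohort = simulate_followup(cohort, truth, seed=6)
        validate_cohort(cohort, require_followup=True)


class TestSimulateOmicsLayer:
    def test_pure_noise_layer_uncorrelated_with_age(self):
        cohort, truth = simulate_cohort(
            CohortConfig(n=1000, determinant_effects={}, shared_loadings={}), seed=7
        )
        cfg = LayerSimConfig(
            name="metabolomic", n_markers=50, n_informative=0, target_r2=0.0,
            n_batches=1, batch_sd=0.0, n_labs=1,
        )
        layer = simulate_omics_layer(cohort, truth, cfg, seed=7)
        age = cohort["age"].to_numpy()
        for j in range(50):
            assert abs(np.corrcoef(layer.values.iloc[:, j], age)[0, 1]) < 0.1

    def test_noiseless_single_marker_is_affine_in_biological_age(self):
        cohort, truth = simulate_cohort(CohortConfig(n=100), seed=8)
        cfg = LayerSimConfig(
            name="proteomic", n_markers=1, n_informative=1, target_r2=0.9,
            noise_sd=0.0, n_batches=1, batch_sd=0.0, n_labs=1,
        )
        layer = simulate_omics_layer(cohort, truth, cfg, seed=8)
        b = truth.biological_age(cohort, "proteomic")
        r = np.corrcoef(layer.values.iloc[:, 0], b)[0, 1]
        assert abs(abs(r) - 1.0) < 1e-12

    def test_oracle_regression_attains_target_r2(self):
        # closed-form least squares on the planted informative set should
        # reach cor = sqrt(R2) = 0.7 against biological age
        cohort, truth = simulate_cohort(
            CohortConfig(n=2000, determinant_effects={}, shared_loadings={}), seed=9
        )
        cfg = LayerSimConfig(
            name="epigenetic", n_markers=400, n_informative=100, target_r2=0.49,
            n_batches=1, batch_sd=0.0, n_labs=1,
        )
        layer = simulate_omics_layer(cohort, truth, cfg, seed=9)
        b = truth.biological_age(cohort, "epigenetic").to_numpy()
        X = np.column_stack(
            [np.ones(len(b)), layer.values.iloc[:, :100].to_numpy()]
        )
        coef, *_ = np.linalg.lstsq(X, b, rcond=None)
        fitted = X @ coef
        assert abs(np.corrcoef(fitted, b)[0, 1] - 0.7) < 0.05

    def test_batch_offsets_recorded_and_applied(self):
        cohort, truth = simulate_cohort(CohortConfig(n=400), seed=10)
        cfg = LayerSimConfig(
            name="transcriptomic", n_markers=20, n_informative=0, target_r2=0.0,
            n_batches=3, batch_sd=5.0, n_labs=1,
        )
        layer = simulate_omics_layer(cohort, truth, cfg, seed=10)
        offsets = truth.batch_offsets["transcriptomic"]
        assert offsets.shape == (3, 20)
        # strong batch offsets should dominate marker means per batch
        g = layer.values.groupby(layer.batch).mean()
        spread = g.max() - g.min()
        assert (spread > 1.0).mean() > 0.8

    def test_censoring_conservation(self):
        # same seed with and without censoring: masked entries are exactly
        # the entries beyond the recorded detection limits
        cohort, truth = simulate_cohort(CohortConfig(n=300), seed=11)
        base = dict(
            name="proteomic", n_markers=40, n_informative=10, target_r2=0.5,
            n_batches=2, batch_sd=0.3, n_labs=1,
        )
        open_layer = simulate_omics_layer(
            cohort, truth, LayerSimConfig(**base), seed=11
        )
        cens = simulate_omics_layer(
            cohort, truth,
            LayerSimConfig(**base, censor_mode="limit", censor_frac=0.05),
            seed=11,
        )
        below = open_layer.values.lt(cens.lower_limits, axis=1)
        assert cens.mask.to_numpy().sum() == below.to_numpy().sum()
        assert (cens.mask == below).all().all()

    def test_invalid_configs_rejected(self):
        cohort, truth = simulate_cohort(CohortConfig(n=50), seed=12)
        with pytest.raises(InputError):
            simulate_omics_layer(
                cohort, truth,
                LayerSimConfig(name="epigenetic", n_markers=5, n_informative=10),
                seed=0,
            )
        with pytest.raises(InputError):
            simulate_omics_layer(
                cohort, truth,
                LayerSimConfig(name="epigenetic", n_markers=5, target_r2=1.0),
                seed=0,
            )


class TestSimulateTelomere:
    def test_calibrated_age_correlation(self):
        cohort, truth = simulate_cohort(
            CohortConfig(n=3000, determinant_effects={}, shared_loadings={}), seed=13
        )
        layer = simulate_telomere(cohort, truth, TelomereConfig(), seed=13)
        ts = layer.values["TS_ratio"].to_numpy()
        age = cohort.loc[layer.subjects, "age"].to_numpy()
        r = np.corrcoef(-ts, age)[0, 1]
        assert 0.25 <= r <= 0.35

    def test_huge_noise_kills_the_correlation(self):
        cohort, truth = simulate_cohort(CohortConfig(n=1000), seed=14)
        layer = simulate_telomere(
            cohort, truth, TelomereConfig(noise_sd=1e3), seed=14
        )
        r = np.corrcoef(-layer.values["TS_ratio"], cohort["age"])[0, 1]
        assert abs(r) < 0.1

    def test_deterministic_decline_without_noise(self):
        cohort, truth = simulate_cohort(CohortConfig(n=200), seed=15)
        layer = simulate_telomere(
            cohort, truth,
            TelomereConfig(noise_sd=0.0, deviation_loading=0.0),
            seed=15,
        )
        r = np.corrcoef(-layer.values["TS_ratio"], cohort["age"])[0, 1]
        assert r > 1 - 1e-12

    def test_positive_slope_rejected(self):
        cohort, truth = simulate_cohort(CohortConfig(n=50), seed=16)
        with pytest.raises(ConfigurationError):
            simulate_telomere(cohort, truth, TelomereConfig(age_slope=0.01), seed=0)


class TestSimulateFollowup:
    def test_zero_rate_zero_effects_gives_no_events(self):
        cohort, truth = simulate_cohort(CohortConfig(n=300), seed=17)
        params = FollowupConfig(
            mortality_rate=0.0,
            onset_rates={c: 0.0 for c in DISEASE_CATEGORIES},
            age_logodds=0.0,
            onset_age_logodds=0.0,
            deviation_logodds={},
        )
        out = simulate_followup(cohort, truth, params, seed=17)
        assert out["mortality_6y"].sum() == 0
        for c in DISEASE_CATEGORIES:
            assert out[f"onset_{c}_6y"].sum() == 0

    def test_certain_onset_only_among_baseline_negative(self):
        cohort, truth = simulate_cohort(CohortConfig(n=300), seed=18)
        params = FollowupConfig(
            onset_rates={c: 1.0 for c in DISEASE_CATEGORIES},
            deviation_logodds={},
        )
        out = simulate_followup(cohort, truth, params, seed=18)
        for c in DISEASE_CATEGORIES:
            onset = out[f"onset_{c}_6y"]
            assert (onset[out[c] == 0] == 1).all()
            assert (onset[out[c] == 1] == 0).all()

    def test_onset_rate_matches_binomial_sampling(self):
        cohort, truth = simulate_cohort(
            CohortConfig(n=5000, determinant_effects={}, shared_loadings={}), seed=19
        )
        params = FollowupConfig(
            mortality_rate=0.1,
            onset_rates={c: 0.1 for c in DISEASE_CATEGORIES},
            age_logodds=0.0,
            onset_age_logodds=0.0,
            deviation_logodds={},
        )
        out = simulate_followup(cohort, truth, params, seed=19)
        assert abs(out["mortality_6y"].mean() - 0.1) < 0.02
        eligible = out["cardiometabolic"] == 0
        assert abs(out.loc[eligible, "onset_cardiometabolic_6y"].mean() - 0.1) < 0.02

    def test_invalid_rate_rejected(self):
        cohort, truth = simulate_cohort(CohortConfig(n=50), seed=20)
        with pytest.raises(InputError):
            simulate_followup(
                cohort, truth, FollowupConfig(mortality_rate=1.5), seed=0
            )
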